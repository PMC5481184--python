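"""Exception hierarchy shared by all phrenoscope modules."""


class PhrenoscopeError(ValueError):
    """Base class for all domain errors raised by this package."""


# --- morphometry ---
class EmptyMask(PhrenoscopeError):
    """A binary mask contains no foreground pixels."""


class DegenerateShape(PhrenoscopeError):
    """A shape has no meaningful major axis (major/minor ratio <= 1.2)."""


class NoPrimarySplit(PhrenoscopeError):
    """A nerve pattern does not split into exactly two primary branches."""


class ZeroDenominator(PhrenoscopeError):
    """A left-side value used as a ratio denominator is not positive."""


class InvalidTree(PhrenoscopeError):
    """The node/edge lists do not form a single tree rooted at the entry node."""


# --- outgrowth ---
class InvalidPolygon(PhrenoscopeError):
    """The explant border polygon is not simple or encloses no pixels."""


class NoDistalSignal(PhrenoscopeError):
    """The distal ring contains no labeled signal; the index is undefined."""


# --- lateralization ---
class MissingSide(PhrenoscopeError):
    """An embryo lacks a left or right sample (paired design broken)."""


class NonPositiveIntensity(PhrenoscopeError):
    """An intensity is negative; ratios are undefined."""


class MissingReference(PhrenoscopeError):
    """A qPCR sample lacks a reference-gene Ct value."""


# --- assay_quant ---
class EmptyROI(PhrenoscopeError):
    """A region of interest contains no pixels."""


class ZeroSurface(PhrenoscopeError):
    """One side has zero supra-threshold surface; log2 ratio is infinite."""

    def __init__(self, message, sentinel):
        super().__init__(message)
        #: signed infinity the ratio would take (not returned silently)
        self.sentinel = sentinel


class NoMarkerCells(PhrenoscopeError):
    """A side has no marker-positive cells; a fraction is undefined."""


class ZeroSum(PhrenoscopeError):
    """A blot replicate has left + right == 0 and cannot be normalized."""


# --- stats ---
class EmptySample(PhrenoscopeError):
    """A statistical test received an empty sample."""


class AllZeroDifferences(PhrenoscopeError):
    """All paired differences are zero; the signed-rank test is undefined."""


# --- synthgen ---
class InvalidParams(PhrenoscopeError):
    """Generator parameters violate their declared constraints."""
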