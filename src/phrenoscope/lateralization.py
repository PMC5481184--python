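"""Paired left/right transcript-lateralization filtering.

Expression profiles of left and right laser-captured motoneuron pools from a
few embryos (one L and one R sample per embryo) are screened for transcripts
enriched on one side.  The screen consumes already-normalised intensities
and present/absent detection calls (produced upstream by the array software;
never computed here) and applies three rules:

1. *expressed*: present in at least one sample of every embryo, and maximal
   normalised intensity over all samples at or above a floor (default 200);
2. *consistent*: the per-embryo log2(R/L) ratios all have the same sign
   (a ratio of exactly 0 in any embryo breaks consistency);
3. *strong*: the mean per-embryo log2 ratio strictly exceeds log2(fold)
   (fold 1.5 -> 0.5849) and at least ``min_embryos`` embryos individually
   exceed it in the consistent direction.

The module also provides annotation-category proportions of a lateralized
gene set and ddCt-style qPCR normalisation against a reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MissingReference, MissingSide, NonPositiveIntensity

__all__ = [
    "ExpressionMatrix",
    "LateralizedGeneSet",
    "log2_fold_threshold",
    "filter_expressed",
    "log2_lr_ratios",
    "detect_lateralized",
    "category_proportions",
    "qpcr_relative",
]


def log2_fold_threshold(fold: float = 1.5) -> float:
    """The fold-change threshold on the log2 scale (1.5-fold -> 0.5849)."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    return float(np.log2(fold))


@dataclass
class ExpressionMatrix:
    """Probes x samples of normalised intensities with calls and metadata.

    ``values`` and ``calls`` share index (probe ids) and columns (sample
    ids); ``calls`` holds booleans (True = present).  ``meta`` is indexed by
    sample id with columns ``embryo`` and ``side`` ("L"/"R").
    """

    values: pd.DataFrame
    calls: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.columns.equals(self.calls.columns) or not self.values.index.equals(
            self.calls.index
        ):
            raise ValueError("values and calls must share probes and samples")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise NonPositiveIntensity("intensities must be finite and >= 0")
        for embryo, group in self.meta.loc[list(self.values.columns)].groupby("embryo"):
            sides = sorted(group["side"])
            if sides != ["L", "R"]:
                raise MissingSide(
                    f"embryo {embryo!r} must have exactly one L and one R sample"
                )

    @property
    def embryos(self) -> list:
        return sorted(self.meta.loc[list(self.values.columns), "embryo"].unique())

    def sample_of(self, embryo, side: str) -> str:
        meta = self.meta.loc[list(self.values.columns)]
        sel = meta[(meta["embryo"] == embryo) & (meta["side"] == side)]
        return sel.index[0]

    def swapped_sides(self) -> "ExpressionMatrix":
        """The same dataset with every sample's side label flipped."""
        meta = self.meta.copy()
        meta["side"] = meta["side"].map({"L": "R", "R": "L"})
        return ExpressionMatrix(self.values, self.calls, meta)


@dataclass
class LateralizedGeneSet:
    left_enriched: list
    right_enriched: list
    log2_ratios: pd.DataFrame  # probes x embryos, log2(R/L)
    fold: float
    floor: float
    min_embryos: int

    def __post_init__(self):
        if set(self.left_enriched) & set(self.right_enriched):
            raise ValueError("left- and right-enriched lists must be disjoint")

    def to_frame(self) -> pd.DataFrame:
        """Gene-list table: probe, side, per-embryo log2 ratios, mean."""
        rows = []
        for side, probes in (("L", self.left_enriched), ("R", self.right_enriched)):
            for probe in probes:
                r = self.log2_ratios.loc[probe]
                rows.append(
                    {"probe": probe, "enriched_side": side, **r.to_dict(),
                     "mean_log2_rl": r.mean()}
                )
        return pd.DataFrame(rows)


def filter_expressed(matrix: ExpressionMatrix, floor: float = 200.0) -> list:
    """Probes present in >= 1 sample of every embryo with max intensity >= floor."""
    present_ok = pd.Series(True, index=matrix.values.index)
    for embryo in matrix.embryos:
        cols = [matrix.sample_of(embryo, "L"), matrix.sample_of(embryo, "R")]
        present_ok &= matrix.calls[cols].any(axis=1)
    intense_ok = matrix.values.max(axis=1) >= floor
    return list(matrix.values.index[present_ok & intense_ok])


def log2_lr_ratios(
    matrix: ExpressionMatrix,
    probes: Optional[Sequence] = None,
    zero_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-probe, per-embryo log2(R/L) ratios.

    Intensities below ``zero_floor`` are floored before taking logs so that
    absent-side zeros do not produce infinities.
    """
    if probes is None:
        probes = matrix.values.index
    values = matrix.values.loc[list(probes)]
    if (values.to_numpy() < 0).any():
        raise NonPositiveIntensity("negative intensity encountered")
    out = {}
    for embryo in matrix.embryos:
        left = values[matrix.sample_of(embryo, "L")].clip(lower=zero_floor)
        right = values[matrix.sample_of(embryo, "R")].clip(lower=zero_floor)
        out[embryo] = np.log2(right / left)
    return pd.DataFrame(out, index=values.index)


def detect_lateralized(
    matrix: ExpressionMatrix,
    fold: float = 1.5,
    min_embryos: int = 2,
    floor: float = 200.0,
    zero_floor: float = 1.0,
    probes: Optional[Sequence] = None,
) -> LateralizedGeneSet:
    """Left- and right-enriched transcripts from a paired L/R dataset.

    ``probes`` defaults to :func:`filter_expressed`.  A probe is
    right-enriched iff every embryo's log2(R/L) is > 0, their mean is
    strictly greater than log2(fold), and at least ``min_embryos`` embryos
    individually exceed log2(fold); left-enrichment is the mirror image.
    """
    if probes is None:
        probes = filter_expressed(matrix, floor=floor)
    ratios = log2_lr_ratios(matrix, probes=probes, zero_floor=zero_floor)
    # strict ">" with a tiny guard so data sitting exactly at the fold
    # threshold are never called on account of floating-point rounding
    thr = log2_fold_threshold(fold) + 1e-9
    arr = ratios.to_numpy()
    mean = arr.mean(axis=1)
    right = (arr > 0).all(axis=1) & (mean > thr) & ((arr > thr).sum(axis=1) >= min_embryos)
    left = (arr < 0).all(axis=1) & (-mean > thr) & ((-arr > thr).sum(axis=1) >= min_embryos)
    return LateralizedGeneSet(
        left_enriched=list(ratios.index[left]),
        right_enriched=list(ratios.index[right]),
        log2_ratios=ratios,
        fold=fold,
        floor=floor,
        min_embryos=min_embryos,
    )


def category_proportions(
    gene_set: LateralizedGeneSet,
    annotation: pd.DataFrame,
    probe_col: str = "probe",
    category_col: str = "category",
) -> pd.DataFrame:
    """Percentage of each annotation category among left/right-enriched probes.

    Probes missing from the annotation table are assigned ``"unannotated"``.
    Percentages sum to 100 per side.
    """
    lookup = annotation.set_index(probe_col)[category_col]
    rows = {}
    for side, probes in (("L", gene_set.left_enriched), ("R", gene_set.right_enriched)):
        cats = pd.Series(
            [lookup.get(p, "unannotated") for p in probes], dtype=object
        )
        if len(cats) == 0:
            rows[side] = pd.Series(dtype=float)
        else:
            rows[side] = cats.value_counts() / len(cats) * 100.0
    return pd.DataFrame(rows).fillna(0.0)


def qpcr_relative(
    ct_table: pd.DataFrame,
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
    embryo_col: str = "embryo",
    side_col: str = "side",
) -> pd.DataFrame:
    """Reference-normalised relative expression and per-embryo R/L ratios.

    Relative expression per sample is ``2**-(Ct_target - Ct_reference)``
    (normalisation to, e.g., GAPDH).  Returns one row per embryo with left
    and right relative expression and their R/L ratio.
    """
    df = ct_table.copy()
    if df[reference_col].isna().any() or not np.isfinite(df[reference_col]).all():
        raise MissingReference("every sample needs a finite reference Ct")
    if not np.isfinite(df[target_col]).all():
        raise ValueError("target Ct values must be finite")
    df["relative"] = 2.0 ** -(df[target_col] - df[reference_col])
    rows = []
    for embryo, group in df.groupby(embryo_col):
        sides = group.set_index(side_col)["relative"]
        if "L" not in sides.index or "R" not in sides.index:
            raise MissingSide(f"embryo {embryo!r} lacks an L or R sample")
        rows.append(
            {
                embryo_col: embryo,
                "left": float(sides["L"]),
                "right": float(sides["R"]),
                "rl_ratio": float(sides["R"] / sides["L"]),
            }
        )
    return pd.DataFrame(rows)
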