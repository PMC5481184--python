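"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's own algorithms: rank-test p-values by
literal enumeration of every arrangement, raster crossing counts by building
the counting band pixel-by-pixel and labeling connected components, and the
lateralization filter as a per-probe python loop.
"""

import itertools

import numpy as np
from scipy import ndimage
from scipy import stats as sps


def brute_force_mann_whitney_p(x, y, alternative):
    """Full enumeration over all C(n1+n2, n1) group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p_ge = np.mean(us >= u_obs - 1e-12)
    p_le = np.mean(us <= u_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def brute_force_signed_rank_p(d, alternative):
    """Full enumeration over all 2**n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def band_component_crossings(pattern, tangent, fraction=0.8, orders=(2, 3)):
    """1-pixel-band connected-component crossing count on a pattern raster.

    Builds the selection image from scratch with whole-image coordinate
    grids and labels it with 8-connectivity.
    """
    ras = pattern.raster
    entry = np.asarray(pattern.nodes[pattern.entry], dtype=float)
    tdir = np.asarray(tangent.direction, dtype=float)
    normal = np.array([-tdir[1], tdir[0]])
    offset = float(normal @ (np.asarray(tangent.point) - entry))
    if offset < 0:
        normal, offset = -normal, -offset
    c = fraction * offset
    t_vals = [
        float(tdir @ (np.asarray(pattern.nodes[n]) - entry))
        for path in pattern.primary_paths()
        for n in path
    ]
    span = (min(t_vals), max(t_vals))
    rows, cols = ras.mask.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    x = ras.origin[0] + cc * ras.scale
    y = ras.origin[1] + rr * ras.scale
    s = (x - entry[0]) * normal[0] + (y - entry[1]) * normal[1]
    t = (x - entry[0]) * tdir[0] + (y - entry[1]) * tdir[1]
    sel = (
        np.isin(ras.order_labels, list(orders))
        & (np.abs(s - c) <= ras.scale / 2)
        & (t >= span[0])
        & (t <= span[1])
    )
    _, n_components = ndimage.label(sel, structure=np.ones((3, 3)))
    return int(n_components), span


def loop_lateralized(values_by_probe, n_embryos=3, fold=1.5, floor=200.0,
                     min_embryos=2):
    """Per-probe loop re-implementation of the lateralization filter.

    ``values_by_probe`` maps probe -> [L1, R1, L2, R2, ...]; a value of 0 is
    treated as an absent call.
    """
    thr = np.log2(fold)
    left, right = [], []
    for probe, row in values_by_probe.items():
        present = all(row[2 * e] > 0 or row[2 * e + 1] > 0 for e in range(n_embryos))
        if not present or max(row) < floor:
            continue
        logr = [
            np.log2(max(row[2 * e + 1], 1.0) / max(row[2 * e], 1.0))
            for e in range(n_embryos)
        ]
        if all(r > 0 for r in logr) and np.mean(logr) > thr + 1e-9 and sum(
            r > thr + 1e-9 for r in logr
        ) >= min_embryos:
            right.append(probe)
        if all(r < 0 for r in logr) and -np.mean(logr) > thr + 1e-9 and sum(
            -r > thr + 1e-9 for r in logr
        ) >= min_embryos:
            left.append(probe)
    return left, right
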