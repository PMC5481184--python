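#!/usr/bin/env python
"""Effector-level assays: in situ surface ratios, zymography, western blots.

Quantifies the three downstream assays on synthetic data generated at the
published rates: punctate in situ hybridisation signal with more spots on
the right (cross-applied threshold, area-normalised surfaces), per-cell
gelatinase activity among marker-positive motoneurons, and paired left/right
band intensities across blot replicates with a planted R/L ratio.
Writes results/effector_assays.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phrenoscope import assay_quant as aq, stats as ps, synthgen

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
rng = np.random.default_rng(404)
rows = []


def spot_stack(n_spots, shape=(128, 128), n_planes=5, spot=2):
    stack = rng.uniform(0, 10, size=(n_planes, *shape))
    for _ in range(n_spots):
        r = int(rng.integers(0, shape[0] - spot))
        c = int(rng.integers(0, shape[1] - spot))
        stack[rng.integers(0, n_planes), r : r + spot, c : c + spot] += 500
    return stack


# --- quantitative in situ hybridisation: ~1.5x more signal on the right ---
roi = np.ones((128, 128), dtype=bool)
log2_ratios = []
for section in range(6):
    left = spot_stack(120)
    right = spot_stack(180)
    res = aq.rnascope_lr_ratio(left, roi, right, roi, reference="left")
    log2_ratios.append(res.log2_rl_ratio)
mean_l2, sem_l2 = ps.mean_sem(log2_ratios)
rows.append({
    "assay": "in_situ_surface", "quantity": "mean_log2_rl_ratio",
    "value": round(mean_l2, 2), "sem": round(sem_l2, 2), "n": len(log2_ratios),
    "p_value": None,
})

# --- in situ zymography at the published per-side activity rates ---
table, _ = synthgen.make_cell_assay(
    n_cells_per_side=800, p_active_left=0.234, p_active_right=0.379, seed=405
)
zym = aq.zymography_fraction(table)
rows.append({
    "assay": "zymography", "quantity": "left_percent_active",
    "value": round(zym.left_percent, 2), "sem": None, "n": zym.n_left, "p_value": None,
})
rows.append({
    "assay": "zymography", "quantity": "right_percent_active",
    "value": round(zym.right_percent, 2), "sem": None, "n": zym.n_right, "p_value": None,
})
rows.append({
    "assay": "zymography", "quantity": "rl_fold",
    "value": round(zym.rl_fold, 2), "sem": None,
    "n": zym.n_left + zym.n_right, "p_value": None,
})

# --- western blots: planted R/L ratio 1.22, sum-normalised replicates ---
reps, _ = synthgen.make_blot_replicates(n=5, true_ratio=1.22, noise_cv=0.08, seed=406)
normalized = aq.normalize_blot_pairs(reps)
ratios = [r.rl_ratio for r in normalized]
wsr = ps.wilcoxon_signed_rank(
    [r.right for r in normalized], [r.left for r in normalized],
    alternative="two-sided",
)
mean_ratio, sem_ratio = ps.mean_sem(ratios)
rows.append({
    "assay": "western_blot", "quantity": "mean_rl_ratio",
    "value": round(mean_ratio, 2), "sem": round(sem_ratio, 2),
    "n": len(ratios), "p_value": wsr.p_value,
})

out = pd.DataFrame(rows)
out.to_csv(OUT / "effector_assays.csv", index=False)
print(out.to_string(index=False))
print(
    "\nAll three effector assays report the planted rightward bias: more"
    "\nsupra-threshold in situ surface, a higher fraction of gelatinase-active"
    "\nmotoneurons, and a right-shifted blot ratio after sum normalisation."
)
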