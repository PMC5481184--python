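#!/usr/bin/env python
"""Ring-based outgrowth of simulated left and right spinal-cord explants.

Right cervical explants in culture grow more axonal surface and defasciculate
more than left ones.  This driver simulates both groups (right explants get
more fascicles, longer extent and width-adding bifurcations), quantifies each
image with the concentric-ring analysis, normalises areas to the left-group
mean (left = 100%), and tests the groups with the exact Mann-Whitney test.
Writes results/outgrowth_explants.csv and results/outgrowth_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phrenoscope import outgrowth as og, stats as ps, synthgen

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_PER_SIDE = 8
GROUPS = {
    "left": dict(n_fascicles=10, fascicle_width=9, split_fraction=0.2,
                 max_extent=150.0, split_at=0.25, conserve_width=True),
    "right": dict(n_fascicles=11, fascicle_width=9, split_fraction=0.8,
                  max_extent=185.0, split_at=0.25, conserve_width=False),
}
rng = np.random.default_rng(202)

rows = []
for side, kwargs in GROUPS.items():
    for i in range(N_PER_SIDE):
        varied = dict(
            kwargs,
            n_fascicles=int(kwargs["n_fascicles"] + rng.integers(-2, 3)),
            max_extent=float(kwargs["max_extent"] * rng.uniform(0.9, 1.1)),
        )
        mask, border, _ = synthgen.make_explant_image(
            seed=int(rng.integers(0, 2**31)), **varied
        )
        rec = og.quantify_explant(mask, border, side=side)
        rows.append({
            "side": side, "explant": i + 1, "total_area": rec.total_area,
            "max_distance": rec.max_distance,
            "defasciculation_index": rec.defasciculation_index,
        })

explants = pd.DataFrame(rows)
left_mean_area = explants.loc[explants.side == "left", "total_area"].mean()
explants["area_percent_of_left"] = 100.0 * explants.total_area / left_mean_area
explants.to_csv(OUT / "outgrowth_explants.csv", index=False)

summary_rows = []
for quantity in ("area_percent_of_left", "defasciculation_index"):
    left = explants.loc[explants.side == "left", quantity].to_numpy()
    right = explants.loc[explants.side == "right", quantity].to_numpy()
    mw = ps.mann_whitney(left, right, alternative="two-sided")
    lm, ls = ps.mean_sem(left)
    rm, rs = ps.mean_sem(right)
    summary_rows.append({
        "quantity": quantity,
        "left_mean": round(lm, 1), "left_sem": round(ls, 1),
        "right_mean": round(rm, 1), "right_sem": round(rs, 1),
        "mann_whitney_p": mw.p_value, "method": mw.method,
    })
summary = pd.DataFrame(summary_rows)
summary.to_csv(OUT / "outgrowth_summary.csv", index=False)
print(summary.to_string(index=False))
print(
    "\nRight explants occupy roughly twice the labeled surface of left ones"
    "\n(left normalised to 100%) and show a lower proximal/distal width ratio,"
    "\nthe signature of distal width-adding defasciculation."
)
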