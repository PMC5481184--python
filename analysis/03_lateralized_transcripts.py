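#!/usr/bin/env python
"""Paired L/R transcript screen on a simulated laser-capture microarray.

Simulates the study's array design — 3 embryos, one left and one right
laser-captured motoneuron sample each, ~20,000 probes with a planted
minority of lateralized transcripts — then runs the expression filter and
the lateralization screen, summarises annotation-category proportions of
the detected sets, and demonstrates the reference-normalised qPCR ratio.
Writes results/lateralized_genes.csv and results/lateralization_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phrenoscope import lateralization as lat, synthgen

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# planted design: 146 left- and 194 right-enriched transcripts (the sizes of
# the study's published gene lists) at 2-fold over log-normal noise
matrix, truth = synthgen.make_expression_dataset(
    n_probes=20_000, n_left_enriched=146, n_right_enriched=194,
    fold=2.0, noise_sigma_log2=0.1, n_embryos=3, seed=303,
)
expressed = lat.filter_expressed(matrix)
gene_set = lat.detect_lateralized(matrix)
gene_set.to_frame().to_csv(OUT / "lateralized_genes.csv", index=False)

planted_left = set(truth.derived["left_enriched"])
planted_right = set(truth.derived["right_enriched"])
tp = len(set(gene_set.left_enriched) & planted_left) + len(
    set(gene_set.right_enriched) & planted_right
)
fp = len(gene_set.left_enriched) + len(gene_set.right_enriched) - tp

# toy annotation: planted lateralized transcripts are biased toward nuclear
# proteins, as in the published gene lists
rng = np.random.default_rng(304)
cats = ["nucleus", "membrane", "cytoplasm", "extracellular"]
annotation = pd.DataFrame({
    "probe": list(matrix.values.index),
    "category": [
        rng.choice(cats, p=[0.35, 0.25, 0.3, 0.1])
        if p in planted_left | planted_right
        else rng.choice(cats, p=[0.2, 0.3, 0.35, 0.15])
        for p in matrix.values.index
    ],
})
proportions = lat.category_proportions(gene_set, annotation)

# qPCR confirmation of one right-enriched transcript (ddCt against GAPDH)
ct = pd.DataFrame({
    "embryo": ["e1", "e1", "e2", "e2", "e3", "e3"],
    "side": ["L", "R"] * 3,
    "ct_target": [27.3, 26.9, 27.8, 27.1, 26.9, 26.3],
    "ct_reference": [21.1, 21.0, 21.5, 21.4, 21.0, 21.0],
})
qpcr = lat.qpcr_relative(ct)

summary = pd.DataFrame([
    {"quantity": "probes_total", "value": len(matrix.values)},
    {"quantity": "probes_expressed", "value": len(expressed)},
    {"quantity": "left_enriched_detected", "value": len(gene_set.left_enriched)},
    {"quantity": "right_enriched_detected", "value": len(gene_set.right_enriched)},
    {"quantity": "planted_recovered_fraction", "value": round(tp / 340, 3)},
    {"quantity": "false_positives", "value": fp},
    {"quantity": "nucleus_percent_left", "value": round(proportions.loc["nucleus", "L"], 2)},
    {"quantity": "nucleus_percent_right", "value": round(proportions.loc["nucleus", "R"], 2)},
    {"quantity": "qpcr_mean_rl_ratio", "value": round(qpcr.rl_ratio.mean(), 2)},
])
summary.to_csv(OUT / "lateralization_summary.csv", index=False)
print(summary.to_string(index=False))
print(
    "\nThe screen recovers the planted lateralized minority with the strict"
    "\nsame-trend / >1.5-fold-average / >=2-embryos rule, and the qPCR ddCt"
    "\nratios confirm right-enrichment of the spot-checked transcript."
)
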