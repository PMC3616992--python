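#!/usr/bin/env python
"""Bik under apoptotic stress: accumulation hypothesis vs activation.

Two candidate explanations for how Bik triggers death after staurosporine:
(1) degradation stops and Bik accumulates -- the closed-form profile shows
only a doubling in six hours, too slow to matter, and measured Bik stays
flat, so the hypothesis is rejected; (2) Bik is activated by relocating
from ER to mitochondria -- synthetic single-cell colocalization fractions
(45% +/- 13% at 2 h, 30 cells) invert to a first-order relocation rate of
~0.005/min, the value used by the network model.

Outputs: results/bik_stress.json
"""

import json
from pathlib import Path

import numpy as np

from apoptosim.bik import PARENTAL_BIK, accumulation_profile
from apoptosim.network import estimate_kact
from apoptosim.synth import gen_colocalization

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

doubling = accumulation_profile(360.0, 50.0, PARENTAL_BIK.k_syn)
print("Accumulation hypothesis (degradation off, synthesis unchanged):")
print(f"  Bik after 6 h would be {doubling:.1f} nM from 50 nM -- a doubling,")
print("  far from a lethal surge; measured Bik is flat -> hypothesis rejected.")

fractions = gen_colocalization(n_cells=30, mean=0.45, sd=0.13, seed=7)
k_point = estimate_kact(0.45, 120.0)
k_sample = estimate_kact(float(fractions.mean()), 120.0)
reps = [estimate_kact(float(gen_colocalization(30, seed=s).mean()), 120.0)
        for s in range(100)]

print("\nActivation-by-relocation estimate:")
print(f"  point estimate  k_act = {k_point:.5f} /min (from the 45% fraction)")
print(f"  sample of 30 cells    = {k_sample:.5f} /min (mean fraction {fractions.mean():.3f})")
print(f"  median over 100 replicates = {np.median(reps):.5f} /min")

json.dump({
    "accumulation_six_hours_nM": doubling,
    "k_act_point": k_point,
    "k_act_sample": k_sample,
    "k_act_median_100_reps": float(np.median(reps)),
    "colocalization_mean": float(fractions.mean()),
    "colocalization_sd": float(fractions.std(ddof=1)),
}, open(OUT / "bik_stress.json", "w"), indent=2)
print(f"\nwrote {OUT / 'bik_stress.json'}")
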