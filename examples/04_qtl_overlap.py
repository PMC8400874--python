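"""Overlap decoded HBD segments with QTL-style feature intervals.

Builds a small feature set (0-based half-open BED convention), decodes
segments from a simulated individual, and reports which features each
segment hits and the per-category totals — the generic core of asking which
trait loci fall inside runs of autozygosity.
"""

import pandas as pd

import hbdhmm as h

import numpy as np

rates = h.default_model().rates
occ = np.append(np.full(9, 0.3 / 9), 0.7)  # 30% HBD mass: plenty of segments
truth_model = h.HBDModel(rates, h.mixing_for_occupancy(occ, rates), eps=0.001)
cfg = h.SimConfig(n_chrom=2, markers_per_chrom=500, model=truth_model,
                  n_individuals=1, seed=3)
panel, truth = h.simulate_panel(cfg)
# one individual cannot estimate its own allele frequencies; use the
# generator's true ones (a real analysis pools frequencies across the panel)
freqs = truth.freqs
model = h.default_model(eps=0.001)
fitted, dec = h.em_fit(panel.G[0], freqs, panel.markers, model)
path = h.viterbi(panel.G[0], freqs, panel.markers, fitted)
segs = h.path_to_segments(path, panel.markers, fitted, "sim_001", "SIM")
print(f"decoded {len(segs)} HBD segments (F = {dec.F:.3f})")

features = h.FeatureSet(pd.DataFrame([
    ("1", 0, 8_000_000, "QTL_litter_size", "Reproduction"),
    ("1", 20_000_000, 30_000_000, "QTL_backfat", "Meat and Carcass"),
    ("2", 5_000_000, 15_000_000, "QTL_growth", "Production"),
    ("2", 40_000_000, 45_000_000, "QTL_leg_conf", "Exterior"),
], columns=["chrom", "start", "end", "name", "category"]))

res = h.overlap(segs, features)
print(f"features overlapped by any segment: {res.n_features_overlapped}")
print("\nper category (n_hits = features touched by >=1 segment):")
print(res.per_category.to_string(index=False))
for seg, ids in zip(segs, res.per_segment):
    if ids:
        names = ", ".join(features.intervals["name"][i] for i in ids)
        print(f"segment {seg.chrom}:{seg.start_bp}-{seg.end_bp} "
              f"(R={seg.class_rate:g}) overlaps {names}")
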