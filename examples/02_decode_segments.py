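"""Viterbi-decode HBD segments and build the group summary tables.

Simulates two small 'breeds' with different autozygosity levels, decodes each
individual's most likely HBD/non-HBD path, converts runs into segment
records, and prints the per-class segment table and the inbreeding
five-number summary (the layout used to compare breeds).
"""

import numpy as np

import hbdhmm as h

rates = h.default_model().rates
panels = {}
for group, total_hbd, seed in [("HI", 0.30, 1), ("LO", 0.10, 2)]:
    occ = np.append(np.full(9, total_hbd / 9), 1 - total_hbd)
    model = h.HBDModel(rates, h.mixing_for_occupancy(occ, rates), eps=0.001)
    cfg = h.SimConfig(n_chrom=4, markers_per_chrom=600, model=model,
                      n_individuals=4, seed=seed, group=group)
    panels[group] = h.simulate_panel(cfg)

model = h.default_model(eps=0.001)
segments, F, groups = [], {}, {}
for group, (panel, truth) in panels.items():
    freqs = h.allele_frequencies(panel)
    for i, sid in enumerate(panel.sample_ids):
        sid = f"{group}_{sid}"
        fitted, dec = h.em_fit(panel.G[i], freqs, panel.markers, model)
        path = h.viterbi(panel.G[i], freqs, panel.markers, fitted)
        segments += h.path_to_segments(path, panel.markers, fitted, sid, group)
        F[sid], groups[sid] = dec.F, group

print("inbreeding coefficient by group (five-number summary + mean):")
print(h.inbreeding_table(F, groups).to_string(index=False,
                                              float_format="%.3f"))
summ = h.summarize(segments, groups)
print("\nHBD segments per class (count, mean length in Mb +/- SE):")
print(summ.per_class.to_string(index=False, float_format="%.3f"))
print("\nper-group totals:")
print(summ.per_group.to_string(index=False, float_format="%.2f"))
print("\nThe 'HI' group was simulated with 3x the HBD genome share of 'LO'; "
      "its higher F and segment counts show the decoding separating the two.")
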