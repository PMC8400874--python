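"""Simulate a pig-like SNP panel and recover each individual's inbreeding.

Draws 6 individuals from the default truth model (total autozygosity ~0.23,
dominated by the R=128 class), EM-fits the HBD-class mixing proportions per
individual, and compares the fitted inbreeding coefficient F with the
simulated truth.
"""

import numpy as np

import hbdhmm as h

cfg = h.SimConfig(n_chrom=5, markers_per_chrom=800, n_individuals=6, seed=11)
panel, truth = h.simulate_panel(cfg)
freqs = h.allele_frequencies(panel)

print(f"panel: {panel.n_samples} individuals x {panel.n_markers} markers "
      f"({cfg.n_chrom} chromosomes)")
print(f"{'sample':>8} {'true F':>8} {'fitted F':>9} {'EM iters':>9}")
errs = []
for i, sid in enumerate(panel.sample_ids):
    fitted, dec = h.em_fit(panel.G[i], freqs, panel.markers, cfg.model)
    errs.append(abs(dec.F - truth.F[i]))
    print(f"{sid:>8} {truth.F[i]:8.3f} {dec.F:9.3f} {dec.n_iter:9d}")
print(f"\nmean |fitted - true| F: {np.mean(errs):.4f}")
print("F is the genome fraction in any HBD class = 1 - Pr(non-HBD). Fitted F "
      "tracks the truth, with the mild downward shrinkage expected at this "
      "marker density: very short segments of the oldest classes are hard "
      "to distinguish from chance homozygosity.")
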