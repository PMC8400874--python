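import numpy as np
import pytest

from hbdhmm import GenotypePanel, HBDModel, MarkerMap
from hbdhmm.io import MISSING


def make_map(bp_per_chrom, cm_per_mb=1.0, alleles=None):
    """Marker map from {chrom: [bp, ...]}; gpos at the given constant rate."""
    chroms, bps, gpos, ids, a1, a2 = [], [], [], [], [], []
    k = 0
    for chrom, bps_c in bp_per_chrom.items():
        for bp in bps_c:
            chroms.append(str(chrom))
            bps.append(bp)
            gpos.append(bp * cm_per_mb / 1e8)
            ids.append(f"m{k}")
            ca, oa = (alleles[k] if alleles else ("A", "G"))
            a1.append(ca)
            a2.append(oa)
            k += 1
    return MarkerMap(np.array(chroms, dtype=object), np.array(bps),
                     np.array(gpos), np.array(ids, dtype=object),
                     np.array(a1, dtype=object), np.array(a2, dtype=object))


@pytest.fixture
def small_panel():
    """3 samples x 4 markers over 2 chromosomes, with one missing call."""
    mmap = make_map({"1": [1_000_000, 2_500_000], "2": [500_000, 900_000]})
    G = np.array([[0, 1, 2, 1],
                  [2, 2, MISSING, 0],
                  [1, 0, 1, 2]], dtype=np.int8)
    return GenotypePanel(mmap, ["s1", "s2", "s3"], G, ["LW", "LW", "LR"])


@pytest.fixture
def three_state_model():
    return HBDModel(np.array([4.0, 32.0, 32.0]),
                    np.array([0.25, 0.25, 0.5]), eps=0.01)


def random_panel(rng, n_samples, n_markers, missing_rate=0.0, n_chrom=1):
    per = n_markers // n_chrom
    mmap = make_map({str(c + 1): [(j + 1) * 100_000 for j in range(per)]
                     for c in range(n_chrom)})
    G = rng.integers(0, 3, size=(n_samples, mmap.n_markers)).astype(np.int8)
    if missing_rate:
        G[rng.random(G.shape) < missing_rate] = MISSING
    return GenotypePanel(mmap, [f"s{i}" for i in range(n_samples)], G)
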