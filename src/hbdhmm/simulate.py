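"""Synthetic genotype panels drawn from the HBD-class generative model.

Latent state paths are sampled at marker resolution through the same
transition kernel the inference uses (segment survives a gap of ``d`` Morgans
with probability ``exp(-R d)``; on termination the new class is drawn from
the mixing proportions, possibly re-entering the same class as a fresh
segment). Genotypes then come from the class emission distributions. The
recorded truth — state path, segment-start flags, per-class occupancy and
true F — supports parameter-recovery and segment-length-law tests with an
exactly known data-generating process.

An outcross generator produces F1-like individuals by drawing one allele from
each of two independent allele-frequency pools, i.e. individuals with no
recent autozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .io import GenotypePanel, MarkerMap
from .model import HBDModel, default_model


def mixing_for_occupancy(occupancy: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Mixing proportions whose stationary state occupancy equals ``occupancy``.

    Segments of class c arise with probability m_c and last 1/R_c Morgans on
    average, so occupancy is proportional to m_c / R_c; inverting gives
    m_c proportional to occupancy_c * R_c.
    """
    occupancy = np.asarray(occupancy, dtype=np.float64)
    m = occupancy * np.asarray(rates, dtype=np.float64)
    return m / m.sum()


def pig_like_model(eps: float = 0.001) -> HBDModel:
    """Default simulation truth: a commercial-pig-like autozygosity profile.

    Total autozygosity ~0.23 (as seen in intensively selected purebred pig
    populations), dominated by the R=128 class (~64 generations back) with
    smaller recent contributions; non-HBD occupancy 0.77.
    """
    base = default_model(eps=eps)
    occ = np.array([0.005, 0.005, 0.01, 0.02, 0.03, 0.04, 0.08, 0.03, 0.01,
                    0.77])
    return HBDModel(base.rates, mixing_for_occupancy(occ, base.rates), eps)


@dataclass
class SimConfig:
    """Study design of a simulated panel.

    Markers are evenly spaced ``marker_spacing_morgans`` apart on each of
    ``n_chrom`` chromosomes; coded-allele frequencies are i.i.d. uniform on
    ``freq_bounds``. ``model`` is the generative truth. Physical positions
    follow the genetic ones at 1 Mb per cM.
    """

    n_chrom: int = 10
    markers_per_chrom: int = 1000
    marker_spacing_morgans: float = 0.001
    freq_bounds: tuple = (0.05, 0.95)
    model: HBDModel = field(default_factory=pig_like_model)
    n_individuals: int = 20
    seed: int = 0
    group: str = "SIM"

    def __post_init__(self):
        if self.marker_spacing_morgans <= 0:
            raise ValueError("marker spacing must be positive")
        lo, hi = self.freq_bounds
        if not (0 < lo <= hi < 1):
            raise ValueError("freq_bounds must lie inside (0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a simulated panel.

    ``states[i, t]`` is individual i's latent class at marker t;
    ``new_segment`` flags markers where a fresh segment starts (including
    resets back into the same class). ``occupancy`` are per-individual
    fractions of markers in each state; ``F[i] = 1 - occupancy[i, non-HBD]``.
    """

    states: np.ndarray
    new_segment: np.ndarray
    occupancy: np.ndarray
    F: np.ndarray
    freqs: np.ndarray
    chrom_ends: np.ndarray  # marker indices one past each chromosome's last

    def segment_lengths(self, spacing: float, state: int,
                        drop_censored: bool = True) -> np.ndarray:
        """Lengths (Morgans) of true segments of ``state``, as run-length times
        spacing, pooled over individuals.

        Runs cut short by a chromosome end are right-censored and are dropped
        by default so the empirical mean estimates the full segment-length
        law.
        """
        ends = set(int(e) for e in self.chrom_ends)
        out = []
        n_ind, T = self.states.shape
        for i in range(n_ind):
            starts = np.flatnonzero(self.new_segment[i])
            bounds = np.append(starts, T)
            for a, b in zip(bounds[:-1], bounds[1:]):
                if self.states[i, a] != state:
                    continue
                if drop_censored and int(b) in ends:
                    continue
                out.append((b - a) * spacing)
        return np.array(out)


def build_marker_map(n_chrom: int, markers_per_chrom: int,
                     spacing: float) -> MarkerMap:
    """Uniformly spaced multi-chromosome map; bp at 1 Mb per cM."""
    chroms, bps, gpos, ids = [], [], [], []
    for c in range(1, n_chrom + 1):
        g = np.arange(markers_per_chrom) * spacing
        chroms.extend([str(c)] * markers_per_chrom)
        gpos.extend(g)
        bps.extend((g * 1e8).astype(np.int64) + 1)
        ids.extend(f"snp{c}_{j}" for j in range(markers_per_chrom))
    n = len(ids)
    return MarkerMap(np.array(chroms, dtype=object), np.array(bps),
                     np.array(gpos), np.array(ids, dtype=object),
                     np.full(n, "A", dtype=object), np.full(n, "B", dtype=object))


def _sample_genotypes(states, p, model, rng):
    """Genotypes given a state path, via the class emission distributions."""
    T = len(states)
    is_hbd = states != model.non_hbd_state
    eps = model.eps
    # per-marker genotype cdf under the active class
    p0 = np.where(is_hbd, (1 - eps) * (1 - p) + eps * (1 - p) ** 2, (1 - p) ** 2)
    p1 = np.where(is_hbd, eps * 2 * p * (1 - p), 2 * p * (1 - p))
    u = rng.random(T)
    return ((u > p0).astype(np.int8) + (u > p0 + p1).astype(np.int8))


def simulate_panel(cfg: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Draw a panel and its latent truth; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    model = cfg.model
    mmap = build_marker_map(cfg.n_chrom, cfg.markers_per_chrom,
                            cfg.marker_spacing_morgans)
    T = mmap.n_markers
    p = rng.uniform(*cfg.freq_bounds, size=T)
    pterm = 1.0 - np.exp(-model.rates * cfg.marker_spacing_morgans)

    S = model.n_states
    states = np.empty((cfg.n_individuals, T), dtype=np.int64)
    new_seg = np.zeros((cfg.n_individuals, T), dtype=bool)
    G = np.empty((cfg.n_individuals, T), dtype=np.int8)
    occupancy = np.empty((cfg.n_individuals, S))
    for i in range(cfg.n_individuals):
        for _, sl in mmap.chrom_slices():
            n = sl.stop - sl.start
            st, ns = _kernels.sample_state_path(
                pterm, model.mixing, rng.random(n), rng.random(n))
            states[i, sl] = st
            new_seg[i, sl] = ns
        G[i] = _sample_genotypes(states[i], p, model, rng)
        occupancy[i] = np.bincount(states[i], minlength=S) / T
    truth = SimTruth(states=states, new_segment=new_seg, occupancy=occupancy,
                     F=1.0 - occupancy[:, model.non_hbd_state], freqs=p,
                     chrom_ends=np.array([sl.stop for _, sl in
                                          mmap.chrom_slices()]))
    ids = [f"sim_{i + 1:03d}" for i in range(cfg.n_individuals)]
    panel = GenotypePanel(mmap, ids, G, [cfg.group] * cfg.n_individuals)
    return panel, truth


def simulate_outcross(freqs_a: np.ndarray, freqs_b: np.ndarray,
                      n_individuals: int, seed: int,
                      markers: MarkerMap | None = None,
                      group: str = "F1") -> GenotypePanel:
    """F1-like individuals: one allele per parent pool, independent per marker.

    With no map given, markers fall on a single chromosome 0.001 Morgans
    apart.
    """
    freqs_a = np.asarray(freqs_a, dtype=np.float64)
    freqs_b = np.asarray(freqs_b, dtype=np.float64)
    if freqs_a.shape != freqs_b.shape:
        raise ValueError("frequency vectors must have equal length")
    T = len(freqs_a)
    if markers is None:
        markers = build_marker_map(1, T, 0.001)
    if markers.n_markers != T:
        raise ValueError("marker map length does not match frequency vectors")
    rng = np.random.default_rng(seed)
    a = rng.random((n_individuals, T)) < freqs_a
    b = rng.random((n_individuals, T)) < freqs_b
    G = (a.astype(np.int8) + b.astype(np.int8))
    ids = [f"f1_{i + 1:03d}" for i in range(n_individuals)]
    return GenotypePanel(markers, ids, G, [group] * n_individuals)


def write_truth_tsv(truth: SimTruth, panel: GenotypePanel, model: HBDModel,
                    path_prefix: str):
    """Truth tables: per-marker states and a per-individual summary."""
    labels = model.state_labels()
    with open(path_prefix + "_truth_states.tsv", "w") as fh:
        fh.write("sample_id\tmarker_id\tstate\tnew_segment\n")
        for i, sid in enumerate(panel.sample_ids):
            for j in range(panel.n_markers):
                fh.write(f"{sid}\t{panel.markers.marker_id[j]}\t"
                         f"{labels[truth.states[i, j]]}\t"
                         f"{int(truth.new_segment[i, j])}\n")
    with open(path_prefix + "_truth_summary.tsv", "w") as fh:
        fh.write("sample_id\ttrue_F\t" + "\t".join(labels) + "\n")
        for i, sid in enumerate(panel.sample_ids):
            occ = "\t".join(f"{x:.6g}" for x in truth.occupancy[i])
            fh.write(f"{sid}\t{truth.F[i]:.6g}\t{occ}\n")
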