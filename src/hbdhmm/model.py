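"""Multiple-class homozygosity-by-descent (HBD) hidden Markov model.

The genome of a diploid individual is modelled as an alternating sequence of
HBD and non-HBD segments. Each HBD class ``k`` has an exponential
segment-length distribution with rate ``R_k`` (expected length ``1/R_k``
Morgans); classes on a doubling ladder 2, 4, ..., 512 capture inbreeding
events of increasing age, with ``R_k / 2`` the approximate number of
generations back to the common ancestor. The non-HBD class shares the rate of
the oldest HBD class. Between two markers separated by ``d`` Morgans the
current segment survives with probability ``exp(-R_k * d)``; on termination a
new segment's class is drawn from the mixing proportions ``m``.

Emissions: inside an HBD segment both chromosome copies descend from one
ancestral copy, so a marker with coded-allele frequency ``p`` is homozygous
unless a genotyping error / mutation (probability ``eps``) intervenes;
outside HBD the genotype follows Hardy-Weinberg proportions.

Per individual the model yields posterior state probabilities (realized
autozygosity per class when genome-averaged), the inbreeding coefficient
``F = 1 - Pr(non-HBD)``, maximum-likelihood mixing proportions via EM, and a
Viterbi-decoded segment path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .io import MISSING, AlleleFrequencies, MarkerMap


@dataclass
class HBDModel:
    """Parameterization of the HBD-class HMM.

    ``rates[:-1]`` are the HBD class rates (non-decreasing, Morgans^-1);
    ``rates[-1]`` is the non-HBD rate. ``mixing`` lies on the simplex; ``eps``
    is the genotyping-error/mutation probability perturbing HBD emissions.
    """

    rates: np.ndarray
    mixing: np.ndarray
    eps: float = 0.001

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        if self.rates.ndim != 1 or len(self.rates) < 2:
            raise ValueError("need at least one HBD class plus the non-HBD class")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")
        if np.any(np.diff(self.rates[:-1]) < 0):
            raise ValueError("HBD class rates must be non-decreasing")
        if len(self.mixing) != len(self.rates):
            raise ValueError("mixing and rates length mismatch")
        if np.any(self.mixing < 0) or abs(self.mixing.sum() - 1.0) > 1e-12:
            raise ValueError("mixing must be a probability vector summing to 1")
        if not 0 <= self.eps < 0.5:
            raise ValueError("eps must lie in [0, 0.5)")

    @property
    def n_states(self) -> int:
        return len(self.rates)

    @property
    def n_hbd_classes(self) -> int:
        return len(self.rates) - 1

    @property
    def non_hbd_state(self) -> int:
        return len(self.rates) - 1

    def state_labels(self) -> list[str]:
        return [f"R_{r:g}" for r in self.rates[:-1]] + ["nonHBD"]


@dataclass
class Decoding:
    """Posterior decoding of one individual.

    ``gamma`` holds per-marker posterior state probabilities; ``realized`` is
    its genome average (realized autozygosity per class); ``F`` the inbreeding
    coefficient 1 - realized[non-HBD].
    """

    gamma: np.ndarray
    loglik: float
    realized: np.ndarray
    F: float
    viterbi_path: np.ndarray | None = None
    n_iter: int | None = None
    loglik_history: list | None = None


def default_model(n_classes: int = 10, eps: float = 0.001) -> HBDModel:
    """Standard model: HBD rates on the doubling ladder 2..2^(n_classes-1).

    With the default 10 states that is 9 HBD classes at rates
    (2, 4, 8, 16, 32, 64, 128, 256, 512) plus a non-HBD class sharing the
    oldest rate; mixing starts uniform.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    hbd = 2.0 ** np.arange(1, n_classes)
    rates = np.append(hbd, hbd[-1])
    mixing = np.full(n_classes, 1.0 / n_classes)
    return HBDModel(rates, mixing, eps)


def class_generation(rate: float) -> float:
    """Approximate number of generations to the class ancestor: rate / 2."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return rate / 2.0


def expected_segment_length(rate: float) -> float:
    """Expected HBD segment length in Morgans, 1/rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return 1.0 / rate


def inbreeding_from_nonhbd(non_hbd_proportion: float) -> float:
    """Inbreeding coefficient as 1 minus the non-HBD genome proportion."""
    if not 0 <= non_hbd_proportion <= 1:
        raise ValueError("proportion must lie in [0, 1]")
    return 1.0 - non_hbd_proportion


def _emission_components(g: int, p: float, eps: float) -> tuple[float, float]:
    """(HBD likelihood, non-HBD likelihood) of one genotype."""
    if g == MISSING:
        return 1.0, 1.0
    if g == 2:
        return (1 - eps) * p + eps * p * p, p * p
    if g == 1:
        return eps * 2 * p * (1 - p), 2 * p * (1 - p)
    if g == 0:
        return (1 - eps) * (1 - p) + eps * (1 - p) ** 2, (1 - p) ** 2
    raise ValueError(f"invalid genotype {g}")


def emission_probs(g: int, p: float, eps: float,
                   model: HBDModel | None = None) -> np.ndarray:
    """Per-state likelihood of genotype ``g`` at a marker with frequency ``p``.

    All HBD classes share one emission distribution; the last entry is the
    Hardy-Weinberg non-HBD likelihood. With no model given a 2-state
    (HBD, non-HBD) vector is returned.
    """
    if not 0 <= p <= 1:
        raise ValueError("allele frequency must lie in [0, 1]")
    hbd, non = _emission_components(g, p, eps)
    n_hbd = model.n_hbd_classes if model is not None else 1
    return np.append(np.full(n_hbd, hbd), non)


def emission_matrix(genotypes: np.ndarray, p: np.ndarray,
                    model: HBDModel) -> np.ndarray:
    """(T, S) emission likelihoods for one individual's genotype sequence."""
    genotypes = np.asarray(genotypes)
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    eps = model.eps
    hbd = np.ones_like(p)
    non = np.ones_like(p)
    for g in (0, 1, 2):
        mask = genotypes == g
        if mask.any():
            q = p[mask]
            hbd[mask] = [(1 - eps) * (1 - q) + eps * (1 - q) ** 2,
                         eps * 2 * q * (1 - q),
                         (1 - eps) * q + eps * q ** 2][g]
            non[mask] = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2][g]
    B = np.empty((len(p), model.n_states))
    B[:, :-1] = hbd[:, None]
    B[:, -1] = non
    return B


def transition_matrix(d: float, model: HBDModel) -> np.ndarray:
    """State-transition matrix across a gap of ``d`` Morgans.

    ``A[c, c'] = exp(-R_c d) [c = c'] + (1 - exp(-R_c d)) m_c'`` — the current
    segment either survives the gap or terminates and a new class is drawn
    from the mixing proportions.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    stay = np.exp(-model.rates * d)
    return np.diag(stay) + (1 - stay)[:, None] * model.mixing[None, :]


def _frequencies_vector(freqs, n_markers: int) -> np.ndarray:
    p = freqs.p if isinstance(freqs, AlleleFrequencies) else np.asarray(freqs, float)
    if len(p) != n_markers:
        raise ValueError("allele-frequency vector length does not match the map")
    return p


def _chrom_blocks(genotypes, p, mmap, model):
    """Per-chromosome (stay, B) arrays ready for the kernels."""
    blocks = []
    for chrom, sl in mmap.chrom_slices():
        if sl.stop == sl.start:
            warnings.warn(f"chromosome {chrom} has no markers; skipped")
            continue
        d = np.diff(mmap.gpos[sl])
        if np.any(d < 0):
            raise ValueError(f"gpos decreasing on chromosome {chrom}")
        stay = np.exp(-np.outer(d, model.rates))
        B = emission_matrix(genotypes[sl], p[sl], model)
        blocks.append((sl, np.ascontiguousarray(stay), np.ascontiguousarray(B)))
    return blocks


def _forward_backward_pass(blocks, model):
    """One E-step: returns gamma, loglik and mixing sufficient statistics."""
    T = sum(sl.stop - sl.start for sl, _, _ in blocks)
    gamma = np.empty((T, model.n_states))
    loglik = 0.0
    start_counts = np.zeros(model.n_states)
    for sl, stay, B in blocks:
        g, ll, resets = _kernels.forward_backward_chrom(stay, B, model.mixing)
        gamma[sl] = g
        loglik += ll
        start_counts += g[0] + resets
    if not np.isfinite(loglik):
        raise FloatingPointError("non-finite log-likelihood")
    return gamma, loglik, start_counts


def _decoding_from_gamma(gamma, loglik, model, n_iter=None) -> Decoding:
    realized = gamma.mean(axis=0)
    return Decoding(gamma=gamma, loglik=loglik, realized=realized,
                    F=1.0 - realized[model.non_hbd_state], n_iter=n_iter)


def forward_backward(genotypes: np.ndarray, freqs, mmap: MarkerMap,
                     model: HBDModel) -> Decoding:
    """Posterior decoding of one individual under a fixed model.

    Chromosomes are independent, each starting from the mixing distribution;
    the log-likelihood sums over chromosomes. ``realized`` is the mean of
    gamma over all markers and ``F = 1 - realized[non-HBD]``.
    """
    genotypes = np.asarray(genotypes)
    p = _frequencies_vector(freqs, mmap.n_markers)
    if len(genotypes) != mmap.n_markers:
        raise ValueError("genotype sequence length does not match the map")
    blocks = _chrom_blocks(genotypes, p, mmap, model)
    gamma, loglik, _ = _forward_backward_pass(blocks, model)
    return _decoding_from_gamma(gamma, loglik, model)


def em_fit(genotypes: np.ndarray, freqs, mmap: MarkerMap, model: HBDModel,
           max_iter: int = 1000, tol: float = 1e-6,
           init_mixing: np.ndarray | None = None) -> tuple[HBDModel, Decoding]:
    """Estimate the mixing proportions of one individual by EM.

    Rates stay fixed on their ladder; mixing is initialized uniform (unless
    ``init_mixing`` is given) and updated proportionally to the expected
    number of segment starts of each class (chromosome-start occupancies plus
    within-chromosome reset events). Stops when |delta loglik| < tol or after
    ``max_iter`` M-steps. The log-likelihood is checked to be non-decreasing;
    a decrease beyond numerical tolerance raises. The returned Decoding
    carries the full log-likelihood history.
    """
    genotypes = np.asarray(genotypes)
    p = _frequencies_vector(freqs, mmap.n_markers)
    if init_mixing is None:
        init_mixing = np.full(model.n_states, 1.0 / model.n_states)
    cur = replace(model, mixing=np.asarray(init_mixing, dtype=np.float64))
    blocks = _chrom_blocks(genotypes, p, mmap, cur)
    prev_ll = -np.inf
    n_iter = 0
    history: list[float] = []

    def finish(gamma, ll):
        dec = _decoding_from_gamma(gamma, ll, cur, n_iter=n_iter)
        dec.loglik_history = history
        return cur, dec

    while True:
        gamma, ll, counts = _forward_backward_pass(blocks, cur)
        history.append(ll)
        if ll < prev_ll - 1e-9 * (1.0 + abs(prev_ll)):
            raise FloatingPointError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll})")
        if abs(ll - prev_ll) < tol or n_iter >= max_iter:
            return finish(gamma, ll)
        total = counts.sum()
        if total <= 0:
            return finish(gamma, ll)
        cur = replace(cur, mixing=counts / total)
        n_iter += 1
        prev_ll = ll
        if not np.isfinite(tol):
            # tol=inf: one update, then report the (finite) likelihood reached
            gamma, ll, _ = _forward_backward_pass(blocks, cur)
            history.append(ll)
            return finish(gamma, ll)


def viterbi(genotypes: np.ndarray, freqs, mmap: MarkerMap,
            model: HBDModel) -> np.ndarray:
    """Most likely state path, decoded per chromosome in log space.

    Ties break toward the lowest state index (the most recent HBD class).
    """
    genotypes = np.asarray(genotypes)
    p = _frequencies_vector(freqs, mmap.n_markers)
    path = np.empty(mmap.n_markers, dtype=np.int64)
    for sl, stay, B in _chrom_blocks(genotypes, p, mmap, model):
        path[sl], _ = _kernels.viterbi_chrom(stay, B, model.mixing)
    return path


def viterbi_log_prob(genotypes: np.ndarray, freqs, mmap: MarkerMap,
                     model: HBDModel) -> float:
    """Log-probability of the best state path (summed over chromosomes)."""
    genotypes = np.asarray(genotypes)
    p = _frequencies_vector(freqs, mmap.n_markers)
    total = 0.0
    for sl, stay, B in _chrom_blocks(genotypes, p, mmap, model):
        _, lp = _kernels.viterbi_chrom(stay, B, model.mixing)
        total += lp
    return total
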