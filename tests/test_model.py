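import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbdhmm import (HBDModel, class_generation, default_model, em_fit,
                    emission_probs, expected_segment_length, forward_backward,
                    inbreeding_from_nonhbd, transition_matrix, viterbi,
                    viterbi_log_prob)
from hbdhmm.io import MISSING
from hbdhmm.simulate import SimConfig, build_marker_map, simulate_panel

from conftest import make_map


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def enumerate_paths(genotypes, p, mmap, model):
    """Total and best path probability by exhaustive enumeration."""
    total, best = 1.0, 1.0
    S = model.n_states
    for chrom, sl in mmap.chrom_slices():
        g, pp = genotypes[sl], p[sl]
        d = np.diff(mmap.gpos[sl])
        As = [transition_matrix(di, model) for di in d]
        tot_c, best_c = 0.0, 0.0
        for seq in itertools.product(range(S), repeat=len(g)):
            pr = model.mixing[seq[0]] * emission_probs(g[0], pp[0], model.eps, model)[seq[0]]
            for t in range(1, len(g)):
                pr *= As[t - 1][seq[t - 1], seq[t]]
                pr *= emission_probs(g[t], pp[t], model.eps, model)[seq[t]]
            tot_c += pr
            best_c = max(best_c, pr)
        total *= tot_c
        best *= best_c
    return total, best


def random_instance(rng, n_markers, n_chrom=1, missing_rate=0.2):
    mmap = build_marker_map(n_chrom, n_markers // n_chrom, 0.01)
    model = HBDModel(np.sort(rng.uniform(2, 64, 2)).tolist() + [64.0],
                     rng.dirichlet(np.ones(3)), eps=rng.uniform(0, 0.05))
    p = rng.uniform(0.05, 0.95, mmap.n_markers)
    g = rng.integers(0, 3, mmap.n_markers)
    g[rng.random(mmap.n_markers) < missing_rate] = MISSING
    return g, p, mmap, model


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

class TestModelConstruction:
    def test_default_ladder(self):
        m = default_model()
        np.testing.assert_array_equal(
            m.rates, [2, 4, 8, 16, 32, 64, 128, 256, 512, 512])
        assert m.n_states == 10
        assert m.mixing.sum() == pytest.approx(1.0)
        assert np.all(m.mixing == 0.1)

    def test_two_state(self):
        m = default_model(n_classes=2)
        np.testing.assert_array_equal(m.rates, [2, 2])
        np.testing.assert_allclose(m.mixing, [0.5, 0.5])

    def test_too_few_classes(self):
        with pytest.raises(ValueError):
            default_model(n_classes=1)

    @pytest.mark.parametrize("bad_kwargs", [
        dict(rates=[-2.0, 2.0], mixing=[0.5, 0.5]),
        dict(rates=[8.0, 2.0, 8.0], mixing=[0.3, 0.3, 0.4]),  # decreasing HBD rates
        dict(rates=[2.0, 2.0], mixing=[0.6, 0.6]),
        dict(rates=[2.0, 2.0], mixing=[0.5, 0.5], eps=0.7),
    ])
    def test_invalid_models_rejected(self, bad_kwargs):
        with pytest.raises(ValueError):
            HBDModel(np.array(bad_kwargs.pop("rates")),
                     np.array(bad_kwargs.pop("mixing")), **bad_kwargs)

    def test_class_generation(self):
        assert class_generation(2) == 1    # parents
        assert class_generation(4) == 2    # grandparents
        assert class_generation(512) == 256
        with pytest.raises(ValueError):
            class_generation(0)

    def test_expected_length_reciprocal_rate(self):
        assert expected_segment_length(2) == 0.5
        assert expected_segment_length(512) == pytest.approx(1 / 512)

    def test_inbreeding_complement(self):
        assert inbreeding_from_nonhbd(0.89) == pytest.approx(0.11)


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

class TestEmissions:
    def test_heterozygote_impossible_in_errorfree_hbd(self):
        v = emission_probs(1, 0.5, 0.0)
        assert v[0] == 0.0 and v[-1] == pytest.approx(0.5)

    def test_homozygote_closed_form(self):
        v = emission_probs(2, 0.5, 0.0)
        assert v[0] == pytest.approx(0.5) and v[-1] == pytest.approx(0.25)

    def test_error_rate_formula(self):
        v = emission_probs(2, 0.3, 0.01)
        assert v[0] == pytest.approx(0.99 * 0.3 + 0.01 * 0.09)

    def test_missing_uninformative(self):
        np.testing.assert_array_equal(emission_probs(MISSING, 0.3, 0.01), [1, 1])

    def test_frequency_bounds(self):
        with pytest.raises(ValueError):
            emission_probs(1, 1.2, 0.0)

    @given(p=st.floats(0, 1), eps=st.floats(0, 0.49))
    @settings(max_examples=100, deadline=None)
    def test_genotype_distribution_normalized_per_state(self, p, eps):
        dist = np.array([emission_probs(g, p, eps) for g in (0, 1, 2)])
        np.testing.assert_allclose(dist.sum(axis=0), [1.0, 1.0], atol=1e-12)


# ---------------------------------------------------------------------------
# Transitions
# ---------------------------------------------------------------------------

class TestTransitions:
    def test_zero_distance_identity(self, three_state_model):
        np.testing.assert_allclose(transition_matrix(0.0, three_state_model),
                                   np.eye(3), atol=1e-15)

    def test_large_distance_reaches_mixing(self, three_state_model):
        A = transition_matrix(100.0, three_state_model)
        for row in A:
            np.testing.assert_allclose(row, three_state_model.mixing, atol=1e-10)

    def test_two_state_closed_form(self):
        m = HBDModel(np.array([2.0, 2.0]), np.array([0.4, 0.6]))
        A = transition_matrix(0.1, m)
        e = np.exp(-0.2)
        assert A[0, 0] == pytest.approx(e + (1 - e) * 0.4)
        assert A[0, 1] == pytest.approx((1 - e) * 0.6)

    def test_negative_distance_error(self, three_state_model):
        with pytest.raises(ValueError):
            transition_matrix(-0.1, three_state_model)

    @given(d=st.floats(0, 50), seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_rows_sum_to_one(self, d, seed):
        rng = np.random.default_rng(seed)
        model = HBDModel(np.sort(rng.uniform(1, 512, 4)).tolist() + [512.0],
                         rng.dirichlet(np.ones(5)))
        A = transition_matrix(d, model)
        np.testing.assert_allclose(A.sum(axis=1), np.ones(5), atol=1e-12)


# ---------------------------------------------------------------------------
# Forward-backward, Viterbi, EM
# ---------------------------------------------------------------------------

class TestForwardBackward:
    @pytest.mark.parametrize("seed,n_markers,n_chrom", [
        (0, 6, 1), (1, 8, 1), (2, 8, 2), (3, 5, 1), (4, 6, 2),
    ])
    def test_loglik_matches_enumeration(self, seed, n_markers, n_chrom):
        rng = np.random.default_rng(seed)
        g, p, mmap, model = random_instance(rng, n_markers, n_chrom)
        dec = forward_backward(g, p, mmap, model)
        total, _ = enumerate_paths(g, p, mmap, model)
        assert dec.loglik == pytest.approx(np.log(total), rel=1e-10)

    def test_gamma_rows_and_realized_normalized(self):
        rng = np.random.default_rng(5)
        g, p, mmap, model = random_instance(rng, 8)
        dec = forward_backward(g, p, mmap, model)
        np.testing.assert_allclose(dec.gamma.sum(axis=1), 1.0, atol=1e-8)
        assert dec.realized.sum() == pytest.approx(1.0, abs=1e-8)
        assert dec.F == 1.0 - dec.realized[-1]
        assert 0.0 <= dec.F <= 1.0

    def test_all_missing_gives_chain_marginals(self, three_state_model):
        mmap = build_marker_map(1, 5, 0.02)
        g = np.full(5, MISSING)
        dec = forward_backward(g, np.full(5, 0.5), mmap, three_state_model)
        marg = three_state_model.mixing.copy()
        A = transition_matrix(0.02, three_state_model)
        expected = [marg]
        for _ in range(4):
            expected.append(expected[-1] @ A)
        np.testing.assert_allclose(dec.gamma, expected, atol=1e-12)
        assert dec.F == pytest.approx(1 - np.mean([e[-1] for e in expected]))

    def test_chromosome_split_changes_loglik_little(self):
        """Splitting a chromosome at a marker boundary perturbs the likelihood
        only through the one reset at the split point."""
        cfg = SimConfig(n_chrom=1, markers_per_chrom=400, seed=8, n_individuals=1)
        panel, tr = simulate_panel(cfg)
        model = cfg.model
        ll_one = forward_backward(panel.G[0], tr.freqs, panel.markers,
                                  model).loglik
        split = make_map({"1": list(panel.markers.bp[:200]),
                          "2": list(panel.markers.bp[200:])})
        split.gpos[:] = panel.markers.gpos
        ll_two = forward_backward(panel.G[0], tr.freqs, split, model).loglik
        assert abs(ll_one - ll_two) < 5.0


class TestViterbi:
    @pytest.mark.parametrize("seed,n_markers,n_chrom", [
        (10, 6, 1), (11, 8, 1), (12, 8, 2), (13, 7, 1),
    ])
    def test_best_path_matches_enumeration(self, seed, n_markers, n_chrom):
        rng = np.random.default_rng(seed)
        g, p, mmap, model = random_instance(rng, n_markers, n_chrom)
        lp = viterbi_log_prob(g, p, mmap, model)
        _, best = enumerate_paths(g, p, mmap, model)
        assert lp == pytest.approx(np.log(best), rel=1e-10)
        # the decoded path itself attains the optimum
        path = viterbi(g, p, mmap, model)
        pr = 1.0
        for chrom, sl in mmap.chrom_slices():
            seq = path[sl]
            pr *= model.mixing[seq[0]] * emission_probs(g[sl][0], p[sl][0],
                                                        model.eps, model)[seq[0]]
            d = np.diff(mmap.gpos[sl])
            for t in range(1, len(seq)):
                A = transition_matrix(d[t - 1], model)
                pr *= A[seq[t - 1], seq[t]] * emission_probs(
                    g[sl][t], p[sl][t], model.eps, model)[seq[t]]
        assert np.log(pr) == pytest.approx(np.log(best), rel=1e-10)

    def test_homozygous_informative_markers_called_hbd(self):
        # generous recent-class mass, error-free, all-homozygous rare alleles
        model = HBDModel(np.array([2.0, 2.0]), np.array([0.5, 0.5]), eps=0.0)
        mmap = build_marker_map(1, 20, 0.01)
        g = np.full(20, 2, dtype=np.int8)
        p = np.full(20, 0.1)
        path = viterbi(g, p, mmap, model)
        assert np.all(path == 0)

    def test_all_missing_constant_apriori_path(self):
        model = HBDModel(np.array([2.0, 2.0]), np.array([0.2, 0.8]), eps=0.0)
        mmap = build_marker_map(1, 10, 0.01)
        path = viterbi(np.full(10, MISSING), np.full(10, 0.5), mmap, model)
        assert np.all(path == 1)  # the a-priori most probable state


class TestEM:
    def test_mixing_recovery_two_state(self):
        truth = HBDModel(np.array([4.0, 4.0]), np.array([0.3, 0.7]), eps=0.001)
        cfg = SimConfig(n_chrom=1, markers_per_chrom=5000,
                        marker_spacing_morgans=0.002, model=truth,
                        n_individuals=1, seed=21)
        panel, tr = simulate_panel(cfg)
        fitted, dec = em_fit(panel.G[0], tr.freqs, panel.markers, truth)
        np.testing.assert_allclose(fitted.mixing, truth.mixing, atol=0.1)

    def test_monotone_loglik(self):
        cfg = SimConfig(n_chrom=2, markers_per_chrom=300, seed=14, n_individuals=2)
        panel, tr = simulate_panel(cfg)
        for i in range(2):
            _, dec = em_fit(panel.G[i], tr.freqs, panel.markers, cfg.model)
            diffs = np.diff(dec.loglik_history)
            assert np.all(diffs >= -1e-9 * (1 + np.abs(dec.loglik)))

    def test_start_from_truth_does_not_decrease(self):
        cfg = SimConfig(n_chrom=1, markers_per_chrom=500, seed=15, n_individuals=1)
        panel, tr = simulate_panel(cfg)
        ll0 = forward_backward(panel.G[0], tr.freqs, panel.markers,
                               cfg.model).loglik
        _, dec = em_fit(panel.G[0], tr.freqs, panel.markers, cfg.model,
                        max_iter=1, init_mixing=cfg.model.mixing)
        assert dec.loglik >= ll0 - 1e-9 * (1 + abs(ll0))

    def test_infinite_tol_single_iteration(self):
        cfg = SimConfig(n_chrom=1, markers_per_chrom=200, seed=16, n_individuals=1)
        panel, tr = simulate_panel(cfg)
        _, dec = em_fit(panel.G[0], tr.freqs, panel.markers, cfg.model,
                        tol=np.inf)
        assert dec.n_iter == 1
        assert np.isfinite(dec.loglik)

    def test_f_recovery_small(self):
        """Fitted F tracks the simulated truth on a modest panel."""
        cfg = SimConfig(n_chrom=4, markers_per_chrom=500, seed=17,
                        n_individuals=5, model=default_model(eps=0.001))
        panel, tr = simulate_panel(cfg)
        errs = []
        for i in range(5):
            _, dec = em_fit(panel.G[i], tr.freqs, panel.markers, cfg.model)
            errs.append(abs(dec.F - tr.F[i]))
        assert np.mean(errs) <= 0.03
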