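from itertools import product

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist
from scipy.stats import vonmises

from sitefidelity.hmm import (MovementHMM, _log_emission, extract_sites,
                              fit_hmm, hmm_loglik, label_states, n_free_params,
                              select_n_states, states_per_fix, viterbi)

from conftest import make_trip, sample_obs


def brute_force_loglik_and_path(model, steps, angles):
    """Exhaustive enumeration over all S^T state paths (oracle)."""
    logb = _log_emission(model, steps, angles)
    T, S = logb.shape
    with np.errstate(divide="ignore"):
        ld, lt = np.log(model.delta), np.log(model.tpm)
    lls, best, best_lp = [], None, -np.inf
    for path in product(range(S), repeat=T):
        lp = ld[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += lt[path[t - 1], path[t]] + logb[t, path[t]]
        lls.append(lp)
        if lp > best_lp:
            best_lp, best = lp, path
    return logsumexp(lls), np.array(best)


class TestLikelihoodAndDecoding:
    def test_forward_and_viterbi_match_enumeration(self, small_hmm, rng):
        steps, angles, _ = sample_obs(small_hmm, 8, rng)
        oracle_ll, oracle_path = brute_force_loglik_and_path(small_hmm, steps, angles)
        assert hmm_loglik(small_hmm, (steps, angles)) == pytest.approx(oracle_ll,
                                                                       abs=1e-8)
        assert np.array_equal(viterbi(small_hmm, (steps, angles)), oracle_path)

    def test_single_state_loglik_is_sum_of_emissions(self, rng):
        m = MovementHMM([100.0], [80.0], [0.5], [1.2], [[1.0]], [1.0])
        steps, angles, _ = sample_obs(m, 50, rng)
        shape, scale = 100.0 ** 2 / 80.0 ** 2, 80.0 ** 2 / 100.0
        expected = gamma_dist.logpdf(np.maximum(steps, 0.1), a=shape,
                                     scale=scale).sum() + \
            vonmises.logpdf(angles[1:], kappa=1.2, loc=0.5).sum()
        assert hmm_loglik(m, (steps, angles)) == pytest.approx(expected, abs=1e-8)
        assert np.all(viterbi(m, (steps, angles)) == 0)

    def test_loglik_invariant_under_state_relabelling(self, small_hmm, rng):
        steps, angles, _ = sample_obs(small_hmm, 60, rng)
        perm = [2, 0, 1]
        permuted = small_hmm.permuted(perm)
        ll1 = hmm_loglik(small_hmm, (steps, angles))
        ll2 = hmm_loglik(permuted, (steps, angles))
        assert ll1 == pytest.approx(ll2, abs=1e-8)
        # decoding commutes with the relabelling
        p1 = viterbi(small_hmm, (steps, angles))
        p2 = viterbi(permuted, (steps, angles))
        assert np.array_equal(np.asarray(perm)[p2], p1)

    def test_persistent_chain_switches_less_than_uniform(self, small_hmm, rng):
        steps, angles, _ = sample_obs(small_hmm, 300, rng)
        sticky_tpm = np.full((3, 3), 0.0005)
        np.fill_diagonal(sticky_tpm, 0.999)
        sticky = MovementHMM(small_hmm.step_mean, small_hmm.step_sd,
                             small_hmm.angle_mean, small_hmm.angle_kappa,
                             sticky_tpm, small_hmm.delta)
        uniform = MovementHMM(small_hmm.step_mean, small_hmm.step_sd,
                              small_hmm.angle_mean, small_hmm.angle_kappa,
                              np.full((3, 3), 1 / 3), small_hmm.delta)
        n_sw = lambda p: int(np.sum(p[1:] != p[:-1]))
        assert n_sw(viterbi(sticky, (steps, angles))) < \
            n_sw(viterbi(uniform, (steps, angles)))

    def test_multiple_trips_pool_as_independent_chains(self, small_hmm, rng):
        seqs = [sample_obs(small_hmm, 20, rng)[:2] for _ in range(3)]
        pooled = hmm_loglik(small_hmm, seqs)
        assert pooled == pytest.approx(sum(hmm_loglik(small_hmm, s) for s in seqs))


class TestFitting:
    def test_recovers_generating_parameters(self, rng):
        truth = MovementHMM([2000.0, 300.0, 60.0], [1000.0, 250.0, 50.0],
                            [0.0, np.pi, 0.0], [8.0, 1.5, 0.3],
                            [[0.9, 0.06, 0.04], [0.08, 0.86, 0.06],
                             [0.06, 0.1, 0.84]], [1.0, 0.0, 0.0])
        seqs = [sample_obs(truth, 250, rng)[:2] for _ in range(8)]
        fit = fit_hmm(seqs, n_states=3, n_restarts=1, seed=0, maxiter=400)
        est = fit.model.permuted(np.argsort(fit.model.step_mean)[::-1])
        assert np.all(np.abs(est.step_mean - truth.step_mean)
                      / truth.step_mean < 0.10)
        # the MLE dominates the truth on its own training data
        assert fit.loglik >= hmm_loglik(truth, seqs) - 1e-6
        # fitted parameters satisfy the model constraints
        assert np.allclose(est.tpm.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(est.angle_kappa >= 0) and np.all(est.step_mean > 0)
        assert label_states(est) == {0: "travelling", 1: "foraging", 2: "resting"}

    def test_single_state_fit_matches_pooled_mle(self, rng):
        m = MovementHMM([150.0], [100.0], [0.3], [0.8], [[1.0]], [1.0])
        steps, angles, _ = sample_obs(m, 800, rng)
        fit = fit_hmm([(steps, angles)], n_states=1, n_restarts=1, seed=0)
        shape, loc, scale = gamma_dist.fit(np.maximum(steps, 0.1), floc=0)
        kappa, mu, _ = vonmises.fit(angles[1:], fscale=1)
        direct = MovementHMM([shape * scale], [np.sqrt(shape) * scale], [mu],
                             [kappa], [[1.0]], [1.0])
        assert fit.loglik >= hmm_loglik(direct, (steps, angles)) - 1e-3
        assert fit.model.step_mean[0] == pytest.approx(shape * scale, rel=1e-2)

    def test_aic_definition_and_selection(self, rng):
        truth = MovementHMM([2000.0, 100.0], [1000.0, 80.0], [0.0, np.pi],
                            [6.0, 1.0], [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        seqs = [sample_obs(truth, 200, rng)[:2] for _ in range(5)]
        n_best, fits = select_n_states(seqs, candidates=(1, 2), n_restarts=1,
                                       seed=1, maxiter=300)
        for n, f in fits.items():
            assert f.aic == pytest.approx(2 * n_free_params(n) - 2 * f.loglik)
        assert n_best == 2

    def test_all_restarts_failing_raises(self):
        with pytest.raises(ValueError):
            fit_hmm([], n_states=3)


class TestSites:
    def test_single_foraging_run_becomes_one_site(self):
        trip = make_trip([(0, 5000 + 100 * i) for i in range(8)])
        states = np.array([0, 0, 1, 1, 1, 1, 0])  # step-level
        labels = {0: "travelling", 1: "foraging"}
        sites = extract_sites(trip, states, labels)
        assert len(sites) == 1
        row = sites.iloc[0]
        # a fix takes the state of the step leaving it, so foraging steps
        # 2-5 put the foraging label on fixes 2-5
        member = trip.fixes.iloc[2:6]
        assert row["n_fixes"] == 4
        assert row["lat_c"] == pytest.approx(member["lat"].mean())
        assert row["lon_c"] == pytest.approx(member["lon"].mean())

    def test_interrupted_foraging_gives_two_sites(self):
        trip = make_trip([(0, 5000 + 100 * i) for i in range(7)])
        states = np.array([1, 1, 0, 0, 1, 1])
        sites = extract_sites(trip, states, {0: "travelling", 1: "foraging"})
        assert len(sites) == 2
        # second run: steps 4-5 label fixes 4-5 plus the final fix (inherits)
        assert sites["n_fixes"].tolist() == [2, 3]

    def test_no_foraging_yields_empty(self):
        trip = make_trip([(0, 5000 + 100 * i) for i in range(5)])
        sites = extract_sites(trip, np.zeros(4, dtype=int), {0: "travelling"})
        assert len(sites) == 0

    def test_state_alignment_length(self):
        assert len(states_per_fix(np.array([0, 1, 1]), 4)) == 4
        with pytest.raises(ValueError):
            states_per_fix(np.array([0, 1]), 4)


def test_foraging_label_prefers_turn_reversing_state():
    # resting has the smallest steps but diffuse angles near zero; foraging
    # reverses direction: the labeller must not confuse them
    m = MovementHMM([3000.0, 300.0, 60.0], [1500.0, 250.0, 50.0],
                    [0.0, np.pi, 0.0], [8.0, 1.5, 0.3],
                    np.full((3, 3), 1 / 3), [1 / 3] * 3)
    assert label_states(m) == {0: "travelling", 1: "foraging", 2: "resting"}
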