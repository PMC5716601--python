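"""Tests of adaptive choice design and convergence analysis."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from valuetasks.design import (
    DesignPosterior,
    convergence_trace,
    grid_offers,
    information_sigma_trace,
    informative_pairs,
    one_dimension_candidates,
    optimized_order,
    pair_features,
    run_adaptive_session,
    select_next_pair,
    update_posterior,
)
from valuetasks.fitting import ValueTaskModel


def brute_force_informative_pairs(step):
    """Exhaustive oracle: filter all ordered offer pairs, dedupe unordered."""
    offers = grid_offers(step)
    seen = set()
    for g1, d1 in offers:
        for g2, d2 in offers:
            if g1 == g2 or d1 == d2:
                continue
            if np.sign(g1 - g2) != -np.sign(d1 - d2):
                continue
            key = tuple(sorted([(g1, d1), (g2, d2)]))
            seen.add(key)
    return seen


class TestInformativePairs:
    def test_count_matches_closed_form_and_brute_force(self):
        pairs = informative_pairs(10.0)
        n_amounts = 11
        assert len(pairs) == comb(n_amounts, 2) ** 2 == 3025
        oracle = brute_force_informative_pairs(10.0)
        ours = {
            tuple(sorted([(p[0], p[1]), (p[2], p[3])])) for p in pairs
        }
        assert ours == oracle

    def test_count_closed_form_other_steps(self):
        for step in (20.0, 25.0, 50.0):
            n = int(100 / step) + 1
            assert len(informative_pairs(step)) == comb(n, 2) ** 2

    def test_dominated_pair_excluded(self):
        pairs = informative_pairs(10.0)
        as_set = {tuple(p) for p in pairs}
        # (50,50) vs (60,60): dominated on both dimensions -> excluded
        assert (50.0, 50.0, 60.0, 60.0) not in as_set
        assert (60.0, 60.0, 50.0, 50.0) not in as_set

    def test_ordered_pair_count(self):
        assert len(grid_offers(10.0)) ** 2 == 14641


class TestPosteriorUpdate:
    def test_uninformative_observation_keeps_trace(self):
        post = DesignPosterior.default()
        # equal utilities under the prior mean: p = 0.5, weak information
        pair = (50.0, 50.0, 50.0, 50.0)
        updated = update_posterior(post, pair, 1)
        assert updated.trace <= post.trace + 1e-12

    def test_repeated_informative_trials_shrink_trace(self):
        rng = np.random.default_rng(0)
        post = DesignPosterior.default()
        true = np.array([0.7, 0.3, 0.0])
        traces = [post.trace]
        for _ in range(50):
            g = rng.choice(np.arange(0, 101, 10), 2, replace=False)
            d = rng.choice(np.arange(0, 101, 10), 2, replace=False)
            pair = (min(g), max(d), max(g), min(d))
            p = 1 / (1 + np.exp(-(pair_features(pair) @ true) / post.temperature))
            post = update_posterior(post, pair, int(rng.random() < p))
            traces.append(post.trace)
        assert traces[-1] < traces[0] / 2
        assert np.all(np.linalg.eigvalsh(post.cov) > 0)

    def test_sequential_close_to_batch_map(self):
        rng = np.random.default_rng(1)
        true = np.array([0.6, 0.5, 0.0])
        post = DesignPosterior.default()
        rows = []
        for _ in range(80):
            g = rng.choice(np.arange(0, 101, 10), 2, replace=False)
            d = rng.choice(np.arange(0, 101, 10), 2, replace=False)
            pair = (min(g), max(d), max(g), min(d))
            p = 1 / (1 + np.exp(-(pair_features(pair) @ true) / post.temperature))
            y = int(rng.random() < p)
            post = update_posterior(post, pair, y)
            rows.append((*pair, y))
        # batch MAP refit of the same logistic model on the same trials
        from scipy.optimize import minimize

        X = np.array([pair_features(r[:4]) for r in rows]) / post.temperature
        yv = np.array([r[4] for r in rows], dtype=float)
        prior = DesignPosterior.default()
        P0 = np.linalg.inv(prior.cov)

        def neg(th):
            z = X @ th
            ll = -(yv * np.logaddexp(0, -z) + (1 - yv) * np.logaddexp(0, z)).sum()
            return -ll + 0.5 * (th - prior.mean) @ P0 @ (th - prior.mean)

        res = minimize(neg, prior.mean, method="BFGS")
        z = X @ res.x
        w = 1 / (1 + np.exp(-z))
        H = P0 + (X * (w * (1 - w))[:, None]).T @ X
        batch_trace = float(np.trace(np.linalg.inv(H)))
        assert post.trace == pytest.approx(batch_trace, rel=0.10)


class TestSelection:
    def test_picks_strictly_better_candidate(self):
        post = DesignPosterior.default()
        cands = np.array(
            [
                [50.0, 50.0, 50.0, 50.0],  # uninformative (identical offers)
                [0.0, 100.0, 100.0, 0.0],  # maximally spread
            ]
        )
        pair, score = select_next_pair(post, cands)
        assert tuple(pair) == (0.0, 100.0, 100.0, 0.0)

    def test_tie_break_seeded(self):
        post = DesignPosterior.default()
        # two mirrored candidates with identical information content
        cands = np.array([[0.0, 100.0, 100.0, 0.0], [0.0, 100.0, 100.0, 0.0]])
        picks = {
            tuple(select_next_pair(post, cands, np.random.default_rng(s))[0])
            for s in range(3)
        }
        assert len(picks) == 1  # identical rows: any pick is the same pair

    def test_one_dimension_candidates_respect_constraints(self):
        prev = (10.0, 80.0, 60.0, 20.0)
        amounts = np.arange(0.0, 101.0, 10.0)
        cands = one_dimension_candidates(prev, "gain", amounts)
        assert len(cands) > 0
        for c in cands:
            assert {c[1], c[3]} == {80.0, 20.0}  # donations carried over
            assert c[0] != c[2]
            assert np.sign(c[0] - c[2]) == -np.sign(c[1] - c[3])

    def test_adaptive_session_beats_random_pairs(self):
        rng_master = np.random.default_rng(0)
        true = np.array([0.6, 0.4, 0.001])
        finals = {"adaptive": [], "random": []}
        for rep in range(6):
            for mode in ("adaptive", "random"):
                rng = np.random.default_rng((rep, hash(mode) % 1000))

                def responder(pair):
                    p = 1 / (1 + np.exp(-(pair_features(pair) @ true) / 10.0))
                    return int(rng.random() < p)

                if mode == "adaptive":
                    sess = run_adaptive_session(60, responder, rng)
                    finals[mode].append(sess.posterior_trace.iloc[-1])
                else:
                    post = DesignPosterior.default()
                    amounts = np.arange(0.0, 101.0, 5.0)
                    for _ in range(60):
                        g = rng.choice(amounts, 2, replace=False)
                        d = rng.choice(amounts, 2, replace=False)
                        pair = (min(g), max(d), max(g), min(d))
                        post = update_posterior(post, pair, responder(pair))
                    finals[mode].append(post.trace)
        assert np.mean(finals["adaptive"]) < np.mean(finals["random"])


class TestConvergence:
    def test_hand_arithmetic(self):
        trace = convergence_trace([10.0, 8.0, 7.8])
        np.testing.assert_allclose(trace.gamma, [0.2, 0.025])
        assert trace.threshold_trial == 2

    def test_constant_series_converged_at_start(self):
        trace = convergence_trace([5.0, 5.0, 5.0])
        np.testing.assert_allclose(trace.gamma, 0.0)
        assert trace.threshold_trial == 1

    def test_halving_series_never_converges(self):
        sigma = 10.0 * 0.5 ** np.arange(8)
        trace = convergence_trace(sigma)
        np.testing.assert_allclose(trace.gamma, 0.5)
        assert trace.threshold_trial == 8

    def test_rejects_degenerate_series(self):
        with pytest.raises(ValueError):
            convergence_trace([1.0])
        with pytest.raises(ValueError):
            convergence_trace([1.0, -2.0])


class TestOptimizedOrder:
    def test_lead_in_covers_coverage_amounts(self, one_subject):
        trials = one_subject.task("rating")
        out = optimized_order(trials, rng=np.random.default_rng(0))
        lead = out.iloc[:11]
        amounts = set(lead.gain_left).union(lead.donation_left)
        assert amounts <= {0.0, 30.0, 50.0, 70.0, 100.0}
        # a reordering: same trials, same multiset of offers
        assert sorted(out.gain_left) == sorted(trials.gain_left)

    def test_optimized_order_front_loads_information(self, one_subject):
        trials = one_subject.task("rating")
        res = ValueTaskModel(trials, "ces", "rating").fit(n_restarts=2, seed=0)
        opt = optimized_order(trials, results=res, rng=np.random.default_rng(0))
        _, sig_nat = information_sigma_trace(trials, res)
        _, sig_opt = information_sigma_trace(opt, res)
        # after the lead-in the optimized order should dominate
        assert np.mean(sig_opt[11:60] <= sig_nat[11:60] + 1e-12) > 0.9

    def test_sigma_trace_positive_and_decreasing_overall(self, one_subject):
        trials = one_subject.task("rating")
        res = ValueTaskModel(trials, "ces", "rating").fit(n_restarts=2, seed=0)
        ts, sig = information_sigma_trace(trials, res)
        assert np.all(sig > 0)
        assert sig[-1] < sig[0]
        assert len(ts) == len(trials)
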