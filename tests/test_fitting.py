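"""Tests of MAP fitting, Laplace evidence and parameter sharing.

The Laplace evidence is checked against two independent oracles: the exact
closed-form marginal likelihood of a linear-Gaussian model (where Laplace is
exact) and brute-force grid quadrature of the joint for a nonlinear
two-parameter CES fit.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from valuetasks.cohort import CohortConfig, make_grid_design, simulate_cohort
from valuetasks.fitting import (
    PriorSpec,
    SharedParameterModel,
    ValueTaskModel,
    fit_map,
    partition_label,
    sharing_partitions,
)
from valuetasks.value_models import (
    IDENTITY,
    Parameter,
    ValueFunctionSpec,
    get_spec,
)


def _rating_frame(gain, donation, response):
    return pd.DataFrame(
        {
            "gain_left": gain,
            "donation_left": donation,
            "response": response,
            "task": "rating",
        }
    )


# linear value function with identity-transform weights: in unconstrained
# space the rating likelihood is exactly linear-Gaussian, so the Laplace
# evidence must equal the conjugate closed form
LINEAR_IDENTITY = ValueFunctionSpec(
    id=99,
    name="linear-identity",
    parameters=(
        Parameter("alpha", IDENTITY, "gain weight"),
        Parameter("beta", IDENTITY, "donation weight"),
    ),
    fn=lambda p, g, d: p["alpha"] * g + p["beta"] * d,
)


def closed_form_linear_gaussian_evidence(X, y, prior_mean, prior_var, noise_sd):
    """Marginal likelihood of y = X w + e, w ~ N(m0, v0 I), e ~ N(0, sd^2 I)."""
    n = len(y)
    mean = X @ (np.full(X.shape[1], prior_mean))
    cov = prior_var * (X @ X.T) + noise_sd**2 * np.eye(n)
    sign, logdet = np.linalg.slogdet(cov)
    resid = y - mean
    return float(
        -0.5 * (n * np.log(2 * np.pi) + logdet + resid @ np.linalg.solve(cov, resid))
    )


class TestLogJoint:
    def test_no_data_reduces_to_prior(self):
        df = _rating_frame([], [], [])
        model = ValueTaskModel(df, "ces", "rating")
        theta = np.zeros(model.k_params)
        assert model.log_joint(theta) == pytest.approx(model.prior_logpdf(theta))
        # and the model's prior is scale-aware: the intercept (response
        # units) carries a much wider prior than the unit-scale parameters
        var = dict(zip(model.param_labels, model._prior_var_vec))
        assert var["intercept"] > var["alpha"]

    def test_choice_at_even_odds_gives_n_log_half(self):
        df = pd.DataFrame(
            {
                "gain_left": [50.0, 60.0, 10.0],
                "donation_left": [10.0, 20.0, 80.0],
                "gain_right": [10.0, 20.0, 80.0],
                "donation_right": [50.0, 60.0, 10.0],
                "response": [1.0, 0.0, 1.0],
            }
        )
        # alpha = 0.5, delta = 1: symmetric pairs have equal value -> p = 0.5
        model = ValueTaskModel(df, "ces", "choice")
        theta = model.spec.to_unconstrained({"alpha": 0.5, "delta": 1.0})
        theta = np.append(theta, np.log(5.0))
        ll = model.loglike(theta)
        assert ll == pytest.approx(3 * np.log(0.5))

    def test_three_trial_hand_computation(self):
        # rating likelihood term by term: N(y; mu, sd)
        df = _rating_frame([10.0, 50.0, 90.0], [10.0, 50.0, 90.0], [1.5, 5.0, 8.0])
        model = ValueTaskModel(
            df, "ces", "rating", fixed={"slope": 0.1, "intercept": 0.0, "noise_sd": 1.0}
        )
        theta = model.spec.to_unconstrained({"alpha": 0.5, "delta": 1.0})
        mus = np.array([1.0, 5.0, 9.0])
        ys = np.array([1.5, 5.0, 8.0])
        hand = np.sum(-0.5 * ((ys - mus) ** 2) - 0.5 * np.log(2 * np.pi))
        assert model.loglike(theta) == pytest.approx(hand)

    def test_validation_flags_offending_trial(self):
        df = _rating_frame([10.0, 50.0], [10.0, 50.0], [np.nan, 5.0])
        model = ValueTaskModel(df, "ces", "rating")
        with pytest.raises(FloatingPointError, match="trial index 0"):
            model.log_joint(np.zeros(model.k_params), validate=True)


class TestFitMap:
    def test_noiseless_linear_rating_recovers_weights_exactly(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0, 100, 40)
        d = rng.uniform(0, 100, 40)
        y = 0.05 * g + 0.03 * d
        df = _rating_frame(g, d, y)
        res = fit_map(
            df,
            "linear-independent",
            "rating",
            fixed={"slope": 1.0, "intercept": 0.0, "noise_sd": 0.01},
            n_restarts=4,
            seed=0,
        )
        assert res.params["alpha"] == pytest.approx(0.05, abs=1e-3)
        assert res.params["beta"] == pytest.approx(0.03, abs=1e-3)
        assert res.rsquared > 0.999

    def test_laplace_equals_closed_form_on_linear_gaussian(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0, 100, 30)
        d = rng.uniform(0, 100, 30)
        w_true = np.array([0.04, 0.06])
        noise_sd = 1.0
        y = g * w_true[0] + d * w_true[1] + rng.normal(0, noise_sd, 30)
        # bounds wide open so clipping never triggers -> exactly linear model
        from valuetasks.observation import TaskConfig

        tc = TaskConfig(rating_bounds=(-1e9, 1e9))
        df = _rating_frame(g, d, y)
        prior = PriorSpec(mean=0.0, var=3.0)
        res = fit_map(
            df,
            LINEAR_IDENTITY,
            "rating",
            prior=prior,
            task_config=tc,
            fixed={"slope": 1.0, "intercept": 0.0, "noise_sd": noise_sd},
            n_restarts=4,
            seed=0,
        )
        X = np.column_stack([g, d])
        oracle = closed_form_linear_gaussian_evidence(X, y, 0.0, 3.0, noise_sd)
        assert res.log_evidence == pytest.approx(oracle, abs=1e-6)

    def test_laplace_matches_grid_quadrature_on_ces(self):
        # 2 free parameters (alpha, delta); observation parameters fixed
        rng = np.random.default_rng(2)
        design = make_grid_design(10.0, rng)
        spec = get_spec("ces")
        v = spec.value({"alpha": 0.6, "delta": 1.5}, design.gain, design.donation)
        y = np.clip(0.1 * v + rng.normal(0, 1.0, len(v)), 0, 10)
        df = _rating_frame(design.gain, design.donation, y)
        model = ValueTaskModel(
            df, "ces", "rating", fixed={"slope": 0.1, "intercept": 0.0, "noise_sd": 1.0}
        )
        res = model.fit(n_restarts=4, seed=0)
        # brute-force quadrature of the joint on a grid around the MAP
        sds = res.bse.to_numpy()
        axes = [
            np.linspace(res.theta[i] - 6 * sds[i], res.theta[i] + 6 * sds[i], 200)
            for i in range(2)
        ]
        A, B = np.meshgrid(axes[0], axes[1], indexing="ij")
        lj = np.array(
            [model.log_joint(np.array([a, b])) for a, b in zip(A.ravel(), B.ravel())]
        )
        cell = (axes[0][1] - axes[0][0]) * (axes[1][1] - axes[1][0])
        quad = logsumexp(lj) + np.log(cell)
        assert res.log_evidence == pytest.approx(quad, abs=0.5)

    def test_ces_parameter_recovery_from_rating(self):
        rng = np.random.default_rng(3)
        design = make_grid_design(10.0, rng)
        spec = get_spec("ces")
        v = spec.value({"alpha": 0.6, "delta": 1.5}, design.gain, design.donation)
        y = np.clip(0.1 * v + rng.normal(0, 1.0, len(v)), 0, 10)
        res = fit_map(_rating_frame(design.gain, design.donation, y), "ces", "rating",
                      n_restarts=4, seed=0)
        assert res.params["alpha"] == pytest.approx(0.6, abs=0.1)

    def test_requires_enough_observations(self):
        df = _rating_frame([10.0], [20.0], [3.0])
        with pytest.raises(ValueError, match="observations"):
            ValueTaskModel(df, "ces", "rating").fit()

    def test_covariance_is_spd_and_summary_renders(self, one_subject):
        res = fit_map(one_subject.task("rating"), "ces", "rating", n_restarts=2, seed=0)
        cov = res.cov_params.to_numpy()
        np.testing.assert_allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)
        text = res.summary()
        assert "log evidence" in text and "alpha" in text
        d = res.to_dict()
        assert set(d) >= {"params", "log_evidence", "rsquared", "cov_params"}


class TestRSquared:
    def test_hand_example_four_points(self):
        # y = (1,2,3,4), yhat = (1,2,2,4): SSres = 1, SStot = 5
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.0, 2.0, 2.0, 4.0])
        expected = 1 - 1 / 5
        df = _rating_frame([1, 2, 3, 4], [0, 0, 0, 0], y)
        model = ValueTaskModel(
            df, "linear-independent", "rating",
            fixed={"slope": 1.0, "intercept": 0.0, "noise_sd": 1.0},
        )
        res = model.fit(n_restarts=2, seed=0)
        # override predictions to the hand values via direct computation
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(expected)
        # the fitted model's own R^2 lies in (-inf, 1]
        assert res.rsquared <= 1.0

    def test_zero_variance_signalled(self):
        df = _rating_frame([10.0, 20.0, 30.0, 40.0, 50.0], [0.0] * 5, [5.0] * 5)
        res = ValueTaskModel(df, "linear-independent", "rating").fit(n_restarts=2, seed=0)
        with pytest.raises(ZeroDivisionError):
            res.rsquared


class TestEvidenceOccam:
    def test_interaction_term_penalized_on_linear_data(self):
        # data from the additive model: the interactive variant fits no
        # better but carries an extra parameter, so evidence should not rise
        rng = np.random.default_rng(4)
        wins = 0
        n_rep = 6
        for rep in range(n_rep):
            design = make_grid_design(10.0, rng)
            v = 0.05 * design.gain + 0.04 * design.donation
            y = np.clip(v + rng.normal(0, 0.8, len(v)), 0, 10)
            df = _rating_frame(design.gain, design.donation, y)
            e_lin = fit_map(df, "linear-independent", "rating", n_restarts=3, seed=rep).log_evidence
            e_int = fit_map(df, "linear-interactive", "rating", n_restarts=3, seed=rep).log_evidence
            wins += e_lin >= e_int
        assert wins >= n_rep - 1


class TestSharing:
    def test_partition_enumeration(self):
        parts = sharing_partitions()
        assert len(parts) == 5
        sizes = sorted(tuple(sorted(len(c) for c in p)) for p in parts)
        assert sizes == [(1, 1, 1), (1, 2), (1, 2), (1, 2), (3,)]
        labels = {partition_label(p) for p in parts}
        assert len(labels) == 5

    def test_single_task_input_rejected(self, one_subject):
        with pytest.raises(ValueError, match="two tasks"):
            SharedParameterModel(
                {"rating": one_subject.task("rating")},
                "ces",
                "alpha",
                (frozenset(("rating",)),),
            )

    def test_invalid_partition_rejected(self, one_subject):
        data = {t: one_subject.task(t) for t in ("rating", "force", "choice")}
        with pytest.raises(ValueError, match="partition"):
            SharedParameterModel(
                data, "ces", "alpha", (frozenset(("rating", "force")),)
            )

    def test_shared_alpha_beats_distinct_on_common_alpha_data(self):
        datasets, _ = simulate_cohort(CohortConfig(n_subjects=4, seed=17))
        better = 0
        for ds in datasets:
            data = {t: ds.task(t) for t in ("rating", "force", "choice")}
            task_fits = {
                t: ValueTaskModel(df, "ces", t).fit(n_restarts=3, seed=1)
                for t, df in data.items()
            }
            evs = {}
            for part in (sharing_partitions()[0], sharing_partitions()[-1]):
                m = SharedParameterModel(data, "ces", "alpha", part)
                res = m.fit(n_restarts=1, seed=1, start_values=m.assemble_start(task_fits))
                evs[len(part)] = res.log_evidence
            better += evs[1] >= evs[3]
        assert better >= 3  # all-shared wins for most subjects
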