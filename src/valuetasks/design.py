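"""Adaptive optimization of binary-choice designs and convergence analysis.

The choice task selects offer pairs online so as to sharpen the estimate of
an a-priori value function, linear in gain, donation and their interaction:
``V(G,D) = b_G*G + b_D*D + b_GD*G*D``.  After each observed choice the
Gaussian posterior over ``(b_G, b_D, b_GD)`` is refreshed with a single
Newton/Laplace step for the logistic observation, and the next pair is the
candidate minimizing the expected (choice-probability-weighted) trace of the
post-update posterior covariance — the A-optimality criterion — with the
search restricted to pairs varying a single dimension (gain or donation,
alternating) from the previous pair.

Informative pairs are those where the options are crossed (neither dominates
on both dimensions), differ on both dimensions, and have not been shown
before; on the 10-euro grid exactly C(11,2)^2 = 3025 such unordered pairs
exist.

Estimation convergence is tracked through the per-trial relative drop in
mean posterior variance, ``gamma_t = (sigma_{t-1} - sigma_t)/sigma_{t-1}``;
the minimum informative trial count is the last trial with ``gamma_t`` above
the 5% threshold.  The trace can be computed for the native trial order or
for a reordered ("optimized") sequence whose first eleven trials cover the
amount range {0, 30, 50, 70, 100} euros on both dimensions and whose
remaining trials are appended greedily by minimum expected posterior trace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .fitting import PriorSpec, ValueTaskModel

logger = logging.getLogger(__name__)

__all__ = [
    "DesignPosterior",
    "ConvergenceTrace",
    "grid_offers",
    "informative_pairs",
    "pair_features",
    "update_posterior",
    "expected_posterior_trace",
    "select_next_pair",
    "one_dimension_candidates",
    "run_adaptive_session",
    "convergence_trace",
    "optimized_order",
    "trial_information",
    "information_sigma_trace",
    "sequential_sigma_trace",
    "incremental_sigma_trace",
]

COVERAGE_AMOUNTS = (0.0, 30.0, 50.0, 70.0, 100.0)


def grid_offers(step: float = 10.0) -> np.ndarray:
    """All (gain, donation) offers on the euro grid, shape (n, 2)."""
    if 100.0 % step:
        raise ValueError(f"step {step} does not divide 100")
    amounts = np.arange(0.0, 100.0 + step / 2, step)
    g, d = np.meshgrid(amounts, amounts, indexing="ij")
    return np.column_stack([g.ravel(), d.ravel()])


def informative_pairs(step: float = 10.0) -> np.ndarray:
    """All informative unordered offer pairs on the euro grid.

    Each row is ``(g1, d1, g2, d2)`` in the canonical orientation g1 < g2 and
    d1 > d2 (crossed options, both dimensions differing).  With an n-amount
    grid there are C(n, 2)^2 such pairs — 3025 at the 10-euro step.
    """
    if 100.0 % step:
        raise ValueError(f"step {step} does not divide 100")
    amounts = np.arange(0.0, 100.0 + step / 2, step)
    n = len(amounts)
    gi, gj = np.triu_indices(n, k=1)
    di, dj = np.triu_indices(n, k=1)
    g_lo, g_hi = amounts[gi], amounts[gj]
    d_lo, d_hi = amounts[di], amounts[dj]
    rows = []
    for a, b in zip(g_lo, g_hi):
        rows.append(
            np.column_stack([np.full_like(d_hi, a), d_hi, np.full_like(d_lo, b), d_lo])
        )
    return np.vstack(rows)


@dataclass(frozen=True)
class DesignPosterior:
    """Gaussian belief over the a-priori value parameters (b_G, b_D, b_GD)."""

    mean: np.ndarray
    cov: np.ndarray
    temperature: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "cov", _ensure_spd(np.asarray(self.cov, dtype=float)))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @classmethod
    def default(cls, temperature: float = 10.0) -> "DesignPosterior":
        # Weak prior spanning plausible euro-scale weights; the interaction
        # weight works on the G*D scale (up to 1e4), hence the tighter SD.
        return cls(
            mean=np.array([0.5, 0.5, 0.0]),
            cov=np.diag([0.25, 0.25, 2.5e-5]),
            temperature=temperature,
        )

    @property
    def trace(self) -> float:
        return float(np.trace(self.cov))


def _ensure_spd(m: np.ndarray, max_tries: int = 10) -> np.ndarray:
    sym = 0.5 * (m + m.T)
    scale = max(float(np.max(np.abs(np.diag(sym)))), 1e-300)
    jitter = 0.0
    for i in range(max_tries):
        try:
            np.linalg.cholesky(sym + jitter * np.eye(len(sym)))
            return sym + jitter * np.eye(len(sym))
        except np.linalg.LinAlgError:
            jitter = scale * 10.0 ** (i - 12)
    raise np.linalg.LinAlgError("design posterior covariance is not repairable to SPD")


def pair_features(pair) -> np.ndarray:
    """Regressor difference vector (dG, dD, d(G*D)) for a left-vs-right pair."""
    g1, d1, g2, d2 = (float(v) for v in pair)
    return np.array([g1 - g2, d1 - d2, g1 * d1 - g2 * d2])


def _laplace_step(post: DesignPosterior, x: np.ndarray, y: int):
    prec = np.linalg.inv(post.cov)
    z = x / post.temperature
    p = float(expit(z @ post.mean))
    grad = -z * (y - p)  # gradient of the negative log posterior at the mean
    hess = prec + p * (1.0 - p) * np.outer(z, z)
    cov = _ensure_spd(np.linalg.inv(hess))
    mean = post.mean - cov @ grad
    return mean, cov, p


def update_posterior(post: DesignPosterior, pair, choice: int) -> DesignPosterior:
    """One Newton/Laplace refresh after observing ``choice`` (1 = first/left
    option) on the given pair."""
    mean, cov, _ = _laplace_step(post, pair_features(pair), int(choice))
    # re-evaluate curvature at the stepped mean for a better local Laplace fit
    z = pair_features(pair) / post.temperature
    p2 = float(expit(z @ mean))
    hess = np.linalg.inv(post.cov) + p2 * (1.0 - p2) * np.outer(z, z)
    return replace(post, mean=mean, cov=_ensure_spd(np.linalg.inv(hess)))


def expected_posterior_trace(post: DesignPosterior, pair) -> float:
    """One-step preposterior A-optimality score: the expected trace of the
    updated covariance, averaging the two choice outcomes under the current
    predictive probability."""
    x = pair_features(pair)
    z = x / post.temperature
    p_pred = float(expit(z @ post.mean))
    prec = np.linalg.inv(post.cov)
    total = 0.0
    for y, w in ((1, p_pred), (0, 1.0 - p_pred)):
        if w <= 0.0:
            continue
        mean, _, _ = _laplace_step(post, x, y)
        p2 = float(expit(z @ mean))
        hess = prec + p2 * (1.0 - p2) * np.outer(z, z)
        total += w * float(np.trace(np.linalg.inv(hess)))
    return total


def one_dimension_candidates(
    previous_pair, vary: str, amounts: np.ndarray, seen: set | None = None
) -> np.ndarray:
    """Informative pairs differing from ``previous_pair`` only on one
    dimension (the other dimension's two amounts are carried over)."""
    g1, d1, g2, d2 = (float(v) for v in previous_pair)
    rows = []
    if vary == "gain":
        lo, hi = sorted((d1, d2))
        for a in amounts:
            for b in amounts:
                if a == b:
                    continue
                # crossed: lower gain goes with the higher donation
                cand = (min(a, b), hi, max(a, b), lo)
                rows.append(cand)
    elif vary == "donation":
        lo, hi = sorted((g1, g2))
        for a in amounts:
            for b in amounts:
                if a == b:
                    continue
                cand = (lo, max(a, b), hi, min(a, b))
                rows.append(cand)
    else:
        raise ValueError("vary must be 'gain' or 'donation'")
    uniq = sorted(set(rows))
    if seen:
        uniq = [r for r in uniq if r not in seen]
    return np.array(uniq) if uniq else np.empty((0, 4))


def select_next_pair(
    post: DesignPosterior, candidates: np.ndarray, rng=None
) -> tuple[np.ndarray, float]:
    """A-optimal greedy selection among candidate pairs.

    Returns the candidate minimizing the expected post-update trace and that
    trace; exact ties are broken uniformly at random (seeded via ``rng``).
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    scores = np.array([expected_posterior_trace(post, c) for c in candidates])
    best = np.flatnonzero(np.isclose(scores, scores.min(), rtol=1e-12, atol=0.0))
    pick = best[0] if rng is None or len(best) == 1 else rng.choice(best)
    return candidates[pick], float(scores[pick])


def run_adaptive_session(
    n_trials: int,
    responder,
    rng,
    step: float = 1.0,
    posterior: DesignPosterior | None = None,
    candidate_step: float = 5.0,
) -> pd.DataFrame:
    """Run an online A-optimal choice session.

    ``responder(pair) -> 1 or 0`` supplies the simulated (or real) choice.
    The first pair is drawn at random from the informative set on the
    candidate grid; afterwards the varied dimension alternates between gain
    and donation.  Candidate amounts are subsampled to ``candidate_step``
    euros for tractability (set equal to ``step`` for the full grid).
    """
    post = posterior or DesignPosterior.default()
    amounts = np.arange(0.0, 100.0 + candidate_step / 2, candidate_step)
    seen: set[tuple] = set()
    records = []
    pair = None
    for t in range(1, n_trials + 1):
        if pair is None:
            lo_g, hi_g = sorted(rng.choice(amounts, size=2, replace=False))
            lo_d, hi_d = sorted(rng.choice(amounts, size=2, replace=False))
            pair = np.array([lo_g, hi_d, hi_g, lo_d])
            score = expected_posterior_trace(post, pair)
        else:
            vary = "gain" if t % 2 == 0 else "donation"
            cands = one_dimension_candidates(pair, vary, amounts, seen)
            if len(cands) == 0:
                cands = one_dimension_candidates(
                    pair, "donation" if vary == "gain" else "gain", amounts, seen
                )
            pair, score = select_next_pair(post, cands, rng)
        seen.add(tuple(pair))
        y = int(responder(pair))
        post = update_posterior(post, pair, y)
        records.append(
            {
                "trial": t,
                "gain_left": pair[0],
                "donation_left": pair[1],
                "gain_right": pair[2],
                "donation_right": pair[3],
                "response": y,
                "expected_trace": score,
                "posterior_trace": post.trace,
            }
        )
    return pd.DataFrame(records)


@dataclass
class ConvergenceTrace:
    """Per-trial estimation-precision trace and its 5% convergence point."""

    trials: np.ndarray  # trial numbers the sigmas correspond to
    sigma: np.ndarray  # mean posterior variance after each trial
    gamma: np.ndarray  # relative precision gain, defined from the 2nd entry
    threshold_trial: int  # last trial with gamma above the threshold
    threshold: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trials,
                "sigma": self.sigma,
                "gamma": np.concatenate([[np.nan], self.gamma]),
            }
        )


def convergence_trace(sigma, trials=None, threshold: float = 0.05) -> ConvergenceTrace:
    """Relative per-trial precision gain ``gamma_t = (s_{t-1}-s_t)/s_{t-1}``.

    The convergence point is the last trial whose gain exceeds the threshold
    (trial 1 if none does — estimation never improved by more than the
    threshold).
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.size < 2:
        raise ValueError("need at least two sigma values")
    if np.any(sigma <= 0):
        raise ValueError("sigma values must be positive")
    trials = np.arange(1, sigma.size + 1) if trials is None else np.asarray(trials)
    gamma = (sigma[:-1] - sigma[1:]) / sigma[:-1]
    above = np.flatnonzero(gamma > threshold)
    threshold_trial = int(trials[above[-1] + 1]) if above.size else int(trials[0])
    return ConvergenceTrace(
        trials=trials, sigma=sigma, gamma=gamma, threshold_trial=threshold_trial,
        threshold=threshold,
    )


def _is_choice_frame(trials: pd.DataFrame) -> bool:
    return "gain_right" in trials.columns and trials["gain_right"].notna().any()


def trial_information(trials: pd.DataFrame, results) -> np.ndarray:
    """Per-trial Fisher information contributions (k x k per trial) for all
    free parameters of a fitted model, evaluated at its MAP estimate.

    Gaussian tasks use ``(1/sd^2) * dmu dmu'`` plus the constant curvature 2
    of the log-noise-SD coordinate; choice uses the Bernoulli information
    ``(dp dp') / (p(1-p))``.
    """
    src = results.model
    model = ValueTaskModel(
        trials, src.spec, src.task, prior=src.prior,
        task_config=src.task_config, fixed=src.fixed,
    )
    theta = results.theta
    k = len(theta)
    eps = 1e-5
    grads = []
    for j in range(k):
        hi, lo = theta.copy(), theta.copy()
        hi[j] += eps
        lo[j] -= eps
        grads.append((model.predict(hi) - model.predict(lo)) / (2 * eps))
    G = np.column_stack(grads)  # trials x k
    if model.task == "choice":
        p = np.clip(model.predict(theta), 1e-6, 1 - 1e-6)
        w = 1.0 / (p * (1.0 - p))
        return np.einsum("t,ti,tj->tij", w, G, G)
    sd = results.params.get("noise_sd", 1.0)
    infos = np.einsum("ti,tj->tij", G, G) / sd**2
    labels = model.param_labels
    if "noise_sd" in labels:
        j = labels.index("noise_sd")
        infos[:, j, j] += 2.0  # Gaussian curvature of the log-SD coordinate
    return infos


def information_sigma_trace(
    trials: pd.DataFrame,
    results,
    prior_var=None,
    value_params_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-variance decay from accumulated per-trial Fisher information.

    Evaluated post-hoc at the subject's full-data MAP estimate: the posterior
    precision after t trials is the prior precision plus the summed
    information of trials 1..t, so sigma decays deterministically and
    smoothly, and the decay rate directly measures how informative each
    successive trial was under the given ordering.
    """
    infos = trial_information(trials, results)
    k = infos.shape[1]
    if value_params_only:
        spec_names = results.model.spec.param_names
        idx = [i for i, l in enumerate(results.model.param_labels) if l in spec_names]
    else:
        idx = list(range(k))
    if prior_var is None:
        prior_var = results.model._prior_var_vec
    prec = np.diag(1.0 / np.broadcast_to(np.asarray(prior_var, dtype=float), (k,)))
    sigmas = []
    for t in range(len(infos)):
        prec = prec + infos[t]
        cov = np.linalg.inv(_ensure_spd(prec))
        sigmas.append(float(np.mean(np.diag(cov)[idx])))
    return np.arange(1, len(infos) + 1), np.array(sigmas)


def optimized_order(
    trials: pd.DataFrame,
    results=None,
    noise_sd: float = 1.0,
    posterior: DesignPosterior | None = None,
    prior_var=None,
    rng=None,
    coverage_amounts=COVERAGE_AMOUNTS,
) -> pd.DataFrame:
    """Reorder one subject's trials by informativeness.

    The first eleven trials are drawn (seeded random order) from offers whose
    amounts lie in the coverage set on both dimensions; the remaining trials
    are appended greedily, each minimizing the posterior-covariance trace
    given the trials already placed.

    If ``results`` (a fitted `ValueTaskResults`) is supplied, informativeness
    is each trial's Fisher information for the fitted value parameters at the
    MAP estimate — the natural post-hoc notion when the order is derived
    after fitting.  Otherwise the a-priori linear-interaction value model is
    used: the exact Gaussian posterior for single-offer trials (with
    ``noise_sd``), the logistic preposterior for choice pairs.
    """
    rng = rng or np.random.default_rng(0)
    trials = trials.reset_index(drop=True)
    is_choice = _is_choice_frame(trials)
    cov_set = set(float(a) for a in coverage_amounts)

    if is_choice:
        cols = ["gain_left", "donation_left", "gain_right", "donation_right"]
        eligible = [
            i
            for i in range(len(trials))
            if set(trials.loc[i, cols].astype(float)) <= cov_set
        ]
    else:
        g = trials["gain_left"].to_numpy(dtype=float)
        d = trials["donation_left"].to_numpy(dtype=float)
        eligible = [i for i in range(len(trials)) if g[i] in cov_set and d[i] in cov_set]

    if results is not None:
        infos = trial_information(trials, results)
        k = infos.shape[1]
        if prior_var is None:
            prior_var = results.model._prior_var_vec
        prec0 = np.diag(1.0 / np.broadcast_to(np.asarray(prior_var, dtype=float), (k,)))
        absorb_h = lambda i, prec: prec + infos[i]
    else:
        post = posterior or DesignPosterior.default()
        if is_choice:
            feats = np.array(
                [
                    pair_features(r)
                    for r in trials[
                        ["gain_left", "donation_left", "gain_right", "donation_right"]
                    ].to_numpy()
                ]
            )
            z = feats / post.temperature
            p = np.clip(expit(z @ post.mean), 1e-6, 1 - 1e-6)
            infos = np.einsum("t,ti,tj->tij", p * (1 - p), z, z)
        else:
            g = trials["gain_left"].to_numpy(dtype=float)
            d = trials["donation_left"].to_numpy(dtype=float)
            feats = np.column_stack([g, d, g * d])
            infos = np.einsum("ti,tj->tij", feats, feats) / noise_sd**2
        prec0 = np.linalg.inv(post.cov)
        absorb_h = lambda i, prec: prec + infos[i]

    n_lead = min(11, len(eligible))
    if n_lead < 11:
        logger.warning(
            "only %d trials eligible for the coverage-based lead-in (11 requested)",
            n_lead,
        )
    lead = list(rng.permutation(eligible)[:n_lead])
    remaining = [i for i in range(len(trials)) if i not in set(lead)]

    prec = prec0
    order = []
    for i in lead:
        order.append(i)
        prec = absorb_h(i, prec)
    while remaining:
        scores = np.array(
            [float(np.trace(np.linalg.inv(absorb_h(i, prec)))) for i in remaining]
        )
        best = np.flatnonzero(np.isclose(scores, scores.min(), rtol=1e-12, atol=0.0))
        pick = remaining[best[0] if len(best) == 1 else rng.choice(best)]
        order.append(pick)
        prec = absorb_h(pick, prec)
        remaining.remove(pick)
    out = trials.iloc[order].reset_index(drop=True)
    out["trial"] = np.arange(1, len(out) + 1)
    return out


def sequential_sigma_trace(
    trials: pd.DataFrame,
    value_spec="ces",
    task: str = "rating",
    prior: PriorSpec | None = None,
    value_params_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean posterior variance from sequential Laplace updating, one trial at
    a time.

    Starting from the Gaussian prior, each trial contributes its local
    curvature (projected to be positive semi-definite) to the posterior
    precision and shifts the mean by one damped Newton step.  Because
    precision only accumulates, the resulting sigma series decays smoothly,
    which makes the relative-gain convergence measure well behaved; the decay
    rate directly reflects how informative each successive trial is.

    Returns ``(trial_numbers, sigma)``; sigma is the mean posterior variance
    over the value-function parameters (all parameters if
    ``value_params_only`` is False).
    """
    from statsmodels.tools.numdiff import approx_fprime, approx_hess

    prior = prior or PriorSpec()
    full = ValueTaskModel(trials, value_spec, task, prior=prior)
    k = full.k_params
    if value_params_only:
        idx = [
            i
            for i, p in enumerate(full.free_params)
            if p.label in full.spec.param_names
        ]
    else:
        idx = list(range(k))
    mean = full._prior_mean_vec.copy()
    prec = np.diag(1.0 / full._prior_var_vec)
    sigmas, ts = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in range(1, len(trials) + 1):
            one = ValueTaskModel(trials.iloc[t - 1 : t], value_spec, task, prior=prior)
            nll = lambda th: -one.loglike(th)
            grad = approx_fprime(mean, nll)
            hess = 0.5 * (approx_hess(mean, nll) + approx_hess(mean, nll).T)
            w, v = np.linalg.eigh(hess)
            hess_psd = (v * np.clip(w, 0.0, None)) @ v.T
            prec = prec + hess_psd
            cov = np.linalg.inv(_ensure_spd(prec))
            step = cov @ grad
            norm = float(np.linalg.norm(step))
            if norm > 2.0:  # damp occasional unstable Newton steps
                step *= 2.0 / norm
            mean = mean - step
            sigmas.append(float(np.mean(np.diag(cov)[idx])))
            ts.append(t)
    return np.array(ts), np.array(sigmas)


def incremental_sigma_trace(
    trials: pd.DataFrame,
    value_spec="ces",
    task: str = "rating",
    prior: PriorSpec | None = None,
    fit_kwargs: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean posterior variance from incremental refits with trials 1..t.

    Refits start once the observation count reaches the parameter count and
    are warm-started from the previous MAP estimate for speed.  Returns
    ``(trial_numbers, sigma)`` where sigma is the mean posterior variance
    over the value-function parameters (unconstrained scale); the nuisance
    observation parameters are excluded so the trace measures how precisely
    the value function itself is pinned down.
    """
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_restarts", 0)  # warm start only, after the first fit
    prior = prior or PriorSpec()
    probe = ValueTaskModel(trials, value_spec, task, prior=prior)
    k = probe.k_params
    value_labels = [
        p.label for p in probe.free_params if p.label in probe.spec.param_names
    ]
    t0 = max(k, 2)
    sigmas, ts = [], []
    warm = None
    for t in range(t0, len(trials) + 1):
        model = ValueTaskModel(trials.iloc[:t], value_spec, task, prior=prior)
        kw = dict(fit_kwargs) if warm is not None else {**fit_kwargs, "n_restarts": 2}
        res = model.fit(start_values=warm, **kw)
        warm = res.theta
        sigmas.append(res.mean_posterior_variance_of(value_labels))
        ts.append(t)
    return np.array(ts), np.array(sigmas)
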