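"""MAP fitting of (value function x observation model) pairs, with Laplace
model evidence.

The central objects follow the statsmodels idiom: a model is built from one
subject's trial data for one task (`ValueTaskModel`, or `SharedParameterModel`
for pooled three-task fits with tied parameters) and its ``fit()`` returns a
results object carrying the MAP estimate in native and unconstrained space,
the posterior covariance, the Laplace approximation to the log model
evidence, and explained variance.

All inference happens on the unconstrained scale of each parameter (logistic
for unit-interval parameters, log for positive ones), under independent
Gaussian priors.  The Laplace free energy is

    log p(y | m)  ~=  log p(y, theta* | m) + (k/2) log 2 pi
                      + (1/2) log det Sigma_post

with theta* the MAP estimate and Sigma_post the inverse Hessian of the
negative log joint at theta*.  For linear-Gaussian problems this is exact,
which the test suite exploits as an oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

from .observation import TASKS, TaskConfig
from .value_models import (
    IDENTITY,
    LOG,
    Parameter,
    Transform,
    ValueFunctionSpec,
    get_spec,
)

__all__ = [
    "PriorSpec",
    "FitError",
    "ValueTaskModel",
    "SharedParameterModel",
    "ValueTaskResults",
    "FitResult",
    "fit_map",
    "sharing_partitions",
    "partition_label",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian priors on the unconstrained parameters.

    ``mean``/``var`` apply to every parameter not listed in ``overrides``
    (a mapping of parameter name to a (mean, variance) pair).  Parameters
    living on the response scale — the rating/force intercept in particular —
    get a scale-aware default override from the model builder, since a unit
    variance-3 prior would be absurdly tight for an intercept of tens of
    response units.
    """

    mean: float = 0.0
    var: float = 3.0
    overrides: tuple = ()  # ((name, (mean, var)), ...); tuple keeps it hashable

    def __post_init__(self):
        if self.var <= 0:
            raise ValueError("prior variance must be positive")
        for _, (_, v) in self.overrides:
            if v <= 0:
                raise ValueError("prior variance must be positive")

    def moments_for(self, names, defaults: dict | None = None):
        """Per-parameter (mean, var) vectors for the given base names.

        ``defaults`` supplies model-derived overrides (e.g. the response
        scale of the intercept); explicit ``overrides`` take precedence.
        """
        explicit = dict(self.overrides)
        defaults = defaults or {}
        means, variances = [], []
        for name in names:
            m, v = explicit.get(name, defaults.get(name, (self.mean, self.var)))
            means.append(m)
            variances.append(v)
        return np.array(means), np.array(variances)

    def logpdf(self, theta: np.ndarray) -> float:
        z = (theta - self.mean) ** 2 / self.var
        return float(-0.5 * np.sum(z + _LOG2PI + np.log(self.var)))


class FitError(RuntimeError):
    """All optimization restarts failed; carries the best diagnostics seen."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class _FreeParam:
    label: str
    transform: Transform


def _obs_params(task: str) -> tuple[Parameter, ...]:
    if task == "choice":
        return (Parameter("temperature", LOG, "softmax temperature"),)
    if task in ("rating", "force"):
        return (
            Parameter("slope", IDENTITY, "response units per utility unit"),
            Parameter("intercept", IDENTITY, "response units"),
            Parameter("noise_sd", LOG, "response noise SD"),
        )
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def _repair_spd(matrix: np.ndarray, max_tries: int = 12) -> np.ndarray:
    """Symmetrize and, if needed, add a growing diagonal jitter until the
    matrix admits a Cholesky factorization."""
    sym = 0.5 * (matrix + matrix.T)
    scale = max(float(np.max(np.abs(np.diag(sym)))), 1e-12)
    jitter = 0.0
    for i in range(max_tries):
        try:
            np.linalg.cholesky(sym + jitter * np.eye(len(sym)))
            return sym + jitter * np.eye(len(sym))
        except np.linalg.LinAlgError:
            jitter = scale * 10.0 ** (i - 10)
    raise np.linalg.LinAlgError("posterior covariance could not be repaired to SPD")


class _BaseMAPModel:
    """Shared multistart-MAP / Laplace machinery.

    Subclasses define ``free_params`` (ordered list of `_FreeParam`) and
    ``loglike(theta)`` on the unconstrained vector, plus prediction helpers.
    """

    free_params: list[_FreeParam]
    prior: PriorSpec

    @property
    def k_params(self) -> int:
        return len(self.free_params)

    @property
    def param_labels(self) -> list[str]:
        return [p.label for p in self.free_params]

    def loglike(self, theta: np.ndarray) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    # large finite penalty instead of -inf keeps finite-difference gradients
    # well defined on the infeasible plateau
    _PENALTY = -1e12

    def _init_prior(self, defaults: dict | None = None, names=None) -> None:
        names = names if names is not None else [p.label for p in self.free_params]
        self._prior_mean_vec, self._prior_var_vec = self.prior.moments_for(
            names, defaults
        )

    def prior_logpdf(self, theta: np.ndarray) -> float:
        z = (theta - self._prior_mean_vec) ** 2 / self._prior_var_vec
        return float(-0.5 * np.sum(z + _LOG2PI + np.log(self._prior_var_vec)))

    def log_joint(self, theta: np.ndarray) -> float:
        """Unnormalized log posterior: log-likelihood plus log-prior."""
        theta = np.asarray(theta, dtype=float)
        ll = self.loglike(theta)
        if not np.isfinite(ll):
            return self._PENALTY
        lj = ll + self.prior_logpdf(theta)
        return lj if np.isfinite(lj) else self._PENALTY

    def to_native(self, theta: np.ndarray) -> dict[str, float]:
        return {
            p.label: float(p.transform.to_native(t))
            for p, t in zip(self.free_params, theta)
        }

    def initial_start(self) -> np.ndarray:
        """Default starting point; subclasses may moment-match the data."""
        return self._prior_mean_vec.copy()

    def _starts(self, n_restarts: int, seed, start_values) -> list[np.ndarray]:
        starts = []
        if start_values is not None:
            starts.append(np.asarray(start_values, dtype=float))
        anchor = self.initial_start()
        if n_restarts >= 1 or not starts:
            starts.append(anchor)
        rng = np.random.default_rng(seed)
        # perturbation capped at the base prior SD so wide response-scale
        # priors do not throw restarts into absurd regions
        sd = np.minimum(np.sqrt(self._prior_var_vec), np.sqrt(self.prior.var))
        while len(starts) < n_restarts + (start_values is not None):
            starts.append(anchor + rng.normal(0.0, 0.5, size=self.k_params) * sd)
        return starts

    def fit(
        self,
        n_restarts: int = 8,
        seed: int | None = 0,
        start_values=None,
        maxiter: int = 500,
    ) -> "ValueTaskResults":
        """Multistart quasi-Newton MAP fit with Laplace evidence.

        Restarts draw their initial points from the prior (plus the prior
        mean, plus an optional warm start); ties between converged restarts
        are broken by the higher log joint, then by the smaller parameter
        norm.
        """
        if self.nobs < self.k_params:
            raise ValueError(
                f"need at least as many observations ({self.nobs}) as free "
                f"parameters ({self.k_params})"
            )
        neg = lambda th: -self.log_joint(th)
        best = None
        diagnostics = []
        for x0 in self._starts(n_restarts, seed, start_values):
            try:
                res = minimize(
                    neg,
                    x0,
                    method="L-BFGS-B",
                    options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
                )
            except (FloatingPointError, OverflowError) as exc:
                diagnostics.append(str(exc))
                continue
            diagnostics.append((res.status, res.message, -res.fun))
            if not np.isfinite(res.fun) or -res.fun <= self._PENALTY:
                continue
            cand = (float(-res.fun), -float(np.linalg.norm(res.x)), res)
            if best is None or cand[:2] > best[:2]:
                best = cand
        if best is None:
            raise FitError("all optimization restarts failed", diagnostics)
        lj, _, res = best
        theta = res.x
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(theta, neg)
        try:
            cov = _repair_spd(np.linalg.inv(_repair_spd(hess)))
        except np.linalg.LinAlgError:
            cov = _repair_spd(np.linalg.pinv(0.5 * (hess + hess.T)))
        k = self.k_params
        sign, logdet = np.linalg.slogdet(cov)
        log_evidence = lj + 0.5 * k * _LOG2PI + 0.5 * logdet
        return ValueTaskResults(
            model=self,
            theta=theta,
            cov=cov,
            log_joint_value=lj,
            log_evidence=float(log_evidence),
            converged=bool(res.success),
            n_restarts=n_restarts,
        )


class ValueTaskModel(_BaseMAPModel):
    """One subject's data for one task, under one candidate value function.

    Parameters
    ----------
    data : DataFrame with the trial-table columns for a single task
        (``gain_left``/``donation_left`` plus, for choice, the right-hand
        offer; ``response`` is the rating, the force percentage, or 1/0 for a
        left/right choice).
    value_spec : value-function id, name or `ValueFunctionSpec`.
    task : 'force' | 'rating' | 'choice'.
    fixed : optional mapping of parameter name to a fixed native value
        (value or observation parameters), removed from the free vector.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        value_spec: ValueFunctionSpec | str | int,
        task: str,
        prior: PriorSpec | None = None,
        task_config: TaskConfig | None = None,
        fixed: dict[str, float] | None = None,
    ):
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}")
        self.spec = value_spec if isinstance(value_spec, ValueFunctionSpec) else get_spec(value_spec)
        self.task = task
        self.prior = prior or PriorSpec()
        self.task_config = task_config or TaskConfig()
        self.fixed = dict(fixed or {})
        self.data = data.reset_index(drop=True)

        self._gl = self.data["gain_left"].to_numpy(dtype=float)
        self._dl = self.data["donation_left"].to_numpy(dtype=float)
        self._y = self.data["response"].to_numpy(dtype=float)
        if task == "choice":
            self._gr = self.data["gain_right"].to_numpy(dtype=float)
            self._dr = self.data["donation_right"].to_numpy(dtype=float)
            if not np.all(np.isin(self._y, (0.0, 1.0))):
                raise ValueError("choice responses must be 1 (left) or 0 (right)")

        all_params = list(self.spec.parameters) + list(_obs_params(task))
        names = [p.name for p in all_params]
        unknown = set(self.fixed) - set(names)
        if unknown:
            raise ValueError(f"fixed parameters not in model: {sorted(unknown)}")
        self._value_names = self.spec.param_names
        self._all_params = all_params
        self.free_params = [
            _FreeParam(p.name, p.transform) for p in all_params if p.name not in self.fixed
        ]
        # scale-aware prior for the intercept, which lives on the response
        # scale (tens of units for force); the generic unit-scale prior
        # would otherwise dominate the likelihood
        defaults = {}
        if task in ("rating", "force"):
            lo, hi = self.task_config.bounds(task)
            defaults["intercept"] = (0.0, float((hi - lo) ** 2))
        self._init_prior(defaults)

    @classmethod
    def from_dataframe(cls, data, value_spec, task, **kwargs):
        """Build the model from a (possibly multi-task) trial table; rows of
        other tasks are dropped."""
        if "task" in data.columns:
            data = data[data["task"] == task]
        return cls(data, value_spec, task, **kwargs)

    @property
    def nobs(self) -> int:
        return len(self.data)

    def initial_start(self) -> np.ndarray:
        """Moment-matched start: value parameters at the prior mean, the
        observation parameters set by regressing responses on the
        prior-mean utilities.

        This keeps the optimizer's anchor inside the response bounds, where
        the clipped-mean likelihood has informative gradients (a zero
        slope/intercept start predicts at the clip boundary, where the
        surface is locally flat).
        """
        theta = self._prior_mean_vec.copy()
        labels = self.param_labels
        value, _ = self._unpack(theta)
        with np.errstate(all="ignore"):
            v = self.spec.fn(value, self._gl, self._dl)
        if not np.all(np.isfinite(v)) or self.nobs == 0:
            return theta

        def set_if_free(name, unconstrained_value):
            if name in labels and np.isfinite(unconstrained_value):
                theta[labels.index(name)] = unconstrained_value

        if self.task == "choice":
            dv = v - self.spec.fn(value, self._gr, self._dr)
            scale = float(np.std(dv))
            if scale > 0:
                set_if_free("temperature", np.log(scale))
            return theta
        y = self._y
        v_sd = float(np.std(v))
        if v_sd > 0:
            slope = float(np.cov(v, y)[0, 1] / v_sd**2)
        else:
            slope = 0.0
        intercept = float(np.mean(y) - slope * np.mean(v))
        resid_sd = float(np.std(y - (slope * v + intercept)))
        set_if_free("slope", slope)
        set_if_free("intercept", intercept)
        set_if_free("noise_sd", np.log(max(resid_sd, 1e-2)))
        return theta

    def _unpack(self, theta: np.ndarray) -> tuple[dict, dict]:
        full = dict(self.fixed)
        it = iter(theta)
        for p in self._all_params:
            if p.name not in self.fixed:
                full[p.name] = float(p.transform.to_native(next(it)))
        value = {n: full[n] for n in self._value_names}
        obs = {p.name: full[p.name] for p in _obs_params(self.task)}
        return value, obs

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """Model prediction per trial: expected response (rating/force) or
        probability of choosing left (choice)."""
        value, obs = self._unpack(np.asarray(theta, dtype=float))
        v = self.spec.fn(value, self._gl, self._dl)
        if self.task == "choice":
            vr = self.spec.fn(value, self._gr, self._dr)
            return expit((v - vr) / obs["temperature"])
        lo, hi = self.task_config.bounds(self.task)
        return np.clip(obs["slope"] * v + obs["intercept"], lo, hi)

    def _loglike_terms(self, theta: np.ndarray) -> np.ndarray:
        value, obs = self._unpack(theta)
        if self.task == "choice":
            vl = self.spec.fn(value, self._gl, self._dl)
            vr = self.spec.fn(value, self._gr, self._dr)
            dv = (vl - vr) / obs["temperature"]
            # log p(left) = -log(1+e^-dv); log p(right) = -log(1+e^dv)
            return -(self._y * np.logaddexp(0.0, -dv) + (1.0 - self._y) * np.logaddexp(0.0, dv))
        mu = self.predict(theta)
        sd = obs["noise_sd"]
        return -0.5 * (((self._y - mu) / sd) ** 2 + _LOG2PI) - np.log(sd)

    def loglike(self, theta: np.ndarray) -> float:
        with np.errstate(all="ignore"):
            terms = self._loglike_terms(np.asarray(theta, dtype=float))
        return float(np.sum(terms))

    def log_joint(self, theta: np.ndarray, validate: bool = False) -> float:
        if validate:
            with np.errstate(all="ignore"):
                terms = self._loglike_terms(np.asarray(theta, dtype=float))
            bad = np.flatnonzero(~np.isfinite(terms))
            if bad.size:
                raise FloatingPointError(
                    f"non-finite likelihood at trial index {int(bad[0])} "
                    f"(task {self.task}, {bad.size} offending trials)"
                )
        return super().log_joint(theta)


class SharedParameterModel(_BaseMAPModel):
    """Pooled three-task fit with one named value parameter tied across tasks
    according to a partition.

    For the tied role (e.g. CES ``alpha``) one free parameter is created per
    partition class; every other value parameter and all observation
    parameters remain task-specific.  The joint likelihood is the sum of the
    per-task likelihoods.
    """

    def __init__(
        self,
        data_by_task: dict[str, pd.DataFrame],
        value_spec,
        role: str,
        partition: tuple[frozenset, ...],
        prior: PriorSpec | None = None,
        task_config: TaskConfig | None = None,
    ):
        spec = value_spec if isinstance(value_spec, ValueFunctionSpec) else get_spec(value_spec)
        if role not in spec.param_names:
            raise ValueError(f"role {role!r} is not a parameter of {spec.name}")
        tasks = sorted(data_by_task)
        if len(tasks) < 2:
            raise ValueError("shared-parameter fitting requires at least two tasks")
        covered = sorted(t for cls in partition for t in cls)
        if covered != tasks or sum(len(c) for c in partition) != len(tasks):
            raise ValueError(f"partition {partition} does not partition tasks {tasks}")
        self.spec = spec
        self.role = role
        self.partition = tuple(frozenset(c) for c in partition)
        self.prior = prior or PriorSpec()
        self.tasks = tasks
        self._sub = {
            t: ValueTaskModel(df, spec, t, prior=self.prior, task_config=task_config)
            for t, df in data_by_task.items()
        }

        role_tf = next(p.transform for p in spec.parameters if p.name == role)
        self.free_params = []
        self._role_slot: dict[str, int] = {}
        for cls in self.partition:
            label = f"{role}[{'+'.join(sorted(cls))}]"
            idx = len(self.free_params)
            self.free_params.append(_FreeParam(label, role_tf))
            for t in cls:
                self._role_slot[t] = idx
        self._task_slots: dict[str, list[int]] = {}
        for t in tasks:
            slots = []
            for p in self._sub[t].free_params:
                if p.label == role:
                    slots.append(self._role_slot[t])
                else:
                    slots.append(len(self.free_params))
                    self.free_params.append(_FreeParam(f"{p.label}[{t}]", p.transform))
            self._task_slots[t] = slots
        # inherit each slot's prior moments from the owning sub-model
        mean_vec = np.full(self.k_params, self.prior.mean)
        var_vec = np.full(self.k_params, self.prior.var)
        for t in self.tasks:
            sub = self._sub[t]
            for j, slot in enumerate(self._task_slots[t]):
                mean_vec[slot] = sub._prior_mean_vec[j]
                var_vec[slot] = sub._prior_var_vec[j]
        self._prior_mean_vec, self._prior_var_vec = mean_vec, var_vec

    @property
    def nobs(self) -> int:
        return sum(m.nobs for m in self._sub.values())

    def initial_start(self) -> np.ndarray:
        theta = np.zeros(self.k_params)
        counts = np.zeros(self.k_params)
        for t in self.tasks:
            sub_theta = self._sub[t].initial_start()
            for val, slot in zip(sub_theta, self._task_slots[t]):
                theta[slot] += val
                counts[slot] += 1
        counts[counts == 0] = 1
        return theta / counts

    def assemble_start(self, task_results: dict[str, "ValueTaskResults"]) -> np.ndarray:
        """Build a warm start from independent per-task fits: tied-role slots
        take the mean unconstrained estimate over their class, task-specific
        slots copy the task's own estimate."""
        theta = np.zeros(self.k_params)
        counts = np.zeros(self.k_params)
        for t in self.tasks:
            res = task_results[t]
            labels = res.model.param_labels
            for label, slot in zip(labels, self._task_slots[t]):
                theta[slot] += res.theta[labels.index(label)]
                counts[slot] += 1
        counts[counts == 0] = 1
        return theta / counts

    def task_theta(self, task: str, theta: np.ndarray) -> np.ndarray:
        return np.asarray(theta, dtype=float)[self._task_slots[task]]

    def loglike(self, theta: np.ndarray) -> float:
        return sum(m.loglike(self.task_theta(t, theta)) for t, m in self._sub.items())

    def predict(self, theta):
        return {t: m.predict(self.task_theta(t, theta)) for t, m in self._sub.items()}


class ValueTaskResults:
    """MAP fit results: estimates, posterior covariance, Laplace evidence.

    Attributes
    ----------
    params : dict of native-space estimates keyed by parameter label.
    theta : MAP estimate on the unconstrained scale.
    cov_params : posterior covariance (unconstrained scale), as a DataFrame.
    log_evidence : Laplace free-energy approximation to log p(data | model).
    """

    def __init__(self, model, theta, cov, log_joint_value, log_evidence, converged, n_restarts):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self._cov = np.asarray(cov, dtype=float)
        self.log_joint_value = float(log_joint_value)
        self.log_evidence = float(log_evidence)
        self.converged = converged
        self.n_restarts = n_restarts
        self.params = model.to_native(self.theta)
        self.nobs = model.nobs

    @property
    def cov_params(self) -> pd.DataFrame:
        labels = self.model.param_labels
        return pd.DataFrame(self._cov, index=labels, columns=labels)

    @property
    def bse(self) -> pd.Series:
        """Posterior SDs on the unconstrained scale."""
        return pd.Series(np.sqrt(np.diag(self._cov)), index=self.model.param_labels)

    @property
    def mean_posterior_variance(self) -> float:
        """Mean posterior variance over all parameters (unconstrained scale)."""
        return float(np.mean(np.diag(self._cov)))

    def mean_posterior_variance_of(self, labels) -> float:
        """Mean posterior variance restricted to the named parameters."""
        all_labels = self.model.param_labels
        idx = [all_labels.index(l) for l in labels]
        if not idx:
            raise ValueError("no parameters selected")
        return float(np.mean(np.diag(self._cov)[idx]))

    def predict(self):
        return self.model.predict(self.theta)

    @property
    def rsquared(self) -> float:
        """Explained variance, 1 - SS_res / SS_tot.

        For rating/force this is computed on responses around the model mean;
        for choice the 0/1 outcome is compared with the predicted probability.
        Raises on zero-variance responses, where it is undefined.
        """
        model = self.model
        if isinstance(model, SharedParameterModel):
            y = np.concatenate([m._y for m in model._sub.values()])
            yhat = np.concatenate(
                [model._sub[t].predict(model.task_theta(t, self.theta)) for t in model.tasks]
            )
        else:
            y = model._y
            yhat = self.predict()
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            raise ZeroDivisionError("explained variance undefined: responses have zero variance")
        return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "theta": self.theta.tolist(),
            "param_labels": self.model.param_labels,
            "cov_params": self._cov.tolist(),
            "log_evidence": self.log_evidence,
            "rsquared": self.rsquared,
            "nobs": self.nobs,
            "converged": self.converged,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            "MAP fit summary",
            "=" * 58,
            f"observations: {self.nobs}    free parameters: {len(self.theta)}",
            f"log evidence (Laplace): {self.log_evidence:.3f}",
            f"explained variance R^2: {self.rsquared:.3f}",
            f"converged: {self.converged}",
            "-" * 58,
            f"{'parameter':<28}{'estimate':>12}{'post. SD*':>12}",
        ]
        bse = self.bse
        for label in self.model.param_labels:
            lines.append(f"{label:<28}{self.params[label]:>12.4f}{bse[label]:>12.4f}")
        lines.append("-" * 58)
        lines.append("* posterior SD on the unconstrained (transformed) scale")
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ValueTaskResults nobs={self.nobs} k={len(self.theta)} "
            f"log_evidence={self.log_evidence:.2f}>"
        )


FitResult = ValueTaskResults


def fit_map(data, value_spec, task, prior=None, **fit_kwargs) -> ValueTaskResults:
    """Convenience wrapper: build a `ValueTaskModel` and fit it."""
    model_kwargs = {}
    for key in ("task_config", "fixed"):
        if key in fit_kwargs:
            model_kwargs[key] = fit_kwargs.pop(key)
    return ValueTaskModel(data, value_spec, task, prior=prior, **model_kwargs).fit(**fit_kwargs)


def sharing_partitions(items: tuple[str, ...] = ("force", "rating", "choice")):
    """All set partitions of the three tasks (there are exactly 5): one fully
    shared, three pairings, one fully distinct."""
    items = tuple(items)
    if len(items) != 3:
        raise ValueError("sharing partitions are defined over exactly three tasks")
    a, b, c = items
    return (
        (frozenset((a, b, c)),),
        (frozenset((a, b)), frozenset((c,))),
        (frozenset((a, c)), frozenset((b,))),
        (frozenset((b, c)), frozenset((a,))),
        (frozenset((a,)), frozenset((b,)), frozenset((c,))),
    )


def partition_label(partition) -> str:
    return " | ".join("+".join(sorted(cls)) for cls in partition)
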