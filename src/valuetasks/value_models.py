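"""Candidate value functions for composite monetary offers.

An offer couples a gain ``G`` for the subject with a donation ``D`` for a
charity, both in euros on [0, 100].  Twelve candidate functions map an offer
to a scalar utility; they span single-dimension rules (Leontief-style ``mini``
and its ``maxi`` counterpart), additive models with optional curvature and
interaction, equity-sensitive forms (linear-equity, Fehr-Schmidt inequity
aversion), and two production functions: Cobb-Douglas and the constant
elasticity of substitution (CES) family

    V(G, D) = (alpha * G**delta + (1 - alpha) * D**delta) ** (1 / delta)

whose weight ``alpha`` ("selfishness") and exponent ``delta`` ("concavity")
are the quantities of scientific interest.  Leontief, linear and Cobb-Douglas
all arise as special or limit cases of CES.

Each free parameter carries a bijective transform between its native domain
and an unconstrained real axis, so that downstream MAP fitting and Laplace
approximations operate on an unbounded space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "Offer",
    "Parameter",
    "ParameterDomainError",
    "ValueFunctionSpec",
    "MODEL_NAMES",
    "list_model_space",
    "get_spec",
    "special_case_residual",
    "registry_json",
]


class Offer(NamedTuple):
    """A composite outcome: gain for the subject, donation for the charity."""

    gain: float
    donation: float


class ParameterDomainError(ValueError):
    """A parameter value lies outside its native domain."""


class Transform:
    """Bijection between a native parameter domain and the real line."""

    name = "identity"

    def to_unconstrained(self, value):
        return np.asarray(value, dtype=float)

    def to_native(self, value):
        return np.asarray(value, dtype=float)

    def contains(self, value) -> bool:
        return bool(np.isfinite(value))


class LogTransform(Transform):
    """Non-negative parameters; native = exp(unconstrained).

    Zero is a legal native value (it maps to an infinite unconstrained
    coordinate, so the fitter never reaches it exactly).
    """

    name = "log"

    def to_unconstrained(self, value):
        with np.errstate(divide="ignore"):
            return np.log(np.asarray(value, dtype=float))

    def to_native(self, value):
        return np.exp(np.asarray(value, dtype=float))

    def contains(self, value) -> bool:
        return bool(np.isfinite(value) and value >= 0)


class LogitTransform(Transform):
    """Parameters on the unit interval; native = logistic(unconstrained).

    The closed endpoints are valid native values (they map to infinite
    unconstrained coordinates and so are never visited by the fitter, but
    e.g. a fully selfish CES weight of exactly 1 is a legal evaluation).
    """

    name = "logistic"

    def to_unconstrained(self, value):
        return logit(np.asarray(value, dtype=float))

    def to_native(self, value):
        return expit(np.asarray(value, dtype=float))

    def contains(self, value) -> bool:
        return bool(np.isfinite(value) and 0 <= value <= 1)


IDENTITY = Transform()
LOG = LogTransform()
LOGIT = LogitTransform()


@dataclass(frozen=True)
class Parameter:
    name: str
    transform: Transform
    description: str = ""


@dataclass(frozen=True)
class ValueFunctionSpec:
    """One candidate value function: id, name, parameters and evaluation rule."""

    id: int
    name: str
    parameters: tuple[Parameter, ...]
    fn: Callable[..., np.ndarray] = field(repr=False)

    @property
    def n_params(self) -> int:
        return len(self.parameters)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def validate(self, params: dict[str, float]) -> None:
        for p in self.parameters:
            if p.name not in params:
                raise ParameterDomainError(
                    f"{self.name}: missing parameter {p.name!r}"
                )
            if not p.transform.contains(params[p.name]):
                raise ParameterDomainError(
                    f"{self.name}: parameter {p.name!r}={params[p.name]!r} "
                    f"outside native domain ({p.transform.name} transform)"
                )

    def value(self, params: dict[str, float], gain, donation) -> np.ndarray:
        """Evaluate the utility of offers; vectorized over gain/donation."""
        self.validate(params)
        g = np.asarray(gain, dtype=float)
        d = np.asarray(donation, dtype=float)
        return self.fn(params, g, d)

    def to_unconstrained(self, params: dict[str, float]) -> np.ndarray:
        self.validate(params)
        return np.array(
            [float(p.transform.to_unconstrained(params[p.name])) for p in self.parameters]
        )

    def to_native(self, theta: np.ndarray) -> dict[str, float]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"{self.name}: expected {self.n_params} unconstrained values, "
                f"got shape {theta.shape}"
            )
        return {
            p.name: float(p.transform.to_native(t))
            for p, t in zip(self.parameters, theta)
        }


def _pow(x: np.ndarray, e: float) -> np.ndarray:
    # 0**e with e > 0 is 0.0 in numpy, which is the convention adopted here.
    return np.power(x, e)


def _mini(p, g, d):
    return np.minimum(p["alpha"] * g, p["beta"] * d)


def _maxi(p, g, d):
    return np.maximum(p["alpha"] * g, p["beta"] * d)


def _linear_independent(p, g, d):
    return p["alpha"] * g + p["beta"] * d


def _similarly_nonlinear_independent(p, g, d):
    return p["alpha"] * _pow(g, p["delta"]) + p["beta"] * _pow(d, p["delta"])


def _nonlinear_independent(p, g, d):
    return p["alpha"] * _pow(g, p["delta"]) + p["beta"] * _pow(d, p["epsilon"])


def _linear_interactive(p, g, d):
    return p["alpha"] * g + p["beta"] * d + p["gamma"] * g * d


def _similarly_nonlinear_interactive(p, g, d):
    gd, dd = _pow(g, p["delta"]), _pow(d, p["delta"])
    return p["alpha"] * gd + p["beta"] * dd + p["gamma"] * gd * dd


def _nonlinear_interactive(p, g, d):
    gd, de = _pow(g, p["delta"]), _pow(d, p["epsilon"])
    return p["alpha"] * gd + p["beta"] * de + p["gamma"] * gd * de


def _linear_equity(p, g, d):
    return p["alpha"] * g + p["beta"] * d + p["gamma"] * np.abs(g - d)


def _fehr_schmidt(p, g, d):
    envy = np.maximum(d - g, 0.0)
    guilt = np.maximum(g - d, 0.0)
    return g - p["alpha"] * envy - p["beta"] * guilt


def _cobb_douglas(p, g, d):
    return _pow(g, p["delta"]) * _pow(d, 1.0 - p["delta"])


def _ces(p, g, d):
    a, delta = p["alpha"], p["delta"]
    if delta < 1e-8:
        # delta -> 0 limit is the weighted geometric mean (Cobb-Douglas form)
        return _pow(g, a) * _pow(d, 1.0 - a)
    inner = a * _pow(g, delta) + (1.0 - a) * _pow(d, delta)
    return _pow(inner, 1.0 / delta)


def _w(name):  # non-negative weight
    return Parameter(name, LOG, "non-negative weight")


def _e(name):  # positive exponent
    return Parameter(name, LOG, "positive exponent")


_SPECS: tuple[ValueFunctionSpec, ...] = (
    ValueFunctionSpec(1, "mini", (_w("alpha"), _w("beta")), _mini),
    ValueFunctionSpec(2, "maxi", (_w("alpha"), _w("beta")), _maxi),
    ValueFunctionSpec(3, "linear-independent", (_w("alpha"), _w("beta")), _linear_independent),
    ValueFunctionSpec(
        4,
        "similarly-nonlinear-independent",
        (_w("alpha"), _w("beta"), _e("delta")),
        _similarly_nonlinear_independent,
    ),
    ValueFunctionSpec(
        5,
        "nonlinear-independent",
        (_w("alpha"), _w("beta"), _e("delta"), _e("epsilon")),
        _nonlinear_independent,
    ),
    ValueFunctionSpec(
        6,
        "linear-interactive",
        (_w("alpha"), _w("beta"), Parameter("gamma", IDENTITY, "interaction weight")),
        _linear_interactive,
    ),
    ValueFunctionSpec(
        7,
        "similarly-nonlinear-interactive",
        (_w("alpha"), _w("beta"), Parameter("gamma", IDENTITY, "interaction weight"), _e("delta")),
        _similarly_nonlinear_interactive,
    ),
    ValueFunctionSpec(
        8,
        "nonlinear-interactive",
        (
            _w("alpha"),
            _w("beta"),
            Parameter("gamma", IDENTITY, "interaction weight"),
            _e("delta"),
            _e("epsilon"),
        ),
        _nonlinear_interactive,
    ),
    ValueFunctionSpec(
        9,
        "linear-equity",
        (_w("alpha"), _w("beta"), Parameter("gamma", IDENTITY, "inequity weight")),
        _linear_equity,
    ),
    ValueFunctionSpec(
        10,
        "fehr-schmidt",
        (
            Parameter("alpha", IDENTITY, "envy weight (disadvantageous inequity)"),
            Parameter("beta", IDENTITY, "guilt weight (advantageous inequity)"),
        ),
        _fehr_schmidt,
    ),
    ValueFunctionSpec(
        11,
        "cobb-douglas",
        # delta in (0,1): the implicit D-exponent 1-delta must stay positive
        # for the function to be monotone in both dimensions and finite at D=0.
        (Parameter("delta", LOGIT, "gain exponent in (0,1)"),),
        _cobb_douglas,
    ),
    ValueFunctionSpec(
        12,
        "ces",
        (
            Parameter("alpha", LOGIT, "selfishness weight in (0,1)"),
            _e("delta"),
        ),
        _ces,
    ),
)

MODEL_NAMES: tuple[str, ...] = tuple(s.name for s in _SPECS)
_BY_NAME = {s.name: s for s in _SPECS}
_BY_ID = {s.id: s for s in _SPECS}


def list_model_space() -> tuple[ValueFunctionSpec, ...]:
    """The twelve candidate value functions, in canonical order (1=mini ... 12=CES)."""
    return _SPECS


def get_spec(key: int | str) -> ValueFunctionSpec:
    """Look a spec up by integer id (1-12) or canonical name."""
    if isinstance(key, str):
        try:
            return _BY_NAME[key]
        except KeyError:
            raise KeyError(f"unknown value function {key!r}; choose from {MODEL_NAMES}")
    try:
        return _BY_ID[int(key)]
    except (KeyError, ValueError):
        raise KeyError(f"unknown value-function id {key!r}; ids run 1-12")


def special_case_residual(
    gains, donations, alpha: float, delta: float = 1.0
) -> float:
    """Sup-norm discrepancy between CES and the matched linear rule.

    At ``delta = 1`` the CES function collapses algebraically onto the
    linear-independent function with weights ``(alpha, 1 - alpha)``; the
    returned maximum absolute discrepancy over the supplied offers is then
    zero to rounding.  For ``delta != 1`` it quantifies the departure.
    """
    ces = get_spec("ces").value({"alpha": alpha, "delta": delta}, gains, donations)
    lin = get_spec("linear-independent").value(
        {"alpha": alpha, "beta": 1.0 - alpha}, gains, donations
    )
    return float(np.max(np.abs(ces - lin)))


def registry_json() -> str:
    """JSON registry of the model space (id, name, parameter names, transforms)."""
    entries = [
        {
            "id": s.id,
            "name": s.name,
            "parameters": [
                {"name": p.name, "transform": p.transform.name, "description": p.description}
                for p in s.parameters
            ],
        }
        for s in _SPECS
    ]
    return json.dumps(entries, indent=2)
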