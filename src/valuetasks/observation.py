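"""Mapping from covert utilities to observable behavior, per task.

Three response modalities share the same underlying value function:

* choice  — the subject picks one of two offers; the win probability of the
  chosen offer is fixed (70%), so the net utility of a choice is
  ``0.7 * (V_chosen - V_unchosen)`` and choices follow a softmax (logistic)
  rule on the value difference with temperature ``beta``.
* rating  — a desirability rating on a 0-10 scale; the subject minimises the
  squared error between the overt rating and the covert judgment, so the
  optimal rating equals the value itself.
* force   — grip force as a percentage of maximal force; the win probability
  equals the force fraction, and a quadratic effort cost is subtracted:
  ``U = V*F - gamma_effort*F**2``, maximised at ``F* = V / (2*gamma_effort)``.

In all three cases the optimal overt response is linear in value, which
licenses the affine observation rule ``R = a*V + b`` (clipped to the response
bounds) used for rating and force data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "TASKS",
    "ChoiceObsParams",
    "ScaleObsParams",
    "TaskConfig",
    "choice_probability",
    "net_utility",
    "optimal_response",
    "expected_scaled_response",
]

TASKS = ("force", "rating", "choice")


@dataclass(frozen=True)
class ChoiceObsParams:
    """Softmax observation parameters for the choice task."""

    temperature: float  # utility units; larger = more stochastic

    def __post_init__(self):
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")


@dataclass(frozen=True)
class ScaleObsParams:
    """Affine scaling of value onto the response scale, with Gaussian noise."""

    slope: float  # response units per utility unit
    intercept: float  # response units
    noise_sd: float = 0.0  # response units

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")


@dataclass(frozen=True)
class TaskConfig:
    """Fixed features of the task design."""

    win_probability: float = 0.7
    rating_bounds: tuple[float, float] = (0.0, 10.0)
    force_bounds: tuple[float, float] = (10.0, 100.0)  # percent of maximal force
    effort_cost_scale: float = 0.5  # quadratic effort-cost weight

    def __post_init__(self):
        if not (0 < self.win_probability <= 1):
            raise ValueError("win_probability must lie in (0, 1]")
        for lo, hi in (self.rating_bounds, self.force_bounds):
            if not lo < hi:
                raise ValueError("bounds must be ordered (low < high)")

    def bounds(self, task: str) -> tuple[float, float]:
        if task == "rating":
            return self.rating_bounds
        if task == "force":
            return self.force_bounds
        raise ValueError(f"no response bounds for task {task!r}")


def choice_probability(value_left, value_right, temperature) -> np.ndarray:
    """Softmax probability of choosing the left offer.

    ``p_left = 1 / (1 + exp(-(V_L - V_R) / temperature))``; the right-option
    probability is its complement.  Numerically stable for large scaled value
    differences.
    """
    temperature = float(temperature)
    if not (np.isfinite(temperature) and temperature > 0):
        raise ValueError(f"temperature must be positive, got {temperature}")
    dv = np.asarray(value_left, dtype=float) - np.asarray(value_right, dtype=float)
    return expit(dv / temperature)


def net_utility(task: str, *args, win_probability: float = 0.7) -> np.ndarray:
    """Task-specific net utility the responder maximises.

    choice:  ``net_utility('choice', v_chosen, v_unchosen)``
             -> ``win_probability * (v_chosen - v_unchosen)``
    rating:  ``net_utility('rating', rating, value)`` -> ``-(rating - value)**2``
    force:   ``net_utility('force', force_frac, value, gamma_effort)``
             -> ``value * force_frac - gamma_effort * force_frac**2``
             with ``force_frac`` the force as a fraction of maximum in [0, 1].
    """
    if task == "choice":
        v_chosen, v_unchosen = (np.asarray(a, dtype=float) for a in args)
        return win_probability * (v_chosen - v_unchosen)
    if task == "rating":
        rating, value = (np.asarray(a, dtype=float) for a in args)
        return -((rating - value) ** 2)
    if task == "force":
        force, value, gamma_effort = (np.asarray(a, dtype=float) for a in args)
        return value * force - gamma_effort * force**2
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def optimal_response(task: str, value, gamma_effort: float | None = None):
    """Response maximising the net utility: the value itself for rating,
    ``V / (2 * gamma_effort)`` for force."""
    value = np.asarray(value, dtype=float)
    if task == "rating":
        return value
    if task == "force":
        if gamma_effort is None or gamma_effort <= 0:
            raise ValueError("force requires a positive effort-cost scale")
        return value / (2.0 * gamma_effort)
    raise ValueError(f"no closed-form optimal response for task {task!r}")


def expected_scaled_response(value, params: ScaleObsParams, bounds) -> np.ndarray:
    """Affine mapping ``a*V + b`` of value onto the response scale, clipped."""
    value = np.asarray(value, dtype=float)
    lo, hi = bounds
    return np.clip(params.slope * value + params.intercept, lo, hi)
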