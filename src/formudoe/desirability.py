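"""Derringer-type desirability scoring and multi-response optimization.

Each predicted response :math:`\\hat y_i` is mapped to an individual
desirability :math:`d_i \\in [0, 1]` by a linear ramp between acceptability
bounds ``(y_min, y_max)``:

* maximize: 0 at or below ``y_min``, 1 at or above ``y_max``, linear between;
* minimize: the mirror image, 1 at or below ``y_min``, 0 at or above ``y_max``.

Individual desirabilities combine by the geometric mean into the overall
desirability ``D = (d_1 d_2 ... d_m)^(1/m)``, which is 0 whenever any single
response is unacceptable.  The optimizer maximizes D over a box region of
the coded factor space by dense grid search followed by a derivative-free
local polish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .rsm import ResponseSurfaceResults

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "d_individual",
    "overall_D",
    "optimize",
]


@dataclass(frozen=True)
class DesirabilityGoal:
    """Target for one response: direction plus acceptability bounds."""

    response_name: str
    direction: str  # "maximize" | "minimize"
    y_min: float
    y_max: float

    def __post_init__(self):
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")
        if not self.y_min < self.y_max:
            raise ValueError("need y_min < y_max")


def d_individual(y_hat, goal: DesirabilityGoal):
    """Individual desirability of predicted value(s) under ``goal``."""
    y = np.asarray(y_hat, dtype=float)
    span = goal.y_max - goal.y_min
    if goal.direction == "maximize":
        d = (y - goal.y_min) / span
    else:
        d = (goal.y_max - y) / span
    d = np.clip(d, 0.0, 1.0)
    return float(d) if np.isscalar(y_hat) else d


def overall_D(d):
    """Geometric mean of individual desirabilities."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one desirability value")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("individual desirabilities must lie in [0, 1]")
    return float(np.prod(d) ** (1.0 / d.size))


@dataclass
class OptimizationResult:
    """Argmax of the overall desirability over the search region."""

    coded: np.ndarray
    actual: np.ndarray
    predicted: dict
    d_individual: dict
    overall_D: float
    all_zero: bool = False  # True when D == 0 everywhere on the grid

    def to_dict(self) -> dict:
        return {
            "coded": list(map(float, self.coded)),
            "actual": list(map(float, self.actual)),
            "predicted": self.predicted,
            "d_individual": self.d_individual,
            "overall_D": self.overall_D,
            "all_zero": self.all_zero,
        }


def _grid_axes(k, bounds, step):
    lo, hi = bounds
    npts = int(round((hi - lo) / step)) + 1
    return [np.linspace(lo, hi, npts) for _ in range(k)]


def _eval_D(points, results, goals):
    """Overall D (and per-goal d) at an (n, k) array of coded points."""
    d_all = []
    for goal in goals:
        yhat = results[goal.response_name].predict(points)
        d_all.append(d_individual(yhat, goal))
    d_all = np.column_stack(d_all)
    D = np.prod(d_all, axis=1) ** (1.0 / len(goals))
    return D, d_all


def optimize(
    results: dict[str, ResponseSurfaceResults] | list[ResponseSurfaceResults],
    goals: list[DesirabilityGoal],
    bounds: tuple[float, float] = (-1.0, 1.0),
    grid_step: float = 0.02,
    polish: bool = True,
) -> OptimizationResult:
    """Maximize overall desirability over the coded box ``bounds^k``.

    The grid search is exhaustive at ``grid_step`` resolution (ties broken
    by first occurrence in canonical grid order), then refined by
    Nelder-Mead on the clipped objective.  Deterministic for a fixed step.

    If D is zero on the whole grid, the returned point instead maximizes
    the *minimum* individual desirability (the least-bad compromise) and
    ``all_zero`` is flagged.
    """
    if isinstance(results, (list, tuple)):
        results = {r.response_name: r for r in results}
    if not goals:
        raise ValueError("need at least one goal")
    missing = [g.response_name for g in goals if g.response_name not in results]
    if missing:
        raise ValueError(f"no fitted model for goals: {missing}")
    factors = results[goals[0].response_name].factors
    k = len(factors)
    axes = _grid_axes(k, bounds, grid_step)
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([m.ravel() for m in mesh])

    best_D = -1.0
    best_point = None
    best_mind_val = -1.0
    best_mind_point = None
    chunk = 400_000
    for start in range(0, len(grid), chunk):
        pts = grid[start : start + chunk]
        D, d_all = _eval_D(pts, results, goals)
        i = int(np.argmax(D))
        if D[i] > best_D:
            best_D = float(D[i])
            best_point = pts[i]
        mind = d_all.min(axis=1)
        j = int(np.argmax(mind))
        if mind[j] > best_mind_val:
            best_mind_val = float(mind[j])
            best_mind_point = pts[j]

    all_zero = best_D <= 0.0
    x = best_mind_point if all_zero else best_point

    if polish and not all_zero:
        lo, hi = bounds

        def neg_D(z):
            z = np.clip(z, lo, hi)
            return -_eval_D(z[None, :], results, goals)[0][0]

        res = minimize(neg_D, x, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
        cand = np.clip(res.x, lo, hi)
        if -res.fun >= best_D:
            x = cand

    x = np.asarray(x, dtype=float)
    D, d_all = _eval_D(x[None, :], results, goals)
    actual = np.array([f.coded_to_actual(c) for f, c in zip(factors, x)])
    predicted = {
        g.response_name: float(results[g.response_name].predict(x[None, :])[0])
        for g in goals
    }
    return OptimizationResult(
        coded=x,
        actual=actual,
        predicted=predicted,
        d_individual={g.response_name: float(d) for g, d in zip(goals, d_all[0])},
        overall_D=float(D[0]) if not all_zero else 0.0,
        all_zero=all_zero,
    )
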