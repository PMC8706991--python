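"""Rotatable central composite designs and coded/actual unit conversion.

A central composite design (CCD) for ``k`` factors augments the 2^k
two-level factorial core with ``2k`` axial (star) points at coded distance
``alpha`` from the center and a block of replicated center points.  With
``alpha = (2^k)**0.25`` the design is rotatable: the variance of the model
prediction depends only on the distance from the design center.

Factors are handled on two scales.  The *coded* scale places the factorial
levels at -1/+1 and the center at 0; the *actual* scale is the laboratory
unit (mM, %, ...).  The two are related by an affine map per factor,
``actual = center + coded * half_width``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorDef",
    "DesignSpec",
    "DesignMatrix",
    "rotatable_alpha",
    "build_ccd",
    "coded_to_actual",
    "actual_to_coded",
]


def rotatable_alpha(k: int) -> float:
    """Axial distance making a k-factor CCD rotatable: ``(2**k) ** 0.25``.

    For k = 3 this is 8**0.25 = 1.6818, the familiar "1.682" of
    three-factor rotatable designs.
    """
    if not isinstance(k, (int, np.integer)) or k < 2:
        raise ValueError(f"need an integer factor count k >= 2, got {k!r}")
    return float((2.0**k) ** 0.25)


@dataclass(frozen=True)
class FactorDef:
    """One experimental factor with its coded-to-actual affine map.

    Parameters
    ----------
    name : str
        Column name used in design tables.
    center : float
        Actual value at coded level 0.
    half_width : float
        Actual units per coded unit (distance from center to the +-1 level).
    unit_label : str
        Display unit, e.g. ``"mM"``.
    """

    name: str
    center: float
    half_width: float
    unit_label: str = ""

    def __post_init__(self):
        if not self.half_width > 0:
            raise ValueError(f"half_width must be > 0, got {self.half_width}")

    def coded_to_actual(self, code):
        return self.center + np.asarray(code, dtype=float) * self.half_width

    def actual_to_coded(self, value):
        return (np.asarray(value, dtype=float) - self.center) / self.half_width


def coded_to_actual(code, factor: FactorDef):
    """Map a coded level to actual units: ``center + code * half_width``."""
    return factor.coded_to_actual(code)


def actual_to_coded(value, factor: FactorDef):
    """Exact inverse of :func:`coded_to_actual`."""
    return factor.actual_to_coded(value)


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a CCD: factors, center replication, axial distance.

    ``alpha`` may be the string ``"rotatable"`` (the default), which
    resolves to ``(2**k) ** 0.25``, or an explicit positive real.
    """

    factors: tuple[FactorDef, ...]
    n_center: int = 6
    alpha: float | str = "rotatable"

    def __init__(self, factors, n_center=6, alpha="rotatable"):
        object.__setattr__(self, "factors", tuple(factors))
        object.__setattr__(self, "n_center", int(n_center))
        object.__setattr__(self, "alpha", alpha)
        if self.k < 2:
            raise ValueError("a CCD needs at least 2 factors")
        if self.n_center < 0:
            raise ValueError("n_center must be nonnegative")
        if alpha != "rotatable" and not float(alpha) > 0:
            raise ValueError("alpha must be positive or 'rotatable'")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def alpha_value(self) -> float:
        if self.alpha == "rotatable":
            return rotatable_alpha(self.k)
        return float(self.alpha)

    @property
    def n_runs(self) -> int:
        return 2**self.k + 2 * self.k + self.n_center


class DesignMatrix:
    """Runs-by-factors table carrying coded levels, actual levels, responses.

    Attributes
    ----------
    factors : tuple of FactorDef
    coded : ndarray, shape (n_runs, k)
        Coded factor settings, one row per run.
    is_center : ndarray of bool
    responses : pandas.DataFrame
        Named response columns (may be empty), index aligned with runs.
    run_ids : ndarray of int, 1-based.
    """

    def __init__(self, factors, coded, is_center=None, responses=None, run_ids=None):
        self.factors = tuple(factors)
        self.coded = np.atleast_2d(np.asarray(coded, dtype=float))
        n = len(self.coded)
        if self.coded.shape[1] != len(self.factors):
            raise ValueError("coded matrix width must equal number of factors")
        if is_center is None:
            is_center = np.all(self.coded == 0.0, axis=1)
        self.is_center = np.asarray(is_center, dtype=bool)
        self.run_ids = (
            np.arange(1, n + 1) if run_ids is None else np.asarray(run_ids, dtype=int)
        )
        self.responses = (
            pd.DataFrame(index=range(n))
            if responses is None
            else pd.DataFrame(responses).reset_index(drop=True)
        )
        if len(self.responses) != n:
            raise ValueError("responses must have one row per run")

    # -- basic introspection ------------------------------------------------
    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def actual(self) -> np.ndarray:
        centers = np.array([f.center for f in self.factors])
        widths = np.array([f.half_width for f in self.factors])
        return centers + self.coded * widths

    def response(self, name: str) -> np.ndarray:
        if name not in self.responses.columns:
            raise KeyError(f"no response column {name!r}")
        return self.responses[name].to_numpy(dtype=float)

    def with_responses(self, **columns) -> "DesignMatrix":
        resp = self.responses.copy()
        for name, values in columns.items():
            values = np.asarray(values, dtype=float)
            if len(values) != self.n_runs:
                raise ValueError(f"response {name!r} must have one value per run")
            resp[name] = values
        return DesignMatrix(
            self.factors, self.coded, self.is_center, resp, self.run_ids
        )

    # -- I/O ---------------------------------------------------------------
    def to_frame(self, coded: bool = False) -> pd.DataFrame:
        """Tabular view: run_id, factor columns (actual or coded), responses."""
        values = self.coded if coded else self.actual
        df = pd.DataFrame({"run_id": self.run_ids})
        for j, name in enumerate(self.factor_names):
            df[name] = values[:, j]
        for col in self.responses.columns:
            df[col] = self.responses[col].to_numpy()
        return df

    def to_csv(self, path, coded: bool = False) -> None:
        self.to_frame(coded=coded).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, factors) -> "DesignMatrix":
        """Build from a table of *actual* factor values plus response columns."""
        factors = tuple(factors)
        names = [f.name for f in factors]
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise ValueError(f"missing factor columns: {missing}")
        coded = np.column_stack(
            [f.actual_to_coded(df[f.name].to_numpy(dtype=float)) for f in factors]
        )
        resp_cols = [c for c in df.columns if c not in names and c != "run_id"]
        run_ids = (
            df["run_id"].to_numpy(dtype=int) if "run_id" in df.columns else None
        )
        return cls(factors, coded, responses=df[resp_cols], run_ids=run_ids)

    @classmethod
    def from_csv(cls, path, factors) -> "DesignMatrix":
        return cls.from_frame(pd.read_csv(path), factors)

    def __repr__(self):
        return (
            f"DesignMatrix(k={self.k}, n_runs={self.n_runs}, "
            f"responses={list(self.responses.columns)!r})"
        )


def build_ccd(spec: DesignSpec, seed: int | None = None) -> DesignMatrix:
    """Construct the CCD run list for ``spec``.

    The canonical run order is deterministic: the 2^k factorial points in
    binary counting order (last factor fastest), then the 2k axial points
    factor by factor (-alpha before +alpha), then the center replicates.
    Passing ``seed`` applies a reproducible random permutation of the rows,
    mirroring the randomized run sheets practitioners actually execute.
    """
    k = spec.k
    a = spec.alpha_value
    factorial = np.array(
        [row for row in itertools.product((-1.0, 1.0), repeat=k)], dtype=float
    )
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -a
        axial[2 * j + 1, j] = a
    center = np.zeros((spec.n_center, k))
    coded = np.vstack([factorial, axial, center])
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(coded))
        coded = coded[order]
    return DesignMatrix(spec.factors, coded)
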