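"""Cumulative drug-release curves and kinetic model fitting.

Release experiments with aliquot sampling remove drug at every timepoint
and replace the withdrawn volume with fresh medium, so the measured
concentration under-reports the released mass.  The mass-balance
correction

.. math::

    Q_n = C_n V + V_s \\sum_{i<n} C_i, \\qquad CR_n = Q_n / \\text{dose}

(total medium volume ``V``, aliquot volume ``V_s``) restores the true
cumulative release, expressed as the fraction ``CR`` of the dose.

Four empirical kinetic laws are fitted to ``(t, CR)`` by least squares,
with CR a fraction in [0, 1] and t in hours:

=================  ==========================  ==================
model              equation                    parameters
=================  ==========================  ==================
zero_order         CR = k0 * t                 k0 (1/h)
first_order        CR = 1 - exp(-k1 * t)       k1 (1/h)
korsmeyer_peppas   CR = k_KP * t^n             k_KP (1/h^n), n
higuchi            CR = k_H * sqrt(t)          k_H (1/sqrt(h))
=================  ==========================  ==================

Model selection ranks by R^2 (ties broken by fewer parameters).  The
Korsmeyer-Peppas law with n = 0.5 coincides with Higuchi's square-root law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError

__all__ = [
    "ReleaseCurve",
    "KineticFit",
    "cumulative_release",
    "fit_kinetic",
    "select_model",
    "ReleaseKinetics",
    "KINETIC_MODELS",
]

DEFAULT_TIMEPOINTS_H = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0])
"""Standard 48-hour sampling schedule for dialysis release runs."""


@dataclass
class ReleaseCurve:
    """Cumulative-fraction-released series from a sampled release run.

    ``cr`` is Mt/Me, the released fraction of the dose; small analytic
    overshoot above 1 (up to 1.05) is tolerated.
    """

    times: np.ndarray
    cr: np.ndarray
    medium_volume: float | None = None  # mL
    sample_volume: float = 0.0  # mL
    dose: float | None = None  # ug

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cr = np.asarray(self.cr, dtype=float)
        if self.times.shape != self.cr.shape:
            raise ValueError("times and cr must have equal length")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if np.any(self.cr < 0) or np.any(self.cr > 1.05):
            raise ValueError("cr must lie in [0, 1.05]")


def cumulative_release(sample_concentrations, times, medium_volume, sample_volume,
                       dose) -> ReleaseCurve:
    """Replacement-corrected cumulative release from sampled concentrations.

    Parameters
    ----------
    sample_concentrations : array, ug/mL, one per timepoint
    times : array, hours
    medium_volume : float, mL (total, held constant by replacement)
    sample_volume : float, mL withdrawn per timepoint
    dose : float, ug of drug in the donor at t = 0
    """
    c = np.asarray(sample_concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    if not 0 <= sample_volume < medium_volume:
        raise ValueError("need 0 <= sample_volume < medium_volume")
    if not dose > 0:
        raise ValueError("dose must be positive")
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    q = c * medium_volume + sample_volume * prior
    return ReleaseCurve(times, q / dose, medium_volume, sample_volume, dose)


# --------------------------------------------------------------------------
# kinetic models

def _zero_order(t, k0):
    return k0 * t


def _first_order(t, k1):
    return 1.0 - np.exp(-k1 * t)


def _korsmeyer_peppas(t, k, n):
    return k * np.power(t, n)


def _higuchi(t, kh):
    return kh * np.sqrt(t)


def _init_zero(t, y):
    return [max(np.sum(t * y) / np.sum(t * t), 1e-6)]


def _init_first(t, y):
    # log-linear regression of -ln(1 - cr) on t, using points safely below 1
    mask = (y < 0.999) & (t > 0)
    if mask.sum() >= 2:
        z = -np.log(1.0 - y[mask])
        k = np.sum(t[mask] * z) / np.sum(t[mask] ** 2)
    else:
        k = 1.0 / max(t[np.argmax(y >= 0.5)] if np.any(y >= 0.5) else t[-1], 1e-6)
    return [max(k, 1e-6)]


def _init_kp(t, y):
    # log-log regression; t = 0 / cr = 0 points excluded
    mask = (t > 0) & (y > 0)
    if mask.sum() >= 2:
        lt, ly = np.log(t[mask]), np.log(y[mask])
        n, logk = np.polyfit(lt, ly, 1)
        return [max(np.exp(logk), 1e-6), min(max(n, 1e-3), 3.0)]
    return [0.1, 0.5]


def _init_higuchi(t, y):
    s = np.sqrt(t)
    return [max(np.sum(s * y) / np.sum(s * s), 1e-6)]


KINETIC_MODELS = {
    "zero_order": {
        "func": _zero_order, "names": ("k0",), "init": _init_zero,
        "bounds": ([1e-12], [np.inf]),
    },
    "first_order": {
        "func": _first_order, "names": ("k1",), "init": _init_first,
        "bounds": ([1e-12], [np.inf]),
    },
    "korsmeyer_peppas": {
        "func": _korsmeyer_peppas, "names": ("k_KP", "n"), "init": _init_kp,
        "bounds": ([1e-12, 1e-6], [np.inf, 5.0]),
    },
    "higuchi": {
        "func": _higuchi, "names": ("k_H",), "init": _init_higuchi,
        "bounds": ([1e-12], [np.inf]),
    },
}


@dataclass
class KineticFit:
    """One fitted kinetic law: parameters and goodness of fit."""

    model_id: str
    params: dict
    r2: float

    def predict(self, times) -> np.ndarray:
        spec = KINETIC_MODELS[self.model_id]
        return spec["func"](np.asarray(times, dtype=float),
                            *[self.params[n] for n in spec["names"]])


def _r2(y, yhat) -> float:
    sst = np.sum((y - y.mean()) ** 2)
    sse = np.sum((y - yhat) ** 2)
    return 1.0 - sse / sst


def fit_kinetic(model_id: str, curve: ReleaseCurve, kp_60: bool = False) -> KineticFit:
    """Least-squares fit of one kinetic model to a release curve.

    ``kp_60`` restricts the Korsmeyer-Peppas fit to the conventional
    <= 60%-released prefix of the curve; by default all points are used.
    t = 0 points are kept for the zero/first-order laws (both pass through
    the origin) and for the evaluation of R^2.
    """
    if model_id not in KINETIC_MODELS:
        raise ValueError(f"unknown kinetic model {model_id!r}")
    t, y = curve.times, curve.cr
    if np.sum(t > 0) < 3:
        raise ValueError("need at least 3 points with t > 0")
    t_fit, y_fit = t, y
    if model_id == "korsmeyer_peppas" and kp_60:
        mask = y <= 0.60
        if mask.sum() >= 3:
            t_fit, y_fit = t[mask], y[mask]
    spec = KINETIC_MODELS[model_id]
    p0 = spec["init"](t_fit, y_fit)
    try:
        popt, _ = curve_fit(spec["func"], t_fit, y_fit, p0=p0,
                            bounds=spec["bounds"], maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        best = KineticFit(model_id, dict(zip(spec["names"], p0)),
                          _r2(y, spec["func"](t, *p0)))
        raise FitFailureError(
            f"{model_id} fit did not converge: {exc}", best_attempt=best
        ) from exc
    return KineticFit(model_id, dict(zip(spec["names"], map(float, popt))),
                      _r2(y, spec["func"](t, *popt)))


def select_model(curve: ReleaseCurve, kp_60: bool = False) -> list[KineticFit]:
    """Fit all four kinetic laws and rank by R^2 (ties: fewer parameters)."""
    fits, failures = [], []
    for model_id in KINETIC_MODELS:
        try:
            fits.append(fit_kinetic(model_id, curve, kp_60=kp_60))
        except FitFailureError as exc:
            failures.append(exc)
    if len(fits) < 2:
        raise FitFailureError(
            f"only {len(fits)} of {len(KINETIC_MODELS)} kinetic fits converged",
            best_attempt=fits[0] if fits else None,
        )
    return sorted(fits, key=lambda f: (-f.r2, len(f.params)))


class ReleaseKinetics:
    """Model-object wrapper: a release curve plus its kinetic fits.

    ``ReleaseKinetics(curve).fit("first_order")`` returns a single
    :class:`KineticFit`; ``.fit_all()`` returns the R^2-ranked list.
    """

    def __init__(self, curve: ReleaseCurve, kp_60: bool = False):
        self.curve = curve
        self.kp_60 = kp_60

    @classmethod
    def from_concentrations(cls, sample_concentrations, times, medium_volume,
                            sample_volume, dose, kp_60: bool = False):
        return cls(cumulative_release(sample_concentrations, times,
                                      medium_volume, sample_volume, dose), kp_60)

    def fit(self, model_id: str) -> KineticFit:
        return fit_kinetic(model_id, self.curve, kp_60=self.kp_60)

    def fit_all(self) -> list[KineticFit]:
        return select_model(self.curve, kp_60=self.kp_60)

    def summary(self) -> str:
        lines = [f"{'model':<18}{'R^2':>9}  parameters"]
        for f in self.fit_all():
            pars = ", ".join(f"{k} = {v:.4g}" for k, v in f.params.items())
            lines.append(f"{f.model_id:<18}{f.r2:>9.4f}  {pars}")
        return "\n".join(lines)
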