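"""Synthetic data generators matching the pipeline's statistical assumptions.

Three generators cover the three data shapes the analysis consumes:

* quadratic response surfaces over a design, with additive Gaussian noise
  per run (center replicates share the surface value but draw independent
  noise) — for exercising the regression and optimization stages;
* well-mixed withdraw-and-replace release sampling — a mass-balance
  simulator that tracks the medium composition through aliquot withdrawals
  so the replacement correction can be validated against ground truth;
* Franz-cell receptor sampling under a constant-flux donor, optionally as
  a blocked/unblocked pair where only the unblocked skin receives an
  additional follicular-route flux.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix
from .kinetics import DEFAULT_TIMEPOINTS_H, KINETIC_MODELS
from .rsm import quadratic_matrix, quadratic_terms

__all__ = [
    "SurfaceSimConfig",
    "ReleaseSimConfig",
    "simulate_design_responses",
    "simulate_release_sampling",
    "simulate_permeation_sampling",
    "emulate_release_profile",
]


def simulate_design_responses(design: DesignMatrix, true_beta: dict,
                              noise_sd: float = 0.0, seed: int | None = None,
                              response_name: str = "y") -> DesignMatrix:
    """Add a simulated response column: quadratic surface plus N(0, sd^2).

    ``true_beta`` maps full-quadratic term labels (see
    :func:`formudoe.rsm.quadratic_terms`, built from the design's factor
    names) to coefficients on the *coded* scale; missing terms default
    to 0.
    """
    terms = quadratic_terms(design.factor_names)
    unknown = [t for t in true_beta if t not in terms]
    if unknown:
        raise ValueError(f"unknown terms in true_beta: {unknown}")
    beta = np.array([true_beta.get(t, 0.0) for t in terms])
    surface = quadratic_matrix(design.coded) @ beta
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, design.n_runs) if noise_sd > 0 else 0.0
    return design.with_responses(**{response_name: surface + noise})


@dataclass(frozen=True)
class SurfaceSimConfig:
    """Reproducible surface-simulation settings (coded-scale truth)."""

    true_beta: dict
    noise_sd: float = 0.0
    seed: int | None = None
    response_name: str = "y"

    def simulate(self, design: DesignMatrix) -> DesignMatrix:
        return simulate_design_responses(design, self.true_beta, self.noise_sd,
                                         self.seed, self.response_name)


def _released_fraction(model_id: str, params: dict, times: np.ndarray) -> np.ndarray:
    spec = KINETIC_MODELS[model_id]
    frac = spec["func"](times, *[params[n] for n in spec["names"]])
    return np.clip(frac, 0.0, 1.0)


def simulate_release_sampling(model_id: str, params: dict,
                              times=DEFAULT_TIMEPOINTS_H,
                              medium_volume: float = 20.0,
                              sample_volume: float = 1.0,
                              dose: float = 100.0,
                              noise_sd: float = 0.0,
                              seed: int | None = None):
    """Simulate aliquot sampling of a release run; return observations + truth.

    The medium is well mixed: at each timepoint the drug mass present is
    the true cumulative release minus everything carried away by earlier
    aliquots; withdrawing ``sample_volume`` removes mass at the current
    concentration and fresh medium replaces the volume.  Measurement noise
    (ug/mL, additive Gaussian) perturbs the *observed* concentration only,
    not the mass balance.

    Returns
    -------
    (times, observed_concentrations, true_fraction) : three ndarrays
    """
    times = np.asarray(times, dtype=float)
    frac = _released_fraction(model_id, params, times)
    rng = np.random.default_rng(seed)
    removed = 0.0
    observed = np.empty_like(times)
    for i, f in enumerate(frac):
        mass_in_medium = dose * f - removed
        conc = mass_in_medium / medium_volume
        removed += conc * sample_volume
        obs = conc + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        observed[i] = max(obs, 0.0)
    return times, observed, frac


@dataclass(frozen=True)
class ReleaseSimConfig:
    """Reproducible release-sampling simulation settings."""

    model_id: str
    true_params: dict
    times: tuple = tuple(DEFAULT_TIMEPOINTS_H)
    noise_sd: float = 0.0
    seed: int | None = None
    medium_volume: float = 20.0
    sample_volume: float = 1.0
    dose: float = 100.0

    def simulate(self):
        return simulate_release_sampling(
            self.model_id, self.true_params, np.asarray(self.times),
            self.medium_volume, self.sample_volume, self.dose,
            self.noise_sd, self.seed,
        )


def simulate_permeation_sampling(times, transepidermal_flux: float,
                                 follicular_flux: float = 0.0,
                                 receptor_volume: float = 12.0,
                                 sample_volume: float = 0.5,
                                 diffusion_area: float = 3.5,
                                 noise_sd: float = 0.0,
                                 seed: int | None = None):
    """Constant-flux Franz-cell simulation with aliquot sampling.

    Fluxes are in ug/cm^2/h; drug enters the receptor at
    ``(transepidermal_flux + follicular_flux) * area``.  A follicle-blocked
    cell is emulated by ``follicular_flux = 0``.

    Returns
    -------
    (times, observed_concentrations, true_cumulation) where
    ``true_cumulation`` is the cumulative permeated amount per area
    (ug/cm^2) at each timepoint.
    """
    times = np.asarray(times, dtype=float)
    total_flux = transepidermal_flux + follicular_flux
    cum_per_area = total_flux * times
    cum_mass = cum_per_area * diffusion_area
    rng = np.random.default_rng(seed)
    removed = 0.0
    observed = np.empty_like(times)
    for i, m in enumerate(cum_mass):
        conc = (m - removed) / receptor_volume
        removed += conc * sample_volume
        obs = conc + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        observed[i] = max(obs, 0.0)
    return times, observed, cum_per_area


def emulate_release_profile(kind: str, times=DEFAULT_TIMEPOINTS_H) -> np.ndarray:
    """Noise-free cumulative-release fractions of two canonical shapes.

    ``"fast"`` is a free drug in solution: first-order escape through the
    dialysis membrane, essentially complete by 12 h.  ``"sustained"`` is a
    vesicle-entrapped drug: a saturating exponential reaching ~80% by 4 h
    and plateauing near 98% by 48 h.
    """
    times = np.asarray(times, dtype=float)
    if kind == "fast":
        return 1.0 - np.exp(-0.5 * times)
    if kind == "sustained":
        f_inf = 0.98
        k = -np.log(1.0 - 0.80 / f_inf) / 4.0
        return f_inf * (1.0 - np.exp(-k * times))
    raise ValueError("kind must be 'fast' or 'sustained'")
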