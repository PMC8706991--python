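"""Formulation assay metrics: entrapment, loading, permeation, irritation.

Entrapment efficiency and drug loading summarize how much drug a vesicle
batch carries::

    EE (%) = 100 * (total - free) / total
    DL (%) = 100 * (total - free) / ((total - free) + total_lipid)

(drug and lipid amounts must be in a common unit for DL).

Franz-cell permeation uses the same withdraw-and-replace mass balance as
release sampling, normalized per diffusion area.  The transfollicular
contribution is isolated by the follicle-blocking difference: cumulation
through full skin minus cumulation through follicle-blocked skin.

Dermal irritation uses Draize scoring: erythema and edema each graded 0-4
at each observation time; the primary irritation index (PII) is the mean
of all recorded scores, Sum(erythema_t + edema_t) / (2 T), banded into
none / slight / moderate / severe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError

__all__ = [
    "entrapment_efficiency",
    "drug_loading",
    "PermeationSeries",
    "cumulative_permeation",
    "transfollicular_cumulation",
    "DraizeRecord",
    "draize_pii",
    "classify_pii",
    "PII_BANDS",
]


def entrapment_efficiency(total_drug: float, free_drug: float) -> float:
    """Percent of drug entrapped: 100 * (total - free) / total."""
    if not total_drug > 0:
        raise ValueError("total_drug must be positive")
    if not 0 <= free_drug <= total_drug:
        raise ValueError("need 0 <= free_drug <= total_drug")
    return 100.0 * (total_drug - free_drug) / total_drug


def drug_loading(total_drug: float, free_drug: float, total_lipid: float) -> float:
    """Percent loading: entrapped drug over entrapped drug plus carrier lipid.

    ``total_drug``/``free_drug`` and ``total_lipid`` must share one unit.
    """
    if not total_drug > 0:
        raise ValueError("total_drug must be positive")
    if not 0 <= free_drug <= total_drug:
        raise ValueError("need 0 <= free_drug <= total_drug")
    if not total_lipid > 0:
        raise ValueError("total_lipid must be positive")
    entrapped = total_drug - free_drug
    return 100.0 * entrapped / (entrapped + total_lipid)


@dataclass
class PermeationSeries:
    """Receptor-compartment concentration series from one Franz cell."""

    times: np.ndarray  # hours
    receptor_concentrations: np.ndarray  # ug/mL
    receptor_volume: float  # mL
    sample_volume: float = 0.5  # mL
    diffusion_area: float = 3.5  # cm^2
    condition: str = "unblocked"  # or "blocked"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.receptor_concentrations = np.asarray(
            self.receptor_concentrations, dtype=float
        )
        if self.times.shape != self.receptor_concentrations.shape:
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.receptor_concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if not self.receptor_volume > 0:
            raise ValueError("receptor_volume must be positive")
        if not 0 <= self.sample_volume < self.receptor_volume:
            raise ValueError("need 0 <= sample_volume < receptor_volume")
        if not self.diffusion_area > 0:
            raise ValueError("diffusion_area must be positive")
        if self.condition not in ("unblocked", "blocked"):
            raise ValueError("condition must be 'unblocked' or 'blocked'")


def cumulative_permeation(series: PermeationSeries) -> np.ndarray:
    """Cumulative permeated amount per area (ug/cm^2) at each timepoint.

    Applies the withdraw-and-replace correction
    ``Q_n = C_n V + V_s * Sum_{i<n} C_i`` then divides by the diffusion
    area.
    """
    c = series.receptor_concentrations
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    q = c * series.receptor_volume + series.sample_volume * prior
    return q / series.diffusion_area


def transfollicular_cumulation(full, blocked, full_times=None, blocked_times=None):
    """Follicular-route contribution: full-skin minus blocked-skin cumulation.

    Works on scalars or per-timepoint vectors in any common unit
    (percent or ug/cm^2).  When timepoint grids are supplied they must
    match exactly.
    """
    if full_times is not None or blocked_times is not None:
        ft = np.asarray(full_times, dtype=float)
        bt = np.asarray(blocked_times, dtype=float)
        if ft.shape != bt.shape or not np.array_equal(ft, bt):
            raise AlignmentError("full and blocked series use different timepoints")
    full = np.asarray(full, dtype=float)
    blocked = np.asarray(blocked, dtype=float)
    if full.shape != blocked.shape:
        raise AlignmentError("full and blocked series have different lengths")
    out = full - blocked
    return float(out) if out.ndim == 0 else out


PII_BANDS = (
    (0.0, 0.5, "No irritation"),
    (0.5, 2.0, "Slight irritation"),
    (2.0, 5.0, "Moderate irritation"),
    (5.0, 8.0 + 1e-9, "Severe irritation"),
)
"""Half-open PII bands [lo, hi) with their class labels (last band closed)."""


def classify_pii(pii: float) -> str:
    for lo, hi, label in PII_BANDS:
        if lo <= pii < hi:
            return label
    if pii == 8.0:
        return "Severe irritation"
    raise ValueError(f"PII {pii} outside the Draize range [0, 8]")


@dataclass
class DraizeRecord:
    """Erythema/edema scores for one treatment group over T timepoints."""

    group_name: str
    observations: list  # (timepoint_h, erythema, edema)

    def __post_init__(self):
        if len(self.observations) < 1:
            raise ValueError("need at least one observation")
        tps = [t for t, _, _ in self.observations]
        if len(set(tps)) != len(tps):
            raise ValueError("timepoints must be distinct")
        for _, ery, ede in self.observations:
            if not (0 <= ery <= 4 and 0 <= ede <= 4):
                raise ValueError("Draize scores must lie in [0, 4]")


def draize_pii(record: DraizeRecord) -> tuple[float, str]:
    """Primary irritation index and irritation class for one group.

    PII = Sum_t (erythema_t + edema_t) / (2 T), i.e. the arithmetic mean
    of all 2T recorded category scores, reported rounded to 2 decimals.
    """
    scores = np.array(
        [[ery, ede] for _, ery, ede in record.observations], dtype=float
    )
    pii = round(float(scores.mean()), 2)
    return pii, classify_pii(pii)
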