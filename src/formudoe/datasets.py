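"""Packaged example data: the finasteride-proniosome CCD study.

The package ships the published run table of a 3-factor rotatable CCD
optimizing finasteride-loaded proniosomes (finasteride concentration,
total lipid content, cholesterol proportion; responses: vesicle size,
entrapment efficiency, drug loading), and the matching Draize skin
irritation score grid.  Values are preserved exactly as printed in the
source study, including the replicated center rows; they serve as a
realistic worked example and as regression fixtures.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .assays import DraizeRecord
from .design import DesignMatrix, FactorDef
from .desirability import DesirabilityGoal

__all__ = [
    "finasteride_factors",
    "proniosome_design",
    "proniosome_design_frame",
    "draize_scores",
    "draize_records",
    "default_goals",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = ("size_nm", "ee_pct", "dl_pct")
"""Measured responses: vesicle diameter (nm), % entrapment, % drug loading."""


def _data_path(name: str):
    return resources.files("formudoe.data").joinpath(name)


def finasteride_factors() -> tuple[FactorDef, ...]:
    """Factor definitions of the proniosome CCD.

    Centers and half-widths reproduce the published coded levels: the -1/+1
    levels are 1.50/5.00 mM finasteride, 10/30 mM total lipid, and 30/50 %
    cholesterol-in-lipid; axial points sit at coded +-(2^3)^(1/4).
    """
    return (
        FactorDef("finasteride_mM", center=3.25, half_width=1.75, unit_label="mM"),
        FactorDef("total_lipid_mM", center=20.0, half_width=10.0, unit_label="mM"),
        FactorDef("cholesterol_pct", center=40.0, half_width=10.0, unit_label="%"),
    )


def proniosome_design_frame() -> pd.DataFrame:
    """The raw packaged run table (actual units, responses, per-run SDs)."""
    with resources.as_file(_data_path("proniosome_design.csv")) as path:
        return pd.read_csv(path)


def proniosome_design(include_sd: bool = False) -> DesignMatrix:
    """The 20-run CCD as a :class:`~formudoe.design.DesignMatrix`.

    Responses are the published per-run triplicate means; ``include_sd``
    keeps the ``*_sd`` columns as additional response columns.
    """
    df = proniosome_design_frame().drop(columns=["is_center"])
    if not include_sd:
        df = df.drop(columns=[c for c in df.columns if c.endswith("_sd")])
    return DesignMatrix.from_frame(df, finasteride_factors())


def draize_scores() -> pd.DataFrame:
    """Draize erythema/edema scores per group and timepoint (long format)."""
    with resources.as_file(_data_path("draize_scores.csv")) as path:
        return pd.read_csv(path)


def draize_records() -> list[DraizeRecord]:
    """The score grid regrouped into :class:`~formudoe.assays.DraizeRecord`."""
    df = draize_scores()
    records = []
    for group, sub in df.groupby("group", sort=False):
        obs = list(
            zip(sub["timepoint_h"].astype(float), sub["erythema"].astype(float),
                sub["edema"].astype(float))
        )
        records.append(DraizeRecord(group, obs))
    return records


def default_goals(design: DesignMatrix, directions: dict[str, str]) -> list[
        DesirabilityGoal]:
    """Desirability goals with bounds set to each response's observed range.

    ``directions`` maps response column name to "minimize"/"maximize".
    Using the observed min/max as the acceptability window is the common
    default when no explicit specification limits exist.
    """
    goals = []
    for name, direction in directions.items():
        y = design.response(name)
        goals.append(
            DesirabilityGoal(name, direction, float(np.min(y)), float(np.max(y)))
        )
    return goals
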