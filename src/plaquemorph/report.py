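"""Per-specimen joins and study-level aggregates.

Joins the mechanical, biochemical (FTIR) and structural (micro-CT) results
into one row per plaque specimen, then computes the study-level summaries:
per-stiffness-group means and standard deviations, overall ultimate-strength
statistics, geometry-class totals, the ordering of calcification volume
fractions, and the SEM-EDX hydroxyapatite stoichiometry check.

The published per-specimen tables are packaged as CSV fixtures
(``data/table1.csv``, ``data/table2.csv``) so the aggregate computations can
be exercised against printed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .mechanics import assign_group

__all__ = [
    "SpecimenSummary",
    "EDXReading",
    "load_table1",
    "load_table2",
    "group_summary",
    "overall_strength_summary",
    "count_totals",
    "cvf_order_statistics",
    "ca_p_molar_ratio",
    "hydroxyapatite_check",
    "build_specimen_table",
]

GROUP_ORDER = ["LS", "MS", "HS"]

MOLAR_MASS_CA = 40.078
MOLAR_MASS_P = 30.974


@dataclass(frozen=True)
class SpecimenSummary:
    """One joined row: mechanics + composition + structure for one plaque."""

    specimen_id: str
    group: str
    initial_stiffness_MPa: float
    peak_stress_MPa: float
    stretch_at_peak: float
    calc_col: float
    lip_col: float
    cvf: float
    total_surface_area_mm2: float
    n_spherical: int
    n_sheet: int
    n_irregular: int


@dataclass(frozen=True)
class EDXReading:
    """Elemental calcium/phosphorus abundances for one analysed region.

    ``basis`` is 'molar' (atomic fractions or counts) or 'mass'
    (mass fractions / weight percent, converted with the element molar
    masses).
    """

    region_id: str
    calcium: float
    phosphorus: float
    basis: str = "molar"

    def __post_init__(self):
        if self.calcium <= 0 or self.phosphorus <= 0:
            raise ValueError("elemental abundances must be positive")
        if self.basis not in ("molar", "mass"):
            raise ValueError("basis must be 'molar' or 'mass'")

    @property
    def ca_p_ratio(self) -> float:
        return ca_p_molar_ratio(self.calcium, self.phosphorus, self.basis)


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("plaquemorph.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Per-specimen mechanical/biochemical/structural table (printed values)."""
    return _load_fixture("table1.csv")


def load_table2() -> pd.DataFrame:
    """Per-specimen CVF and geometry-class counts. '-' entries parse as 0."""
    df = _load_fixture("table2.csv")
    for col in ("spherical", "sheet", "irregular"):
        df[col] = (
            pd.to_numeric(df[col].replace("-", 0), errors="raise").astype(int)
        )
    return df


def group_summary(table: pd.DataFrame, field: str) -> pd.DataFrame:
    """Mean, sample SD (n-1) and n of one column per stiffness group.

    Groups of size 1 report SD = 0 with a flag; empty groups are omitted
    with a warning.
    """
    if "group" not in table.columns:
        raise ValueError("table must carry a 'group' column")
    rows = []
    for g in GROUP_ORDER:
        vals = table.loc[table["group"] == g, field].astype(float)
        n = len(vals)
        if n == 0:
            warnings.warn(f"group {g} is empty; omitted from summary", stacklevel=2)
            continue
        rows.append(
            {
                "group": g,
                "mean": float(vals.mean()),
                "sd": 0.0 if n == 1 else float(vals.std(ddof=1)),
                "n": n,
                "sd_flagged": n == 1,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def overall_strength_summary(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Mean and sample SD of peak stress and stretch at peak over all specimens."""
    if len(table) < 2:
        raise ValueError("need at least 2 specimens for a strength summary")
    out = {}
    for key, col in (
        ("peak_stress_MPa", "cauchy_stress_MPa"),
        ("stretch_at_peak", "stretch_ratio"),
    ):
        vals = table[col].astype(float)
        out[key] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def count_totals(table: pd.DataFrame) -> dict[str, int]:
    """Study-wide totals of each calcification geometry class."""
    totals = {}
    for col in ("spherical", "sheet", "irregular"):
        vals = pd.to_numeric(table[col].replace("-", 0), errors="raise")
        if (vals < 0).any():
            raise ValueError(f"negative count in column {col}")
        totals[col] = int(vals.sum())
    return totals


def cvf_order_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """Specimens sorted by CVF, highest first; ties stable by specimen id.

    The top rows answer "which plaque is most calcified, and which next" —
    in the published cohort the most calcified plaque (CVF 0.52) is the
    stiffest, while the runner-up (0.32) sits in the low-stiffness group.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 specimens for order statistics")
    df = table.sort_values("specimen_id").sort_values(
        "cvf", ascending=False, kind="stable"
    )
    return df[["specimen_id", "group", "cvf"]].reset_index(drop=True)


def ca_p_molar_ratio(calcium: float, phosphorus: float, basis: str = "molar") -> float:
    """Molar Ca:P ratio; mass-based inputs are converted via molar masses."""
    if calcium <= 0 or phosphorus <= 0:
        raise ValueError("elemental abundances must be positive")
    if basis == "molar":
        return calcium / phosphorus
    if basis == "mass":
        return (calcium / MOLAR_MASS_CA) / (phosphorus / MOLAR_MASS_P)
    raise ValueError("basis must be 'molar' or 'mass'")


def hydroxyapatite_check(
    reading: EDXReading, threshold: float = 10.0 / 6.0, tolerance: float = 0.005
) -> bool:
    """Does a region's Ca:P match hydroxyapatite stoichiometry?

    Stoichiometric hydroxyapatite Ca10(PO4)6(OH)2 has molar Ca:P = 10/6
    (1.67). A region passes when its molar ratio is at least the threshold,
    within a small rounding ``tolerance`` so a ratio printed as 1.67 counts
    as equivalent. Calcium-deficient phases such as tricalcium phosphate
    (Ca:P = 1.5) fail.
    """
    return reading.ca_p_ratio >= threshold - tolerance


def build_specimen_table(summaries: list[SpecimenSummary]) -> pd.DataFrame:
    """One row per specimen; group labels re-derived from stiffness for consistency."""
    rows = []
    for s in summaries:
        expected = assign_group(s.initial_stiffness_MPa)
        if expected != s.group:
            warnings.warn(
                f"{s.specimen_id}: stated group {s.group} disagrees with "
                f"stiffness-derived group {expected}",
                stacklevel=2,
            )
        rows.append(s.__dict__.copy())
    return pd.DataFrame(rows)
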