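"""Uniaxial stress-stretch analysis of plaque tensile tests.

Force-displacement records from circumferential uniaxial extension are
converted to Cauchy stress versus stretch ratio. Under the incompressibility
assumption standard for soft tissue, the current cross-section is A0/lambda,
so sigma = (F/A0) * lambda. From the curve we extract the initial stiffness
(slope of sigma against lambda-1 in a low-stretch window), the ultimate
strength (peak stress and the stretch at which it occurs), and a
stiffness-group label (LS / MS / HS) used to stratify specimens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TestRecord",
    "StressStretchCurve",
    "MechanicalSummary",
    "to_stress_stretch",
    "initial_stiffness",
    "peak_strength",
    "assign_group",
    "summarise",
]


@dataclass(frozen=True)
class TestRecord:
    """A uniaxial force-displacement record with specimen geometry.

    displacement_mm must start at 0 and increase strictly; force_N is the
    measured axial force; gauge_length_mm (L0) and cross_section_mm2 (A0)
    are the undeformed reference dimensions.
    """

    displacement_mm: np.ndarray
    force_N: np.ndarray
    gauge_length_mm: float
    cross_section_mm2: float

    def __post_init__(self):
        d = np.asarray(self.displacement_mm, dtype=float)
        f = np.asarray(self.force_N, dtype=float)
        if d.ndim != 1 or d.shape != f.shape or d.size == 0:
            raise ValueError("displacement and force must be equal-length 1D arrays")
        if d[0] != 0:
            raise ValueError("first displacement sample must be 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("displacement must be strictly increasing")
        if not (self.gauge_length_mm > 0 and self.cross_section_mm2 > 0):
            raise ValueError("gauge length and cross-section must be positive")
        object.__setattr__(self, "displacement_mm", d)
        object.__setattr__(self, "force_N", f)


@dataclass(frozen=True)
class StressStretchCurve:
    """Cauchy stress (MPa) against stretch ratio lambda (>= 1)."""

    stretch: np.ndarray
    cauchy_stress_MPa: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.stretch, dtype=float)
        sig = np.asarray(self.cauchy_stress_MPa, dtype=float)
        if lam.ndim != 1 or lam.shape != sig.shape or lam.size == 0:
            raise ValueError("stretch and stress must be equal-length 1D arrays")
        if lam[0] != 1.0:
            raise ValueError("curve must start at lambda = 1")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("stretch must be strictly increasing")
        object.__setattr__(self, "stretch", lam)
        object.__setattr__(self, "cauchy_stress_MPa", sig)


@dataclass(frozen=True)
class MechanicalSummary:
    initial_stiffness_MPa: float
    peak_stress_MPa: float
    stretch_at_peak: float
    group: str


def to_stress_stretch(record: TestRecord, convention: str = "cauchy") -> StressStretchCurve:
    """Convert force-displacement to a stress-stretch curve.

    lambda_i = (L0 + d_i)/L0. 'cauchy' (default) reports F*lambda/A0 in MPa
    (incompressible uniaxial extension); 'engineering' reports F/A0.
    """
    lam = (record.gauge_length_mm + record.displacement_mm) / record.gauge_length_mm
    nominal = record.force_N / record.cross_section_mm2  # N/mm^2 == MPa
    if convention == "cauchy":
        sigma = nominal * lam
    elif convention == "engineering":
        sigma = nominal
    else:
        raise ValueError("convention must be 'cauchy' or 'engineering'")
    return StressStretchCurve(lam, sigma)


def initial_stiffness(
    curve: StressStretchCurve, fit_window: tuple[float, float] = (1.0, 1.1)
) -> float:
    """Least-squares slope of sigma against (lambda - 1) inside ``fit_window``.

    The default window [1.0, 1.1] matches a preconditioning regime of 10% of
    gauge length; whether "initial stiffness" is a tangent or a small secant
    is a convention, so the window is a parameter.
    """
    lo, hi = fit_window
    sel = (curve.stretch >= lo) & (curve.stretch <= hi)
    if int(sel.sum()) < 3:
        raise ValueError(
            f"fewer than 3 samples in the stiffness fit window [{lo}, {hi}]"
        )
    x = curve.stretch[sel] - 1.0
    y = curve.cauchy_stress_MPa[sel]
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def peak_strength(curve: StressStretchCurve) -> tuple[float, float]:
    """Ultimate strength: global stress maximum and its stretch.

    Ties are broken toward the first occurrence.
    """
    idx = int(np.argmax(curve.cauchy_stress_MPa))
    return float(curve.cauchy_stress_MPa[idx]), float(curve.stretch[idx])


def assign_group(
    initial_stiffness_MPa: float, breakpoints: tuple[float, float] = (1.0, 2.0)
) -> str:
    """Stiffness group label with half-open intervals.

    LS below b1, MS in [b1, b2), HS at or above b2. The default breakpoints
    (1.0, 2.0 MPa) separate the three stiffness levels observed in carotid
    plaque specimens (~0.6-0.75 | 1.25-1.6 | ~3.8 MPa).
    """
    b1, b2 = breakpoints
    if not b1 < b2:
        raise ValueError("breakpoints must satisfy b1 < b2")
    if initial_stiffness_MPa < b1:
        return "LS"
    if initial_stiffness_MPa < b2:
        return "MS"
    return "HS"


def summarise(
    record: TestRecord,
    fit_window: tuple[float, float] = (1.0, 1.1),
    breakpoints: tuple[float, float] = (1.0, 2.0),
    convention: str = "cauchy",
) -> MechanicalSummary:
    """Full per-specimen mechanical summary from a raw test record."""
    curve = to_stress_stretch(record, convention)
    E = initial_stiffness(curve, fit_window)
    peak, lam_peak = peak_strength(curve)
    return MechanicalSummary(
        initial_stiffness_MPa=E,
        peak_stress_MPa=peak,
        stretch_at_peak=lam_peak,
        group=assign_group(E, breakpoints),
    )
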