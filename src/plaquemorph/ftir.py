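"""ATR-FTIR peak-area composition ratios.

Plaque composition is summarised by two ratios of baseline-corrected
absorbance band areas: lipid-to-collagen (Lip:Col) and
calcification-to-collagen (Calc:Col). Peak area is proportional to component
concentration, so the ratios track relative composition without an absolute
concentration calibration. Spectra are measured at several intimal-surface
locations per specimen and the per-location ratios are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BandWindow",
    "CompositionRatios",
    "default_windows",
    "integrate_band",
    "composition_ratios",
    "average_over_locations",
]


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly monotone wavenumber grid (cm^-1).

    Instruments conventionally store mid-IR spectra with descending
    wavenumber (4000 -> 700 cm^-1); ascending grids are accepted too.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or wn.shape != ab.shape:
            raise ValueError("wavenumbers and absorbance must be equal-length 1D arrays")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class BandWindow:
    """Integration window [low, high] cm^-1 for one component band.

    baseline_mode 'linear-endpoints' subtracts the chord between the
    window's endpoint absorbances (standard ATR practice); 'none' integrates
    the raw absorbance.
    """

    component: str
    low: float
    high: float
    baseline_mode: str = "linear-endpoints"
    anchor_points: int = 5  # samples averaged at each endpoint to anchor the chord

    def __post_init__(self):
        if not (700.0 <= self.low < self.high <= 4000.0):
            raise ValueError("window must satisfy 700 <= low < high <= 4000 cm^-1")
        if self.baseline_mode not in ("linear-endpoints", "none"):
            raise ValueError("baseline_mode must be 'linear-endpoints' or 'none'")
        if self.anchor_points < 1:
            raise ValueError("anchor_points must be >= 1")


def default_windows(baseline_mode: str = "linear-endpoints") -> dict[str, BandWindow]:
    """Default integration windows around standard mid-IR assignments.

    lipid: ester carbonyl stretch, 1780-1710 cm^-1; collagen: amide I,
    1700-1600 cm^-1; calcification: phosphate nu3 of hydroxyapatite,
    1100-960 cm^-1. All three are configuration, not constants of the method.
    """
    return {
        "lipid": BandWindow("lipid", 1710.0, 1780.0, baseline_mode),
        "collagen": BandWindow("collagen", 1600.0, 1700.0, baseline_mode),
        "calcification": BandWindow("calcification", 960.0, 1100.0, baseline_mode),
    }


@dataclass
class CompositionRatios:
    """Lip:Col and Calc:Col for one specimen (possibly averaged over locations)."""

    lip_col: float
    calc_col: float
    n_locations: int = 1
    per_location: pd.DataFrame | None = None


def integrate_band(spectrum: Spectrum, window: BandWindow) -> float:
    """Baseline-corrected trapezoidal area of one band, in absorbance * cm^-1.

    With ``linear-endpoints`` the baseline is the chord between the window's
    two endpoint absorbances, each estimated as the mean of the
    ``anchor_points`` innermost samples at that end (averaging the anchors is
    standard ATR practice and keeps single-sample noise from tilting the
    whole chord). A negative net area (band weaker than its local baseline)
    is floored at zero with a warning, since a concentration proxy cannot be
    negative.
    """
    wn = spectrum.wavenumbers
    ab = spectrum.absorbance
    if wn[0] > wn[-1]:  # integrate on an ascending axis
        wn = wn[::-1]
        ab = ab[::-1]
    if window.low < wn[0] or window.high > wn[-1]:
        raise ValueError(
            f"window [{window.low}, {window.high}] extends outside the "
            f"spectrum range [{wn[0]}, {wn[-1]}]"
        )
    sel = (wn >= window.low) & (wn <= window.high)
    if int(sel.sum()) < 3:
        raise ValueError("fewer than 3 samples inside the integration window")
    x = wn[sel]
    y = ab[sel]
    if window.baseline_mode == "linear-endpoints":
        k = min(window.anchor_points, len(y) // 2)
        y0, x0 = float(np.mean(y[:k])), float(np.mean(x[:k]))
        y1, x1 = float(np.mean(y[-k:])), float(np.mean(x[-k:]))
        baseline = y0 + (y1 - y0) * (x - x0) / (x1 - x0)
        y = y - baseline
    area = float(np.trapezoid(y, x))
    if area < 0:
        warnings.warn(
            f"negative net area in {window.component} window; floored at 0",
            stacklevel=2,
        )
        area = 0.0
    return area


def composition_ratios(
    spectrum: Spectrum, windows: dict[str, BandWindow] | None = None
) -> CompositionRatios:
    """Lip:Col and Calc:Col from one spectrum (one measurement location)."""
    if windows is None:
        windows = default_windows()
    for name in ("lipid", "collagen", "calcification"):
        if name not in windows:
            raise ValueError(f"missing integration window for {name}")
    col = integrate_band(spectrum, windows["collagen"])
    if col == 0:
        raise ZeroDivisionError("collagen band area is zero: ratios undefined")
    lip = integrate_band(spectrum, windows["lipid"])
    calc = integrate_band(spectrum, windows["calcification"])
    return CompositionRatios(lip_col=lip / col, calc_col=calc / col)


def average_over_locations(ratios: Sequence[CompositionRatios]) -> CompositionRatios:
    """Arithmetic mean of per-location ratios; per-location values retained."""
    if len(ratios) == 0:
        raise ValueError("no measurement locations")
    per = pd.DataFrame(
        {
            "lip_col": [r.lip_col for r in ratios],
            "calc_col": [r.calc_col for r in ratios],
        }
    )
    return CompositionRatios(
        lip_col=float(per["lip_col"].mean()),
        calc_col=float(per["calc_col"].mean()),
        n_locations=len(ratios),
        per_location=per,
    )
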