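"""Synthetic ground-truth generators for every pipeline stage.

No raw scans, spectra or tensile records are publicly deposited for the
carotid-plaque study this pipeline models, so validation rests on phantoms
with known ground truth:

* voxel phantoms emulating 16-bit reconstructed micro-CT volumes at 15.5 um
  isotropic voxels, with background / plaque-tissue / calcification grey
  levels and embedded inclusions of the three geometry classes (spheres,
  sheets, irregular agglomerates of overlapping spheres);
* mid-IR absorbance spectra (4000-700 cm^-1, 2 cm^-1 resolution) built from
  bands of specified integrated area, so composition ratios have exact
  targets;
* uniaxial force-displacement records derived from an exponential
  stiffening law sigma(lambda) = a (exp(b (lambda-1)) - 1), truncated at a
  rupture stretch, inverted through the same Cauchy-stress convention the
  mechanics module uses so round-trips are exact at zero noise.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .mechanics import TestRecord
from .ftir import Spectrum
from .morphometry import (
    UM_PER_MM,
    VoxelVolume,
    label_components,
    measure_surface_area,
)

__all__ = [
    "SphereSpec",
    "SheetSpec",
    "IrregularSpec",
    "BoxRegion",
    "PhantomSpec",
    "generate_phantom_volume",
    "sample_phantom_spec",
    "BandSpec",
    "SpectrumSpec",
    "generate_spectrum",
    "MechCurveSpec",
    "generate_mechanical_curve",
]


# ---------------------------------------------------------------------------
# inclusion primitives (coordinates and sizes in micrometres, z/y/x order)


@dataclass(frozen=True)
class SphereSpec:
    """A spherical calcification inclusion."""

    label: str
    centre_um: tuple[float, float, float]
    diameter_um: float

    @property
    def bounding_radius_um(self) -> float:
        return self.diameter_um / 2

    def contains(self, coords_um: np.ndarray) -> np.ndarray:
        r = self.diameter_um / 2
        d2 = ((coords_um - np.asarray(self.centre_um)) ** 2).sum(axis=-1)
        return d2 <= r * r

    def true_volume_mm3(self) -> float:
        return np.pi / 6 * (self.diameter_um / UM_PER_MM) ** 3

    def true_area_mm2(self) -> float:
        return np.pi * (self.diameter_um / UM_PER_MM) ** 2


@dataclass(frozen=True)
class SheetSpec:
    """A thin plate-like inclusion: box of length x width x thickness.

    ``rotation`` is a 3x3 matrix taking body axes (l, w, t) to grid axes;
    identity means the length lies along z, width along y, thickness along x.
    """

    label: str
    centre_um: tuple[float, float, float]
    length_um: float
    width_um: float
    thickness_um: float
    rotation: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    def __post_init__(self):
        if not (self.length_um > self.width_um > self.thickness_um > 0):
            raise ValueError("sheet must satisfy length > width > thickness > 0")

    @property
    def bounding_radius_um(self) -> float:
        return 0.5 * float(
            np.sqrt(self.length_um**2 + self.width_um**2 + self.thickness_um**2)
        )

    def contains(self, coords_um: np.ndarray) -> np.ndarray:
        R = np.asarray(self.rotation, dtype=float)
        body = (coords_um - np.asarray(self.centre_um)) @ R  # grid -> body axes
        half = np.array([self.length_um, self.width_um, self.thickness_um]) / 2
        return np.all(np.abs(body) <= half, axis=-1)

    def true_volume_mm3(self) -> float:
        l, w, t = (
            self.length_um / UM_PER_MM,
            self.width_um / UM_PER_MM,
            self.thickness_um / UM_PER_MM,
        )
        return l * w * t

    def true_area_mm2(self) -> float:
        l, w, t = (
            self.length_um / UM_PER_MM,
            self.width_um / UM_PER_MM,
            self.thickness_um / UM_PER_MM,
        )
        return 2 * (l * w + w * t + t * l)


@dataclass(frozen=True)
class IrregularSpec:
    """An agglomerated macro-node: the union of >= 3 overlapping spheres.

    Connectivity of the union is validated on the voxelised mask at
    generation time. True volume and area are numeric (supersampled
    voxelisation) because unions with triple overlaps have no closed form.
    """

    label: str
    lobes: tuple[tuple[tuple[float, float, float], float], ...]  # (centre, diameter)

    def __post_init__(self):
        if len(self.lobes) < 3:
            raise ValueError("irregular inclusion needs at least 3 sphere lobes")

    @property
    def centre_um(self) -> tuple[float, float, float]:
        cs = np.array([c for c, _ in self.lobes])
        return tuple(float(x) for x in cs.mean(axis=0))

    @property
    def bounding_radius_um(self) -> float:
        centre = np.asarray(self.centre_um)
        return max(
            float(np.linalg.norm(np.asarray(c) - centre)) + d / 2 for c, d in self.lobes
        )

    def contains(self, coords_um: np.ndarray) -> np.ndarray:
        inside = np.zeros(coords_um.shape[:-1], dtype=bool)
        for c, d in self.lobes:
            d2 = ((coords_um - np.asarray(c)) ** 2).sum(axis=-1)
            inside |= d2 <= (d / 2) ** 2
        return inside

    def true_volume_mm3(self, subsample_um: float = 4.0) -> float:
        mask, _ = self._fine_mask(subsample_um)
        return float(mask.sum()) * (subsample_um / UM_PER_MM) ** 3

    def true_area_mm2(self, subsample_um: float = 4.0) -> float:
        mask, _ = self._fine_mask(subsample_um)
        return measure_surface_area(mask, subsample_um)

    def _fine_mask(self, subsample_um: float):
        centre = np.asarray(self.centre_um)
        r = self.bounding_radius_um + 2 * subsample_um
        axes = [
            np.arange(centre[i] - r, centre[i] + r + subsample_um, subsample_um)
            for i in range(3)
        ]
        coords = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return self.contains(coords), coords


InclusionSpec = SphereSpec | SheetSpec | IrregularSpec


# ---------------------------------------------------------------------------
# phantom volumes


@dataclass(frozen=True)
class BoxRegion:
    """Plaque-tissue body: the central box of the grid with a margin fraction."""

    margin_frac: float = 0.05

    def mask(self, grid_shape, voxel_size_um) -> np.ndarray:
        mask = np.zeros(grid_shape, dtype=bool)
        lo = [int(np.floor(n * self.margin_frac)) for n in grid_shape]
        hi = [int(np.ceil(n * (1 - self.margin_frac))) for n in grid_shape]
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        return mask

    def bounds_um(self, grid_shape, voxel_size_um):
        lo = [np.floor(n * self.margin_frac) * voxel_size_um for n in grid_shape]
        hi = [np.ceil(n * (1 - self.margin_frac)) * voxel_size_um for n in grid_shape]
        return np.array(lo), np.array(hi)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one micro-CT phantom volume.

    Grey-level class means default to 100 (background), 700 (plaque tissue)
    and 1800 (calcification) on the 16-bit scale, sitting well inside the
    segmentation bands <324, 324-1249 and >=1250 GV; noise_sd is the
    per-voxel Gaussian grey-value noise.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_um: float = 15.5
    tissue_region: BoxRegion = BoxRegion()
    inclusions: tuple = ()
    background_mean: float = 100.0
    tissue_mean: float = 700.0
    calc_mean: float = 1800.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not all(int(n) > 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if not (self.background_mean < self.tissue_mean < self.calc_mean):
            raise ValueError("class means must be ordered background < tissue < calcification")
        labels = [inc.label for inc in self.inclusions]
        if len(set(labels)) != len(labels):
            raise ValueError("inclusion labels must be unique")
        for inc in self.inclusions:
            if isinstance(inc, SphereSpec) and inc.diameter_um <= 2 * self.voxel_size_um:
                raise ValueError(
                    f"inclusion {inc.label}: sphere diameter must exceed 2 voxels to be resolvable"
                )


def _voxel_centre_coords(grid_shape, voxel_size_um, sl=None):
    """Voxel-centre coordinates (um) for the full grid or a sub-slice."""
    if sl is None:
        sl = tuple(slice(0, n) for n in grid_shape)
    axes = [
        (np.arange(s.start, s.stop) + 0.5) * voxel_size_um for s in sl
    ]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _inclusion_mask(inc: InclusionSpec, spec: PhantomSpec) -> tuple[np.ndarray, tuple]:
    """Binary mask of one inclusion, restricted to its bounding sub-box."""
    vs = spec.voxel_size_um
    centre = np.asarray(inc.centre_um)
    r = inc.bounding_radius_um + vs
    lo = np.maximum(np.floor((centre - r) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((centre + r) / vs).astype(int), np.array(spec.grid_shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    coords = _voxel_centre_coords(spec.grid_shape, vs, sl)
    return inc.contains(coords), sl


def generate_phantom_volume(spec: PhantomSpec) -> tuple[VoxelVolume, pd.DataFrame]:
    """Voxelise a phantom and return the volume plus its ground-truth table.

    Voxels whose centres fall inside an inclusion primitive get
    calcification-class grey values; the tissue region gets tissue-class
    values; the rest is background. Gaussian noise of ``noise_sd`` GV is
    added and the result is rounded and clipped to 16-bit.

    Raises if an inclusion does not fit inside the tissue region or if two
    inclusions with different labels overlap (the ground truth would be
    ambiguous).
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    vs = spec.voxel_size_um
    tissue = spec.tissue_region.mask(shape, vs)
    class_grid = np.where(tissue, 1, 0).astype(np.int8)  # 0 bg, 1 tissue, 2 calc

    owner = np.zeros(shape, dtype=np.int32)  # voxel ownership for overlap detection
    rows = []
    for i, inc in enumerate(spec.inclusions, start=1):
        mask, sl = _inclusion_mask(inc, spec)
        if not mask.any():
            raise ValueError(f"inclusion {inc.label} voxelises to an empty set")
        if not np.all(tissue[sl][mask]):
            raise ValueError(f"inclusion {inc.label} extends outside the tissue region")
        taken = owner[sl][mask]
        if np.any(taken != 0):
            other = spec.inclusions[int(taken[taken != 0][0]) - 1].label
            raise ValueError(
                f"inclusions {inc.label} and {other} overlap: ground truth ambiguous"
            )
        owner[sl][mask] = i
        class_grid[sl][mask] = 2

        if isinstance(inc, SphereSpec):
            kind = "sphere"
            true_v, true_a = inc.true_volume_mm3(), inc.true_area_mm2()
        elif isinstance(inc, SheetSpec):
            kind = "sheet"
            true_v, true_a = inc.true_volume_mm3(), inc.true_area_mm2()
        else:
            kind = "irregular"
            true_v, true_a = inc.true_volume_mm3(), inc.true_area_mm2()
            n_comp = label_components(mask, 26)[1]
            if n_comp != 1:
                raise ValueError(
                    f"irregular inclusion {inc.label} is not connected at 26-connectivity"
                )
        cz, cy, cx = inc.centre_um
        rows.append(
            {
                "label": inc.label,
                "kind": kind,
                "centre_z_um": cz,
                "centre_y_um": cy,
                "centre_x_um": cx,
                "true_volume_mm3": true_v,
                "true_area_mm2": true_a,
                "true_equiv_diameter_um": (6 * true_v / np.pi) ** (1 / 3) * UM_PER_MM,
                "voxel_count": int(mask.sum()),
            }
        )

    means = np.array([spec.background_mean, spec.tissue_mean, spec.calc_mean])
    grey = means[class_grid]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grey = grey + rng.normal(0.0, spec.noise_sd, size=shape)
    grey = np.clip(np.rint(grey), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        rows,
        columns=[
            "label",
            "kind",
            "centre_z_um",
            "centre_y_um",
            "centre_x_um",
            "true_volume_mm3",
            "true_area_mm2",
            "true_equiv_diameter_um",
            "voxel_count",
        ],
    )
    return VoxelVolume(grey, vs), truth


def _random_rotation(rng: np.random.Generator) -> tuple:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return tuple(tuple(float(x) for x in row) for row in q)


def sample_phantom_spec(
    n_spheres: int = 16,
    n_sheets: int = 2,
    n_irregular: int = 2,
    grid_shape: tuple[int, int, int] = (200, 200, 200),
    voxel_size_um: float = 15.5,
    sphere_diameter_range_um: tuple[float, float] = (100.0, 250.0),
    sheet_dims_um: tuple[float, float, float] = (1200.0, 500.0, 80.0),
    irregular_lobes: int = 5,
    irregular_lobe_diameter_um: float = 220.0,
    noise_sd: float = 30.0,
    seed: int = 0,
) -> PhantomSpec:
    """Randomly place non-touching inclusions of all three classes.

    Placement is rejection sampling on bounding spheres separated by at
    least two voxels, inside the tissue region. Defaults give the standard
    validation phantom: a 200^3 grid (3.1 mm cube) at 15.5 um with 16
    spheres of 100-250 um, 2 sheets of 1200 x 500 x 80 um and 2 agglomerates
    of 5 overlapping ~220 um lobes, under 30 GV noise.
    """
    rng = np.random.default_rng(seed)
    spec0 = PhantomSpec(grid_shape, voxel_size_um, noise_sd=noise_sd, seed=seed)
    lo, hi = spec0.tissue_region.bounds_um(grid_shape, voxel_size_um)
    placed: list[tuple[np.ndarray, float]] = []
    inclusions: list[InclusionSpec] = []
    clearance = 2 * voxel_size_um

    def place(radius_um: float) -> np.ndarray:
        for _ in range(20000):
            c = rng.uniform(lo + radius_um + voxel_size_um, hi - radius_um - voxel_size_um)
            if all(
                np.linalg.norm(c - pc) > radius_um + pr + clearance for pc, pr in placed
            ):
                placed.append((c, radius_um))
                return c
        raise RuntimeError("could not place inclusion: phantom too crowded")

    # largest objects first so placement succeeds in a crowded grid
    for i in range(n_sheets):
        sheet = SheetSpec(
            label=f"sheet_{i}",
            centre_um=(0, 0, 0),
            length_um=sheet_dims_um[0],
            width_um=sheet_dims_um[1],
            thickness_um=sheet_dims_um[2],
            rotation=_random_rotation(rng),
        )
        c = place(sheet.bounding_radius_um)
        inclusions.append(replace(sheet, centre_um=tuple(float(x) for x in c)))

    for i in range(n_irregular):
        d = irregular_lobe_diameter_um
        offsets = [np.zeros(3)]
        for _ in range(irregular_lobes - 1):
            step = rng.normal(size=3)
            step *= (0.7 * d) / np.linalg.norm(step)  # overlap guaranteed: step < 2r
            offsets.append(offsets[rng.integers(len(offsets))] + step)
        offsets = np.array(offsets)
        offsets -= offsets.mean(axis=0)
        radius = max(np.linalg.norm(o) + d / 2 for o in offsets)
        c = place(radius)
        lobes = tuple(
            (tuple(float(x) for x in (c + o)), float(d * rng.uniform(0.8, 1.1)))
            for o in offsets
        )
        inclusions.append(IrregularSpec(label=f"irregular_{i}", lobes=lobes))

    d_lo, d_hi = sphere_diameter_range_um
    for i in range(n_spheres):
        d = float(rng.uniform(d_lo, d_hi))
        c = place(d / 2)
        inclusions.append(
            SphereSpec(label=f"sphere_{i}", centre_um=tuple(float(x) for x in c), diameter_um=d)
        )

    return replace(spec0, inclusions=tuple(inclusions))


# ---------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class BandSpec:
    """One absorption band with a specified integrated area."""

    component: str
    centre_cm1: float
    fwhm_cm1: float
    area: float
    shape: str = "gaussian"

    def __post_init__(self):
        if not (700.0 <= self.centre_cm1 <= 4000.0):
            raise ValueError("band centre must lie in [700, 4000] cm^-1")
        if self.area < 0:
            raise ValueError("band area must be non-negative")
        if self.fwhm_cm1 <= 0:
            raise ValueError("band FWHM must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("band shape must be 'gaussian' or 'lorentzian'")

    def profile(self, wn: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            sigma = self.fwhm_cm1 / (2 * np.sqrt(2 * np.log(2)))
            return (
                self.area
                / (sigma * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((wn - self.centre_cm1) / sigma) ** 2)
            )
        gamma = self.fwhm_cm1 / 2
        return self.area / np.pi * gamma / ((wn - self.centre_cm1) ** 2 + gamma**2)


def default_bands(
    lipid_area: float, collagen_area: float, calc_area: float
) -> tuple[BandSpec, ...]:
    """Bands at the standard assignments used by the default windows.

    Lipid ester C=O at 1745, collagen amide I at 1655, phosphate nu3 at
    1030 cm^-1. Default widths (FWHM 16 / 24 / 40 cm^-1) keep each band
    >= 3.4 sigma inside its default integration window, so the windowed
    area equals the specified area to well under 1%.
    """
    return (
        BandSpec("lipid", 1745.0, 16.0, lipid_area),
        BandSpec("collagen", 1655.0, 24.0, collagen_area),
        BandSpec("calcification", 1030.0, 40.0, calc_area),
    )


@dataclass(frozen=True)
class SpectrumSpec:
    """Grid, bands, baseline and noise of one synthetic spectrum."""

    bands: tuple[BandSpec, ...]
    wn_start_cm1: float = 4000.0
    wn_end_cm1: float = 700.0
    resolution_cm1: float = 2.0
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0  # absorbance per cm^-1
    noise_sd: float = 0.0
    seed: int = 0

    def grid(self) -> np.ndarray:
        n = int(round(abs(self.wn_start_cm1 - self.wn_end_cm1) / self.resolution_cm1)) + 1
        wn = np.linspace(self.wn_start_cm1, self.wn_end_cm1, n)
        if wn[0] == wn[-1] or self.resolution_cm1 <= 0:
            raise ValueError("degenerate wavenumber grid")
        return wn


def generate_spectrum(spec: SpectrumSpec) -> Spectrum:
    """Baseline + sum of bands + Gaussian noise on a descending grid."""
    wn = spec.grid()
    ab = spec.baseline_offset + spec.baseline_slope * (wn - wn.min())
    for band in spec.bands:
        ab = ab + band.profile(wn)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ab = ab + rng.normal(0.0, spec.noise_sd, size=wn.shape)
    return Spectrum(wn, ab)


# ---------------------------------------------------------------------------
# mechanical curves


@dataclass(frozen=True)
class MechCurveSpec:
    """Exponential-stiffening uniaxial test: sigma = a (exp(b (lambda-1)) - 1).

    a (MPa) scales the stress, b the stiffening rate; small-strain modulus
    is a*b. The curve is sampled on a uniform stretch grid up to the rupture
    stretch and converted to force through the incompressible Cauchy-stress
    convention, F = sigma * A0 / lambda, so the mechanics module recovers
    sigma(lambda) exactly at zero noise.
    """

    gauge_length_mm: float = 10.0
    cross_section_mm2: float = 10.0
    a_MPa: float = 0.05
    b: float = 5.0
    rupture_stretch: float = 1.44
    stretch_step: float = 0.002
    noise_sd_N: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.a_MPa <= 0 or self.b <= 0:
            raise ValueError("constitutive parameters a and b must be positive")
        if self.rupture_stretch <= 1:
            raise ValueError("rupture stretch must exceed 1")

    def stress(self, stretch: np.ndarray) -> np.ndarray:
        return self.a_MPa * (np.exp(self.b * (np.asarray(stretch) - 1.0)) - 1.0)


def generate_mechanical_curve(spec: MechCurveSpec) -> TestRecord:
    """Sample the constitutive curve up to rupture as a force-displacement record."""
    lam = np.arange(1.0, spec.rupture_stretch + spec.stretch_step / 2, spec.stretch_step)
    if lam[-1] < spec.rupture_stretch - 1e-12:
        lam = np.append(lam, spec.rupture_stretch)
    sigma = spec.stress(lam)
    force = sigma * spec.cross_section_mm2 / lam
    if spec.noise_sd_N > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd_N, size=lam.shape)
        noise[0] = 0.0  # the unloaded state is exact by definition
        force = force + noise
    displacement = (lam - 1.0) * spec.gauge_length_mm
    return TestRecord(
        displacement_mm=displacement,
        force_N=force,
        gauge_length_mm=spec.gauge_length_mm,
        cross_section_mm2=spec.cross_section_mm2,
    )
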