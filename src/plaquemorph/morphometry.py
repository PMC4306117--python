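"""Grey-value segmentation and 3D morphometry of calcification inclusions.

The micro-CT characterisation pipeline: calibrate grey values, threshold the
volume into plaque tissue and calcification, extract connected calcification
components, measure each one (volume, mesh surface area, sphericity,
equivalent diameter, principal extents), classify its geometry
(spherical / sheet / irregular) and compute the calcification volume
fraction (CVF) of the specimen.

Units follow the field's conventions: voxel size in micrometres, volumes in
mm^3, areas in mm^2, diameters and extents in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

__all__ = [
    "VoxelVolume",
    "ThresholdConfig",
    "MorphometryParams",
    "InclusionRecord",
    "MorphometryReport",
    "fit_calibration",
    "calibrate_grey_values",
    "segment_volume",
    "label_components",
    "measure_volume",
    "measure_surface_area",
    "sphericity",
    "equivalent_diameter",
    "principal_extents",
    "classify_inclusion",
    "compute_cvf",
    "run_morphometry",
]

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class VoxelVolume:
    """A reconstructed grey-value volume with isotropic voxel spacing.

    Parameters
    ----------
    grid : ndarray, shape (nz, ny, nx)
        Grey values on the 16-bit scale [0, 65535].
    voxel_size_um : float
        Isotropic voxel edge length in micrometres (15.5 um for the
        scans this pipeline models).
    """

    grid: np.ndarray
    voxel_size_um: float = 15.5

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3 or grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if grid.min() < 0 or grid.max() > 65535:
            raise ValueError("grey values must lie in [0, 65535]")
        object.__setattr__(self, "grid", grid)

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um / UM_PER_MM) ** 3


@dataclass(frozen=True)
class ThresholdConfig:
    """Fixed grey-value bands separating background, tissue and calcification.

    Defaults are the published bands: plaque tissue 324-1249 GV,
    calcification above that. GV 1250 itself is assigned to calcification
    (the >= convention keeps the bands contiguous).
    """

    tissue_low: int = 324
    tissue_high: int = 1249
    calc_low: int = 1250

    def __post_init__(self):
        if not (self.tissue_low < self.tissue_high < self.calc_low):
            raise ValueError(
                "thresholds must satisfy tissue_low < tissue_high < calc_low"
            )


@dataclass(frozen=True)
class MorphometryParams:
    """Tunable parameters of inclusion extraction and classification.

    connectivity : 26 (default) or 6 voxel neighbourhood for component
        labelling.
    psi_min : sphericity floor of the spherical class (mesh-measured true
        spheres score ~0.99 with the default area estimator).
    aspect_ratio : minimum l/w and w/t ratio of the sheet class.
    diameter_max_um : upper diameter bound of the spherical class.
    diameter_convention : 'equivalent' uses the volume-equivalent sphere
        diameter for the size rule; 'max_extent' uses the longest
        principal extent.
    smooth_sigma : Gaussian pre-smoothing (in voxels) applied to the binary
        component before meshing its surface.
    mesh_psi_tolerance : documented slack above 1 allowed for sphericity of
        near-spherical meshes before a record is flagged.
    """

    connectivity: int = 26
    psi_min: float = 0.85
    aspect_ratio: float = 2.0
    diameter_max_um: float = 300.0
    diameter_convention: str = "equivalent"
    smooth_sigma: float = 1.0
    mesh_psi_tolerance: float = 0.02

    def __post_init__(self):
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.diameter_convention not in ("equivalent", "max_extent"):
            raise ValueError("diameter_convention must be 'equivalent' or 'max_extent'")


@dataclass
class InclusionRecord:
    """Morphometric measurements of one connected calcification component."""

    label: int
    voxel_count: int
    volume_mm3: float
    surface_area_mm2: float
    sphericity: float
    equivalent_diameter_um: float
    length_um: float
    width_um: float
    thickness_um: float
    centroid_mm: tuple[float, float, float]
    geometry_class: str = ""
    flags: list[str] = field(default_factory=list)


@dataclass
class MorphometryReport:
    """Per-inclusion records plus specimen-level totals."""

    records: list[InclusionRecord]
    total_calc_volume_mm3: float
    total_tissue_volume_mm3: float
    cvf: float | None
    class_counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "label": r.label,
                    "voxel_count": r.voxel_count,
                    "volume_mm3": r.volume_mm3,
                    "surface_area_mm2": r.surface_area_mm2,
                    "sphericity": r.sphericity,
                    "equivalent_diameter_um": r.equivalent_diameter_um,
                    "length_um": r.length_um,
                    "width_um": r.width_um,
                    "thickness_um": r.thickness_um,
                    "centroid_z_mm": r.centroid_mm[0],
                    "centroid_y_mm": r.centroid_mm[1],
                    "centroid_x_mm": r.centroid_mm[2],
                    "geometry_class": r.geometry_class,
                    "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration and segmentation


def fit_calibration(
    reference_points: Sequence[tuple[str, float, float]],
) -> tuple[float, float]:
    """Least-squares (slope, intercept) of target value against measured GV."""
    if len(reference_points) < 2:
        raise ValueError("need at least 2 reference points")
    measured = np.array([p[1] for p in reference_points], dtype=float)
    target = np.array([p[2] for p in reference_points], dtype=float)
    if np.ptp(measured) == 0:
        raise ValueError("reference points have identical measured grey values: singular fit")
    slope, intercept = np.polyfit(measured, target, 1)
    return float(slope), float(intercept)


def calibrate_grey_values(
    volume: VoxelVolume,
    reference_points: Sequence[tuple[str, float, float]],
) -> VoxelVolume:
    """Least-squares linear rescaling of grey values against reference materials.

    ``reference_points`` holds (material, measured_gv, target_value) triples,
    e.g. air and water measurements mapped onto a Hounsfield-like scale. With
    exactly two points the fitted line interpolates both; with more, it is the
    ordinary least-squares line. The result is rounded and clipped back to
    the 16-bit range.
    """
    slope, intercept = fit_calibration(reference_points)
    rescaled = slope * volume.grid.astype(float) + intercept
    rescaled = np.clip(np.rint(rescaled), 0, 65535).astype(volume.grid.dtype)
    return VoxelVolume(rescaled, volume.voxel_size_um)


def segment_volume(
    volume: VoxelVolume, thresholds: ThresholdConfig = ThresholdConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold a volume into disjoint tissue and calcification masks.

    Voxels in [tissue_low, tissue_high] are plaque tissue; voxels at or above
    calc_low are calcification; everything below tissue_low is background and
    belongs to neither mask.
    """
    grid = volume.grid
    tissue_mask = (grid >= thresholds.tissue_low) & (grid <= thresholds.tissue_high)
    calc_mask = grid >= thresholds.calc_low
    return tissue_mask, calc_mask


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_components(calc_mask: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Partition a binary mask into maximal connected components.

    Returns the labelled array (0 = background) and the component count.
    26-neighbour connectivity is the default so that corner-touching
    agglomerate lobes count as one inclusion.
    """
    if calc_mask.dtype != bool:
        calc_mask = calc_mask.astype(bool)
    labels, n = ndimage.label(calc_mask, structure=_STRUCTS[connectivity])
    return labels, n


# ---------------------------------------------------------------------------
# per-component measurements


def measure_volume(component_mask: np.ndarray, voxel_size_um: float) -> float:
    """Component volume in mm^3: voxel count times voxel volume."""
    count = int(np.count_nonzero(component_mask))
    if count == 0:
        raise ValueError("empty component")
    return count * (voxel_size_um / UM_PER_MM) ** 3


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    # divergence theorem: sum of signed tetrahedra against the origin
    v0 = verts[faces[:, 0]]
    v1 = verts[faces[:, 1]]
    v2 = verts[faces[:, 2]]
    return abs(float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum())) / 6.0


def measure_surface_area(
    component_mask: np.ndarray,
    voxel_size_um: float,
    smooth_sigma: float = 1.0,
    _flags: list[str] | None = None,
) -> float:
    """Mesh surface area of one component in mm^2.

    The binary mask is Gaussian-smoothed (``smooth_sigma`` voxels) and an
    isosurface is extracted with marching cubes at the level, found by
    bisection, at which the mesh encloses exactly the component's voxel
    volume. Matching the enclosed volume removes both the staircase bias of
    meshing the raw mask (which overestimates a digitised sphere's area by
    ~9%) and the curvature shrinkage of a fixed 0.5 level on small blobs.
    Sharp edges are slightly rounded, so thin plates with crisp corners read
    a few percent low; smooth physiological shapes are measured to ~1%.

    Components thinner than 2 voxels along every axis cannot be meshed and
    fall back to the summed voxel-face area (flagged).
    """
    mask = component_mask.astype(bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty component")
    vs_mm = voxel_size_um / UM_PER_MM

    objslice = ndimage.find_objects(mask.astype(np.int8))[0]
    mask = mask[objslice]
    extents = mask.shape
    if min(extents) < 2:
        if _flags is not None:
            _flags.append("voxel_face_area_fallback")
        return _voxel_face_area(mask) * vs_mm**2

    pad = max(3, int(np.ceil(3 * smooth_sigma)))
    f = ndimage.gaussian_filter(np.pad(mask, pad).astype(float), smooth_sigma)

    def mesh_at(level):
        verts, faces, _, _ = skmeasure.marching_cubes(f, level)
        return verts, faces

    fmax = float(f.max())
    lo, hi = 0.02, min(0.98, fmax - 1e-6)
    if hi <= lo:
        if _flags is not None:
            _flags.append("voxel_face_area_fallback")
        return _voxel_face_area(mask) * vs_mm**2
    target = float(count)
    for _ in range(24):
        level = 0.5 * (lo + hi)
        verts, faces = mesh_at(level)
        if _mesh_volume(verts, faces) > target:
            lo = level
        else:
            hi = level
    verts, faces = mesh_at(0.5 * (lo + hi))
    return float(skmeasure.mesh_surface_area(verts, faces)) * vs_mm**2


def _voxel_face_area(mask: np.ndarray) -> float:
    """Exposed voxel faces, in voxel-face units (voxel_size^2)."""
    area = 0
    m = np.pad(mask, 1)
    for axis in range(3):
        area += int(np.count_nonzero(np.diff(m.astype(np.int8), axis=axis) != 0))
    return float(area)


def sphericity(volume_mm3: float, surface_area_mm2: float) -> float:
    """psi = pi^(1/3) (6 V_p)^(2/3) / A_p; 1 for a perfect sphere."""
    if volume_mm3 <= 0 or surface_area_mm2 <= 0:
        raise ValueError("volume and surface area must be positive")
    return float(np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / surface_area_mm2)


def equivalent_diameter(volume_mm3: float) -> float:
    """Diameter (um) of the sphere with the same volume: d = (6V/pi)^(1/3)."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    return float((6 * volume_mm3 / np.pi) ** (1 / 3) * UM_PER_MM)


def principal_extents(
    component_mask: np.ndarray, voxel_size_um: float
) -> tuple[float, float, float]:
    """Length, width, thickness (um) along the component's principal axes.

    Peak-to-peak spans of voxel-centre coordinates projected on the
    eigenvectors of the coordinate covariance, plus one voxel size for the
    finite voxel extent; returned sorted l >= w >= t.
    """
    coords = np.argwhere(component_mask).astype(float)
    if coords.shape[0] == 0:
        raise ValueError("empty component")
    if coords.shape[0] == 1:
        return (voxel_size_um,) * 3
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0]
    _, eigvecs = np.linalg.eigh(cov)
    proj = centred @ eigvecs
    spans = np.ptp(proj, axis=0) + 1.0
    spans = np.sort(spans)[::-1] * voxel_size_um
    return tuple(float(s) for s in spans)


def classify_inclusion(
    record: InclusionRecord, params: MorphometryParams = MorphometryParams()
) -> str:
    """Assign one of the three calcification geometry classes.

    spherical: diameter below ``diameter_max_um`` and sphericity at least
    ``psi_min``; else sheet when both principal aspect ratios l/w and w/t
    reach ``aspect_ratio``; everything else is an irregular agglomerate.
    The order makes the classes mutually exclusive; ties fall to irregular.
    """
    if params.diameter_convention == "equivalent":
        d = record.equivalent_diameter_um
    else:
        d = record.length_um
    if d < params.diameter_max_um and record.sphericity >= params.psi_min:
        return "spherical"
    if (
        record.width_um > 0
        and record.thickness_um > 0
        and record.length_um / record.width_um >= params.aspect_ratio
        and record.width_um / record.thickness_um >= params.aspect_ratio
    ):
        return "sheet"
    return "irregular"


def compute_cvf(total_calc_volume_mm3: float, total_tissue_volume_mm3: float) -> float:
    """Calcification volume fraction: calc / (calc + tissue)."""
    total = total_calc_volume_mm3 + total_tissue_volume_mm3
    if total <= 0:
        raise ValueError("CVF undefined: no segmented plaque volume")
    return total_calc_volume_mm3 / total


# ---------------------------------------------------------------------------
# pipeline


def run_morphometry(
    volume: VoxelVolume,
    thresholds: ThresholdConfig = ThresholdConfig(),
    params: MorphometryParams = MorphometryParams(),
) -> MorphometryReport:
    """Segment, label, measure and classify every calcification inclusion."""
    tissue_mask, calc_mask = segment_volume(volume, thresholds)
    labels, n = label_components(calc_mask, params.connectivity)
    vs = volume.voxel_size_um
    vs_mm = vs / UM_PER_MM

    records: list[InclusionRecord] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        comp = labels[sl] == lab
        flags: list[str] = []
        count = int(comp.sum())
        if count == 1:
            flags.append("single_voxel_low_confidence")
        vol = measure_volume(comp, vs)
        area = measure_surface_area(comp, vs, params.smooth_sigma, _flags=flags)
        psi = sphericity(vol, area)
        if psi > 1.0 + params.mesh_psi_tolerance:
            flags.append("sphericity_above_unity")
        l, w, t = principal_extents(comp, vs)
        offset = np.array([s.start for s in sl], dtype=float)
        centroid_vox = np.argwhere(comp).mean(axis=0) + offset
        centroid_mm = tuple(float(c) * vs_mm for c in centroid_vox)
        rec = InclusionRecord(
            label=lab,
            voxel_count=count,
            volume_mm3=vol,
            surface_area_mm2=area,
            sphericity=psi,
            equivalent_diameter_um=equivalent_diameter(vol),
            length_um=l,
            width_um=w,
            thickness_um=t,
            centroid_mm=centroid_mm,
            flags=flags,
        )
        rec.geometry_class = classify_inclusion(rec, params)
        records.append(rec)

    total_calc = float(np.count_nonzero(calc_mask)) * vs_mm**3
    total_tissue = float(np.count_nonzero(tissue_mask)) * vs_mm**3
    if total_calc + total_tissue > 0:
        cvf = compute_cvf(total_calc, total_tissue)
    else:
        warnings.warn("all-background volume: CVF undefined", stacklevel=2)
        cvf = None
    counts = {"spherical": 0, "sheet": 0, "irregular": 0}
    for r in records:
        counts[r.geometry_class] += 1
    return MorphometryReport(
        records=records,
        total_calc_volume_mm3=total_calc,
        total_tissue_volume_mm3=total_tissue,
        cvf=cvf,
        class_counts=counts,
    )
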