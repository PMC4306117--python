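"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as numbered TIFF slice series (one 2D image per z slice) with
a JSON sidecar carrying the voxel size in micrometres, matching how
reconstructed micro-CT stacks are exported; a single multi-page 3D TIFF is
accepted too. Spectra are two-column wavenumber/absorbance text files and
tensile tests are CSV with commented metadata header lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ftir import Spectrum
from .mechanics import TestRecord
from .morphometry import MorphometryReport, VoxelVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_spectrum",
    "read_spectrum",
    "write_test_record",
    "read_test_record",
    "write_morphometry_report",
]

SIDECAR = "volume.json"


def write_volume(directory: str | Path, volume: VoxelVolume) -> Path:
    """Write a volume as slice_0000.tif ... plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for z in range(volume.grid.shape[0]):
        tifffile.imwrite(directory / f"slice_{z:04d}.tif", volume.grid[z])
    meta = {
        "voxel_size_um": volume.voxel_size_um,
        "grid_shape": list(volume.grid.shape),
    }
    (directory / SIDECAR).write_text(json.dumps(meta, indent=2))
    return directory


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> VoxelVolume:
    """Read a slice directory (with sidecar) or a single 3D TIFF."""
    path = Path(path)
    if path.is_dir():
        sidecar = path / SIDECAR
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            voxel_size_um = meta["voxel_size_um"]
        if voxel_size_um is None:
            raise ValueError("voxel size not given and no sidecar found")
        slices = sorted(path.glob("slice_*.tif"))
        if not slices:
            raise FileNotFoundError(f"no slice_*.tif files in {path}")
        grid = np.stack([tifffile.imread(s) for s in slices])
    else:
        if voxel_size_um is None:
            raise ValueError("voxel size required when reading a bare TIFF")
        grid = tifffile.imread(path)
    return VoxelVolume(grid, voxel_size_um)


def write_spectrum(path: str | Path, spectrum: Spectrum) -> Path:
    """Two-column text: wavenumber_cm-1, absorbance (grid order preserved)."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([spectrum.wavenumbers, spectrum.absorbance]),
        fmt="%.6f",
        header="wavenumber_cm-1 absorbance",
    )
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path} is not a two-column spectrum file")
    return Spectrum(data[:, 0], data[:, 1])


def write_test_record(path: str | Path, record: TestRecord) -> Path:
    """CSV of displacement/force with gauge length and cross-section in the header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# gauge_length_mm = {record.gauge_length_mm}\n")
        fh.write(f"# cross_section_mm2 = {record.cross_section_mm2}\n")
        fh.write("displacement_mm,force_N\n")
        for d, f in zip(record.displacement_mm, record.force_N):
            fh.write(f"{d:.9g},{f:.9g}\n")
    return path


def read_test_record(path: str | Path) -> TestRecord:
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = float(value)
            body_start = i + 1
        else:
            break
    for key in ("gauge_length_mm", "cross_section_mm2"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata header '# {key} = ...'")
    df = pd.read_csv(path, skiprows=body_start)
    return TestRecord(
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
        gauge_length_mm=meta["gauge_length_mm"],
        cross_section_mm2=meta["cross_section_mm2"],
    )


def write_morphometry_report(directory: str | Path, report: MorphometryReport) -> Path:
    """Per-inclusion CSV plus a JSON summary (CVF, totals, class counts)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(directory / "inclusions.csv", index=False)
    summary = {
        "total_calc_volume_mm3": report.total_calc_volume_mm3,
        "total_tissue_volume_mm3": report.total_tissue_volume_mm3,
        "cvf": report.cvf,
        "class_counts": report.class_counts,
        "n_inclusions": len(report.records),
    }
    (directory / "summary.json").write_text(json.dumps(summary, indent=2))
    return directory
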