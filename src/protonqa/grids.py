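"""3D dose grids and 1D profiles: containers, validation, I/O and slicing.

The central exchange object is :class:`DoseGrid3D`, a regular scalar dose
field with explicit geometry.  Coordinate convention (used everywhere in the
package): 0-based voxel indices, voxel-center positions, so the physical
coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing`` per axis.
Values are absorbed dose in Gy, indexed ``values[ix, iy, iz]``.

Supported formats:

* DICOM RT Dose (read/write, uniform ``GridFrameOffsetVector`` required),
* an internal self-describing NumPy container (``.npz``),
* two-column CSV for :class:`Profile1D`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DoseGrid3D",
    "Profile1D",
    "GridFormatError",
    "read_dose_grid",
    "write_dose_grid",
    "extract_axis_profile",
    "read_profile",
    "write_profile",
]

_AXES = {"x": 0, "y": 1, "z": 2}

# DICOM dose is quantized by DoseGridScaling; pick the scaling so that the
# grid maximum maps near the top of the uint32 range (>= 6 significant digits).
_DICOM_MAX_INT = 2**32 - 1


class GridFormatError(ValueError):
    """File does not describe a valid regular dose grid."""


@dataclass(frozen=True)
class DoseGrid3D:
    """Regular 3D dose grid with voxel-center geometry.

    Parameters
    ----------
    origin : (3,) array_like
        Physical position (mm) of the center of voxel (0, 0, 0).
    spacing : (3,) array_like
        Voxel spacing (mm) per axis; all strictly positive.
    values : (nx, ny, nz) ndarray
        Dose per voxel in Gy; finite and non-negative.
    frame : str
        Which grid axis is the beam/depth axis: ``"x"``, ``"y"`` or ``"z"``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    frame: str = "z"

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be length-3")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("all spacings must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")
        if self.frame not in _AXES:
            raise ValueError(f"frame must be one of {sorted(_AXES)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def depth_axis(self) -> int:
        return _AXES[self.frame]

    def axis_coords(self, axis: int | str) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        a = _AXES[axis] if isinstance(axis, str) else axis
        return self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "DoseGrid3D", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "DoseGrid3D":
        return replace(self, values=values)

    def slice_plane(self, axis: int | str, coord: float) -> np.ndarray:
        """Nearest-plane 2D slice perpendicular to ``axis`` at ``coord`` (mm)."""
        a = _AXES[axis] if isinstance(axis, str) else axis
        coords = self.axis_coords(a)
        if coord < coords[0] - 0.5 * self.spacing[a] or coord > coords[-1] + 0.5 * self.spacing[a]:
            raise ValueError(f"coordinate {coord} mm outside grid along axis {a}")
        idx = int(np.argmin(np.abs(coords - coord)))
        return np.take(self.values, idx, axis=a)


@dataclass(frozen=True)
class Profile1D:
    """1D dose profile: strictly increasing positions (mm) and dose values."""

    positions: np.ndarray
    values: np.ndarray
    kind: str = "depth"  # {"depth", "lateral"}

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be 1D and the same length")
        if self.positions.size >= 2 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.kind not in ("depth", "lateral"):
            raise ValueError("kind must be 'depth' or 'lateral'")

    def __len__(self) -> int:
        return self.positions.size

    def interp(self, x) -> np.ndarray:
        return np.interp(x, self.positions, self.values)


# ---------------------------------------------------------------------------
# Internal container (.npz)
# ---------------------------------------------------------------------------

def _write_internal(grid: DoseGrid3D, path: str) -> None:
    np.savez(
        path,
        origin=grid.origin,
        spacing=grid.spacing,
        values=grid.values,
        frame=np.array(grid.frame),
    )


def _read_internal(path: str) -> DoseGrid3D:
    with np.load(path, allow_pickle=False) as data:
        for key in ("origin", "spacing", "values"):
            if key not in data:
                raise GridFormatError(f"internal grid file missing field '{key}'")
        frame = str(data["frame"]) if "frame" in data else "z"
        return DoseGrid3D(data["origin"], data["spacing"], data["values"], frame=frame)


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

def _write_dicom(grid: DoseGrid3D, path: str) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    rt_dose_class = "1.2.840.10008.5.1.4.1.1.481.2"

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(rt_dose_class)
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = rt_dose_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.PatientName = ""
    ds.PatientID = ""

    nx, ny, nz = grid.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # row, col
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2]) for k in range(nz)]
    ds.FrameOfReferenceUID = generate_uid()

    vmax = float(grid.values.max())
    scaling = vmax / _DICOM_MAX_INT if vmax > 0 else 1.0
    # DICOM frames are (z, y, x)
    pixels = np.round(grid.values.transpose(2, 1, 0) / scaling if vmax > 0 else
                      grid.values.transpose(2, 1, 0)).astype(np.uint32)
    ds.DoseGridScaling = scaling
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.tobytes()

    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: str) -> DoseGrid3D:
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise GridFormatError("not an RT Dose file")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if offsets.size < 2:
        raise GridFormatError("RT Dose must contain at least two frames")
    steps = np.diff(offsets)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise GridFormatError(f"non-uniform GridFrameOffsetVector steps: {steps}")
    dz = float(steps[0])
    if dz <= 0:
        raise GridFormatError("GridFrameOffsetVector must be increasing")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = np.asarray([float(v) for v in ds.ImagePositionPatient])
    origin = origin + np.array([0.0, 0.0, float(offsets[0])])
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    if values.ndim == 2:
        values = values[None]
    values = values.transpose(2, 1, 0)
    if np.any(values < 0):
        raise GridFormatError("negative dose values in file")
    return DoseGrid3D(origin, np.array([col_sp, row_sp, dz]), values)


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def write_dose_grid(grid: DoseGrid3D, path: str, format: str = "internal") -> None:
    """Write a dose grid; ``format`` is ``"internal"`` (.npz) or ``"dicom-rt-dose"``."""
    if format == "internal":
        _write_internal(grid, path)
    elif format == "dicom-rt-dose":
        _write_dicom(grid, path)
    else:
        raise ValueError(f"unknown grid format: {format}")


def read_dose_grid(path: str, format: str | None = None) -> DoseGrid3D:
    """Read a dose grid, sniffing the format from the extension if not given."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "internal" if str(path).endswith(".npz") else "dicom-rt-dose"
    if format == "internal":
        return _read_internal(path)
    if format == "dicom-rt-dose":
        return _read_dicom(path)
    raise ValueError(f"unknown grid format: {format}")


def extract_axis_profile(
    grid: DoseGrid3D,
    axis: int | str = "z",
    mode: str = "integrated",
    point: tuple[float, float, float] | None = None,
) -> Profile1D:
    """Extract a 1D profile along a grid axis.

    ``integrated`` mode sums every plane perpendicular to ``axis`` times the
    voxel cross-area (units Gy*mm^2) — the integrated radial profile (IRPD)
    when the axis is the beam axis.  ``line-through-point`` samples the voxel
    line nearest to ``point``.
    """
    a = _AXES[axis] if isinstance(axis, str) else axis
    if a not in (0, 1, 2):
        raise ValueError("axis must be 0, 1, 2 or 'x', 'y', 'z'")
    positions = grid.axis_coords(a)
    others = [i for i in range(3) if i != a]
    if mode == "integrated":
        cross_area = float(grid.spacing[others[0]] * grid.spacing[others[1]])
        values = grid.values.sum(axis=tuple(others)) * cross_area
    elif mode == "line-through-point":
        if point is None:
            raise ValueError("line-through-point mode requires a point")
        point = np.asarray(point, dtype=float)
        idx = [0, 0, 0]
        for i in others:
            coords = grid.axis_coords(i)
            if point[i] < coords[0] - 0.5 * grid.spacing[i] or point[i] > coords[-1] + 0.5 * grid.spacing[i]:
                raise ValueError(f"point outside grid along axis {i}")
            idx[i] = int(np.argmin(np.abs(coords - point[i])))
        slicer = tuple(slice(None) if i == a else idx[i] for i in range(3))
        values = grid.values[slicer]
    else:
        raise ValueError("mode must be 'integrated' or 'line-through-point'")
    kind = "depth" if a == grid.depth_axis else "lateral"
    return Profile1D(positions, values, kind=kind)


def write_profile(profile: Profile1D, path: str) -> None:
    """Write a profile as two-column CSV (position_mm, value)."""
    arr = np.column_stack([profile.positions, profile.values])
    np.savetxt(path, arr, delimiter=",", header=f"position_mm,value ({profile.kind})")


def read_profile(path: str, kind: str = "depth") -> Profile1D:
    arr = np.loadtxt(path, delimiter=",")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise GridFormatError("profile CSV must have two columns")
    return Profile1D(arr[:, 0], arr[:, 1], kind=kind)
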