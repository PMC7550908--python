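"""Data model and I/O for dose grids, structure masks, and planar contour sets.

Conventions
-----------
* All physical coordinates are patient millimetres, right-handed.
* Voxel addressing is 0-based with *center* semantics: voxel ``(i, j, k)``
  has its center at ``origin + (i*dx, j*dy, k*dz)``.
* Arrays are indexed ``[i, j, k]`` matching the grid ``shape = (nx, ny, nz)``;
  slices are indexed by ``k`` (the z axis).
* Voxel volume is reported in cc: ``dx*dy*dz / 1000``.

Three on-disk dialects are supported:

``json-contours``
    A JSON file holding one contour set (``{"name": ..., "slices":
    [{"z": ..., "polygons": [[[x, y], ...], ...]}]}``) or a list of them.
``mask-volume`` / dose volumes
    NIfTI (via nibabel) with an axis-aligned affine carrying spacing and
    origin; the header ``descrip`` field carries the structure name/source.
``dicom-rt``
    Read-only: RT Structure Set contours and RT Dose grids via pydicom.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath
from typing import Sequence

import numpy as np
from matplotlib.path import Path as PolyPath
from scipy import ndimage

from .errors import (
    ConfigurationError,
    DegenerateContourError,
    InvalidArgumentError,
    InvalidGridError,
    OutOfExtentError,
    ParseError,
)

logger = logging.getLogger("contourdose")

__all__ = [
    "GridSpec",
    "DoseGrid",
    "StructureMask",
    "ContourSet",
    "ContourSlice",
    "rasterize_contours",
    "resample_dose",
    "expand_margin",
    "read_structures",
    "write_structures",
    "read_dose",
    "write_dose",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular 3D lattice: voxel counts, spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise InvalidGridError(f"shape entries must be >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise InvalidGridError(f"spacings must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates in mm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def centers_mm(self) -> np.ndarray:
        """All voxel centers, shape ``(nx, ny, nz, 3)`` in mm."""
        ax = self.axes_mm()
        grid = np.meshgrid(*ax, indexing="ij")
        return np.stack(grid, axis=-1)

    def compatible(self, other: "GridSpec", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a regular grid."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise InvalidGridError(
                f"dose lattice {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidArgumentError("dose values must be finite and >= 0 Gy")


@dataclass
class StructureMask:
    """Boolean voxel volume for one named structure on a named grid."""

    grid: GridSpec
    voxels: np.ndarray
    name: str = ""
    source: str = "manual"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise InvalidGridError(
                f"mask lattice {self.voxels.shape} does not match grid {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class ContourSlice:
    """One axial slice of a delineation: z in mm plus closed planar polygons.

    Each polygon is an ``(n, 2)`` array of (x, y) vertices in mm; the first
    vertex is implicitly joined to the last.
    """

    z: float
    polygons: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.polygons = [np.asarray(p, dtype=float).reshape(-1, 2) for p in self.polygons]


@dataclass
class ContourSet:
    """Per-slice planar contours for one structure (DICOM-RT style)."""

    name: str
    slices: list[ContourSlice] = field(default_factory=list)
    source: str = "manual"


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_contours(contours: ContourSet, grid: GridSpec) -> StructureMask:
    """Rasterize planar contours onto a grid using the even-odd rule.

    A voxel is inside iff its center lies inside an odd number of that
    slice's polygons, which supports holes and multiply connected slices.
    Each contour z must map onto a grid slice within half a slice thickness.
    """
    nx, ny, nz = grid.shape
    dx, dy, dz = grid.spacing
    ox, oy, oz = grid.origin
    voxels = np.zeros(grid.shape, dtype=bool)

    xs = ox + dx * np.arange(nx)
    ys = oy + dy * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])

    for sl in contours.slices:
        k = int(round((sl.z - oz) / dz))
        if k < 0 or k >= nz or abs(sl.z - (oz + k * dz)) > dz / 2 + 1e-9:
            raise OutOfExtentError(
                f"contour slice z={sl.z} mm of '{contours.name}' lies outside the grid extent"
            )
        parity = np.zeros(points.shape[0], dtype=bool)
        for poly in sl.polygons:
            if poly.shape[0] < 3:
                raise DegenerateContourError(
                    f"polygon with {poly.shape[0]} vertices in '{contours.name}' at z={sl.z}"
                )
            # explicit closure: Path(..., closed=True) would drop the last edge
            inside = PolyPath(np.vstack([poly, poly[:1]]), closed=True).contains_points(points)
            parity ^= inside  # XOR across polygons = even-odd parity
        voxels[:, :, k] ^= parity.reshape(nx, ny)

    return StructureMask(grid=grid, voxels=voxels, name=contours.name, source=contours.source)


# ---------------------------------------------------------------------------
# Resampling and margins
# ---------------------------------------------------------------------------

def resample_dose(dose: DoseGrid, target: GridSpec) -> DoseGrid:
    """Trilinearly resample a dose grid at the target's voxel centers.

    Points outside the source voxel-center hull get 0 Gy and a logged
    warning. Structures are never resampled; only dose is.
    """
    if target.compatible(dose.grid):
        return DoseGrid(grid=target, values=dose.values.copy())

    src = dose.grid
    centers = target.centers_mm()
    frac = (centers - np.asarray(src.origin)) / np.asarray(src.spacing)
    coords = frac.reshape(-1, 3).T  # (3, N) fractional source indices

    upper = np.asarray(src.shape, dtype=float) - 1.0
    outside = np.any((coords.T < -1e-9) | (coords.T > upper + 1e-9), axis=1)
    if outside.any():
        logger.warning(
            "resample_dose: %d of %d target voxels outside source extent; set to 0 Gy",
            int(outside.sum()), coords.shape[1],
        )

    values = ndimage.map_coordinates(
        dose.values, coords, order=1, mode="constant", cval=0.0
    )
    values[outside] = 0.0
    return DoseGrid(grid=target, values=values.reshape(target.shape))


def expand_margin(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Euclidean dilation by ``margin_mm`` with anisotropic spacing respected.

    An output voxel is true iff its center lies within ``margin_mm`` of some
    true voxel center of the input; the result always contains the input.
    Used to build PRVs (e.g. spinal cord + safety margin).
    """
    if margin_mm < 0:
        raise InvalidArgumentError(f"margin must be >= 0 mm, got {margin_mm}")
    if margin_mm == 0 or mask.is_empty:
        return replace(mask, voxels=mask.voxels.copy())
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing)
    return replace(mask, voxels=dist <= margin_mm + 1e-9)


def signed_distance_mm(mask: StructureMask) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask boundary: negative inside.

    Distances are between voxel centers, with anisotropic spacing respected.
    """
    sp = mask.grid.spacing
    outside = ndimage.distance_transform_edt(~mask.voxels, sampling=sp)
    inside = ndimage.distance_transform_edt(mask.voxels, sampling=sp)
    return outside - inside


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("json-contours", "mask-volume", "dicom-rt")


def _require_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ConfigurationError(
            f"unknown dialect '{dialect}'; expected one of {_DIALECTS}"
        )


def _contour_set_to_dict(cs: ContourSet) -> dict:
    return {
        "name": cs.name,
        "source": cs.source,
        "slices": [
            {"z": sl.z, "polygons": [p.tolist() for p in sl.polygons]}
            for sl in cs.slices
        ],
    }


def _contour_set_from_dict(d: dict, path: str) -> ContourSet:
    try:
        slices = [
            ContourSlice(z=float(sl["z"]), polygons=[np.asarray(p, float) for p in sl["polygons"]])
            for sl in d["slices"]
        ]
        return ContourSet(name=str(d["name"]), slices=slices, source=str(d.get("source", "manual")))
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed contour record in {path}: {exc!r}") from exc


def _nifti_affine(grid: GridSpec) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_nifti(img, path: str) -> GridSpec:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ParseError(f"{path}: only axis-aligned NIfTI affines are supported")
    spacing = tuple(np.diag(aff[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise ParseError(f"{path}: non-positive spacing in affine diagonal {spacing}")
    return GridSpec(shape=tuple(img.shape[:3]), spacing=spacing, origin=tuple(aff[:3, 3]))


def _parse_descrip(img) -> dict:
    raw = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode("ascii", "ignore")
    out: dict[str, str] = {}
    for part in raw.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_structures(
    structures: "ContourSet | StructureMask | Sequence",
    path: str | FilePath,
    dialect: str,
) -> None:
    """Write contour sets (json-contours) or masks (mask-volume NIfTI).

    Round-trip fidelity: write then read reproduces geometry to <= 1e-6 mm.
    The dicom-rt dialect is read-only.
    """
    _require_dialect(dialect)
    path = FilePath(path)
    items = list(structures) if isinstance(structures, (list, tuple)) else [structures]

    if dialect == "json-contours":
        if not all(isinstance(s, ContourSet) for s in items):
            raise ConfigurationError("json-contours dialect writes ContourSet objects")
        payload = [_contour_set_to_dict(s) for s in items]
        path.write_text(json.dumps(payload[0] if len(payload) == 1 else payload, indent=1))
    elif dialect == "mask-volume":
        import nibabel as nib

        if len(items) != 1 or not isinstance(items[0], StructureMask):
            raise ConfigurationError("mask-volume dialect writes one StructureMask per file")
        mask = items[0]
        img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _nifti_affine(mask.grid))
        img.header["descrip"] = f"name={mask.name};source={mask.source}".encode("ascii")[:79]
        nib.save(img, str(path))
    else:
        raise ConfigurationError("dicom-rt dialect is read-only")


def read_structures(path: str | FilePath, dialect: str) -> list:
    """Read structures; returns a list of ContourSet (json-contours,
    dicom-rt) or StructureMask (mask-volume)."""
    _require_dialect(dialect)
    path = FilePath(path)

    if dialect == "json-contours":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON in {path}: {exc}") from exc
        records = data if isinstance(data, list) else [data]
        return [_contour_set_from_dict(d, str(path)) for d in records]

    if dialect == "mask-volume":
        import nibabel as nib

        img = nib.load(str(path))
        grid = _grid_from_nifti(img, str(path))
        meta = _parse_descrip(img)
        voxels = np.asarray(img.dataobj) > 0
        return [
            StructureMask(
                grid=grid,
                voxels=voxels,
                name=meta.get("name", path.stem),
                source=meta.get("source", "manual"),
            )
        ]

    return _read_dicom_structures(path)


def _read_dicom_structures(path: FilePath) -> list[ContourSet]:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise ParseError(f"{path}: not an RT Structure Set (Modality={getattr(ds, 'Modality', '?')})")
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    out: list[ContourSet] = []
    for roi in getattr(ds, "ROIContourSequence", []):
        number = int(roi.ReferencedROINumber)
        slices: dict[float, ContourSlice] = {}
        for c in getattr(roi, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if pts.shape[0] < 3:
                raise ParseError(
                    f"{path}: degenerate contour ({pts.shape[0]} pts) in ROI {number}"
                )
            z = float(np.round(pts[:, 2].mean(), 6))
            slices.setdefault(z, ContourSlice(z=z)).polygons.append(pts[:, :2])
        out.append(
            ContourSet(
                name=names.get(number, f"ROI{number}"),
                slices=[slices[z] for z in sorted(slices)],
            )
        )
    return out


def write_dose(dose: DoseGrid, path: str | FilePath) -> None:
    """Write a dose grid as NIfTI (Gy, float32 is insufficient; float64 kept)."""
    import nibabel as nib

    img = nib.Nifti1Image(dose.values.astype(np.float64), _nifti_affine(dose.grid))
    img.header["descrip"] = b"dose_gy"
    nib.save(img, str(FilePath(path)))


def read_dose(path: str | FilePath, dialect: str | None = None) -> DoseGrid:
    """Read a dose grid from NIfTI or a DICOM RT Dose file.

    With ``dialect=None`` the format is inferred from the file extension.
    """
    path = FilePath(path)
    if dialect is None:
        dialect = "dicom-rt" if path.suffix.lower() == ".dcm" else "mask-volume"
    if dialect == "mask-volume":
        import nibabel as nib

        img = nib.load(str(path))
        grid = _grid_from_nifti(img, str(path))
        return DoseGrid(grid=grid, values=np.asarray(img.dataobj, dtype=np.float64))
    if dialect == "dicom-rt":
        return _read_dicom_dose(path)
    raise ConfigurationError(f"unknown dose dialect '{dialect}'")


def _read_dicom_dose(path: FilePath) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ParseError(f"{path}: not an RT Dose file (Modality={getattr(ds, 'Modality', '?')})")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(np.float64) * scaling  # (frames, rows, cols) = (z, y, x)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dzs = np.diff(offsets)
    if len(dzs) and not np.allclose(dzs, dzs[0], atol=1e-6):
        raise ParseError(f"{path}: non-uniform GridFrameOffsetVector is unsupported")
    dz = float(dzs[0]) if len(dzs) else 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # row=y, col=x
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = GridSpec(
        shape=(arr.shape[2], arr.shape[1], arr.shape[0]),
        spacing=(col_sp, row_sp, dz),
        origin=origin,
    )
    return DoseGrid(grid=grid, values=arr.transpose(2, 1, 0))
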