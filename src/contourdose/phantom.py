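"""Synthetic thorax phantom: analytic organs, idealized conformal dose, and
perturbed "automatic" delineations with calibrated disagreement.

The phantom emulates the evaluation conditions of a thoracic radiotherapy
contour-QA study without any imaging data: a CT-like grid (default 64×64×40
voxels at 4×4×5 mm — a scaled-down 512×512 / 5 mm thorax), organs at risk
(left/right/bilateral lung ellipsoids, heart ellipsoid, spinal-cord
cylinder and its PRV expansion), a tubular esophageal target, and an
idealized conformal dose: prescription inside the target, exponential
falloff with Euclidean distance outside.

"Automatic" delineations are the manual (analytic) ones after a small
rigid shift plus a smooth band-limited random radial perturbation of the
boundary, applied in the signed-distance representation before
thresholding. One amplitude knob per structure controls the disagreement;
:func:`calibrate_perturbation` bisects that knob until the mean DSC over a
seeded case set lands in a requested band. Per-case anatomy is jittered
(organ scale and position) so between-case variability exists; everything
is a pure function of (master seed, case index, structure).

Axes: x lateral, y anterior→posterior, z inferior→superior, all mm.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path as FilePath

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, ConfigurationError
from .geometry import dsc
from .volumes import (
    ContourSet,
    ContourSlice,
    DoseGrid,
    GridSpec,
    StructureMask,
    expand_margin,
    signed_distance_mm,
    write_dose,
    write_structures,
)

__all__ = [
    "PhantomConfig",
    "OARS",
    "generate_case",
    "calibrate_perturbation",
    "generate_cohort",
    "load_cohort",
]

#: Primitive organs with their own perturbation knob; bilateral lung and the
#: cord PRV are derived (union / margin expansion) on both sides.
PRIMITIVE_OARS = ("lung_l", "lung_r", "heart", "cord")
OARS = ("lung_l", "lung_r", "lung_all", "heart", "cord", "cord_prv")

# Boundary-noise amplitudes (mm) fixed by running calibrate_perturbation
# against per-structure DSC bands (lungs 0.96-0.98, heart 0.89-0.97,
# cord 0.80-0.88) over 10 seeded cases.
DEFAULT_AMPLITUDES = {"lung_l": 2.625, "lung_r": 2.625, "heart": 3.0, "cord": 2.625}


@dataclass
class PhantomConfig:
    """All phantom knobs; the master seed fixes every random draw."""

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = (4.0, 4.0, 5.0)
    prescription_gy: float = 60.0
    falloff_mm: float = 15.0
    dose_noise_sd_gy: float = 0.0

    # organ geometry (mm)
    lung_semiaxes: tuple[float, float, float] = (30.0, 70.0, 80.0)
    lung_center_x: float = 48.0
    lung_center_yz: tuple[float, float] = (20.0, -10.0)
    heart_center: tuple[float, float, float] = (0.0, 18.0, -55.0)
    heart_semiaxes: tuple[float, float, float] = (22.0, 22.0, 28.0)
    cord_center_y: float = 75.0
    cord_radius_mm: float = 6.0
    target_center_y: float = 52.0
    target_radius_mm: float = 9.0
    target_length_mm: float = 170.0
    prv_margin_mm: float = 5.0

    # per-case anatomical variation
    scale_jitter: float = 0.03
    position_jitter_mm: float = 2.0

    # manual -> automatic perturbation
    noise_amplitude_mm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    shift_frac: float = 0.4  # rigid shift = shift_frac * amplitude
    noise_correlation_mm: float = 40.0

    n_cases: int = 19
    master_seed: int = 0

    def grid(self) -> GridSpec:
        origin = tuple(
            -(n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing)
        )
        return GridSpec(shape=self.shape, spacing=self.spacing, origin=origin)


# ---------------------------------------------------------------------------
# Analytic shapes
# ---------------------------------------------------------------------------

def _ellipsoid(centers: np.ndarray, center, semiaxes) -> np.ndarray:
    r = (centers - np.asarray(center)) / np.asarray(semiaxes)
    return np.sum(r**2, axis=-1) <= 1.0


def _zcylinder(centers: np.ndarray, cx, cy, radius, z_lo, z_hi) -> np.ndarray:
    inplane = (centers[..., 0] - cx) ** 2 + (centers[..., 1] - cy) ** 2 <= radius**2
    return inplane & (centers[..., 2] >= z_lo) & (centers[..., 2] <= z_hi)


def _case_rng(cfg: PhantomConfig, case_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.master_seed, case_index, stream])


def _manual_shapes(cfg: PhantomConfig, case_index: int) -> dict[str, np.ndarray]:
    """Per-case jittered analytic masks for the primitive organs + target."""
    grid = cfg.grid()
    centers = grid.centers_mm()
    rng = _case_rng(cfg, case_index, 0)

    def jitter_scale() -> float:
        return float(1.0 + cfg.scale_jitter * rng.standard_normal())

    def jitter_pos(n: int = 3) -> np.ndarray:
        return cfg.position_jitter_mm * rng.standard_normal(n)

    out: dict[str, np.ndarray] = {}
    half_z = (cfg.shape[2] - 1) * cfg.spacing[2] / 2.0

    for side, sign in (("lung_l", 1.0), ("lung_r", -1.0)):
        semi = np.asarray(cfg.lung_semiaxes) * jitter_scale()
        center = np.array(
            [sign * cfg.lung_center_x, cfg.lung_center_yz[0], cfg.lung_center_yz[1]]
        ) + jitter_pos()
        out[side] = _ellipsoid(centers, center, semi)

    out["heart"] = _ellipsoid(
        centers,
        np.asarray(cfg.heart_center) + jitter_pos(),
        np.asarray(cfg.heart_semiaxes) * jitter_scale(),
    )

    cxy = np.array([0.0, cfg.cord_center_y]) + jitter_pos(2)
    out["cord"] = _zcylinder(
        centers, cxy[0], cxy[1], cfg.cord_radius_mm * jitter_scale(), -half_z, half_z
    )

    txy = np.array([0.0, cfg.target_center_y]) + jitter_pos(2)
    tlen = cfg.target_length_mm * jitter_scale() / 2.0
    out["target"] = _zcylinder(
        centers, txy[0], txy[1], cfg.target_radius_mm * jitter_scale(), -tlen, tlen
    )

    for name, vox in out.items():
        if not vox.any():
            raise ConfigurationError(f"phantom organ '{name}' rasterized empty; check geometry")
        if _touches_border(vox):
            raise ConfigurationError(f"phantom organ '{name}' exceeds the grid extent")
    if (out["target"] & out["cord"]).any():
        raise ConfigurationError("phantom target intersects the spinal cord")
    return out


def _touches_border(vox: np.ndarray) -> bool:
    # Only in-plane (x, y) borders: structures such as the spinal cord
    # legitimately run through the whole z stack, as in a real scan.
    return bool(vox[0].any() or vox[-1].any() or vox[:, 0].any() or vox[:, -1].any())


# ---------------------------------------------------------------------------
# Perturbation (manual -> automatic)
# ---------------------------------------------------------------------------

def _smooth_noise_field(
    rng: np.random.Generator, grid: GridSpec, correlation_mm: float
) -> np.ndarray:
    """Band-limited Gaussian field with unit SD on the full grid."""
    coarse_shape = tuple(
        max(2, int(round(n * s / correlation_mm)))
        for n, s in zip(grid.shape, grid.spacing)
    )
    coarse = rng.standard_normal(coarse_shape)
    zoom = [t / c for t, c in zip(grid.shape, coarse_shape)]
    fine = ndimage.zoom(coarse, zoom, order=3)
    fine = fine[: grid.shape[0], : grid.shape[1], : grid.shape[2]]
    sd = fine.std()
    return fine / sd if sd > 0 else fine


def _perturb(
    mask: StructureMask,
    amplitude_mm: float,
    shift_frac: float,
    correlation_mm: float,
    rng: np.random.Generator,
) -> StructureMask:
    """Rigid shift + smooth radial boundary noise, via the signed distance field."""
    if amplitude_mm == 0.0:
        return replace(mask, voxels=mask.voxels.copy(), source="automatic")
    sdf = signed_distance_mm(mask)

    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    shift_mm = shift_frac * amplitude_mm * direction
    shift_idx = shift_mm / np.asarray(mask.grid.spacing)
    idx = np.indices(mask.grid.shape, dtype=float)
    coords = idx - shift_idx.reshape(3, 1, 1, 1)
    sdf_shifted = ndimage.map_coordinates(sdf, coords.reshape(3, -1), order=1, mode="nearest")
    sdf_shifted = sdf_shifted.reshape(mask.grid.shape)

    noise = amplitude_mm * _smooth_noise_field(rng, mask.grid, correlation_mm)
    return replace(mask, voxels=sdf_shifted <= noise, source="automatic")


# ---------------------------------------------------------------------------
# Case and cohort generation
# ---------------------------------------------------------------------------

def generate_case(
    config: PhantomConfig, case_index: int
) -> tuple[DoseGrid, dict[str, StructureMask], dict[str, StructureMask], dict[str, StructureMask]]:
    """One phantom case: (dose, manual OARs, automatic OARs, target masks).

    Manual structures are the jittered analytic shapes; the dose is the
    prescription inside the target with exponential falloff outside;
    automatic structures are seeded perturbations of the manual ones, with
    bilateral lung and cord PRV derived per side (union, margin expansion).
    """
    grid = config.grid()
    shapes = _manual_shapes(config, case_index)

    manual = {
        name: StructureMask(grid=grid, voxels=shapes[name], name=name, source="manual")
        for name in PRIMITIVE_OARS
    }
    target = StructureMask(grid=grid, voxels=shapes["target"], name="target", source="manual")

    automatic: dict[str, StructureMask] = {}
    for stream, name in enumerate(PRIMITIVE_OARS, start=1):
        automatic[name] = _perturb(
            manual[name],
            config.noise_amplitude_mm.get(name, 0.0),
            config.shift_frac,
            config.noise_correlation_mm,
            _case_rng(config, case_index, stream),
        )

    for masks in (manual, automatic):
        masks["lung_all"] = replace(
            masks["lung_l"],
            voxels=masks["lung_l"].voxels | masks["lung_r"].voxels,
            name="lung_all",
        )
        masks["cord_prv"] = replace(
            expand_margin(masks["cord"], config.prv_margin_mm), name="cord_prv"
        )

    dist = ndimage.distance_transform_edt(~target.voxels, sampling=grid.spacing)
    values = config.prescription_gy * np.exp(-dist / config.falloff_mm)
    if config.dose_noise_sd_gy > 0:
        rng = _case_rng(config, case_index, 99)
        values = np.clip(
            values
            + config.dose_noise_sd_gy * _smooth_noise_field(rng, grid, config.noise_correlation_mm),
            0.0,
            None,
        )
    dose = DoseGrid(grid=grid, values=values)
    return dose, manual, automatic, {"target": target}


def calibrate_perturbation(
    structure: str,
    dsc_range: tuple[float, float],
    config: PhantomConfig,
    n_cases: int = 10,
    max_amplitude_mm: float = 12.0,
    max_iter: int = 30,
) -> tuple[float, dict]:
    """Bisect one structure's noise amplitude until mean DSC lands in a band.

    Returns ``(amplitude_mm, stats)`` where stats holds the achieved mean/SD
    DSC over the seeded cases. Mean DSC is monotone non-increasing in the
    amplitude, which is what the bisection relies on.
    """
    lo_target, hi_target = dsc_range
    if not 0.0 <= lo_target <= hi_target <= 1.0:
        raise CalibrationError(f"invalid DSC range {dsc_range}")
    if structure not in PRIMITIVE_OARS:
        raise CalibrationError(
            f"'{structure}' has no perturbation knob; calibrate one of {PRIMITIVE_OARS}"
        )

    def mean_dsc(amplitude: float) -> tuple[float, float]:
        cfg = replace(
            config, noise_amplitude_mm={**config.noise_amplitude_mm, structure: amplitude}
        )
        vals = []
        for i in range(n_cases):
            _, man, auto, _ = generate_case(cfg, i)
            vals.append(dsc(auto[structure], man[structure]))
        return float(np.mean(vals)), float(np.std(vals, ddof=1))

    if hi_target >= 1.0:  # DSC 1 is exactly the zero-perturbation limit
        m, s = mean_dsc(0.0)
        if m >= lo_target:
            return 0.0, {"mean_dsc": m, "sd_dsc": s, "n_cases": n_cases, "iterations": 0}

    lo_amp, hi_amp = 0.0, max_amplitude_mm
    f_lo, _ = mean_dsc(lo_amp)
    f_hi, _ = mean_dsc(hi_amp)
    if f_lo < lo_target or f_hi > hi_target:
        raise CalibrationError(
            f"DSC range {dsc_range} not bracketed for '{structure}': "
            f"f({lo_amp})={f_lo:.4f}, f({hi_amp})={f_hi:.4f}"
        )
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo_amp + hi_amp)
        m, s = mean_dsc(mid)
        if lo_target <= m <= hi_target:
            return mid, {"mean_dsc": m, "sd_dsc": s, "n_cases": n_cases, "iterations": it}
        if m > hi_target:
            lo_amp = mid
        else:
            hi_amp = mid
    raise CalibrationError(
        f"no amplitude found for '{structure}' in {max_iter} bisections; "
        f"final bracket [{lo_amp:.4f}, {hi_amp:.4f}] mm — the band may be "
        f"narrower than the voxelization granularity"
    )


def _config_digest(config: PhantomConfig) -> str:
    payload = json.dumps(
        {k: (sorted(v.items()) if isinstance(v, dict) else v) for k, v in vars(config).items()},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _mask_to_contours(mask: StructureMask) -> ContourSet:
    """Approximate planar contours of a mask (0.5-level iso-contours per slice)."""
    from skimage import measure

    grid = mask.grid
    slices = []
    for k in range(grid.shape[2]):
        plane = mask.voxels[:, :, k].astype(float)
        if not plane.any():
            continue
        polys = []
        for contour in measure.find_contours(plane, 0.5):
            xy = np.asarray(grid.origin[:2]) + contour * np.asarray(grid.spacing[:2])
            if xy.shape[0] >= 3:
                polys.append(xy)
        if polys:
            slices.append(ContourSlice(z=grid.origin[2] + k * grid.spacing[2], polygons=polys))
    return ContourSet(name=mask.name, slices=slices, source=mask.source)


def generate_cohort(
    config: PhantomConfig,
    out_dir: str | FilePath,
    overwrite: bool = False,
    write_contours: bool = True,
) -> dict:
    """Write ``config.n_cases`` phantom cases to disk and return the manifest.

    Each case directory holds the dose volume (NIfTI), every manual and
    automatic mask (NIfTI), the target mask, and (optionally) approximate
    JSON contours per structure. The manifest lists per-case seed material;
    the same master seed reproduces byte-identical files.
    """
    out_dir = FilePath(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise ConfigurationError(
                f"output directory {out_dir} is not empty; pass overwrite=True"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "master_seed": config.master_seed,
        "n_cases": config.n_cases,
        "config_sha256_16": _config_digest(config),
        "contours": "approximate (0.5-level iso-contours of the voxel masks)",
        "cases": [],
    }
    for i in range(config.n_cases):
        case_id = f"case{i:02d}"
        case_dir = out_dir / case_id
        case_dir.mkdir()
        dose, manual, automatic, targets = generate_case(config, i)
        write_dose(dose, case_dir / "dose.nii.gz")
        contour_sets = []
        for source, masks in (("manual", manual), ("automatic", automatic)):
            for name, mask in masks.items():
                write_structures(mask, case_dir / f"{name}_{source}.nii.gz", "mask-volume")
                if write_contours:
                    contour_sets.append(_mask_to_contours(mask))
        write_structures(targets["target"], case_dir / "target_manual.nii.gz", "mask-volume")
        if write_contours:
            contour_sets.append(_mask_to_contours(targets["target"]))
            write_structures(contour_sets, case_dir / "contours.json", "json-contours")
        manifest["cases"].append(
            {"id": case_id, "index": i, "seed": [config.master_seed, i], "dir": case_id}
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_cohort(out_dir: str | FilePath):
    """Yield ``(case_id, dose, manual, automatic, target)`` for a written cohort."""
    from .volumes import read_dose, read_structures

    out_dir = FilePath(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for entry in manifest["cases"]:
        case_dir = out_dir / entry["dir"]
        dose = read_dose(case_dir / "dose.nii.gz")
        manual, automatic = {}, {}
        for name in OARS:
            manual[name] = read_structures(case_dir / f"{name}_manual.nii.gz", "mask-volume")[0]
            automatic[name] = read_structures(
                case_dir / f"{name}_automatic.nii.gz", "mask-volume"
            )[0]
        target = read_structures(case_dir / "target_manual.nii.gz", "mask-volume")[0]
        yield entry["id"], dose, manual, automatic, target
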