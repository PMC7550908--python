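"""DVH construction and dose-volume metrics: Dx%, Vx, Dmean, CI, HI.

The cumulative DVH of a structure gives, for each dose level d, the
percentage of the structure's volume receiving at least d Gy (voxel-count
volumes, no partial-volume weighting). From it:

* ``Dx%``  — largest dose received by at least x% of the volume
  (D2% near-maximum, D98% near-minimum, D50% median dose);
* ``Vx``   — percentage of the volume receiving at least x Gy;
* ``HI``   — ICRU-83 homogeneity index (D2% − D98%) / D50%, 0 = perfectly
  homogeneous target dose;
* ``CI``   — conformity index TVPTV² / (TV·PTV) where TV is the
  prescribed-isodose volume, PTV the target volume and TVPTV their overlap,
  1 = the prescription isodose perfectly conforms to the target.

Dx%/Vx are evaluated with linear interpolation between DVH bin edges; the
inverse lookup is clamped to the structure's actual [min, max] dose so that
degenerate limits (uniform dose, x = 100) are exact rather than off by one
bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyStructureError,
    GridMismatchError,
    InvalidArgumentError,
    UndefinedMetricError,
)
from .volumes import DoseGrid, StructureMask

logger = logging.getLogger("contourdose")

__all__ = [
    "DVH",
    "DoseMetricSet",
    "ConformityInputs",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "mean_dose",
    "conformity_index",
    "homogeneity_index",
    "metric_set",
    "parse_metric_name",
    "metric_unit",
    "evaluate_metrics",
    "dvh_to_frame",
    "plot_dvhs",
]

DEFAULT_BIN_WIDTH_GY = 0.05
DEFAULT_VX_THRESHOLDS = (5.0, 10.0, 20.0, 30.0, 40.0)


@dataclass
class DVH:
    """Cumulative dose-volume curve for one structure.

    ``volume_pct[i]`` is the percentage of structure volume receiving at
    least ``edges_gy[i]``; non-increasing, 100% at 0 Gy.
    """

    structure: str
    edges_gy: np.ndarray
    volume_pct: np.ndarray
    volume_cc: float
    min_dose_gy: float
    max_dose_gy: float

    def __post_init__(self) -> None:
        self.edges_gy = np.asarray(self.edges_gy, dtype=float)
        self.volume_pct = np.asarray(self.volume_pct, dtype=float)
        if np.any(np.diff(self.volume_pct) > 1e-9):
            raise ValueError("cumulative volume fraction must be non-increasing in dose")


@dataclass(frozen=True)
class ConformityInputs:
    """Volumes (cc) entering the conformity index and the resulting CI."""

    tv_cc: float
    ptv_cc: float
    overlap_cc: float
    ci: float


@dataclass
class DoseMetricSet:
    """Standard per-structure metric bundle (all doses Gy, volumes %)."""

    structure: str
    d2: float
    d50: float
    d98: float
    dmean: float
    vx: dict[float, float] = field(default_factory=dict)
    hi: float | None = None


def _check_pair(dose: DoseGrid, mask: StructureMask) -> None:
    if not dose.grid.compatible(mask.grid):
        raise GridMismatchError(
            f"dose grid and mask '{mask.name}' differ; resample the dose first"
        )
    if mask.is_empty:
        raise EmptyStructureError(f"mask '{mask.name}' is empty")


def cumulative_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> DVH:
    """Voxel-count cumulative DVH with uniform bin edges of ``bin_width`` Gy."""
    _check_pair(dose, mask)
    if bin_width <= 0:
        raise InvalidArgumentError(f"bin width must be > 0 Gy, got {bin_width}")
    doses = np.sort(dose.values[mask.voxels])
    n = doses.size
    n_edges = int(np.floor(doses[-1] / bin_width)) + 2
    edges = bin_width * np.arange(n_edges)
    # fraction of voxels with dose >= edge
    pct = 100.0 * (n - np.searchsorted(doses, edges, side="left")) / n
    return DVH(
        structure=mask.name,
        edges_gy=edges,
        volume_pct=pct,
        volume_cc=mask.volume_cc,
        min_dose_gy=float(doses[0]),
        max_dose_gy=float(doses[-1]),
    )


def dose_at_volume(dvh: DVH, x_percent: float) -> float:
    """Dx%: largest dose such that at least ``x_percent`` of the volume
    receives at least that dose, linearly interpolated between bin edges."""
    if not 0 < x_percent <= 100:
        raise InvalidArgumentError(f"x must lie in (0, 100], got {x_percent}")
    v, e = dvh.volume_pct, dvh.edges_gy
    above = np.nonzero(v >= x_percent - 1e-12)[0]
    if above.size == 0:  # cannot happen for x <= 100 with a valid DVH
        return dvh.min_dose_gy
    i = above[-1]
    if i == len(e) - 1 or v[i] == v[i + 1]:
        d = e[i]
    else:
        d = e[i] + (v[i] - x_percent) / (v[i] - v[i + 1]) * (e[i + 1] - e[i])
    return float(np.clip(d, dvh.min_dose_gy, dvh.max_dose_gy))


def volume_at_dose(dvh: DVH, x_gy: float) -> float:
    """Vx: percentage of structure volume receiving at least ``x_gy`` Gy."""
    if x_gy < 0:
        raise InvalidArgumentError(f"dose threshold must be >= 0 Gy, got {x_gy}")
    if x_gy > dvh.edges_gy[-1]:
        return 0.0
    return float(np.interp(x_gy, dvh.edges_gy, dvh.volume_pct))


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """Arithmetic mean dose (Gy) over the structure's voxels."""
    _check_pair(dose, mask)
    return float(dose.values[mask.voxels].mean())


def conformity_index(
    dose: DoseGrid, prescription_gy: float, ptv: StructureMask
) -> ConformityInputs:
    """CI = TVPTV² / (TV · PTV): TV = volume with dose >= prescription."""
    if prescription_gy <= 0:
        raise InvalidArgumentError(f"prescription must be > 0 Gy, got {prescription_gy}")
    _check_pair(dose, ptv)
    vox_cc = dose.grid.voxel_volume_cc
    tv_vox = dose.values >= prescription_gy
    tv = float(tv_vox.sum()) * vox_cc
    ptv_cc = ptv.volume_cc
    overlap = float(np.logical_and(tv_vox, ptv.voxels).sum()) * vox_cc
    if tv == 0:
        logger.warning("conformity_index: prescribed isodose volume empty; CI = 0")
        return ConformityInputs(tv_cc=0.0, ptv_cc=ptv_cc, overlap_cc=0.0, ci=0.0)
    return ConformityInputs(
        tv_cc=tv, ptv_cc=ptv_cc, overlap_cc=overlap, ci=overlap**2 / (tv * ptv_cc)
    )


def homogeneity_index(dvh: DVH) -> float:
    """ICRU-83 HI = (D2% − D98%) / D50%."""
    d50 = dose_at_volume(dvh, 50.0)
    if d50 <= 0:
        raise UndefinedMetricError(f"HI undefined: D50% = {d50} Gy for '{dvh.structure}'")
    return (dose_at_volume(dvh, 2.0) - dose_at_volume(dvh, 98.0)) / d50


def metric_set(
    dose: DoseGrid,
    mask: StructureMask,
    vx_thresholds: tuple[float, ...] = DEFAULT_VX_THRESHOLDS,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
    include_hi: bool = False,
) -> DoseMetricSet:
    """Compute the standard metric bundle for one structure."""
    dvh = cumulative_dvh(dose, mask, bin_width=bin_width)
    return DoseMetricSet(
        structure=mask.name,
        d2=dose_at_volume(dvh, 2.0),
        d50=dose_at_volume(dvh, 50.0),
        d98=dose_at_volume(dvh, 98.0),
        dmean=mean_dose(dose, mask),
        vx={x: volume_at_dose(dvh, x) for x in vx_thresholds},
        hi=homogeneity_index(dvh) if include_hi else None,
    )


# ---------------------------------------------------------------------------
# Named-metric evaluation (the report vocabulary: "D2%", "V30", "Dmean", ...)
# ---------------------------------------------------------------------------

def parse_metric_name(name: str) -> tuple[str, float | None]:
    """Parse a metric name into (kind, parameter).

    Recognized: ``Dmean``/``Mean``, ``Dx%`` (e.g. ``D2%``), ``Vx`` (e.g.
    ``V30``), ``HI``, ``CI``.
    """
    s = name.strip()
    low = s.lower().rstrip("%")
    if low in ("dmean", "mean"):
        return "dmean", None
    if low == "hi":
        return "hi", None
    if low == "ci":
        return "ci", None
    try:
        if low.startswith("d"):
            return "dx", float(low[1:])
        if low.startswith("v"):
            return "vx", float(low[1:])
    except ValueError:
        pass
    from .errors import ConfigurationError

    raise ConfigurationError(f"unrecognized metric name '{name}'")


def metric_unit(name: str) -> str:
    """Unit of a metric: dose metrics in Gy, volume metrics in %."""
    kind, _ = parse_metric_name(name)
    if kind in ("dx", "dmean"):
        return "Gy"
    if kind == "vx":
        return "%"
    return ""  # HI, CI dimensionless


def evaluate_metrics(
    dose: DoseGrid,
    mask: StructureMask,
    metrics: list[str],
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> dict[str, float]:
    """Evaluate a list of named DVH metrics for one structure."""
    dvh = cumulative_dvh(dose, mask, bin_width=bin_width)
    out: dict[str, float] = {}
    for name in metrics:
        kind, param = parse_metric_name(name)
        if kind == "dx":
            out[name] = dose_at_volume(dvh, param)
        elif kind == "vx":
            out[name] = volume_at_dose(dvh, param)
        elif kind == "dmean":
            out[name] = mean_dose(dose, mask)
        elif kind == "hi":
            out[name] = homogeneity_index(dvh)
        else:
            from .errors import ConfigurationError

            raise ConfigurationError(f"metric '{name}' needs a prescription; use conformity_index")
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def dvh_to_frame(dvh: DVH) -> pd.DataFrame:
    """Export a DVH as a (dose_gy, volume_pct) table."""
    return pd.DataFrame({"dose_gy": dvh.edges_gy, "volume_pct": dvh.volume_pct})


def plot_dvhs(dvhs: dict[str, list[DVH]], path: str | None = None):
    """Overlay mean cumulative DVH curves per source (e.g. manual vs automatic).

    ``dvhs`` maps a source label to that source's DVHs (one per case or
    structure); curves with differing supports are aligned on a common dose
    axis before averaging.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    styles = {"manual": "-", "automatic": "--"}
    for label, curves in dvhs.items():
        dmax = max(c.edges_gy[-1] for c in curves)
        axis = np.arange(0.0, dmax + DEFAULT_BIN_WIDTH_GY, DEFAULT_BIN_WIDTH_GY)
        mean_curve = np.mean(
            [np.interp(axis, c.edges_gy, c.volume_pct, right=0.0) for c in curves], axis=0
        )
        ax.plot(axis, mean_curve, styles.get(label, "-"), label=label)
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Volume (%)")
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
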