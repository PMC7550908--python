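"""Paired manual-vs-automatic comparison, significance testing, and
clinical acceptability.

Per (structure, metric) pair, per-case values from the manual (ground
truth) and automatic delineations are compared with a two-sided paired
t-test (t = mean(d)/(sd(d)/√n) on the per-case differences d, sd with the
n−1 denominator, n−1 degrees of freedom); P < 0.05 flags significance.
The clinical acceptability criterion requires the absolute difference of
means Δ to be < 1 Gy for dose metrics and < 1 percentage point for volume
metrics. Tests run on unrounded values; means and SDs are rounded to two
decimals (half away from zero) at report time only. Normality of the
paired differences is assumed; no automatic normality gate is applied, and
no multiple-testing correction by default (Holm adjustment is available by
flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose_metrics import metric_unit
from .errors import ConfigurationError, EmptySelectionError, PairingError

__all__ = [
    "TTestResult",
    "PairedComparison",
    "paired_t_test",
    "build_comparison",
    "summary_differences",
    "clinical_acceptability",
    "max_abs_difference",
    "comparison_table",
    "round_half_away",
    "simulate_flag_rate",
]

SIGNIFICANCE_LEVEL = 0.05
DOSE_LIMIT_GY = 1.0
VOLUME_LIMIT_PCT = 1.0


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on per-case values.

    Zero-variance differences are degenerate: P = 1 is returned, with t = 0
    when the pairs are identical and t = NaN for a constant nonzero shift.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"paired samples must have equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise PairingError(f"paired t-test needs n >= 2 cases, got {n}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        return TTestResult(t=0.0 if d[0] == 0.0 else math.nan, p=1.0, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(p), degenerate=False)


@dataclass
class PairedComparison:
    """Per-structure, per-metric paired record (Δ = |manual mean − automatic mean|)."""

    structure: str
    metric: str
    unit: str
    manual_values: np.ndarray | None
    automatic_values: np.ndarray | None
    manual_mean: float
    manual_sd: float
    automatic_mean: float
    automatic_sd: float
    delta: float
    t: float | None = None
    p: float | None = None
    degenerate: bool = False
    significant: bool | None = None
    acceptable: bool | None = None


def clinical_acceptability(
    delta: float,
    unit: str,
    dose_limit_gy: float = DOSE_LIMIT_GY,
    volume_limit_pct: float = VOLUME_LIMIT_PCT,
) -> bool:
    """Clinical criterion: Δ of means < 1 Gy (dose) or < 1 %-point (volume)."""
    if unit == "Gy":
        return delta < dose_limit_gy
    if unit == "%":
        return delta < volume_limit_pct
    raise ConfigurationError(f"unknown metric unit '{unit}'; expected 'Gy' or '%'")


def _record(
    structure: str,
    metric: str,
    manual: np.ndarray | None,
    automatic: np.ndarray | None,
    manual_mean: float,
    manual_sd: float,
    auto_mean: float,
    auto_sd: float,
    unit: str | None,
) -> PairedComparison:
    unit = metric_unit(metric) if unit is None else unit
    delta = abs(manual_mean - auto_mean)
    rec = PairedComparison(
        structure=structure,
        metric=metric,
        unit=unit,
        manual_values=manual,
        automatic_values=automatic,
        manual_mean=manual_mean,
        manual_sd=manual_sd,
        automatic_mean=auto_mean,
        automatic_sd=auto_sd,
        delta=delta,
        acceptable=clinical_acceptability(delta, unit) if unit in ("Gy", "%") else None,
    )
    if manual is not None and automatic is not None:
        res = paired_t_test(manual, automatic)
        rec.t, rec.p, rec.degenerate = res.t, res.p, res.degenerate
        rec.significant = res.p < SIGNIFICANCE_LEVEL
    return rec


def build_comparison(
    manual: pd.DataFrame,
    automatic: pd.DataFrame,
    metrics: Iterable[str] | None = None,
    holm: bool = False,
) -> list[PairedComparison]:
    """Pair per-case metric tables and test each (structure, metric).

    Both tables need columns ``case``, ``structure``, ``metric``, ``value``;
    cases are matched by ID, so row order is irrelevant. With ``holm=True``
    the significance flags use Holm-adjusted P values (raw P is reported
    either way).
    """
    for df, label in ((manual, "manual"), (automatic, "automatic")):
        missing = {"case", "structure", "metric", "value"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"{label} table lacks columns {sorted(missing)}")

    keys = manual[["structure", "metric"]].drop_duplicates()
    records: list[PairedComparison] = []
    for structure, metric in keys.itertuples(index=False):
        m = manual[(manual.structure == structure) & (manual.metric == metric)]
        a = automatic[(automatic.structure == structure) & (automatic.metric == metric)]
        m = m.set_index("case")["value"]
        a = a.set_index("case")["value"]
        unmatched = sorted(set(m.index) ^ set(a.index))
        if unmatched:
            raise PairingError(
                f"cases {unmatched} present on only one side for {structure}/{metric}"
            )
        a = a.reindex(m.index)
        mv, av = m.to_numpy(float), a.to_numpy(float)
        if metrics is not None and metric not in metrics:
            continue
        records.append(
            _record(
                structure, metric, mv, av,
                float(mv.mean()), float(mv.std(ddof=1)) if mv.size > 1 else 0.0,
                float(av.mean()), float(av.std(ddof=1)) if av.size > 1 else 0.0,
                None,
            )
        )
    if holm and records:
        order = np.argsort([r.p for r in records])
        k = len(records)
        adj, running = {}, 0.0
        for rank, idx in enumerate(order):
            running = max(running, (k - rank) * records[idx].p)
            adj[idx] = min(1.0, running)
        for idx, r in enumerate(records):
            r.significant = adj[idx] < SIGNIFICANCE_LEVEL
    return records


def summary_differences(table: pd.DataFrame) -> list[PairedComparison]:
    """Build Δ records straight from published summary means (no per-case data).

    ``table`` needs columns ``structure``, ``metric``, ``manual_mean``,
    ``automatic_mean`` (optional ``manual_sd``, ``automatic_sd``). No t-test
    is possible; Δ and the acceptability flag are computed.
    """
    records = []
    for row in table.itertuples(index=False):
        records.append(
            _record(
                row.structure, row.metric, None, None,
                float(row.manual_mean), float(getattr(row, "manual_sd", 0.0)),
                float(row.automatic_mean), float(getattr(row, "automatic_sd", 0.0)),
                None,
            )
        )
    return records


def max_abs_difference(
    records: Sequence[PairedComparison],
    unit: str | None = None,
    metrics: Iterable[str] | None = None,
) -> PairedComparison:
    """Record with the largest Δ among the filtered metrics.

    Filter by unit ("Gy" for dose metrics, "%" for volume metrics) and/or an
    explicit metric-name list. Ties break by structure name order.
    """
    pool = [
        r
        for r in records
        if (unit is None or r.unit == unit)
        and (metrics is None or r.metric in set(metrics))
    ]
    if not pool:
        raise EmptySelectionError("no records match the requested metric filter")
    return min(pool, key=lambda r: (-r.delta, r.structure, r.metric))


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (2.005 → 2.01), unlike banker's rounding."""
    import decimal

    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _mean_sd(mean: float, sd: float) -> str:
    return f"{round_half_away(mean, 2):.2f} ± {round_half_away(sd, 2):.2f}"


def comparison_table(records: Sequence[PairedComparison]) -> pd.DataFrame:
    """Report table: metric, GT mean ± SD, AI mean ± SD, P, Δ, acceptability."""
    return pd.DataFrame(
        {
            "structure": [r.structure for r in records],
            "metric": [f"{r.metric} ({r.unit})" if r.unit else r.metric for r in records],
            "GT": [_mean_sd(r.manual_mean, r.manual_sd) for r in records],
            "AI": [_mean_sd(r.automatic_mean, r.automatic_sd) for r in records],
            "P_value": [None if r.p is None else round(r.p, 4) for r in records],
            "delta": [round_half_away(r.delta, 2) for r in records],
            "acceptable": [r.acceptable for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Statistical sanity simulation (null calibration and power)
# ---------------------------------------------------------------------------

def simulate_flag_rate(
    n_cases: int,
    n_replicates: int,
    case_sd: float,
    pair_sd: float,
    shift: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> float:
    """Fraction of replicate cohorts where the P < 0.05 flag fires.

    Each replicate draws ``n_cases`` manual metric values with
    between-case SD ``case_sd``, sets the automatic value to the manual one
    plus pair noise of SD ``pair_sd`` and a systematic ``shift``, and runs
    the paired t-test. With ``shift = 0`` this measures the false-positive
    rate (nominally 5%); with a shift it measures power.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        manual = rng.normal(0.0, case_sd, size=n_cases)
        automatic = manual + rng.normal(shift, pair_sd, size=n_cases)
        if paired_t_test(manual, automatic).p < SIGNIFICANCE_LEVEL:
            hits += 1
    return hits / n_replicates
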