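"""Comparison of target-block window statistics against background regions.

Target windows are compared with pooled windows from neutral regions (or
size-matched control regions downstream of other ancient deletions) with a
Mann-Whitney U test: exact when the pooled sample is small and tie-free,
otherwise the tie-corrected normal approximation with continuity correction.
Because overlapping sliding windows are not independent observations, every
report carries a pseudo-replication warning; a non-overlapping window mode
(step = window) is the recommended default for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genomic_io import Region, SvbalscanError
from .popgen_stats import WindowStats

EXACT_MAX_N = 16  # exact enumeration when n_x + n_y <= this and no ties


@dataclass
class ComparisonReport:
    population: str
    statistic: str
    target_values: list[float]
    background_values: list[float]
    u_statistic: float
    p_value: float
    alternative: str
    target_mean: float
    target_sd: float
    background_mean: float
    background_sd: float
    empirical_quantile: float
    overlapping_windows: bool = False
    warning: str = ""


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U of x against y.

    Exact p by enumeration of rank assignments when n_x + n_y <= 16 with no
    ties; otherwise tie-corrected normal approximation with continuity
    correction.  Returns (U of x, p).
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"bad alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise SvbalscanError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all values identical: U is its null mean, no evidence either way
        return len(x) * len(y) / 2.0, 1.0
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def match_control_windows(
    control_deletions: Sequence[Region], target_length: int
) -> list[Region]:
    """For each control deletion, the size-matched region immediately
    downstream (higher coordinates): [end, end + target_length)."""
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    return [
        Region(d.chrom, d.end, d.end + target_length,
               label=f"ctrl_{d.label}" if d.label else "ctrl")
        for d in control_deletions
    ]


def _stat_values(windows: Sequence[WindowStats], statistic: str) -> list[float]:
    vals: list[float] = []
    for w in windows:
        if statistic == "pi":
            v = w.pi
        elif statistic == "tajima_d":
            v = w.tajima_d
        elif statistic == "fst":
            v = w.fst_mean
        elif statistic == "delta_ihh":
            v = w.delta_ihh
        else:
            raise SvbalscanError(f"unknown statistic {statistic!r}")
        if v is not None and np.isfinite(v):
            vals.append(float(v))
    return vals


def compare_values(
    target: Sequence[float],
    background: Sequence[float],
    statistic: str = "value",
    alternative: str = "greater",
    population: str = "pooled",
    overlapping: bool = False,
) -> ComparisonReport:
    target = [float(v) for v in target]
    background = [float(v) for v in background]
    if not target or not background:
        raise SvbalscanError(f"statistic {statistic!r} absent from target or background")
    u, p = mann_whitney_u(target, background, alternative=alternative)
    tmean = float(np.mean(target))
    bg = np.asarray(background)
    warning = (
        "overlapping sliding windows are pseudo-replicated; p-values are "
        "anti-conservative" if overlapping else ""
    )
    return ComparisonReport(
        population=population,
        statistic=statistic,
        target_values=target,
        background_values=background,
        u_statistic=u,
        p_value=p,
        alternative=alternative,
        target_mean=tmean,
        target_sd=float(np.std(target, ddof=1)) if len(target) > 1 else 0.0,
        background_mean=float(bg.mean()),
        background_sd=float(bg.std(ddof=1)) if len(bg) > 1 else 0.0,
        empirical_quantile=float((bg < tmean).mean()),
        overlapping_windows=overlapping,
        warning=warning,
    )


def compare_target(
    target: Sequence[WindowStats],
    background: Sequence[WindowStats],
    statistic: str,
    alternative: str = "greater",
    population: str = "pooled",
) -> ComparisonReport:
    """One-sided (default) Mann-Whitney of target windows vs background
    windows for one statistic; carries raw values for re-plotting."""
    tvals = _stat_values(target, statistic)
    bvals = _stat_values(background, statistic)
    if not tvals or not bvals:
        raise SvbalscanError(f"statistic {statistic!r} absent from target or background")
    overlapping = _has_overlap(target) or _has_overlap(background)
    return compare_values(
        tvals, bvals, statistic=statistic, alternative=alternative,
        population=population, overlapping=overlapping,
    )


def _has_overlap(windows: Sequence[WindowStats]) -> bool:
    spans = sorted((w.window.start, w.window.end) for w in windows)
    return any(b_start < a_end for (_, a_end), (b_start, _) in zip(spans, spans[1:]))


def report_to_dict(r: ComparisonReport) -> dict:
    return {
        "population": r.population,
        "statistic": r.statistic,
        "alternative": r.alternative,
        "u_statistic": r.u_statistic,
        "p_value": r.p_value,
        "target_mean": r.target_mean,
        "target_sd": r.target_sd,
        "background_mean": r.background_mean,
        "background_sd": r.background_sd,
        "empirical_quantile": r.empirical_quantile,
        "n_target": len(r.target_values),
        "n_background": len(r.background_values),
        "target_values": r.target_values,
        "background_values": r.background_values,
        "warning": r.warning,
    }
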