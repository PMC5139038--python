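"""Neutrality and selection statistics on haplotype matrices.

Implements the window statistics used to contrast a candidate region with
neutral background regions: nucleotide diversity (π, reported per window, the
sum over sites of unbiased heterozygosity, identical to the mean pairwise
Hamming distance), Watterson's θ_W = S/a1, Tajima's D with the 1989 variance
constants, Hudson's FST (ratio-of-averages), EHH/iHH around a core partition
and the ΔiHH contrast between structural-variant carrier classes, plus a
simple cross-haplogroup TMRCA estimator from mean between-class differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genomic_io import HaplotypeMatrix, Region, SvbalscanError

EHH_TRUNCATE = 0.05  # stop extending EHH curves below this homozygosity
MIN_HAP_TAJIMA = 4   # variance constants degenerate below


class DegenerateInput(SvbalscanError):
    """Statistic undefined on this input (e.g. monomorphic window)."""


# ---------------------------------------------------------------------------
# Tajima (1989) constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of Tajima's D for a sample of n haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("need n >= 2 haplotypes")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def _derived_counts(h: HaplotypeMatrix) -> np.ndarray:
    return h.alleles.sum(axis=0).astype(np.int64)


def segregating_sites(h: HaplotypeMatrix) -> int:
    c = _derived_counts(h)
    return int(np.sum((c > 0) & (c < h.n_hap)))


def nucleotide_diversity(h: HaplotypeMatrix, per_bp: bool = False,
                         span_bp: Optional[int] = None) -> float:
    """π: expected pairwise differences, summed over the window's sites.

    Equals the mean pairwise Hamming distance between haplotypes:
    ``sum_sites 2 p (1-p) n/(n-1)``.  With ``per_bp`` the sum is divided by
    ``span_bp`` (defaults to the positional span of the matrix).
    """
    n = h.n_hap
    if n < 2:
        raise DegenerateInput("nucleotide diversity needs >= 2 haplotypes")
    if h.n_site == 0:
        pi = 0.0
    else:
        c = _derived_counts(h)
        p = c / n
        pi = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))
    if per_bp:
        if span_bp is None:
            span_bp = int(h.positions[-1] - h.positions[0] + 1) if h.n_site else 1
        pi /= span_bp
    return pi


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator θ_W = S / a1(n)."""
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return 0.0
    return S / TajimaConstants.for_n(n).a1


def tajimas_d(h: HaplotypeMatrix, min_n: int = MIN_HAP_TAJIMA) -> Optional[float]:
    """Tajima's D = (π − θ_W) / sqrt(e1·S + e2·S(S−1)).

    Returns ``None`` for a monomorphic window (undefined, reason
    "monomorphic"); raises on degenerate variance.
    """
    n = h.n_hap
    if n < min_n:
        raise DegenerateInput(f"Tajima's D needs >= {min_n} haplotypes, got {n}")
    c = _derived_counts(h)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    if S == 0:
        return None
    k = TajimaConstants.for_n(n)
    pi = nucleotide_diversity(h.take_sites(np.flatnonzero(seg)))
    theta_w = S / k.a1
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:
        raise SvbalscanError(f"non-positive Tajima variance for n={n}, S={S}")
    return (pi - theta_w) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def hudson_fst_components(
    h: HaplotypeMatrix, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerators and denominators for two populations.

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

    Sites with zero denominator (fixed for the same allele in both
    populations) are flagged with NaN and skipped by the window estimator.
    """
    ia = h.haplotypes_of_pop(pop_a)
    ib = h.haplotypes_of_pop(pop_b)
    if len(ia) < 2 or len(ib) < 2:
        raise SvbalscanError(
            f"need >= 2 haplotypes per population, got {len(ia)} ({pop_a}) / {len(ib)} ({pop_b})"
        )
    n1, n2 = len(ia), len(ib)
    p1 = h.alleles[ia].mean(axis=0)
    p2 = h.alleles[ib].mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(den == 0, np.nan, num)
    den = np.where(den == 0, np.nan, den)
    return num, den


def hudson_fst(h: HaplotypeMatrix, pop_a: str, pop_b: str) -> Optional[float]:
    """Window Hudson FST as a ratio of averages (negatives reported raw).

    ``None`` when no site has a non-zero denominator.
    """
    num, den = hudson_fst_components(h, pop_a, pop_b)
    ok = ~np.isnan(den)
    if not ok.any():
        return None
    return float(np.nansum(num) / np.nansum(den))


def hudson_fst_per_site(h: HaplotypeMatrix, pop_a: str, pop_b: str) -> np.ndarray:
    """Per-site Hudson FST values (NaN where the denominator is zero)."""
    num, den = hudson_fst_components(h, pop_a, pop_b)
    return num / den


# ---------------------------------------------------------------------------
# EHH / iHH / ΔiHH
# ---------------------------------------------------------------------------

@dataclass
class EHHResult:
    """EHH decay per core class, anchored at a core edge.

    ``distances[c]`` are bp offsets from the anchor (0 first) and ``ehh[c]``
    the matching homozygosity values, per class label c; ``ihh[c]`` is the
    trapezoid integral of the curve over bp.
    """

    core_partition: dict[str, np.ndarray]
    distances: dict[str, np.ndarray]
    ehh: dict[str, np.ndarray]
    ihh: dict[str, float]


def _homozygosity(groups: Iterable[int], m: int) -> float:
    # sum of C(m_k, 2) over extended-haplotype groups / C(m, 2)
    tot = m * (m - 1) / 2
    return sum(g * (g - 1) / 2 for g in groups) / tot


def ehh_curve(
    h: HaplotypeMatrix,
    core: dict[str, np.ndarray],
    direction: str,
    anchor: Optional[int] = None,
    truncate: float = EHH_TRUNCATE,
) -> EHHResult:
    """Extended haplotype homozygosity away from a core.

    ``core`` maps class label -> haplotype indices (each class >= 2).  For
    direction "down" the curve extends through sites with position >= anchor
    in ascending order; "up" through sites with position < anchor in
    descending order.  EHH is 1 at offset 0 by definition and the walk stops
    once it falls below ``truncate``.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    for label, idx in core.items():
        if len(idx) < 2:
            raise DegenerateInput(f"degenerate core class {label!r} (size {len(idx)})")
    if anchor is None:
        anchor = int(h.positions[len(h.positions) // 2]) if h.n_site else 0

    if direction == "down":
        order = np.flatnonzero(h.positions >= anchor)
    else:
        order = np.flatnonzero(h.positions < anchor)[::-1]

    distances: dict[str, np.ndarray] = {}
    ehh: dict[str, np.ndarray] = {}
    ihh: dict[str, float] = {}
    for label, idx in core.items():
        m = len(idx)
        ds = [0.0]
        es = [1.0]
        # group haplotypes by their growing extended haplotype; represented by
        # a vector of group ids refined site by site
        group_ids = np.zeros(m, dtype=np.int64)
        for j in order:
            alleles = h.alleles[idx, j]
            # refine: new group id = (old id, allele)
            pair = group_ids * 2 + alleles
            _, group_ids = np.unique(pair, return_inverse=True)
            counts = np.bincount(group_ids)
            e = _homozygosity(counts, m)
            d = abs(int(h.positions[j]) - anchor)
            ds.append(float(d))
            es.append(e)
            if e < truncate:
                break
        distances[label] = np.asarray(ds)
        ehh[label] = np.asarray(es)
        ihh[label] = float(np.trapezoid(es, ds)) if len(ds) > 1 else 0.0
    return EHHResult(core_partition=dict(core), distances=distances, ehh=ehh, ihh=ihh)


def delta_ihh(
    h: HaplotypeMatrix,
    sv_hap: Sequence[int],
    core_span: Optional[Region] = None,
) -> tuple[float, float, float]:
    """(iHH_carrier, iHH_noncarrier, Δ) with Δ = iHH_noncarrier − iHH_carrier.

    iHH sums the trapezoid EHH integral over both directions away from the
    core span (default: the midpoint of the site range).  Positive Δ means
    the non-deleted class keeps homozygosity over a longer span.
    """
    sv_hap = np.asarray(sv_hap)
    carriers = np.flatnonzero(sv_hap == 1)
    noncar = np.flatnonzero(sv_hap == 0)
    core = {"carrier": carriers, "noncarrier": noncar}
    if core_span is None:
        mid = int(h.positions[len(h.positions) // 2]) if h.n_site else 0
        up_anchor = down_anchor = mid
    else:
        up_anchor, down_anchor = core_span.start, core_span.end
    up = ehh_curve(h, core, "up", anchor=up_anchor)
    down = ehh_curve(h, core, "down", anchor=down_anchor)
    ihh_c = up.ihh["carrier"] + down.ihh["carrier"]
    ihh_n = up.ihh["noncarrier"] + down.ihh["noncarrier"]
    return ihh_c, ihh_n, ihh_n - ihh_c


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

@dataclass
class WindowStats:
    window: Region
    n_hap: int
    S: int
    pi: float
    theta_w: float
    tajima_d: Optional[float]
    fst: dict[tuple[str, str], Optional[float]] = field(default_factory=dict)
    delta_ihh: Optional[float] = None
    partial: bool = False

    @property
    def fst_mean(self) -> Optional[float]:
        vals = [v for v in self.fst.values() if v is not None]
        return float(np.mean(vals)) if vals else None


WINDOW_DEFAULT = 30_000
STEP_DEFAULT = 3_000


def window_spans(region: Region, window: int, step: int) -> list[tuple[Region, bool]]:
    """Tile [region.start, region.end) with (span, is_partial) windows."""
    if step <= 0 or window < step:
        raise ValueError("need window >= step > 0")
    spans: list[tuple[Region, bool]] = []
    s = region.start
    while s + window <= region.end:
        spans.append((Region(region.chrom, s, s + window), False))
        s += step
    if s < region.end:
        spans.append((Region(region.chrom, s, region.end), True))
    if not spans:  # region shorter than one step: single (partial) window
        spans.append((Region(region.chrom, region.start, region.end), True))
    return spans


def compute_window_stats(
    h: HaplotypeMatrix,
    window: Region,
    partial: bool = False,
    pop_pairs: Optional[Sequence[tuple[str, str]]] = None,
    sv_hap: Optional[Sequence[int]] = None,
) -> WindowStats:
    sub = h.subset_region(window)
    S = segregating_sites(sub)
    pi = nucleotide_diversity(sub)
    theta = watterson_theta(S, sub.n_hap)
    try:
        d = tajimas_d(sub)
    except DegenerateInput:
        d = None
    fst: dict[tuple[str, str], Optional[float]] = {}
    if pop_pairs:
        for a, b in pop_pairs:
            fst[(a, b)] = hudson_fst(sub, a, b) if sub.n_site else None
    dihh = None
    if sv_hap is not None and sub.n_site:
        sv_arr = np.asarray(sv_hap)
        if (sv_arr == 1).sum() >= 2 and (sv_arr == 0).sum() >= 2:
            _, _, dihh = delta_ihh(sub, sv_arr)
    return WindowStats(
        window=window, n_hap=h.n_hap, S=S, pi=pi, theta_w=theta,
        tajima_d=d, fst=fst, delta_ihh=dihh, partial=partial,
    )


def sliding_window_scan(
    h: HaplotypeMatrix,
    region: Region,
    window: int = WINDOW_DEFAULT,
    step: int = STEP_DEFAULT,
    pop_pairs: Optional[Sequence[tuple[str, str]]] = None,
    sv_hap: Optional[Sequence[int]] = None,
) -> list[WindowStats]:
    """Per-window statistics tiling ``region`` at the given stride; the last
    partial window is kept and flagged."""
    return [
        compute_window_stats(h, span, partial, pop_pairs=pop_pairs, sv_hap=sv_hap)
        for span, partial in window_spans(region, window, step)
    ]


def all_pop_pairs(h: HaplotypeMatrix) -> list[tuple[str, str]]:
    pops = sorted({p for p in h.pop_labels if p != "NA"})
    return [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]


# ---------------------------------------------------------------------------
# Cross-haplogroup TMRCA
# ---------------------------------------------------------------------------

def cross_group_tmrca(
    h: HaplotypeMatrix,
    partition: tuple[Sequence[int], Sequence[int]],
    mu: float,
    length_bp: int,
) -> float:
    """Mean between-class pairwise difference count / (2 μ L), in generations.

    A deliberately simple divergence-clock estimator for the age of the split
    between two haplogroups (carrier vs non-carrier classes).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    ia = np.asarray(partition[0], dtype=np.intp)
    ib = np.asarray(partition[1], dtype=np.intp)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both classes must be non-empty")
    a = h.alleles[ia].astype(np.int32)
    b = h.alleles[ib].astype(np.int32)
    # mean Hamming distance over all cross pairs, via allele-count algebra
    diffs = 0.0
    for j in range(h.n_site):
        ca = a[:, j].sum()
        cb = b[:, j].sum()
        diffs += ca * (len(ib) - cb) + (len(ia) - ca) * cb
    mean_diff = diffs / (len(ia) * len(ib))
    return mean_diff / (2.0 * mu * length_bp)
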