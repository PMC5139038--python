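"""Tracing a structural variant through time with ancient samples.

The deletion itself is rarely typed in ancient genomes; its frequency is
imputed as the frequency of a tag SNV allele (pure frequency transfer — the
tag's r² is recorded as provenance so the reader can judge imputation
quality).  Where per-base read depth over the locus is available, deletion
copy number is called directly from the inside/flank depth ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genomic_io import MISSING, AncientSample, Region, SvbalscanError

RATIO_HOM_DEL = 0.25   # below: both copies deleted
RATIO_NO_DEL = 0.75    # above: no deletion
LOW_COVERAGE = 5.0     # flank mean below this flags low confidence


@dataclass
class FrequencyPoint:
    population: str
    age_span_years: tuple[float, float]
    n_samples: int
    n_alleles_observed: int
    frequency: Optional[float]  # None when every call is missing
    tag_site: str = ""
    tag_r2_used: Optional[float] = None


@dataclass
class DepthCall:
    sample_id: str
    mean_depth_inside: float
    mean_depth_flank: float
    ratio: float
    call: str  # no_deletion | heterozygous | homozygous_deleted
    low_confidence: bool


def impute_sv_frequency(
    panel: Sequence[AncientSample],
    tag_site: str,
    tag_allele: int,
    tag_r2: Optional[float] = None,
) -> list[FrequencyPoint]:
    """Per population group, the frequency of ``tag_allele`` at ``tag_site``
    among non-missing alleles.  Pseudo-haploid samples contribute one allele,
    diploid samples two."""
    if tag_allele not in (0, 1):
        raise ValueError("tag_allele must be 0 or 1")
    groups: dict[str, list[AncientSample]] = {}
    for s in panel:
        if tag_site not in s.site_ids:
            raise SvbalscanError(f"tag site {tag_site!r} absent from sample {s.sample_id}")
        groups.setdefault(s.population, []).append(s)
    points: list[FrequencyPoint] = []
    for pop in sorted(groups):
        members = groups[pop]
        n_obs = 0
        n_tag = 0
        ages = []
        for s in members:
            j = s.site_ids.index(tag_site)
            alleles = s.calls[j]
            obs = alleles[alleles != MISSING]
            n_obs += len(obs)
            n_tag += int((obs == tag_allele).sum())
            ages.append(s.age_years)
        points.append(
            FrequencyPoint(
                population=pop,
                age_span_years=(float(min(ages)), float(max(ages))),
                n_samples=len(members),
                n_alleles_observed=n_obs,
                frequency=(n_tag / n_obs) if n_obs else None,
                tag_site=tag_site,
                tag_r2_used=tag_r2,
            )
        )
    return points


def call_deletion_from_depth(
    depth: tuple[np.ndarray, np.ndarray],
    sv_span: Region,
    flank_bp: int,
    sample_id: str = "",
) -> DepthCall:
    """Call deletion copy number from the mean inside/flank depth ratio.

    ratio < 0.25 -> homozygous_deleted; 0.25..0.75 -> heterozygous;
    > 0.75 -> no_deletion.  Confidence is flagged low when the flank mean is
    below 5x.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    pos, dep = depth
    pos = np.asarray(pos)
    dep = np.asarray(dep, dtype=float)
    inside = (pos >= sv_span.start) & (pos < sv_span.end)
    flank = ((pos >= sv_span.start - flank_bp) & (pos < sv_span.start)) | (
        (pos >= sv_span.end) & (pos < sv_span.end + flank_bp)
    )
    if not inside.any() or not flank.any():
        raise SvbalscanError("depth track does not cover the SV span and both flanks")
    mean_in = float(dep[inside].mean())
    mean_fl = float(dep[flank].mean())
    if mean_fl == 0:
        raise SvbalscanError("no coverage in flanks")
    ratio = mean_in / mean_fl
    if ratio < RATIO_HOM_DEL:
        call = "homozygous_deleted"
    elif ratio <= RATIO_NO_DEL:
        call = "heterozygous"
    else:
        call = "no_deletion"
    return DepthCall(
        sample_id=sample_id,
        mean_depth_inside=mean_in,
        mean_depth_flank=mean_fl,
        ratio=ratio,
        call=call,
        low_confidence=mean_fl < LOW_COVERAGE,
    )
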