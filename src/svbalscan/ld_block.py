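"""Tag-SNV discovery and haplotype-block delineation around a structural
variant.

LD between the (diploid) deletion genotype and each SNV is the squared
Pearson correlation of dosage vectors (composite LD), computed on the pooled
sample panel rather than per population.  The block is grown outward from the
SV breakpoints through consecutive tag SNVs, stopping when the next tag is
further than ``max_gap`` away.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genomic_io import HaplotypeMatrix, Region, SVGenotypePanel, SvbalscanError

logger = logging.getLogger("svbalscan")

R2_TAG_DEFAULT = 0.9      # tag discovery cutoff
R2_BLOCK_DEFAULT = 0.8    # block-membership cutoff
MAX_GAP_DEFAULT = 2000    # bp; largest allowed inter-tag gap during the walk


@dataclass(frozen=True)
class TagReport:
    site_id: str
    position: int
    r2: Optional[float]  # None when LD is undefined (constant vector)
    is_tag: bool


@dataclass
class BlockDefinition:
    block: Region
    upstream_extent: int
    downstream_extent: int
    tag_sites: list[TagReport]
    mask: list[Region] = field(default_factory=list)


def genotype_r2(sv_dosage: Sequence[int], site_dosage: Sequence[int]) -> Optional[float]:
    """Squared Pearson correlation of two dosage vectors; ``None`` when either
    vector is constant (LD undefined, *not* zero)."""
    x = np.asarray(sv_dosage, dtype=float)
    y = np.asarray(site_dosage, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    sx = x - x.mean()
    sy = y - y.mean()
    vx = float(sx @ sx)
    vy = float(sy @ sy)
    if vx == 0.0 or vy == 0.0:
        return None
    r2 = float((sx @ sy) ** 2 / (vx * vy))
    if r2 > 1.0 + 1e-12:
        raise SvbalscanError(f"r2 exceeded 1 beyond tolerance: {r2}")
    return min(r2, 1.0)


def haplotype_r2(carrier: Sequence[int], site_alleles: Sequence[int]) -> Optional[float]:
    """Haplotype-level r² between SV carrier flags and a site's alleles."""
    return genotype_r2(carrier, site_alleles)


def find_tag_sites(
    h: HaplotypeMatrix,
    sv: SVGenotypePanel,
    threshold: float = R2_TAG_DEFAULT,
    use_haplotypes: bool = False,
) -> list[TagReport]:
    """One TagReport per site, r² against the SV dosage on the pooled panel.

    With ``use_haplotypes`` and a phased SV, r² is computed at the haplotype
    level instead of the diploid-dosage level.
    """
    if h.diploid_sample_ids != sv.sample_ids:
        raise SvbalscanError("haplotype matrix and SV panel samples do not align")
    if use_haplotypes:
        if sv.hap_carrier is None:
            raise SvbalscanError("use_haplotypes requires a phased SV panel")
        sv_vec = sv.hap_carrier
        site_vecs = h.alleles
    else:
        sv_vec = sv.dosage
        site_vecs = h.site_dosage().T  # n_site x n_sample after transpose
        site_vecs = site_vecs  # rows indexed below per site
    reports: list[TagReport] = []
    sv_constant = np.all(sv_vec == sv_vec[0]) if len(sv_vec) else True
    if sv_constant:
        logger.warning("SV dosage is constant; all r2 undefined, no tags")
    for j in range(h.n_site):
        col = site_vecs[j] if not use_haplotypes else site_vecs[:, j]
        r2 = None if sv_constant else genotype_r2(sv_vec, col)
        reports.append(
            TagReport(
                site_id=h.site_ids[j],
                position=int(h.positions[j]),
                r2=r2,
                is_tag=(r2 is not None and r2 > threshold),
            )
        )
    return reports


def delineate_block(
    sv_span: Region,
    tags: Sequence[TagReport],
    max_gap: int = MAX_GAP_DEFAULT,
    mask: Optional[Sequence[Region]] = None,
) -> BlockDefinition:
    """Grow the haplotype block outward from the SV breakpoints.

    Walking upstream (and likewise downstream), the block extends to each next
    tag site while the gap from the current block edge stays <= ``max_gap``.
    With no reachable tags the block equals the SV span (extents 0).
    """
    tag_sites = sorted((t for t in tags if t.is_tag), key=lambda t: t.position)
    up = [t for t in tag_sites if t.position < sv_span.start]
    down = [t for t in tag_sites if t.position >= sv_span.end]

    left = sv_span.start
    for t in reversed(up):
        if left - t.position <= max_gap:
            left = t.position
        else:
            break
    right = sv_span.end
    for t in down:
        if t.position - right <= max_gap:
            right = t.position
        else:
            break
    block = Region(sv_span.chrom, left, right, label="haplotype_block")
    return BlockDefinition(
        block=block,
        upstream_extent=sv_span.start - left,
        downstream_extent=right - sv_span.end,
        tag_sites=list(tag_sites),
        mask=list(mask) if mask else [],
    )


def apply_mask(h: HaplotypeMatrix, mask: Sequence[Region]) -> HaplotypeMatrix:
    """Remove sites falling inside any mask region (e.g. a LINE element)."""
    if not mask:
        return h
    drop = np.zeros(h.n_site, dtype=bool)
    for m in mask:
        if m.chrom != h.chrom:
            continue
        drop |= (h.positions >= m.start) & (h.positions < m.end)
    n_drop = int(drop.sum())
    if n_drop:
        logger.info("apply_mask: removed %d of %d sites", n_drop, h.n_site)
    return h.take_sites(np.flatnonzero(~drop))
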