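"""Coalescent synthetic data with the statistical structure the scan assumes.

Three genealogical regimes are generated, all seeded and fully
deterministic:

* ``neutral`` — the standard Kingman coalescent (pairwise coalescence rate
  C(k,2) with time in units of 2N generations).
* ``balancing`` — a two-class structured coalescent: haplotypes carry or
  lack the deletion; within class c (frequency f_c) lineages coalesce at
  rate C(k_c,2)/f_c, lineages switch class at rate migration/2 each, and the
  two classes fuse into one panmictic process at ``t_split``.  With zero
  migration every cross-class pair coalesces above ``t_split``, producing
  the two deeply diverged haplogroups characteristic of an ancient balanced
  polymorphism.
* ``sweep`` — a hard-sweep caricature: a neutral genealogy whose internal
  coalescence times are compressed into a recent burst,
  t -> s(1-s) + s·t with s = ``sweep_scale``, leaving external branches
  dominant.  Mutations then fall mostly on external branches (singleton
  excess, strongly negative Tajima's D); s = 1 recovers the neutral tree and
  s = 0 the star-tree limit with zero pairwise TMRCA.

Mutations follow the infinite-sites model: Poisson(θ/2 × total branch
length) mutations, each at a unique uniform position, flipping the leaves
below its branch.  A linked deletion, ancient pseudo-haploid degradation
and Poisson read-depth tracks complete the input surface of the pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genomic_io import (
    MISSING,
    AncientSample,
    HaplotypeMatrix,
    Region,
    SVGenotypePanel,
    write_ancient_panel,
    write_depth_track,
    write_phased_vcf,
    write_pop_map,
    write_regions_bed,
    write_sv_panel,
)

logger = logging.getLogger("svbalscan")

GENERATION_YEARS = 29.0
DEPTH_NOISE_FLOOR = 0.01  # residual mis-mapping depth for homozygous deletions


@dataclass
class SimulationConfig:
    """Generative parameters; the seed fully determines the output.

    ``theta`` is the population mutation rate 4Nμ·L for the whole simulated
    region; ``t_split`` (balancing) is the class divergence time in units of
    2N generations; ``class_fraction`` the deletion-class frequency;
    ``sweep_scale`` the burst-compression factor of the sweep caricature.
    ``n_e`` and ``mu`` are only used for conversions to generations/years.
    """

    model: str = "neutral"  # neutral | balancing | sweep
    n_hap: int = 100
    theta: float = 10.0
    region_length_bp: int = 12_000
    t_split: float = 4.0
    class_fraction: float = 0.5
    migration: float = 0.0
    sweep_scale: float = 0.05
    seed: int = 0
    n_e: int = 10_000
    mu: float = 2.5e-8

    def __post_init__(self) -> None:
        if self.model not in ("neutral", "balancing", "sweep"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_hap < 2:
            raise ValueError("n_hap must be >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not (0.0 < self.class_fraction < 1.0):
            raise ValueError("class_fraction must be in (0, 1)")


@dataclass
class Genealogy:
    """A binary coalescent tree over ``n_leaves`` contemporary haplotypes.

    Nodes 0..n_leaves-1 are leaves; ``parent[i]`` is -1 for the root;
    ``time`` is in units of 2N generations; ``class_labels`` marks deletion
    carriers (1) per leaf.
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    class_labels: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                out[i] = self.time[p] - self.time[i]
        return out

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_sets(self) -> list[np.ndarray]:
        """Descendant leaf indices below each node.

        Internal nodes are created in coalescence (time) order, so every
        child has a smaller index than its parent and one bottom-up pass in
        index order suffices.
        """
        sets: list[list[int]] = [
            [i] if i < self.n_leaves else [] for i in range(self.n_nodes)
        ]
        for i in range(self.n_nodes):
            p = int(self.parent[i])
            if p >= 0:
                sets[p].extend(sets[i])
        return [np.asarray(sorted(s), dtype=np.intp) for s in sets]

    def tmrca_matrix(self) -> np.ndarray:
        """Pairwise TMRCA between leaves, in units of 2N generations."""
        n = self.n_leaves
        out = np.zeros((n, n))
        sets = self.leaf_sets()
        # process internal nodes in ascending time; the first common node
        # containing a pair sets its TMRCA
        order = sorted(range(n, self.n_nodes), key=lambda i: self.time[i])
        done = np.zeros((n, n), dtype=bool)
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            p = int(self.parent[i])
            if p >= 0:
                children[p].append(i)
        for node in order:
            kids = children[node]
            for a_i in range(len(kids)):
                for b_i in range(a_i + 1, len(kids)):
                    for x in sets[kids[a_i]]:
                        for y in sets[kids[b_i]]:
                            out[x, y] = out[y, x] = self.time[node]
        return out


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------

def simulate_genealogy(
    config: SimulationConfig,
    class_labels: Optional[np.ndarray] = None,
) -> Genealogy:
    """Simulate one seeded genealogy under the configured model.

    For the balancing model, ``class_labels`` fixes the carrier assignment
    (used by the chunked-recombination panel, where every chunk is linked to
    the same deletion and must share one class partition); by default the
    assignment is drawn binomially from ``class_fraction``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_hap
    parent: list[int] = [-1] * n
    time: list[float] = [0.0] * n

    if config.model == "balancing":
        if class_labels is not None:
            labels = np.asarray(class_labels, dtype=np.int8)
            if len(labels) != n:
                raise ValueError("class_labels must be per haplotype")
        else:
            labels = (rng.random(n) < config.class_fraction).astype(np.int8)
        if labels.sum() == 0 or labels.sum() == n:
            logger.warning(
                "balancing simulation drew an empty class (fraction %.2f, n=%d)",
                config.class_fraction, n,
            )
    else:
        labels = np.zeros(n, dtype=np.int8)

    def merge(lineages: list[int], a: int, b: int, t: float) -> int:
        node = len(parent)
        parent.append(-1)
        time.append(t)
        parent[a] = node
        parent[b] = node
        lineages.remove(a)
        lineages.remove(b)
        lineages.append(node)
        return node

    if config.model in ("neutral", "sweep"):
        lineages = list(range(n))
        t = 0.0
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            merge(lineages, lineages[i], lineages[j], t)
        if config.model == "sweep":
            s = config.sweep_scale
            tarr = np.asarray(time)
            tarr[n:] = s * (1.0 - s) + s * tarr[n:]
            time = tarr.tolist()
    else:
        pools: dict[int, list[int]] = {
            0: [i for i in range(n) if labels[i] == 0],
            1: [i for i in range(n) if labels[i] == 1],
        }
        freq = {0: 1.0 - config.class_fraction, 1: config.class_fraction}
        t = 0.0
        while t < config.t_split and (len(pools[0]) + len(pools[1])) > 1:
            k0, k1 = len(pools[0]), len(pools[1])
            rate0 = k0 * (k0 - 1) / 2.0 / freq[0]
            rate1 = k1 * (k1 - 1) / 2.0 / freq[1]
            rate_m = (k0 + k1) * config.migration / 2.0
            total = rate0 + rate1 + rate_m
            if total == 0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= config.t_split:
                t = config.t_split
                break
            t += dt
            u = rng.random() * total
            if u < rate0:
                i, j = sorted(rng.choice(k0, size=2, replace=False))
                merge(pools[0], pools[0][i], pools[0][j], t)
            elif u < rate0 + rate1:
                i, j = sorted(rng.choice(k1, size=2, replace=False))
                merge(pools[1], pools[1][i], pools[1][j], t)
            else:
                src = 0 if rng.random() * (k0 + k1) < k0 else 1
                if pools[src]:
                    i = int(rng.integers(len(pools[src])))
                    lin = pools[src].pop(i)
                    pools[1 - src].append(lin)
        # panmictic phase above t_split
        lineages = pools[0] + pools[1]
        t = max(t, config.t_split) if len(lineages) > 1 else t
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            merge(lineages, lineages[i], lineages[j], t)

    return Genealogy(
        n_leaves=n,
        parent=np.asarray(parent, dtype=np.int64),
        time=np.asarray(time, dtype=float),
        class_labels=labels,
    )


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def drop_mutations(
    g: Genealogy,
    theta: float,
    region_length_bp: int,
    seed: int,
    sample_prefix: str = "S",
    pop_labels: Optional[Sequence[str]] = None,
    chrom: str = "chr1",
) -> HaplotypeMatrix:
    """Infinite-sites mutations: Poisson(θ/2 × total length) mutations at
    unique uniform positions, each flipping the leaves below its branch."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    lengths = g.branch_lengths()
    total = float(lengths.sum())
    n_mut = int(rng.poisson(theta / 2.0 * total)) if total > 0 else 0
    if n_mut > region_length_bp:
        logger.warning(
            "mutation count %d exceeds region length %d; truncating (infinite-sites "
            "saturation)", n_mut, region_length_bp,
        )
        n_mut = region_length_bp
    n = g.n_leaves
    alleles = np.zeros((n, n_mut), dtype=np.int8)
    if n_mut:
        branches = rng.choice(g.n_nodes, size=n_mut, p=lengths / total)
        positions = np.sort(rng.choice(region_length_bp, size=n_mut, replace=False))
        sets = g.leaf_sets()
        for col, b in enumerate(branches):
            alleles[sets[int(b)], col] = 1
    else:
        positions = np.empty(0, dtype=np.int64)

    sample_ids = [f"{sample_prefix}{i // 2:04d}" for i in range(n)]
    if pop_labels is None:
        pops = ["NA"] * n
    else:
        pops = list(pop_labels)
    return HaplotypeMatrix(
        alleles=alleles,
        positions=np.asarray(positions, dtype=np.int64),
        site_ids=[f"snv_{int(p)}" for p in positions],
        sample_ids=sample_ids,
        pop_labels=pops,
        chrom=chrom,
    )


def overlay_deletion(h: HaplotypeMatrix, g: Genealogy) -> SVGenotypePanel:
    """Carrier flags from the genealogy's class labels; diploid dosages from
    consecutive haplotype pairs."""
    if g.n_leaves != h.n_hap:
        raise ValueError("genealogy and haplotype matrix sizes differ")
    carrier = g.class_labels.astype(np.int8)
    dosage = carrier.reshape(-1, 2).sum(axis=1)
    if carrier.sum() == 0:
        logger.warning("overlay_deletion: no carriers (neutral/single-class input)")
    return SVGenotypePanel(
        sample_ids=h.diploid_sample_ids,
        dosage=dosage,
        hap_carrier=carrier,
    )


# ---------------------------------------------------------------------------
# Ancient degradation & depth
# ---------------------------------------------------------------------------

def degrade_to_ancient(
    h: HaplotypeMatrix,
    missing_rate: float,
    pseudo_haploid: bool,
    ages: Sequence[float],
    seed: int,
    populations: Optional[Sequence[str]] = None,
) -> list[AncientSample]:
    """Degrade each diploid sample of ``h`` into an ancient sample: calls are
    dropped per site with probability ``missing_rate``; pseudo-haploid mode
    keeps one uniformly chosen allele per called site."""
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = h.diploid_sample_ids
    if len(ages) != len(samples):
        raise ValueError("ages must be per diploid sample")
    if populations is None:
        populations = [h.pop_labels[2 * i] for i in range(len(samples))]
    out: list[AncientSample] = []
    for i, sid in enumerate(samples):
        a = h.alleles[2 * i]
        b = h.alleles[2 * i + 1]
        calls = np.stack([a, b], axis=1).astype(np.int8)
        drop = rng.random(h.n_site) < missing_rate
        if pseudo_haploid:
            pick = rng.integers(0, 2, size=h.n_site)
            chosen = np.where(pick == 0, calls[:, 0], calls[:, 1])
            calls = np.stack(
                [chosen, np.full(h.n_site, MISSING, dtype=np.int8)], axis=1
            )
        calls[drop] = MISSING
        out.append(
            AncientSample(
                sample_id=f"anc_{sid}",
                age_years=float(ages[i]),
                population=str(populations[i]),
                calls=calls,
                pseudo_haploid=pseudo_haploid,
                site_ids=list(h.site_ids),
            )
        )
    return out


def simulate_depth(
    genotype: int,
    sv_span: Region,
    flank_bp: int,
    coverage: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base Poisson depth with a drop over the deleted interval.

    Copy number inside the span is 2 − genotype (deletion copies); a
    homozygous deletion keeps a small mis-mapping noise floor of
    0.01 × coverage.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if genotype not in (0, 1, 2):
        raise ValueError("genotype must be 0, 1 or 2 deletion copies")
    rng = np.random.default_rng(seed)
    pos = np.arange(sv_span.start - flank_bp, sv_span.end + flank_bp, dtype=np.int64)
    inside = (pos >= sv_span.start) & (pos < sv_span.end)
    copies = 2 - genotype
    mean_inside = coverage * copies / 2.0 if copies > 0 else DEPTH_NOISE_FLOOR * coverage
    lam = np.where(inside, mean_inside, coverage)
    depth = rng.poisson(lam).astype(np.int64)
    return pos, depth


# ---------------------------------------------------------------------------
# Bundles: the full synthetic input surface of the pipeline
# ---------------------------------------------------------------------------

BUNDLE_POPS = ("CEU", "CHB", "YRI")
DELETION_LENGTH = 32_000
FLANK_LENGTH = 6_000     # simulated SNV panel on each side of the deletion
NEUTRAL_REGION_LENGTH = 6_000
N_NEUTRAL_REGIONS = 50
N_CONTROL_REGIONS = 20
PANEL_ANCHOR = 500_000
BACKGROUND_ANCHOR = 2_000_000
BACKGROUND_SPACING = 50_000
THETA_PER_BP = 1.0e-3    # 4Nμ per bp; N=10,000 and μ=2.5e-8
CHUNK_LENGTH = 1_500     # recombination shim: independent genealogy per chunk


def simulate_chunked_matrix(
    config: SimulationConfig,
    chunk_length: int = CHUNK_LENGTH,
    class_labels: Optional[np.ndarray] = None,
    pop_labels: Optional[Sequence[str]] = None,
    chrom: str = "chr1",
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Simulate a region as independently coalescing chunks (the
    site-partition recombination shim); returns (matrix, class_labels).

    Each ``chunk_length`` slice of the region gets its own genealogy with
    θ scaled accordingly; under the balancing model all chunks share one
    carrier-class partition, mimicking tight linkage to the deletion while
    letting the genealogies decorrelate along the region the way
    recombination does in real data.
    """
    n_chunks = max(1, config.region_length_bp // chunk_length)
    seeds = np.random.SeedSequence(config.seed).generate_state(n_chunks * 2)
    seeds = [int(s % (2**31 - 1)) for s in seeds]
    if config.model == "balancing" and class_labels is None:
        rng = np.random.default_rng(config.seed)
        class_labels = (rng.random(config.n_hap) < config.class_fraction).astype(np.int8)
    mats = []
    for c in range(n_chunks):
        clen = (
            chunk_length if c < n_chunks - 1
            else config.region_length_bp - chunk_length * (n_chunks - 1)
        )
        cfg = SimulationConfig(
            model=config.model,
            n_hap=config.n_hap,
            theta=config.theta * clen / config.region_length_bp,
            region_length_bp=clen,
            t_split=config.t_split,
            class_fraction=config.class_fraction,
            migration=config.migration,
            sweep_scale=config.sweep_scale,
            seed=seeds[2 * c],
            n_e=config.n_e,
            mu=config.mu,
        )
        g = simulate_genealogy(cfg, class_labels=class_labels)
        m = drop_mutations(
            g, cfg.theta, clen, seed=seeds[2 * c + 1],
            pop_labels=pop_labels, chrom=chrom,
        )
        offset = c * chunk_length
        mats.append(
            HaplotypeMatrix(
                alleles=m.alleles,
                positions=m.positions + offset,
                site_ids=[f"snv_{int(p) + offset}" for p in m.positions],
                sample_ids=m.sample_ids,
                pop_labels=m.pop_labels,
                chrom=chrom,
            )
        )
    out = _concat_matrices(mats)
    if class_labels is None:
        class_labels = np.zeros(config.n_hap, dtype=np.int8)
    return out, class_labels


def _split_positions(positions: np.ndarray, flank: int, del_len: int,
                     anchor: int) -> np.ndarray:
    """Map simulated [0, 2·flank) positions onto two flanks around the
    deletion: left flank [anchor, anchor+flank), gap of del_len, right flank."""
    out = positions.copy()
    out = np.where(out < flank, out + anchor, out + anchor + del_len)
    return out


def simulate_target_panel(config: SimulationConfig) -> tuple[
    HaplotypeMatrix, SVGenotypePanel, np.ndarray, Region
]:
    """Simulate the phased SNV panel flanking the deletion, plus the SV.

    Returns (matrix, sv_panel, class_labels, sv_span); positions are laid
    out as two flanks of ``FLANK_LENGTH`` around a ``DELETION_LENGTH`` gap
    anchored at ``PANEL_ANCHOR``.  The panel uses the chunked-recombination
    simulator, with one shared carrier partition across chunks.

    The carrier assignment is stratified by population: balancing selection
    is expected to hold the deletion at the same equilibrium frequency in
    every population, so each population contributes carriers at (rounded)
    ``class_fraction``.
    """
    n = config.n_hap
    pops = [BUNDLE_POPS[(i // 2) % len(BUNDLE_POPS)] for i in range(n)]
    labels = None
    if config.model == "balancing":
        rng = np.random.default_rng(config.seed)
        labels = np.zeros(n, dtype=np.int8)
        for pop in set(pops):
            idx = np.flatnonzero(np.asarray(pops) == pop)
            k = int(round(config.class_fraction * len(idx)))
            labels[rng.choice(idx, size=k, replace=False)] = 1
    h, labels = simulate_chunked_matrix(config, class_labels=labels, pop_labels=pops)
    sv_span = Region(
        h.chrom,
        PANEL_ANCHOR + FLANK_LENGTH,
        PANEL_ANCHOR + FLANK_LENGTH + DELETION_LENGTH,
        label="deletion",
    )
    new_pos = _split_positions(h.positions, FLANK_LENGTH, DELETION_LENGTH, PANEL_ANCHOR)
    h = HaplotypeMatrix(
        alleles=h.alleles,
        positions=new_pos,
        site_ids=[f"snv_{int(p)}" for p in new_pos],
        sample_ids=h.sample_ids,
        pop_labels=h.pop_labels,
        chrom=h.chrom,
    )
    carrier = labels.astype(np.int8)
    sv = SVGenotypePanel(
        sample_ids=h.diploid_sample_ids,
        dosage=carrier.reshape(-1, 2).sum(axis=1),
        hap_carrier=carrier,
    )
    return h, sv, labels, sv_span


@dataclass
class SyntheticBundle:
    """All pipeline inputs for one simulated scenario, written to ``outdir``."""

    outdir: Path
    config: SimulationConfig
    vcf: Path
    sv_table: Path
    pop_map: Path
    neutral_bed: Path
    control_bed: Path
    ancient_calls: Path
    ancient_meta: Path
    depth_tracks: dict[str, Path]
    truth: dict


def simulate_bundle(
    outdir: str | Path,
    model: str = "balancing",
    seed: int = 42,
    n_hap: int = 100,
    theta_per_bp: float = THETA_PER_BP,
    t_split: float = 4.0,
    class_fraction: float = 0.5,
    migration: float = 0.0,
    sweep_scale: float = 0.05,
    n_neutral: int = N_NEUTRAL_REGIONS,
    n_control: int = N_CONTROL_REGIONS,
) -> SyntheticBundle:
    """Generate the complete synthetic input surface for one pipeline run.

    The target panel (two 6 kb flanks around a 32 kb deletion) follows the
    requested model; neutral background regions and control-deletion regions
    are independent neutral simulations of the same per-bp θ over the same
    samples, laid out on the same chromosome.  Also writes the ancient panel
    (pseudo-haploid Neolithic/Bronze-Age groups plus one deep diploid
    individual), depth tracks for one sample per deletion genotype, and a
    truth JSON for test harnesses.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).generate_state(4 + n_neutral + n_control)
    seeds = [int(s % (2**31 - 1)) for s in seeds]

    panel_len = 2 * FLANK_LENGTH
    config = SimulationConfig(
        model=model,
        n_hap=n_hap,
        theta=theta_per_bp * panel_len,
        region_length_bp=panel_len,
        t_split=t_split,
        class_fraction=class_fraction,
        migration=migration,
        sweep_scale=sweep_scale,
        seed=seeds[0],
    )
    h, sv, labels, sv_span = simulate_target_panel(config)

    # background regions: independent neutral chunked simulations over the
    # same sample sheet
    pops = list(h.pop_labels)
    all_mats = [h]
    neutral_regions: list[Region] = []
    control_deletions: list[Region] = []
    for i in range(n_neutral + n_control):
        cfg = SimulationConfig(
            model="neutral",
            n_hap=n_hap,
            theta=theta_per_bp * NEUTRAL_REGION_LENGTH,
            region_length_bp=NEUTRAL_REGION_LENGTH,
            seed=seeds[4 + i],
        )
        hb, _ = simulate_chunked_matrix(cfg, pop_labels=pops)
        anchor = BACKGROUND_ANCHOR + i * BACKGROUND_SPACING
        span = Region(h.chrom, anchor, anchor + NEUTRAL_REGION_LENGTH,
                      label=f"bg_{i}")
        hb = HaplotypeMatrix(
            alleles=hb.alleles,
            positions=hb.positions + anchor,
            site_ids=[f"bg{i}_snv_{int(p)}" for p in hb.positions],
            sample_ids=h.sample_ids,
            pop_labels=pops,
            chrom=h.chrom,
        )
        all_mats.append(hb)
        if i < n_neutral:
            neutral_regions.append(span)
        else:
            # a control "ancient deletion" sits immediately upstream of its
            # simulated downstream region, so the size-matched window
            # [end, end+L) lands exactly on the simulated sites
            control_deletions.append(
                Region(h.chrom, anchor - DELETION_LENGTH, anchor,
                       label=f"ctrl_del_{i - n_neutral}")
            )

    merged = _concat_matrices(all_mats)

    # ancient panel: groups drawn from the modern haplotype pool (an
    # acknowledged caricature: ancients share the modern panel's variation)
    n_samples = n_hap // 2
    group_sizes = {"EN": 10, "MN": 8, "BA": 12}
    ages = {"EN": (7500.0, 6500.0), "MN": (5800.0, 5200.0), "BA": (4500.0, 3500.0)}
    idx = rng.permutation(n_samples)
    ancient: list[AncientSample] = []
    cursor = 0
    for gi, (grp, size) in enumerate(group_sizes.items()):
        size = min(size, max(0, n_samples - cursor - 1))
        take = idx[cursor:cursor + size]
        cursor += size
        hap_idx = np.array([[2 * i, 2 * i + 1] for i in take]).ravel()
        sub_h = HaplotypeMatrix(
            alleles=h.alleles[hap_idx],
            positions=h.positions,
            site_ids=list(h.site_ids),
            sample_ids=[h.sample_ids[i] for i in hap_idx],
            pop_labels=[h.pop_labels[i] for i in hap_idx],
            chrom=h.chrom,
        )
        lo, hi = ages[grp]
        sample_ages = np.linspace(lo, hi, num=len(take)).tolist()
        ancient.extend(
            degrade_to_ancient(
                sub_h, missing_rate=0.2, pseudo_haploid=True,
                ages=sample_ages, seed=seeds[1] + gi,
                populations=[grp] * len(take),
            )
        )
    # one deep, higher-coverage diploid individual, heterozygous for the
    # deletion when the scenario provides one (the 45 ka Central-Asian shape)
    het = np.flatnonzero(sv.dosage == 1)
    deep_idx = int(het[0]) if len(het) else int(idx[cursor] if cursor < len(idx) else 0)
    hap_idx = np.array([2 * deep_idx, 2 * deep_idx + 1])
    sub_h = HaplotypeMatrix(
        alleles=h.alleles[hap_idx],
        positions=h.positions,
        site_ids=list(h.site_ids),
        sample_ids=[h.sample_ids[i] for i in hap_idx],
        pop_labels=[h.pop_labels[i] for i in hap_idx],
        chrom=h.chrom,
    )
    deep = degrade_to_ancient(
        sub_h, missing_rate=0.05, pseudo_haploid=False,
        ages=[45_000.0], seed=seeds[2], populations=["UP"],
    )[0]
    # distinct id: the source sample may also appear in a pseudo-haploid group
    deep.sample_id = f"ancUP_{h.diploid_sample_ids[deep_idx]}"
    ancient.append(deep)

    # depth tracks: one sample per observed deletion genotype + the deep one
    depth_tracks: dict[str, Path] = {}
    showcase = {deep.sample_id: int(sv.dosage[deep_idx])}
    for dose in (0, 1, 2):
        hit = np.flatnonzero(sv.dosage == dose)
        if len(hit):
            showcase[f"depth_{['wt', 'het', 'hom'][dose]}"] = dose
    for k, (name, dose) in enumerate(showcase.items()):
        pos, depth = simulate_depth(
            dose, sv_span, flank_bp=10_000, coverage=30.0, seed=seeds[3] + k
        )
        p = outdir / f"{name}.depth.tsv"
        write_depth_track(pos, depth, p)
        depth_tracks[name] = p

    # write everything
    vcf_path = outdir / "panel.vcf"
    write_phased_vcf(merged, vcf_path, sv=sv, sv_span=sv_span)
    sv_path = outdir / "sv.tsv"
    write_sv_panel(sv, sv_path)
    pop_path = outdir / "pops.tsv"
    write_pop_map(
        {sid: h.pop_labels[2 * i] for i, sid in enumerate(h.diploid_sample_ids)},
        pop_path,
    )
    neutral_bed = outdir / "neutral.bed"
    write_regions_bed(neutral_regions, neutral_bed)
    control_bed = outdir / "control_deletions.bed"
    write_regions_bed(control_deletions, control_bed)
    calls_path = outdir / "ancient_calls.tsv"
    meta_path = outdir / "ancient_samples.tsv"
    write_ancient_panel(ancient, calls_path, meta_path)

    truth = {
        "model": model,
        "seed": seed,
        "t_split": t_split,
        "class_fraction": class_fraction,
        "sv_span": sv_span.to_ucsc(),
        "hap_carrier": sv.hap_carrier.tolist(),
        "dosage": sv.dosage.tolist(),
        "deletion_frequency": float(np.mean(sv.hap_carrier)),
        "theta_per_bp": theta_per_bp,
        "n_hap": n_hap,
        "deep_sample": f"ancUP_{h.diploid_sample_ids[deep_idx]}",
        "deep_sample_dosage": int(sv.dosage[deep_idx]),
        "depth_genotypes": {k: v for k, v in showcase.items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    return SyntheticBundle(
        outdir=outdir,
        config=config,
        vcf=vcf_path,
        sv_table=sv_path,
        pop_map=pop_path,
        neutral_bed=neutral_bed,
        control_bed=control_bed,
        ancient_calls=calls_path,
        ancient_meta=meta_path,
        depth_tracks=depth_tracks,
        truth=truth,
    )


def _concat_matrices(mats: list[HaplotypeMatrix]) -> HaplotypeMatrix:
    mats = sorted(mats, key=lambda m: int(m.positions[0]) if m.n_site else 0)
    return HaplotypeMatrix(
        alleles=np.concatenate([m.alleles for m in mats], axis=1),
        positions=np.concatenate([m.positions for m in mats]),
        site_ids=[s for m in mats for s in m.site_ids],
        sample_ids=list(mats[0].sample_ids),
        pop_labels=list(mats[0].pop_labels),
        chrom=mats[0].chrom,
    )
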