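"""Genomic file I/O and the in-memory haplotype data model.

Internal coordinate convention is 0-based half-open (BED-style).  User-facing
text (CLI region strings, reports) uses 1-based inclusive UCSC-style
coordinates, e.g. ``chr1:152,555,540-152,587,750``; conversion happens at the
I/O boundary and nowhere else.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("svbalscan")

MISSING = -1  # missing allele code in ancient call arrays


class SvbalscanError(Exception):
    """Base error for this package."""


class ParseError(SvbalscanError):
    """Malformed or contract-violating input file."""


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"Region start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    @classmethod
    def from_ucsc(cls, text: str, label: str = "") -> "Region":
        """Parse a 1-based inclusive ``chrom:start-end`` string (commas ok)."""
        m = re.match(r"^([\w.]+):([\d,]+)-([\d,]+)$", text.strip())
        if not m:
            raise ParseError(f"cannot parse region string {text!r}")
        start1 = int(m.group(2).replace(",", ""))
        end1 = int(m.group(3).replace(",", ""))
        if start1 > end1:
            raise ParseError(f"region start exceeds end in {text!r}")
        return cls(m.group(1), start1 - 1, end1, label)

    def to_ucsc(self) -> str:
        """Render as a 1-based inclusive ``chrom:start-end`` string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


# ---------------------------------------------------------------------------
# Haplotype matrix
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes: ``alleles`` is n_hap x n_site with entries
    in {0, 1}.

    Haplotype order follows sample order with the two haplotypes of each
    sample adjacent: (sampleA|left, sampleA|right, sampleB|left, ...).
    ``positions`` are 0-based and strictly increasing; ``sample_ids`` and
    ``pop_labels`` are per-haplotype.
    """

    alleles: np.ndarray
    positions: np.ndarray
    site_ids: list[str]
    sample_ids: list[str]
    pop_labels: list[str] = field(default_factory=list)
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (n_hap x n_site)")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions length does not match site count")
        if len(self.site_ids) != len(self.positions):
            raise ValueError("site_ids length does not match site count")
        if len(self.sample_ids) != self.alleles.shape[0]:
            raise ValueError("sample_ids must be per-haplotype")
        if not self.pop_labels:
            self.pop_labels = ["NA"] * self.alleles.shape[0]
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = (self.alleles != 0) & (self.alleles != 1)
        if bad.any():
            raise ValueError("alleles must be 0/1 (no missing in phased panel)")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_site(self) -> int:
        return self.alleles.shape[1]

    @property
    def hap_ids(self) -> list[str]:
        out, seen = [], {}
        for sid in self.sample_ids:
            k = seen.get(sid, 0)
            seen[sid] = k + 1
            out.append(f"{sid}.{k}")
        return out

    def take_sites(self, index: np.ndarray | Sequence[int]) -> "HaplotypeMatrix":
        index = np.asarray(index, dtype=np.intp)
        return HaplotypeMatrix(
            alleles=self.alleles[:, index],
            positions=self.positions[index],
            site_ids=[self.site_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            pop_labels=list(self.pop_labels),
            chrom=self.chrom,
        )

    def subset_region(self, region: Region) -> "HaplotypeMatrix":
        keep = np.flatnonzero(
            (self.positions >= region.start) & (self.positions < region.end)
        )
        return self.take_sites(keep)

    def haplotypes_of_pop(self, pop: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.pop_labels) == pop)

    def site_dosage(self) -> np.ndarray:
        """Per-sample alternate-allele dosage (n_sample x n_site) formed by
        summing adjacent haplotype pairs."""
        if self.n_hap % 2:
            raise ValueError("odd haplotype count; cannot form diploid dosages")
        return self.alleles.reshape(self.n_hap // 2, 2, self.n_site).sum(axis=1)

    @property
    def diploid_sample_ids(self) -> list[str]:
        return self.sample_ids[::2]


@dataclass
class SVGenotypePanel:
    """Deletion-allele dosage per sample, optionally phased to haplotypes."""

    sample_ids: list[str]
    dosage: np.ndarray  # per sample, in {0, 1, 2}
    hap_carrier: Optional[np.ndarray] = None  # per haplotype, 0/1

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(self.sample_ids) != len(self.dosage):
            raise ValueError("dosage must be per-sample")
        if not np.isin(self.dosage, [0, 1, 2]).all():
            raise ValueError("dosage entries must be 0, 1 or 2")
        if self.hap_carrier is not None:
            self.hap_carrier = np.asarray(self.hap_carrier, dtype=np.int8)
            if len(self.hap_carrier) != 2 * len(self.sample_ids):
                raise ValueError("hap_carrier must be per-haplotype (2 per sample)")
            paired = self.hap_carrier.reshape(-1, 2).sum(axis=1)
            if not np.array_equal(paired, self.dosage):
                raise ValueError("hap_carrier flags do not sum to dosage")


@dataclass
class AncientSample:
    """A dated ancient individual's genotype calls over the panel sites.

    ``calls`` is an (n_site, 2) array of alleles with :data:`MISSING` (= -1)
    for no-calls; pseudo-haploid samples carry exactly one non-missing allele
    per called site (second column all missing).  ``depth`` is an optional
    (positions, depth) pair of arrays covering a region around the SV.
    """

    sample_id: str
    age_years: float
    population: str
    calls: np.ndarray
    pseudo_haploid: bool
    site_ids: list[str]
    depth: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[1] != 2:
            raise ValueError("calls must be (n_site, 2)")
        if self.calls.shape[0] != len(self.site_ids):
            raise ValueError("calls rows must match site_ids")
        if self.pseudo_haploid and (self.calls[:, 1] != MISSING).any():
            raise ValueError("pseudo-haploid sample with a second allele called")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path,
    region: Optional[Region] = None,
    samples: Optional[Sequence[str]] = None,
    pop_map: Optional[dict[str, str]] = None,
    strict: bool = True,
) -> HaplotypeMatrix:
    """Read phased diploid biallelic SNVs into a :class:`HaplotypeMatrix`.

    Multi-allelic and non-SNV records (including symbolic SV records) are
    skipped and counted in the log.  With ``strict`` (default), an unphased
    genotype raises :class:`ParseError`; in lenient mode missing alleles are
    imputed to the major allele with a warning.
    """
    path = str(path)
    vcf = VCF(path, samples=list(samples) if samples else None)
    if samples:
        got = set(vcf.samples)
        missing = [s for s in samples if s not in got]
        if missing:
            raise ParseError(f"samples not present in {path}: {missing}")
    n_samples = len(vcf.samples)
    if n_samples == 0:
        raise ParseError(f"no samples in {path}")

    rows: list[np.ndarray] = []
    positions: list[int] = []
    site_ids: list[str] = []
    n_skipped_multi = 0
    n_skipped_nonsnv = 0
    n_imputed = 0
    chrom_seen = region.chrom if region else None

    for v in vcf:
        if region is not None:
            if v.CHROM != region.chrom:
                continue
            pos0 = v.POS - 1
            if not (region.start <= pos0 < region.end):
                continue
        if chrom_seen is None:
            chrom_seen = v.CHROM
        if len(v.ALT) != 1:
            n_skipped_multi += 1
            continue
        if not v.is_snp:
            n_skipped_nonsnv += 1
            continue
        gts = v.genotypes  # [[a0, a1, phased], ...]
        alleles = np.empty(2 * n_samples, dtype=np.int8)
        for i, gt in enumerate(gts):
            a = gt[:-1]
            phased = gt[-1]
            if len(a) != 2:
                raise ParseError(
                    f"non-diploid genotype at {v.CHROM}:{v.POS} sample {vcf.samples[i]}"
                )
            if a[0] < 0 or a[1] < 0:
                if strict:
                    raise ParseError(
                        f"missing genotype at {v.CHROM}:{v.POS} sample {vcf.samples[i]}"
                    )
                af = np.mean([x for g in gts for x in g[:-1] if x >= 0]) if gts else 0.0
                fill = 1 if af > 0.5 else 0
                a = [fill if x < 0 else x for x in a]
                n_imputed += 1
            elif not phased and a[0] != a[1]:
                # heterozygous unphased cannot be resolved into haplotypes
                if strict:
                    raise ParseError(
                        f"unphased genotype at {v.CHROM}:{v.POS} sample {vcf.samples[i]}"
                    )
                n_imputed += 1
            alleles[2 * i] = a[0]
            alleles[2 * i + 1] = a[1]
        rows.append(alleles)
        positions.append(v.POS - 1)
        site_ids.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")

    if n_skipped_multi or n_skipped_nonsnv:
        logger.info(
            "read_phased_vcf(%s): skipped %d multi-allelic and %d non-SNV records",
            path, n_skipped_multi, n_skipped_nonsnv,
        )
    if n_imputed:
        logger.warning("read_phased_vcf(%s): imputed %d genotypes (lenient mode)", path, n_imputed)

    sample_ids = [s for s in vcf.samples for _ in range(2)]
    pops = [pop_map.get(s, "NA") if pop_map else "NA" for s in sample_ids]
    allele_tab = (
        np.array(rows, dtype=np.int8).T if rows
        else np.zeros((2 * n_samples, 0), dtype=np.int8)
    )
    return HaplotypeMatrix(
        alleles=allele_tab,
        positions=np.array(positions, dtype=np.int64),
        site_ids=site_ids,
        sample_ids=sample_ids,
        pop_labels=pops,
        chrom=chrom_seen or "chr1",
    )


def read_sv_panel(path: str | Path, vcf_samples: Optional[Sequence[str]] = None) -> SVGenotypePanel:
    """Read a two-column (sample, dosage) TSV of deletion-allele counts.

    An optional third/fourth column gives per-haplotype carrier flags.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ParseError(f"SV table {path} needs at least (sample, dosage) columns")
    samples = df[cols[0]].tolist()
    dosage = df[cols[1]].to_numpy()
    hap = None
    if len(cols) >= 4 and df[cols[2]].notna().all():
        hap = np.empty(2 * len(samples), dtype=np.int8)
        hap[0::2] = df[cols[2]].to_numpy()
        hap[1::2] = df[cols[3]].to_numpy()
    panel = SVGenotypePanel(sample_ids=samples, dosage=dosage, hap_carrier=hap)
    if vcf_samples is not None:
        order = {s: i for i, s in enumerate(samples)}
        missing = [s for s in vcf_samples if s not in order]
        if missing:
            raise ParseError(f"SV table {path} lacks samples {missing[:5]}")
        idx = [order[s] for s in vcf_samples]
        hap_idx = None
        if panel.hap_carrier is not None:
            hap_idx = np.array([[2 * i, 2 * i + 1] for i in idx]).ravel()
        panel = SVGenotypePanel(
            sample_ids=list(vcf_samples),
            dosage=panel.dosage[idx],
            hap_carrier=None if hap_idx is None else panel.hap_carrier[hap_idx],
        )
    return panel


def write_sv_panel(panel: SVGenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame({"sample": panel.sample_ids, "dosage": panel.dosage})
    if panel.hap_carrier is not None:
        df["hap1"] = panel.hap_carrier[0::2]
        df["hap2"] = panel.hap_carrier[1::2]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

def write_phased_vcf(
    h: HaplotypeMatrix,
    path: str | Path,
    sv: Optional[SVGenotypePanel] = None,
    sv_span: Optional[Region] = None,
) -> None:
    """Write a phased VCF 4.2; the SV (if given) becomes a symbolic <DEL>
    record with an END info tag.  Round-trips through :func:`read_phased_vcf`
    bit-exactly on the allele table."""
    if h.n_site == 0:
        raise ValueError("refusing to write an empty haplotype matrix")
    if np.any(np.diff(h.positions) <= 0):
        raise ValueError("unsortable positions")
    samples = h.diploid_sample_ids
    if sv is not None and sv.sample_ids != samples:
        raise ValueError("SV panel samples do not match haplotype matrix samples")
    if sv is not None and sv_span is None:
        raise ValueError("sv_span is required when writing an SV record")

    contig_len = int(h.positions[-1]) + 1_000_000
    lines = [
        "##fileformat=VCFv4.2",
        "##source=svbalscan",
        f"##contig=<ID={h.chrom},length={contig_len}>",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]

    records: list[tuple[int, str]] = []
    for j in range(h.n_site):
        gts = "\t".join(
            f"{h.alleles[2 * i, j]}|{h.alleles[2 * i + 1, j]}" for i in range(len(samples))
        )
        pos1 = int(h.positions[j]) + 1
        records.append(
            (pos1, f"{h.chrom}\t{pos1}\t{h.site_ids[j]}\tA\tG\t100\tPASS\t.\tGT\t{gts}")
        )
    if sv is not None:
        if sv.hap_carrier is not None:
            svgts = "\t".join(
                f"{sv.hap_carrier[2 * i]}|{sv.hap_carrier[2 * i + 1]}"
                for i in range(len(samples))
            )
        else:
            svgts = "\t".join({0: "0|0", 1: "0|1", 2: "1|1"}[int(d)] for d in sv.dosage)
        pos1 = sv_span.start + 1
        records.append(
            (pos1,
             f"{h.chrom}\t{pos1}\tDEL_1\tN\t<DEL>\t100\tPASS\t"
             f"SVTYPE=DEL;END={sv_span.end}\tGT\t{svgts}")
        )
    records.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for _, rec in records:
            fh.write(rec + "\n")


# ---------------------------------------------------------------------------
# BED / tables
# ---------------------------------------------------------------------------

def read_regions_bed(path: str | Path) -> list[Region]:
    """Read a BED3/BED4 file into Regions (0-based half-open preserved)."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = parts[3] if len(parts) > 3 else ""
            regions.append(Region(chrom, start, end, label))
    return regions


def write_regions_bed(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a sample<TAB>population map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str,
                     comment="#")
    return dict(zip(df["sample"], df["pop"]))


def write_pop_map(pop_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in pop_map.items():
            fh.write(f"{s}\t{p}\n")


def read_depth_track(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a depth profile from a 2-column (pos, depth) TSV or a 4-column
    BEDGRAPH (chrom, start, end, depth; expanded per base)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 2:
        pos = df[0].to_numpy(dtype=np.int64)
        depth = df[1].to_numpy(dtype=float)
    elif df.shape[1] >= 4:
        pos_list, depth_list = [], []
        for _, row in df.iterrows():
            s, e, d = int(row[1]), int(row[2]), float(row[3])
            pos_list.append(np.arange(s, e, dtype=np.int64))
            depth_list.append(np.full(e - s, d))
        pos = np.concatenate(pos_list)
        depth = np.concatenate(depth_list)
    else:
        raise ParseError(f"depth track {path} must be 2-column TSV or BEDGRAPH")
    order = np.argsort(pos)
    return pos[order], depth[order]


def write_depth_track(pos: np.ndarray, depth: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"pos": pos, "depth": depth}).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Ancient call tables
# ---------------------------------------------------------------------------

def write_ancient_panel(panel: Sequence[AncientSample], calls_path: str | Path,
                        meta_path: str | Path) -> None:
    """Write ancient calls as a site x sample table plus a sample metadata
    table (sample, age_years, population, pseudo_haploid)."""
    if not panel:
        raise ValueError("empty ancient panel")
    site_ids = panel[0].site_ids
    data: dict[str, list[str]] = {"site_id": list(site_ids)}
    for s in panel:
        if s.site_ids != site_ids:
            raise ValueError("ancient samples disagree on site set")
        col = []
        for a, b in s.calls:
            if a == MISSING and b == MISSING:
                col.append("./.")
            elif b == MISSING:
                col.append(str(int(a)))
            else:
                col.append(f"{int(a)}/{int(b)}")
        data[s.sample_id] = col
    pd.DataFrame(data).to_csv(calls_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "sample": [s.sample_id for s in panel],
            "age_years": [s.age_years for s in panel],
            "population": [s.population for s in panel],
            "pseudo_haploid": [int(s.pseudo_haploid) for s in panel],
        }
    ).to_csv(meta_path, sep="\t", index=False)


def read_ancient_panel(calls_path: str | Path, meta_path: str | Path) -> list[AncientSample]:
    calls = pd.read_csv(calls_path, sep="\t", dtype=str)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample": str})
    site_ids = calls["site_id"].tolist()
    out = []
    for _, row in meta.iterrows():
        sid = row["sample"]
        if sid not in calls.columns:
            raise ParseError(f"sample {sid} missing from {calls_path}")
        arr = np.full((len(site_ids), 2), MISSING, dtype=np.int8)
        for i, cell in enumerate(calls[sid]):
            cell = str(cell)
            if cell in ("./.", ".", "nan"):
                continue
            if "/" in cell or "|" in cell:
                a, b = re.split(r"[/|]", cell)
                if a != "." and b != ".":
                    arr[i] = (int(a), int(b))
                elif a != ".":
                    arr[i, 0] = int(a)
            else:
                arr[i, 0] = int(cell)
        out.append(
            AncientSample(
                sample_id=sid,
                age_years=float(row["age_years"]),
                population=str(row["population"]),
                calls=arr,
                pseudo_haploid=bool(int(row["pseudo_haploid"])),
                site_ids=site_ids,
            )
        )
    return out
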