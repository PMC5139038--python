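"""End-to-end orchestration: block -> scan -> tree -> compare -> ancient.

One :class:`RunConfig` (serializable to JSON) drives the whole run; every
stage writes its artifact under the output directory and ``summary.json``
records the resolved config, per-stage record counts and a verdict in
{balancing-like, sweep-like, neutral-like, inconclusive} assigned by fixed,
documented rules:

* balancing-like  — π and Tajima's D each one-sided above background at
  p < 0.05, carrier/non-carrier tree purity >= 0.99, and neither FST nor
  ΔiHH shows a significant increase;
* sweep-like      — FST or ΔiHH significantly increased while target
  Tajima's D tends below the background mean;
* neutral-like    — no coherent signal (a lone marginal significance among
  a four-test panel at α = 0.05 is within null expectation);
* inconclusive    — any other combination.

FST and the ΔiHH asymmetry |Δ|/(iHH_c+iHH_n) are tested one-sided for an
increase (the sweep prediction); the ΔiHH gate additionally requires
asymmetry > 0.8, because rank significance alone is ill-calibrated when
the background null splits one genealogy into pseudo-classes.  Statistics
whose test cannot be computed (e.g. ΔiHH without carrier classes) are
treated as showing no signal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import ancient_freq as af
from . import haplo_tree as ht
from . import ld_block as lb
from . import popgen_stats as ps
from . import region_compare as rc
from .genomic_io import (
    HaplotypeMatrix,
    Region,
    read_depth_track,
    read_ancient_panel,
    read_phased_vcf,
    read_pop_map,
    read_regions_bed,
    read_sv_panel,
)

logger = logging.getLogger("svbalscan")

ALPHA = 0.05
PURITY_MIN = 0.99
# a sweep on one carrier class drives the iHH asymmetry |Δ|/(iHH_c+iHH_n)
# toward 1; rank significance alone is not enough because the background
# null (random splits of one genealogy) understates between-class variance
DIHH_ASYMMETRY_MIN = 0.8


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved inputs and parameters of one pipeline run."""

    vcf: str
    sv_table: str
    sv_span: str                      # UCSC-style region string
    out_dir: str
    pop_map: str = ""
    neutral_bed: str = ""
    control_bed: str = ""
    ancient_calls: str = ""
    ancient_meta: str = ""
    depth_tracks: dict[str, str] = field(default_factory=dict)
    mask_bed: str = ""
    target_region: str = ""           # override; default = downstream flank
    r2_tag: float = lb.R2_TAG_DEFAULT
    r2_block: float = lb.R2_BLOCK_DEFAULT
    max_gap: int = lb.MAX_GAP_DEFAULT
    window: int = 1_500
    step: int = 1_500
    flank: int = 6_000
    tag_site: str = ""                # default: best tag SNV
    tag_allele: int = 1
    depth_flank: int = 10_000
    bootstrap_reps: int = 0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _region_delta_ihh(h: HaplotypeMatrix, region: Region, classes: np.ndarray,
                      core_span: Optional[Region]) -> Optional[tuple[float, float]]:
    """(Δ, asymmetry) for one region; asymmetry = |Δ|/(iHH_c + iHH_n), the
    scale-free statistic used for cross-region comparison (raw iHH levels
    track overall haplotype depth, not class imbalance)."""
    sub = h.subset_region(region)
    if sub.n_site == 0:
        return None
    if (classes == 1).sum() < 2 or (classes == 0).sum() < 2:
        return None
    try:
        ihh_c, ihh_n, delta = ps.delta_ihh(sub, classes, core_span=core_span)
    except ps.DegenerateInput:
        return None
    tot = ihh_c + ihh_n
    return delta, (abs(delta) / tot if tot > 0 else 0.0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk).

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    of completed stages are retained in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    rng = np.random.default_rng(config.seed)
    counts: dict[str, int | float] = {}

    # ---- load stage -------------------------------------------------------
    try:
        sv_span = Region.from_ucsc(config.sv_span, label="deletion")
        pop_map = read_pop_map(config.pop_map) if config.pop_map else None
        block_window = Region(
            sv_span.chrom,
            max(0, sv_span.start - config.flank),
            sv_span.end + config.flank,
        )
        h = read_phased_vcf(config.vcf, region=block_window, pop_map=pop_map)
        sv = read_sv_panel(config.sv_table, vcf_samples=h.diploid_sample_ids)
        if config.mask_bed:
            mask = read_regions_bed(config.mask_bed)
            h = lb.apply_mask(h, mask)
        counts["panel_sites"] = h.n_site
        counts["panel_haplotypes"] = h.n_hap
    except Exception as e:  # noqa: BLE001
        raise StageError("load", str(e)) from e

    # ---- block stage ------------------------------------------------------
    try:
        tags = lb.find_tag_sites(h, sv, threshold=config.r2_tag)
        block_tags = lb.find_tag_sites(h, sv, threshold=config.r2_block)
        block = lb.delineate_block(sv_span, block_tags, max_gap=config.max_gap)
        best_tag = max(
            (t for t in tags if t.r2 is not None),
            key=lambda t: t.r2, default=None,
        )
        block_out = {
            "block": block.block.to_ucsc(),
            "upstream_extent": block.upstream_extent,
            "downstream_extent": block.downstream_extent,
            "n_tags_r2_gt_tag_threshold": sum(t.is_tag for t in tags),
            "n_tags_r2_gt_block_threshold": sum(t.is_tag for t in block_tags),
            "best_tag": None if best_tag is None else {
                "site_id": best_tag.site_id,
                "position_1based": best_tag.position + 1,
                "r2": best_tag.r2,
            },
        }
        with open(out / "block.json", "w") as fh:
            json.dump(block_out, fh, indent=2)
        counts["tag_snvs"] = block_out["n_tags_r2_gt_tag_threshold"]
    except Exception as e:  # noqa: BLE001
        raise StageError("block", str(e)) from e

    # ---- scan stage -------------------------------------------------------
    try:
        if config.target_region:
            target_regions = [Region.from_ucsc(config.target_region, "target")]
        else:
            # default target: both flanks of the deletion — the sequence that
            # travels with the deletion haplotype (the haplotype block minus
            # the deleted interval itself, which has no callable SNVs)
            target_regions = [
                Region(sv_span.chrom, max(0, sv_span.start - config.flank),
                       sv_span.start, "target_up"),
                Region(sv_span.chrom, sv_span.end, sv_span.end + config.flank,
                       "target_down"),
            ]
        pop_pairs = ps.all_pop_pairs(h) if pop_map else None
        sv_hap = sv.hap_carrier
        has_classes = (
            sv_hap is not None
            and (sv_hap == 1).sum() >= 2 and (sv_hap == 0).sum() >= 2
        )
        target_windows = []
        for tr in target_regions:
            target_windows.extend(
                ps.sliding_window_scan(
                    h, tr, window=config.window, step=config.step,
                    pop_pairs=pop_pairs,
                )
            )
        target_dihh = (
            _region_delta_ihh(h, block_window, sv_hap, core_span=sv_span)
            if has_classes else None
        )
        _write_windows_tsv(target_windows, out / "windows.tsv")
        counts["target_windows"] = len(target_windows)
    except Exception as e:  # noqa: BLE001
        raise StageError("scan", str(e)) from e

    # ---- tree stage -------------------------------------------------------
    seg = None
    support = None
    try:
        # tree over the downstream flank, the classic substrate for the
        # haplogroup-segregation question
        target_h = h.subset_region(target_regions[-1])
        if target_h.n_site >= 2:
            tree = ht.haplotype_nj_tree(target_h)
            with open(out / "tree.nwk", "w") as fh:
                fh.write(tree.to_newick() + "\n")
            if sv_hap is not None and has_classes:
                seg = ht.deletion_segregation(tree, sv_hap)
                if config.bootstrap_reps:
                    support = ht.bootstrap_support(
                        target_h, sv_hap, reps=config.bootstrap_reps,
                        seed=config.seed,
                    )
        counts["tree_leaves"] = 0 if target_h.n_site < 2 else tree.n_leaves
    except Exception as e:  # noqa: BLE001
        raise StageError("tree", str(e)) from e

    # ---- compare stage ----------------------------------------------------
    comparisons: dict[str, dict] = {}
    try:
        background_windows: list[ps.WindowStats] = []
        background_dihh: list[float] = []
        full = None
        if config.neutral_bed or config.control_bed:
            full = read_phased_vcf(config.vcf, pop_map=pop_map)
        if config.neutral_bed:
            neutral_regions = read_regions_bed(config.neutral_bed)
            for regn in neutral_regions:
                background_windows.extend(
                    ps.sliding_window_scan(
                        full, regn, window=config.window, step=config.step,
                        pop_pairs=pop_pairs,
                    )
                )
                # null ΔiHH: a seeded random balanced split stands in for
                # carrier classes in regions without a structural variant
                split = np.zeros(full.n_hap, dtype=np.int8)
                split[rng.permutation(full.n_hap)[: full.n_hap // 2]] = 1
                d = _region_delta_ihh(full, regn, split, core_span=None)
                if d is not None:
                    background_dihh.append(d)
            counts["neutral_windows"] = len(background_windows)

            # π and Tajima's D: one-sided "greater" (the balancing claim is
            # directional).  FST and |ΔiHH|: also "greater" — the sweep
            # alternative predicts an *increase*; a decrease carries no
            # selective interpretation here
            for stat, alt in (("pi", "greater"), ("tajima_d", "greater"),
                              ("fst", "greater")):
                try:
                    rep = rc.compare_target(
                        target_windows, background_windows, stat, alternative=alt
                    )
                    comparisons[stat] = rc.report_to_dict(rep)
                except rc.SvbalscanError:
                    comparisons[stat] = {"statistic": stat, "p_value": None,
                                         "note": "not computable"}
            if target_dihh is not None and background_dihh:
                rep = rc.compare_values(
                    [target_dihh[1]], [v[1] for v in background_dihh],
                    statistic="delta_ihh", alternative="greater",
                )
                d = rc.report_to_dict(rep)
                d["target_delta_raw"] = target_dihh[0]
                d["target_asymmetry"] = target_dihh[1]
                comparisons["delta_ihh"] = d
            else:
                comparisons["delta_ihh"] = {
                    "statistic": "delta_ihh", "p_value": None,
                    "note": "no carrier classes or no background",
                }

        control_comparisons: dict[str, dict] = {}
        if config.control_bed:
            control_dels = read_regions_bed(config.control_bed)
            control_regions = rc.match_control_windows(
                control_dels, target_regions[-1].length
            )
            control_windows: list[ps.WindowStats] = []
            for regn in control_regions:
                control_windows.extend(
                    ps.sliding_window_scan(
                        full, regn, window=config.window, step=config.step,
                        pop_pairs=pop_pairs,
                    )
                )
            counts["control_windows"] = len(control_windows)
            for stat, alt in (("pi", "greater"), ("tajima_d", "greater")):
                try:
                    rep = rc.compare_target(
                        target_windows, control_windows, stat, alternative=alt
                    )
                    control_comparisons[stat] = rc.report_to_dict(rep)
                except rc.SvbalscanError:
                    control_comparisons[stat] = {"statistic": stat,
                                                 "p_value": None}
        with open(out / "comparison.json", "w") as fh:
            json.dump({"neutral": comparisons, "control": control_comparisons},
                      fh, indent=2)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("compare", str(e)) from e

    # ---- ancient stage ----------------------------------------------------
    ancient_out: list[dict] = []
    depth_calls: list[dict] = []
    try:
        if config.ancient_calls and config.ancient_meta:
            panel = read_ancient_panel(config.ancient_calls, config.ancient_meta)
            tag_site = config.tag_site
            tag_r2 = None
            if not tag_site and best_tag is not None:
                tag_site = best_tag.site_id
                tag_r2 = best_tag.r2
            if tag_site:
                usable = [s for s in panel if tag_site in s.site_ids]
                if usable:
                    points = af.impute_sv_frequency(
                        usable, tag_site, config.tag_allele, tag_r2=tag_r2
                    )
                    ancient_out = [dataclasses.asdict(p) for p in points]
        for name, path in config.depth_tracks.items():
            track = read_depth_track(path)
            call = af.call_deletion_from_depth(
                track, sv_span, config.depth_flank, sample_id=name
            )
            depth_calls.append(dataclasses.asdict(call))
        if ancient_out:
            _write_freq_tsv(ancient_out, out / "ancient_frequencies.tsv")
        counts["ancient_groups"] = len(ancient_out)
        counts["depth_calls"] = len(depth_calls)
    except Exception as e:  # noqa: BLE001
        raise StageError("ancient", str(e)) from e

    # ---- verdict ----------------------------------------------------------
    def pval(stat: str) -> Optional[float]:
        d = comparisons.get(stat)
        return None if d is None else d.get("p_value")

    pi_sig = (pval("pi") or 1.0) < ALPHA
    d_sig = (pval("tajima_d") or 1.0) < ALPHA
    fst_sig = (pval("fst") or 1.0) < ALPHA
    dihh_sig = (
        (pval("delta_ihh") or 1.0) < ALPHA
        and comparisons.get("delta_ihh", {}).get("target_asymmetry", 0.0)
        > DIHH_ASYMMETRY_MIN
    )
    purity = seg.purity if seg is not None else None
    d_tendency_neg = False
    if comparisons.get("tajima_d", {}).get("p_value") is not None:
        c = comparisons["tajima_d"]
        d_tendency_neg = c["target_mean"] < c["background_mean"]

    # a lone marginal significance among four alpha=0.05 tests is within
    # null expectation; verdicts require a coherent pattern
    coherent_balancing = pi_sig and d_sig
    if coherent_balancing and purity is not None and purity >= PURITY_MIN \
            and not fst_sig and not dihh_sig:
        verdict = "balancing-like"
    elif (fst_sig or dihh_sig) and d_tendency_neg:
        verdict = "sweep-like"
    elif not coherent_balancing and not fst_sig and not dihh_sig:
        verdict = "neutral-like"
    else:
        verdict = "inconclusive"

    summary = {
        "config": dataclasses.asdict(config),
        "counts": counts,
        "block": block_out,
        "segregation": None if seg is None else {
            "is_bipartition": seg.is_bipartition,
            "purity": seg.purity,
            "haplogroup_sizes": list(seg.haplogroup_sizes),
            "bootstrap_support": support,
        },
        "comparisons": comparisons,
        "ancient_frequencies": ancient_out,
        "depth_calls": depth_calls,
        "verdict": verdict,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _write_windows_tsv(windows: list[ps.WindowStats], path: Path) -> None:
    import pandas as pd

    rows = []
    for w in windows:
        rows.append({
            "chrom": w.window.chrom,
            "start_1based": w.window.start + 1,
            "end_1based": w.window.end,
            "n_hap": w.n_hap,
            "S": w.S,
            "pi": w.pi,
            "theta_w": w.theta_w,
            "tajima_d": w.tajima_d,
            "fst_mean": w.fst_mean,
            "partial": int(w.partial),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_freq_tsv(points: list[dict], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(points).to_csv(path, sep="\t", index=False)
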