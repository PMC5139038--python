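"""Distance-based haplotype trees and carrier-segregation tests.

A neighbor-joining tree over pairwise Hamming distances stands in for
maximum-likelihood inference: the biological claim tested here is a
bipartition (deletion carriers vs non-carriers form two haplogroups), which
NJ recovers identically for deeply split classes.  Identical haplotypes can
be collapsed to one weighted leaf, which is lossless for topology and makes
panels of thousands of haplotypes tractable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .genomic_io import HaplotypeMatrix, SvbalscanError

DEDUPE_AUTO_THRESHOLD = 500  # collapse identical haplotypes above this size


@dataclass
class HaploTree:
    """An unrooted NJ tree whose leaves may be weighted haplotype groups."""

    tree: TreeNode
    leaf_weights: dict[str, int]
    leaf_members: dict[str, list[int]]  # leaf name -> original haplotype indices
    negative_branches_clamped: bool = False
    outgroup: Optional[str] = None

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.tips())

    @property
    def n_haplotypes(self) -> int:
        return sum(self.leaf_weights.values())

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass
class SegregationResult:
    is_bipartition: bool
    purity: float
    haplogroup_sizes: tuple[int, int]
    reason: str = ""


def hamming_distance_matrix(h: HaplotypeMatrix) -> np.ndarray:
    """Pairwise count of differing sites between haplotypes (n_hap x n_hap)."""
    if h.n_hap < 2:
        raise SvbalscanError("need >= 2 haplotypes")
    a = h.alleles.astype(np.int32)
    # |x - y| summed over sites == x + y - 2xy for 0/1 data
    g = a @ a.T
    s = a.sum(axis=1)
    d = s[:, None] + s[None, :] - 2 * g
    np.fill_diagonal(d, 0)
    return d


def _dedupe_groups(h: HaplotypeMatrix) -> list[list[int]]:
    _, first, inverse = np.unique(
        h.alleles, axis=0, return_index=True, return_inverse=True
    )
    groups: dict[int, list[int]] = {}
    for i, g in enumerate(inverse):
        groups.setdefault(int(g), []).append(i)
    # stable order: by first occurrence
    return [grp for _, grp in sorted(groups.items(), key=lambda kv: min(kv[1]))]


def build_nj_tree(
    d: np.ndarray,
    ids: Optional[Sequence[str]] = None,
    leaf_members: Optional[dict[str, list[int]]] = None,
) -> HaploTree:
    """Standard neighbor-joining on a symmetric non-negative distance matrix.

    Negative NJ branch lengths are clamped to zero with a flag.  Two- and
    three-taxon inputs use the closed-form solutions.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise SvbalscanError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise SvbalscanError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise SvbalscanError("need >= 2 taxa")
    if ids is None:
        ids = [f"h{i}" for i in range(n)]
    ids = list(ids)
    if leaf_members is None:
        leaf_members = {name: [i] for i, name in enumerate(ids)}
    weights = {name: len(m) for name, m in leaf_members.items()}

    clamped = False
    if n == 2:
        tree = TreeNode.read(io.StringIO(
            f"({ids[0]}:{d[0, 1] / 2},{ids[1]}:{d[0, 1] / 2});"
        ))
    elif n == 3:
        # three-point formulas: x = (dAB + dAC - dBC)/2 etc.
        x = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
        y = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
        z = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
        if min(x, y, z) < 0:
            clamped = True
            x, y, z = max(x, 0), max(y, 0), max(z, 0)
        tree = TreeNode.read(io.StringIO(
            f"({ids[0]}:{x},{ids[1]}:{y},{ids[2]}:{z});"
        ))
    else:
        dm = DistanceMatrix(d, ids)
        tree = nj(dm, neg_as_zero=False)
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
                clamped = True
    return HaploTree(
        tree=tree,
        leaf_weights=weights,
        leaf_members=leaf_members,
        negative_branches_clamped=clamped,
    )


def haplotype_nj_tree(h: HaplotypeMatrix, dedupe: Optional[bool] = None) -> HaploTree:
    """Convenience: Hamming distances -> (optional dedupe) -> NJ tree.

    ``dedupe=None`` collapses identical haplotypes automatically above
    ``DEDUPE_AUTO_THRESHOLD`` haplotypes.
    """
    if dedupe is None:
        dedupe = h.n_hap > DEDUPE_AUTO_THRESHOLD
    hap_ids = h.hap_ids
    if dedupe:
        groups = _dedupe_groups(h)
        reps = [g[0] for g in groups]
        if len(reps) < 2:
            raise SvbalscanError("fewer than 2 distinct haplotypes; tree is degenerate")
        names = [
            hap_ids[g[0]] + (f"_x{len(g)}" if len(g) > 1 else "") for g in groups
        ]
        sub = HaplotypeMatrix(
            alleles=h.alleles[reps],
            positions=h.positions,
            site_ids=list(h.site_ids),
            sample_ids=[h.sample_ids[i] for i in reps],
            pop_labels=[h.pop_labels[i] for i in reps],
            chrom=h.chrom,
        )
        d = hamming_distance_matrix(sub)
        members = {name: list(g) for name, g in zip(names, groups)}
        return build_nj_tree(d, names, members)
    d = hamming_distance_matrix(h)
    return build_nj_tree(d, hap_ids)


def _edge_bipartitions(tree: TreeNode) -> list[set[str]]:
    """Leaf-name sets under each edge (each non-root node) of the tree."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        out.append(tips)
    return out


def deletion_segregation(ht: HaploTree, labels: Sequence[int]) -> SegregationResult:
    """Does some tree edge split carriers from non-carriers exactly?

    ``labels`` are per original haplotype (1 = carrier).  ``purity`` is the
    best two-sided assignment accuracy over all edges; ``is_bipartition`` is
    true iff some edge induces the exact carrier/non-carrier split.
    """
    labels = np.asarray(labels)
    total_carrier = int((labels == 1).sum())
    total_non = int((labels == 0).sum())
    sizes = (total_carrier, total_non)
    if total_carrier == 0 or total_non == 0:
        return SegregationResult(
            is_bipartition=False, purity=1.0, haplogroup_sizes=sizes,
            reason="degenerate: all leaves share one label",
        )
    # per-leaf carrier/non-carrier counts (weighted leaves may mix labels)
    leaf_counts = {
        name: (
            int((labels[members] == 1).sum()),
            int((labels[members] == 0).sum()),
        )
        for name, members in ht.leaf_members.items()
    }
    total = total_carrier + total_non
    best = 0.0
    exact = False
    for side in _edge_bipartitions(ht.tree):
        c_in = sum(leaf_counts[n][0] for n in side)
        n_in = sum(leaf_counts[n][1] for n in side)
        correct = max(
            c_in + (total_non - n_in),      # carriers on this side
            n_in + (total_carrier - c_in),  # carriers on the other side
        )
        best = max(best, correct / total)
        if (c_in == total_carrier and n_in == 0) or (n_in == total_non and c_in == 0):
            exact = True
    return SegregationResult(
        is_bipartition=exact, purity=best, haplogroup_sizes=sizes,
    )


def bootstrap_support(
    h: HaplotypeMatrix,
    labels: Sequence[int],
    reps: int = 1000,
    seed: int = 0,
    dedupe: Optional[bool] = None,
) -> float:
    """Fraction of site-resampled replicates where the carrier bipartition
    holds on the rebuilt NJ tree."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        idx = np.sort(rng.integers(0, h.n_site, size=h.n_site))
        # positions must stay strictly increasing: re-index resampled sites
        boot = HaplotypeMatrix(
            alleles=h.alleles[:, idx],
            positions=np.arange(h.n_site, dtype=np.int64),
            site_ids=[f"b{k}" for k in range(h.n_site)],
            sample_ids=list(h.sample_ids),
            pop_labels=list(h.pop_labels),
            chrom=h.chrom,
        )
        try:
            ht = haplotype_nj_tree(boot, dedupe=dedupe)
        except SvbalscanError:
            continue  # replicate collapsed to < 2 distinct haplotypes
        if deletion_segregation(ht, labels).is_bipartition:
            hits += 1
    return hits / reps


def export_phylip(h: HaplotypeMatrix, path: str) -> None:
    """Relaxed PHYLIP alignment of the 0/1 haplotypes (A = ancestral,
    G = derived) for external ML tree tools."""
    code = np.array(["A", "G"])
    with open(path, "w") as fh:
        fh.write(f"{h.n_hap} {h.n_site}\n")
        for i, name in enumerate(h.hap_ids):
            seq = "".join(code[h.alleles[i]])
            fh.write(f"{name}  {seq}\n")
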