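"""Distance phylogenetics of ERV copies: projected alignment, K2P matrix,
neighbor joining, midpoint rooting, column bootstrap, monophyly tests.

A reference-projected multiple alignment anchors every copy to provirus
coordinates (copy insertions relative to the reference are dropped and
counted), which is deterministic and adequate at the low within-family
divergences of recently endogenized copies. Trees are built by standard
neighbor joining on pairwise K2P distances with deterministic lexicographic
tie-breaking, supported by a nonparametric bootstrap over alignment columns,
and rooted at the midpoint of the longest tip-to-tip path. Per-gene trees are
obtained by slicing the projected alignment at the reference gene intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import Align

from .kimura import k2p_from_codes
from .reference import GENES, ProvirusReference
from .util import GAP, encode, substream

__all__ = ["ProjectedMsa", "reference_projected_msa", "k2p_matrix",
           "neighbor_joining", "midpoint_root", "bootstrap_support",
           "is_monophyletic", "bipartitions", "gene_tree", "compare_topologies"]


@dataclass
class ProjectedMsa:
    ids: list[str]
    matrix: np.ndarray                   # (n, ref_length) uint8, GAP where absent
    ref_length: int
    dropped_insertions: dict[str, int] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def rows(self) -> dict[str, str]:
        from .util import decode
        return {i: decode(self.matrix[k]) for k, i in enumerate(self.ids)}

    def slice(self, start: int, end: int) -> "ProjectedMsa":
        return ProjectedMsa(ids=list(self.ids), matrix=self.matrix[:, start:end],
                            ref_length=end - start,
                            dropped_insertions=dict(self.dropped_insertions))


def _semi_global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    # cheap gap extension: structural deletions spanning kilobases are real
    # features of ERV copies and must beat shifted/noisy alignments
    a.extend_gap_score = -0.5
    # free end gaps only for unaligned reference tails: a partial copy sits
    # inside the reference without penalty, but copy tails must align
    if hasattr(a, "open_end_deletion_score"):
        a.open_end_deletion_score = 0
        a.extend_end_deletion_score = 0
    else:  # older attribute spelling
        a.query_end_open_gap_score = 0
        a.query_end_extend_gap_score = 0
    return a


def reference_projected_msa(elements: dict[str, str],
                            provirus_ref: ProvirusReference,
                            min_alignable: float = 0.30) -> ProjectedMsa:
    """Align every copy to the reference and index columns by reference position."""
    aligner = _semi_global_aligner()
    ref_len = provirus_ref.length
    ids, rows, dropped, excluded = [], [], {}, []
    for cid in sorted(elements):
        seq = elements[cid]
        aln = aligner.align(provirus_ref.seq, seq)[0]
        tb, qb = aln.aligned
        row = np.full(ref_len, GAP, dtype=np.uint8)
        codes = encode(seq)
        aligned = 0
        ins = 0
        for i, ((t0, t1), (q0, q1)) in enumerate(zip(tb, qb)):
            row[t0:t1] = codes[q0:q1]
            aligned += t1 - t0
            if i > 0 and t0 == tb[i - 1][1]:
                ins += q0 - qb[i - 1][1]   # insertion relative to reference
        if aligned < min_alignable * len(seq):
            excluded.append(cid)
            continue
        ids.append(cid)
        rows.append(row)
        dropped[cid] = ins
    if not rows:
        raise ValueError("no copy aligned to the reference")
    return ProjectedMsa(ids=ids, matrix=np.vstack(rows), ref_length=ref_len,
                        dropped_insertions=dropped, excluded=excluded)


def k2p_matrix(msa: ProjectedMsa | np.ndarray,
               ids: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Symmetric pairwise K2P matrix over shared non-gap columns.

    Saturated pairs get a large finite ceiling (5 subs/site) and are counted;
    the triangle inequality is not enforced or repaired.
    """
    if isinstance(msa, ProjectedMsa):
        m, labels = msa.matrix, msa.ids
    else:
        m, labels = msa, ids or [str(i) for i in range(msa.shape[0])]
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p_from_codes(m[i], m[j])
            D[i, j] = D[j, i] = 5.0 if res.saturated else res.K
    return D, list(labels)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Standard NJ agglomeration; ties broken by lexicographic tip label.

    Negative branch lengths are clamped to zero. The returned tree is unrooted
    (trifurcating root node).
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n0 = D.shape[0]
    if n0 < 3:
        raise ValueError("need at least 3 taxa")
    d = {(i, j): D[i, j] for i in range(n0) for j in range(n0)}
    active = list(range(n0))
    newick = {i: "'" + labels[i].replace("'", "_") + "'" for i in range(n0)}
    rep = {i: labels[i] for i in range(n0)}   # representative label for ties
    nxt = n0

    def bl(x: float) -> float:
        return max(0.0, x)

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[(i, j)] for j in active if j != i) for i in active}
        best, bi, bj = None, None, None
        for ii in range(n):
            for jj in range(ii + 1, n):
                i, j = active[ii], active[jj]
                q = (n - 2) * d[(i, j)] - r[i] - r[j]
                key = (q, *sorted((rep[i], rep[j])))
                if best is None or key < best:
                    best, bi, bj = key, i, j
        i, j = (bi, bj) if rep[bi] <= rep[bj] else (bj, bi)
        li = 0.5 * d[(i, j)] + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = d[(i, j)] - li
        newick[nxt] = f"({newick[i]}:{bl(li):.10g},{newick[j]}:{bl(lj):.10g})"
        rep[nxt] = min(rep[i], rep[j])
        for k in active:
            if k in (i, j):
                continue
            d[(nxt, k)] = d[(k, nxt)] = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
        d[(nxt, nxt)] = 0.0
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = sorted(active, key=lambda x: rep[x])
    li = 0.5 * (d[(i, j)] + d[(i, k)] - d[(j, k)])
    lj = 0.5 * (d[(i, j)] + d[(j, k)] - d[(i, k)])
    lk = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
    s = (f"({newick[i]}:{bl(li):.10g},{newick[j]}:{bl(lj):.10g},"
         f"{newick[k]}:{bl(lk):.10g});")
    return dendropy.Tree.get(data=s, schema="newick",
                             preserve_underscores=True)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest tip-to-tip path."""
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=True)
    return t


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the tip-label set of the smaller side
    (lexicographic side as canonical fallback on ties)."""
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_tips - below
        if len(below) <= 1 or len(other) <= 1:
            continue
        if len(below) < len(other):
            out.add(below)
        elif len(other) < len(below):
            out.add(other)
        else:
            out.add(min((below, other), key=lambda s: sorted(s)))
    return out


def bootstrap_support(msa: ProjectedMsa, B: int = 100, seed: int = 0
                      ) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Column-resampled NJ bootstrap; returns the full-data tree with supports.

    Support (% of replicates containing each internal bipartition) is written
    onto the matching internal node labels of the full-data tree.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    D, labels = k2p_matrix(msa)
    tree = neighbor_joining(D, labels)
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = substream(seed, "bootstrap")
    L = msa.matrix.shape[1]
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        Db, _ = k2p_matrix(msa.matrix[:, cols], labels)
        for bp in bipartitions(neighbor_joining(Db, labels)):
            if bp in counts:
                counts[bp] += 1
    support = {bp: 100.0 * c / B for bp, c in counts.items()}
    all_tips = frozenset(labels)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        bp = below if below in support else (all_tips - below)
        if bp in support:
            node.label = str(int(round(support[bp])))
    return tree, support


def is_monophyletic(tree: dendropy.Tree, tip_subset, outgroup: str | None = None) -> bool:
    """True iff the smallest clade containing the subset contains no other tips."""
    subset = set(tip_subset)
    t = tree.clone(depth=1)
    if outgroup is not None:
        og = t.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup} not in tree")
        t.reroot_at_edge(og.edge, update_bipartitions=True)
    t.is_rooted = True
    mrca = t.mrca(taxon_labels=list(subset))
    below = {l.taxon.label for l in mrca.leaf_iter()}
    return below == subset


def gene_tree(msa: ProjectedMsa, provirus_ref: ProvirusReference,
              gene: str) -> dendropy.Tree:
    """NJ tree from the projected-alignment slice of one reference gene."""
    f = provirus_ref.features[gene]
    sub = msa.slice(f.start, f.end)
    D, labels = k2p_matrix(sub)
    return neighbor_joining(D, labels)


def compare_topologies(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> dict:
    """Shared/unique bipartition counts between two trees on the same tips."""
    a, b = bipartitions(tree_a), bipartitions(tree_b)
    return {"shared": len(a & b), "only_a": len(a - b), "only_b": len(b - a),
            "total_a": len(a), "total_b": len(b)}


def gene_vs_genome_table(msa: ProjectedMsa, provirus_ref: ProvirusReference):
    """Descriptive gene-vs-genome topology comparison (no topology test)."""
    import pandas as pd

    D, labels = k2p_matrix(msa)
    genome_tree = neighbor_joining(D, labels)
    rows = []
    for g in GENES:
        if g not in provirus_ref.features:
            continue
        cmp = compare_topologies(gene_tree(msa, provirus_ref, g), genome_tree)
        rows.append({"gene": g, **cmp})
    return pd.DataFrame(rows)
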