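"""Projected alignment, K2P matrix, NJ, rooting, bootstrap, monophyly."""

import itertools

import numpy as np
import pytest

from ervkit.kimura import evolve_codes
from ervkit.phylogeny import (bipartitions, bootstrap_support, is_monophyletic,
                              k2p_matrix, midpoint_root, neighbor_joining,
                              reference_projected_msa)
from ervkit.util import GAP, decode, encode, substream


def path_lengths(tree):
    pdm = tree.phylogenetic_distance_matrix()
    tax = {l.label: l for l in tree.taxon_namespace}
    labels = sorted(tax)
    return {(a, b): pdm.distance(tax[a], tax[b])
            for a, b in itertools.combinations(labels, 2)}


ADDITIVE_D = np.array([[0, 3, 5, 6],
                       [3, 0, 6, 7],
                       [5, 6, 0, 7],
                       [6, 7, 7, 0]], dtype=float)


def test_nj_recovers_additive_tree_exactly():
    tree = neighbor_joining(ADDITIVE_D, ["A", "B", "C", "D"])
    pl = path_lengths(tree)
    labels = ["A", "B", "C", "D"]
    for (i, j) in itertools.combinations(range(4), 2):
        assert pl[(labels[i], labels[j])] == pytest.approx(ADDITIVE_D[i, j],
                                                           abs=1e-9)
    assert bipartitions(tree) == {frozenset({"A", "B"})}


def test_nj_agrees_with_independent_implementation(rng):
    """Cross-check topology against scikit-bio's NJ on a random matrix."""
    skbio = pytest.importorskip("skbio")
    n = 7
    x = rng.random((n, 5))
    D = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    labels = [f"t{i}" for i in range(n)]
    ours = neighbor_joining(D, labels)
    theirs_sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
    import dendropy
    theirs = dendropy.Tree.get(data=str(theirs_sk), schema="newick")
    assert bipartitions(ours) == bipartitions(theirs)


def test_nj_three_taxa_star():
    D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
    tree = neighbor_joining(D, ["A", "B", "C"])
    assert bipartitions(tree) == set()
    pl = path_lengths(tree)
    assert pl[("A", "B")] == pytest.approx(2.0)


def test_nj_rejects_asymmetric_matrix():
    D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
    with pytest.raises(ValueError):
        neighbor_joining(D, list("ABC"))


def test_midpoint_root_chain_and_invariance():
    # chain A -1- B -3- C: root lands on the B-C branch, 2 from each end
    D = np.array([[0, 1, 4], [1, 0, 3], [4, 3, 0]], float)
    tree = neighbor_joining(D, ["A", "B", "C"])
    before = path_lengths(tree)
    rooted = midpoint_root(tree)
    after = path_lengths(rooted)
    for k in before:
        assert after[k] == pytest.approx(before[k], abs=1e-9)
    depths = {l.taxon.label: l.distance_from_root()
              for l in rooted.leaf_node_iter()}
    assert depths["A"] == pytest.approx(2.0)
    assert depths["C"] == pytest.approx(2.0)


def test_projection_identical_copies_identical_rows(ref):
    msa = reference_projected_msa({"a": ref.seq, "b": ref.seq}, ref)
    assert np.array_equal(msa.matrix[0], msa.matrix[1])
    assert not msa.excluded


def test_projection_deletion_becomes_gap_block(ref):
    i0, _ = ref.internal_interval
    start = i0 + 500
    deleted = ref.seq[:start] + ref.seq[start + 1000:]
    msa = reference_projected_msa({"full": ref.seq, "del": deleted}, ref)
    row = msa.matrix[msa.ids.index("del")]
    gap_cols = np.nonzero(row == GAP)[0]
    assert len(gap_cols) == 1000
    assert gap_cols[0] == start and gap_cols[-1] == start + 999


def test_projection_distances_close_to_direct(ref):
    """Projected K2P within 5% of direct pairwise-alignment K2P."""
    from ervkit.dating import date_ltr_pair, align_ltr_pair, k2p_distance
    rng = substream(31, "proj")
    refc = encode(ref.seq)
    seqs = {f"c{i}": decode(evolve_codes(refc, 0.05, 2.0, rng)) for i in range(4)}
    msa = reference_projected_msa(seqs, ref)
    D, labels = k2p_matrix(msa)
    for i, j in itertools.combinations(range(len(labels)), 2):
        aln = align_ltr_pair(seqs[labels[i]], seqs[labels[j]])
        K_direct, *_ = k2p_distance(aln)
        assert D[i, j] == pytest.approx(K_direct, rel=0.05)


def test_bootstrap_single_replicate_support_in_0_100(ref):
    rng = substream(8, "boot")
    refc = encode(ref.seq)
    anc1 = evolve_codes(refc, 0.05, 2.0, rng)
    anc2 = evolve_codes(refc, 0.05, 2.0, rng)
    seqs = {}
    for i in range(2):
        seqs[f"a{i}"] = decode(evolve_codes(anc1, 0.005, 2.0, rng))
        seqs[f"b{i}"] = decode(evolve_codes(anc2, 0.005, 2.0, rng))
    msa = reference_projected_msa(seqs, ref)
    tree, support = bootstrap_support(msa, B=1, seed=3)
    assert all(v in (0.0, 100.0) for v in support.values())
    tree2, support2 = bootstrap_support(msa, B=1, seed=3)
    assert support == support2       # deterministic given seed
    # deep split: full support even at B=10
    _, s10 = bootstrap_support(msa, B=10, seed=3)
    assert s10[frozenset({"a0", "a1"})] == 100.0 or \
        s10[frozenset({"b0", "b1"})] == 100.0


def test_monophyly_trivial_and_nested(ref):
    D = ADDITIVE_D
    tree = neighbor_joining(D, ["A", "B", "C", "D"])
    assert is_monophyletic(tree, ["A", "B", "C", "D"])
    assert is_monophyletic(tree, ["A"])
    assert is_monophyletic(tree, ["A", "B"], outgroup="D")
    assert not is_monophyletic(tree, ["A", "C"], outgroup="D")
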