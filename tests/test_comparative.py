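"""Exact tests, Bonferroni, ortholog grouping and count tables."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from ervkit.comparative import (bonferroni, build_count_tables, fisher_exact,
                                match_orthologous_loci, run_count_comparisons)


def fisher_brute_force(a, b, c, d):
    """Fixed-margin enumeration with exact integer tie handling."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    obs = comb(r1, a) * comb(r2, c1 - a)
    total = comb(n, c1)
    s = sum(comb(r1, k) * comb(r2, c1 - k)
            for k in range(max(0, c1 - r2), min(r1, c1) + 1)
            if comb(r1, k) * comb(r2, c1 - k) <= obs)
    return s / total


def test_fisher_symmetry_and_known_values():
    assert fisher_exact([[1, 1], [1, 1]]) == 1.0
    assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-12)


def test_fisher_matches_printed_gene_loss_bound():
    assert fisher_exact([[65, 0], [50, 15]]) < 0.001


def test_fisher_input_validation():
    with pytest.raises(ValueError):
        fisher_exact([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        fisher_exact([[-1, 2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[0.5, 2], [3, 4]])


def test_fisher_equals_brute_force_on_random_tables(rng):
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            fisher_brute_force(a, b, c, d), abs=1e-12)


def test_bonferroni():
    assert bonferroni([0.01, 0.2, 0.03], 3) == pytest.approx([0.03, 0.6, 0.09])
    assert bonferroni([0.5], 3) == [1.0]
    assert bonferroni([0.2], 1) == [0.2]
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], 1)


# -- ortholog grouping -------------------------------------------------------

class FakeLocus:
    def __init__(self, up, down, scaffold="s", start=0, end=100):
        self.flank_up, self.flank_down = up, down
        self.strand = "+"
        self.scaffold, self.start, self.end = scaffold, start, end

    def oriented_flanks(self):
        return self.flank_up, self.flank_down


class FakeSig:
    def __init__(self, s):
        self.upstream_4mer = s
        self.downstream_4mer = s
        self.is_matching = True


class FakeCopy:
    def __init__(self, cid, up, down, sig, cls="typical"):
        self.locus = FakeLocus(up, down)
        self.copy_id = cid
        self.copy_class = cls
        self.signature = FakeSig(sig)


def _flank(rng, n=800):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate(s, rng, rate=0.005):
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[rng.integers(0, 4)]
    return "".join(out)


def test_shared_locus_groups_and_convergent_signatures_stay_apart(rng):
    up, down = _flank(rng), _flank(rng)
    copies = {
        "g1": [FakeCopy("g1_a", up, down, "GGAG"),
               FakeCopy("g1_b", _flank(rng), _flank(rng), "CCAG")],
        "g2": [FakeCopy("g2_a", _mutate(up, rng), _mutate(down, rng), "GGAG"),
               FakeCopy("g2_b", _flank(rng), _flank(rng), "CCAG")],
    }
    groups = match_orthologous_loci(copies, flank_len=800)
    shared = [g for g in groups if len(g.members) == 2]
    assert len(shared) == 1
    assert sorted(m[1] for m in shared[0].members) == ["g1_a", "g2_a"]
    assert shared[0].evidence == "flank_match"
    assert shared[0].shared_signature == "GGAG"
    # same 4-mer, different loci: reported as convergent, never merged
    conv = [g for g in groups if g.evidence == "signature_only"]
    assert len(conv) == 2
    assert all(len(g.members) == 1 for g in conv)


def test_single_genome_every_copy_its_own_group(rng):
    copies = {"g1": [FakeCopy("a", _flank(rng), _flank(rng), "AAAA"),
                     FakeCopy("b", _flank(rng), _flank(rng), "TTTT")]}
    groups = match_orthologous_loci(copies, flank_len=800)
    assert len(groups) == 2 and all(len(g.members) == 1 for g in groups)


def test_grouping_is_order_independent(rng):
    up, down = _flank(rng), _flank(rng)
    c = {
        "g1": [FakeCopy("a", up, down, "AAAA")],
        "g2": [FakeCopy("b", _mutate(up, rng), _mutate(down, rng), "AAAA")],
        "g3": [FakeCopy("c", _mutate(up, rng), _mutate(down, rng), "AAAA")],
    }
    g_fwd = match_orthologous_loci(c, flank_len=800)
    g_rev = match_orthologous_loci(dict(reversed(list(c.items()))), flank_len=800)
    def key(gs):
        return sorted(tuple(sorted(g.members)) for g in gs)
    assert key(g_fwd) == key(g_rev)
    assert any(len(g.members) == 3 for g in g_fwd)   # single linkage transitivity


# -- count tables ------------------------------------------------------------

class FakeAnn:
    def __init__(self, name, kind, parent=None):
        self.name, self.kind, self.parent = name, kind, parent


class FakeAnnotatedCopy(FakeCopy):
    def __init__(self, cid, cls, genes=(), peptides=(), sig="AAAA"):
        super().__init__(cid, "A" * 600, "A" * 600, sig, cls)
        self._genes = [FakeAnn(g, "gene") for g in genes]
        self._peps = [FakeAnn(p, "peptide", parent) for p, parent in peptides]

    def genes(self):
        return self._genes

    def peptides(self):
        return self._peps


def test_count_tables_sums_and_exclusions():
    copies = {
        "g1": [FakeAnnotatedCopy("t1", "typical", genes=("gag", "pol", "env")),
               FakeAnnotatedCopy("s1", "solo_ltr")],
        "g2": [FakeAnnotatedCopy("t2", "typical", genes=("gag", "env")),
               FakeAnnotatedCopy("t3", "typical", genes=("gag", "pol", "env"))],
    }
    tabs = build_count_tables(copies)
    assert tabs["classes"]["g1"].sum() == 2
    assert tabs["classes"].loc["solo_ltr", "g1"] == 1
    assert tabs["genes"].loc["pol"].sum() == 2      # one pol deletion
    # recombination removals excluded from gene counts
    tabs2 = build_count_tables(copies, removed_ids={"t3"})
    assert tabs2["genes"].loc["pol"].sum() == 1
    assert tabs2["classes"]["g2"].sum() == 2        # class table unaffected


def test_run_count_comparisons_identical_genomes_all_p1():
    copies = {
        "g1": [FakeAnnotatedCopy("a", "typical", genes=("gag", "pol", "env")),
               FakeAnnotatedCopy("b", "solo_ltr")],
        "g2": [FakeAnnotatedCopy("c", "typical", genes=("gag", "pol", "env")),
               FakeAnnotatedCopy("d", "solo_ltr")],
    }
    res = run_count_comparisons(build_count_tables(copies))
    assert res and all(r.p_bonferroni == 1.0 for r in res)
    for r in res:
        assert r.p_bonferroni == min(1.0, r.p_two_sided * r.family_size)
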