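"""Homology search: k-mer index, HSP search, filters, merging, flanks."""

import numpy as np
import pytest

from ervkit.mining import (ErvLocus, KmerIndex, MiningParams, extract_with_flanks,
                           filter_hits, merge_to_loci, mine_genome, search)
from ervkit.util import decode, random_background, revcomp, substream


def make_genome(rng, length=120_000):
    return decode(random_background(length, rng))


def test_index_counts_match_direct_enumeration(rng):
    seq = decode(rng.integers(0, 4, size=5000).astype(np.uint8))
    seq = seq[:1000] + "N" * 7 + seq[1000:]
    k = 11
    idx = KmerIndex({"s": seq}, k)
    direct = sum(1 for i in range(len(seq) - k + 1) if "N" not in seq[i:i + k])
    assert idx.n_positions == direct


def test_all_n_scaffold_indexes_nothing():
    idx = KmerIndex({"s": "N" * 500, "t": "ACGT" * 100}, 11)
    assert idx.n_positions == 400 - 10


def test_empty_genome_rejected():
    with pytest.raises(ValueError):
        KmerIndex({}, 11)
    with pytest.raises(ValueError):
        KmerIndex({"s": ""}, 11)


def test_exact_substring_gives_perfect_hsp(rng):
    bg = make_genome(rng)
    query = decode(rng.integers(0, 4, size=700).astype(np.uint8))
    genome = {"s": bg[:50_000] + query + bg[50_000:]}
    hsps = search("q", query, KmerIndex(genome))
    best = max(hsps, key=lambda h: h.score)
    assert (best.s_start, best.s_end) == (50_000, 50_700)
    assert best.identity == 100.0 and best.query_coverage == 100.0
    assert best.strand == "+"


def test_search_is_strand_symmetric(rng):
    bg = make_genome(rng)
    query = decode(rng.integers(0, 4, size=700).astype(np.uint8))
    genome = {"s": bg[:50_000] + query + bg[50_000:]}
    mirrored = {"s": revcomp(genome["s"])}
    fwd = max(search("q", query, KmerIndex(genome)), key=lambda h: h.score)
    rev = max(search("q", query, KmerIndex(mirrored)), key=lambda h: h.score)
    n = len(genome["s"])
    assert rev.strand == "-"
    assert (rev.s_start, rev.s_end) == (n - fwd.s_end, n - fwd.s_start)
    assert rev.score == fwd.score


def test_diverged_copy_recovered_with_expected_identity(ref):
    from ervkit.kimura import evolve_codes
    from ervkit.util import encode
    rng = substream(17, "divtest")
    bg = make_genome(rng)
    ident = []
    for i in range(10):
        ele = decode(evolve_codes(encode(ref.seq), 0.10, 2.0, rng))
        genome = {"s": bg[:60_000] + ele + bg[60_000:]}
        hsps = search("provirus", ref.seq, KmerIndex(genome))
        best = max(hsps, key=lambda h: h.score)
        ident.append(best.identity)
        assert best.query_coverage > 90
    assert 85 <= np.mean(ident) <= 95


def test_absent_query_yields_no_filtered_hits(rng):
    genome = {"s": make_genome(rng, 200_000)}
    query = decode(np.random.default_rng(999).integers(0, 4, size=600).astype(np.uint8))
    hsps = search("q", query, KmerIndex(genome))
    assert filter_hits(hsps, "locus_mining") == []


def test_filter_modes_and_thresholds():
    def hsp(identity, coverage):
        from ervkit.mining import Hsp
        return Hsp("q", "s", 0, 100, 0, 100, "+", 50.0, identity, coverage)
    hits = [hsp(49.9, 90.0), hsp(50.0, 40.0), hsp(80.0, 50.0)]
    assert [h.identity for h in filter_hits(hits, "host_range")] == [50.0, 80.0]
    assert [h.identity for h in filter_hits(hits, "locus_mining")] == [49.9, 80.0]
    assert filter_hits([], "host_range") == []
    with pytest.raises(ValueError):
        filter_hits(hits, "nonsense")


def test_merge_nested_and_distant_hits():
    from ervkit.mining import Hsp
    inner = Hsp("LTR", "s", 0, 500, 10_000, 10_500, "+", 500.0, 100.0, 100.0)
    outer = Hsp("provirus", "s", 0, 7500, 9_800, 17_300, "+", 7000.0, 99.0, 99.0)
    far = Hsp("LTR", "s", 0, 500, 60_000, 60_500, "+", 500.0, 100.0, 100.0)
    loci = merge_to_loci([inner, outer, far], "g", MiningParams(max_gap=2000))
    assert len(loci) == 2
    assert (loci[0].start, loci[0].end) == (9_800, 17_300)
    assert loci[0].queries == ["LTR", "provirus"]
    assert loci[1].queries == ["LTR"]


def test_extract_with_flanks_arithmetic(rng):
    genome = {"s": make_genome(rng, 100_000)}
    loc = ErvLocus("L0", "g", "s", 50_000, 58_000, "+")
    extract_with_flanks(loc, genome, flank_len=16_000)
    assert len(loc.flank_up) == 16_000 and len(loc.flank_down) == 16_000
    assert not loc.truncated_flank_up and not loc.truncated_flank_down
    assert genome["s"][34_000:74_000] == loc.flank_up + loc.element_seq + loc.flank_down


def test_extract_flank_truncated_at_scaffold_start(rng):
    genome = {"s": make_genome(rng, 100_000)}
    loc = ErvLocus("L0", "g", "s", 5_000, 12_000, "+")
    extract_with_flanks(loc, genome, flank_len=16_000)
    assert len(loc.flank_up) == 5_000 and loc.truncated_flank_up
    assert not loc.truncated_flank_down


def test_extract_rejects_locus_outside_scaffold(rng):
    genome = {"s": make_genome(rng, 1_000)}
    with pytest.raises(ValueError):
        extract_with_flanks(ErvLocus("L0", "g", "s", 500, 2_000, "+"), genome)


def test_minus_strand_locus_oriented_element(ref, rng):
    bg = make_genome(rng)
    ele = revcomp(ref.seq)
    genome = {"s": bg[:60_000] + ele + bg[60_000:]}
    loci = mine_genome(genome, ref.query_set(), "g", MiningParams(flank_len=2000))
    assert len(loci) == 1
    assert loci[0].strand == "-"
    assert loci[0].element_seq == ref.seq
    up, down = loci[0].oriented_flanks()
    assert up == revcomp(genome["s"][60_000 + len(ele): 60_000 + len(ele) + 2000])
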