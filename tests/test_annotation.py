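"""LTR detection, signatures, gene/peptide annotation, ORF scan, classes."""

import numpy as np
import pytest

from ervkit.annotation import (AnnotationConfig, GeneAnnotation, annotate_genes,
                               classify, extract_signature, find_ltrs, pair_ltrs,
                               scan_orfs)
from ervkit.kimura import evolve_codes
from ervkit.simulate import TruthRecord, apply_structural_events
from ervkit.util import decode, encode, substream

CFG = AnnotationConfig()


def element_with_events(ref, events, distance=0.0, seed=0):
    rng = substream(seed, "annot-fixture")
    codes = evolve_codes(encode(ref.seq), distance, 2.0, rng)
    t = TruthRecord("c", 0, 0, 0.0, "ACGT", "x", events=list(events),
                    carriers=["i"])
    return decode(apply_structural_events(codes, t, ref))


# -- LTR detection ----------------------------------------------------------

def test_find_ltrs_full_provirus(ref):
    ivs = find_ltrs(ref.seq, ref.ltr_seq)
    assert ivs == [(0, 500), (7000, 7500)]


def test_find_ltrs_solo(ref):
    assert find_ltrs(ref.ltr_seq, ref.ltr_seq) == [(0, 500)]


def test_find_ltrs_atypical_internal_ltr(ref):
    ele = element_with_events(ref, [{"type": "internal_duplication"}])
    ivs = find_ltrs(ele, ref.ltr_seq)
    assert len(ivs) == 3


def test_pair_ltrs_cases(ref):
    assert pair_ltrs([(0, 500)], 7500) is None
    pair = pair_ltrs([(0, 500), (7000, 7500)], 7500)
    assert pair is not None and pair[0] == ((0, 500), (7000, 7500))
    # three intervals: outermost chosen iff the internal span stays in bounds
    got = pair_ltrs([(0, 500), (3000, 3500), (7000, 7500)], 7500)
    assert got[0] == ((0, 500), (7000, 7500)) and got[1] == [(3000, 3500)]
    # contiguous LTRs: internal span below the lower bound, no pair
    assert pair_ltrs([(0, 500), (550, 1050)], 1050) is None


# -- signatures -------------------------------------------------------------

def test_signature_matching():
    sig = extract_signature("AAAGGAG", "GGAGTTT")
    assert (sig.upstream_4mer, sig.downstream_4mer) == ("GGAG", "GGAG")
    assert sig.is_matching


def test_signature_point_mutation_not_matching():
    assert not extract_signature("AAAGGAG", "GGAATTT").is_matching


def test_signature_short_flank_padded():
    sig = extract_signature("GA", "GGAGTT")
    assert sig.upstream_4mer == "NNGA" and not sig.is_matching


# -- gene annotation --------------------------------------------------------

def test_undiverged_provirus_all_genes_annotated(ref):
    anns = annotate_genes(ref.seq, ref)
    genes = {a.name: a for a in anns if a.kind == "gene"}
    assert set(genes) == {"gag", "pol", "env"}
    for g in genes.values():
        assert g.identity > 99.0 and g.ref_fraction > 95.0
    peptides = {a.name for a in anns if a.kind == "peptide"}
    assert "reverse_transcriptase" in peptides and "SU" in peptides


def test_fully_deleted_pol_not_annotated(ref):
    pf = ref.features["pol"]
    ele = element_with_events(ref, [{"type": "deletion", "start": pf.start,
                                     "end": pf.end, "size": pf.end - pf.start}])
    genes = {a.name for a in annotate_genes(ele, ref) if a.kind == "gene"}
    assert genes == {"gag", "env"}


def test_peptide_rescue_recovers_gene(ref):
    # delete all of pol except the protease peptide: the gene fails the
    # length-fraction cutoff but the peptide passes, so pol is rescued
    pf = ref.features["pol"]
    prot = ref.features["protease"]
    ele = element_with_events(ref, [{"type": "deletion", "start": prot.end,
                                     "end": pf.end, "size": pf.end - prot.end}])
    anns = annotate_genes(ele, ref)
    pol = [a for a in anns if a.kind == "gene" and a.name == "pol"]
    assert pol and pol[0].rescued
    assert not [a for a in anns if a.kind == "gene" and a.name == "pol"
                and not a.rescued]


def test_rescue_can_be_disabled(ref):
    pf = ref.features["pol"]
    prot = ref.features["protease"]
    ele = element_with_events(ref, [{"type": "deletion", "start": prot.end,
                                     "end": pf.end, "size": pf.end - prot.end}])
    anns = annotate_genes(ele, ref, peptide_rescue=False)
    assert not [a for a in anns if a.kind == "gene" and a.name == "pol"]


def test_missing_feature_table_is_an_error(ref):
    from ervkit.reference import ProvirusReference
    bare = ProvirusReference(seq=ref.seq, features={})
    with pytest.raises(ValueError):
        annotate_genes(bare.seq, bare)


# -- ORF scanning -----------------------------------------------------------

def test_age_zero_provirus_fully_open(ref):
    anns = annotate_genes(ref.seq, ref)
    assert scan_orfs(ref.seq, anns) is True


def test_single_nonsense_substitution_interrupts_env(ref):
    env = ref.features["env"]
    seq = list(ref.seq)
    # force a TAA at an env codon boundary
    pos = env.start + 300
    seq[pos:pos + 3] = "TAA"
    seq = "".join(seq)
    anns = annotate_genes(seq, ref)
    fully_open = scan_orfs(seq, anns)
    env_ann = [a for a in anns if a.kind == "gene" and a.name == "env"][0]
    assert env_ann.intact_orf is False and fully_open is False


def test_in_frame_large_deletion_keeps_orf_open(ref):
    pol = ref.features["pol"]
    start = pol.start + 99
    ele = element_with_events(ref, [{"type": "deletion", "start": start,
                                     "end": start + 1200, "size": 1200}])
    anns = annotate_genes(ele, ref)
    pol_ann = [a for a in anns if a.kind == "gene" and a.name == "pol"][0]
    fully_open = scan_orfs(ele, anns)
    assert pol_ann.intact_orf is True
    assert pol_ann.largest_deletion == pytest.approx(1200, abs=5)
    assert fully_open is True


def test_orf_flag_is_monotone_under_added_stops(ref):
    """Introducing a stop codon can only turn fully_open_orf true -> false."""
    anns = annotate_genes(ref.seq, ref)
    assert scan_orfs(ref.seq, anns)
    for gene in ("gag", "pol", "env"):
        f = ref.features[gene]
        seq = ref.seq[:f.start + 30] + "TGA" + ref.seq[f.start + 33:]
        anns2 = annotate_genes(seq, ref)
        assert scan_orfs(seq, anns2) is False


# -- classification ---------------------------------------------------------

def make_gene(name, start, end):
    return GeneAnnotation(name, "gene", None, start, end, 99.0, 99.0)


def test_classify_decision_order(ref):
    genes = [make_gene("gag", 800, 2300), make_gene("pol", 2300, 4900),
             make_gene("env", 4900, 6800)]
    two_ltrs = [(0, 500), (7000, 7500)]
    assert classify(two_ltrs, genes, 7500, clipped=True) == "incomplete_segment"
    assert classify([(0, 500)], [], 500, clipped=False) == "solo_ltr"
    assert classify([(0, 500), (550, 1050)], [], 1050, False) == "paired_solo_ltr"
    assert classify(two_ltrs, genes, 7500, False) == "typical"
    # deletion of a whole gene still typical
    assert classify(two_ltrs, genes[:2], 7500, False) == "typical"
    # duplicated gene -> atypical
    dup = genes + [make_gene("gag", 5000, 5500)]
    assert classify(two_ltrs, dup, 7500, False) == "atypical"
    # internal LTR-like segment -> atypical
    assert classify([(0, 500), (3000, 3500), (7000, 7500)], genes, 7500,
                    False) == "atypical"
    # one LTR with genes: disordered architecture
    assert classify([(0, 500)], genes, 7000, False) == "atypical"
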