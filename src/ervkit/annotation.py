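"""Structural annotation of mined ERV loci and the five-class copy taxonomy.

Given an element in forward (element) orientation and a reference provirus
with a feature table, this module locates LTR copies, pairs the outermost
two, reads the 4-nt target-site signature from the flanks, annotates genes
and peptides by alignment (with an automated "peptide rescue" for genes whose
overall identity falls below the cutoff while an individual peptide still
passes), scans reading frames for interrupting stop codons, and assigns each
copy to one of five structural classes:

    typical            LTR pair with internal genes in reference order
                       (deletions allowed)
    solo_ltr           a single LTR, no other viral gene region
    paired_solo_ltr    two contiguous LTRs (< 200 bp apart) with no viral
                       gene region between them
    incomplete_segment element clipped at a scaffold end
    atypical           everything else (duplicated genes, internal LTR-like
                       segments, disordered architecture)

Annotation identity is nucleotide identity: `identity` is matching columns /
aligned columns of the (end-trimmed) local alignment, and `ref_fraction` (the
emission criterion, default 25%) is matching columns / reference feature
length. Local alignment performs the high-identity trimming deterministically
(terminal columns with negative score contribution are excluded), and a gene
split by an internal deletion is re-assembled by chaining collinear hits, so
deletion sizes are read off the chain junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .mining import ErvLocus
from .reference import GENES, ProvirusReference
from .util import alignment_counts

__all__ = ["AnnotationConfig", "LtrPair", "TsdSignature", "GeneAnnotation",
           "CopyRecord", "find_ltrs", "pair_ltrs", "extract_signature",
           "annotate_genes", "scan_orfs", "classify", "annotate_copy"]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class AnnotationConfig:
    ltr_min_identity: float = 0.70
    ltr_min_span: float = 0.50        # fraction of reference LTR length
    internal_length_bounds: tuple[int, int] = (2000, 12_000)
    paired_solo_gap: int = 200
    gene_cutoff: float = 0.25         # matches / reference feature length
    min_hit_identity: float = 0.80    # identity floor per local hit
    min_hit_matches: int = 35         # matches floor per local hit
    end_proximity: int = 500          # bp from a scaffold end counting as clipped
    peptide_rescue: bool = True
    big_deletion: int = 1000


@dataclass(frozen=True)
class LtrPair:
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity5: float
    identity3: float
    pair_identity: float
    internal_length: int


@dataclass(frozen=True)
class TsdSignature:
    upstream_4mer: str
    downstream_4mer: str

    @property
    def is_matching(self) -> bool:
        return ("N" not in self.upstream_4mer and
                self.upstream_4mer == self.downstream_4mer)


@dataclass
class GeneAnnotation:
    name: str
    kind: str                 # 'gene' | 'peptide'
    parent: str | None
    start: int                # element coordinates, 0-based half-open
    end: int
    identity: float           # % over trimmed aligned columns
    ref_fraction: float       # % matching columns of reference feature length
    largest_deletion: int = 0
    intact_orf: bool | None = None
    rescued: bool = False
    ref_offset: int = 0       # feature coordinate of the first aligned column


@dataclass
class CopyRecord:
    locus: ErvLocus
    copy_class: str = ""
    ltr_intervals: list = field(default_factory=list)
    ltr_pair: LtrPair | None = None
    signature: TsdSignature | None = None
    gene_annotations: list = field(default_factory=list)
    fully_open_orf: bool = False

    @property
    def copy_id(self) -> str:
        return self.locus.locus_id

    def genes(self) -> list[GeneAnnotation]:
        return [a for a in self.gene_annotations if a.kind == "gene"]

    def peptides(self) -> list[GeneAnnotation]:
        return [a for a in self.gene_annotations if a.kind == "peptide"]


def _global_identity(a_seq: str, b_seq: str) -> float:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -2
    aln = al.align(a_seq, b_seq)[0]
    gaps, identities, mismatches = alignment_counts(aln)
    return identities / max(1, gaps + identities + mismatches)


@dataclass(frozen=True)
class _Hit:
    t0: int
    t1: int
    q0: int
    q1: int
    matches: int
    columns: int
    identity: float
    largest_deletion: int


_LOCAL = Align.PairwiseAligner()
_LOCAL.mode = "local"
_LOCAL.match_score = 1
_LOCAL.mismatch_score = -2
_LOCAL.open_gap_score = -5
_LOCAL.extend_gap_score = -2


def _best_local_hit(element: str, feature: str, offset: int = 0) -> _Hit | None:
    """Best affine-gap local alignment of the feature inside an element segment.

    Local alignment ends are trimmed by construction (terminal columns with
    negative score contribution are excluded), which implements the
    "retain only high-identity regions" trimming deterministically.
    """
    if len(element) < 15 or not feature:
        return None
    alns = _LOCAL.align(element, feature)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    gaps, identities, mismatches = alignment_counts(aln)
    columns = gaps + identities + mismatches
    if columns == 0:
        return None
    tb, qb = aln.aligned
    deletion = 0
    for i in range(1, len(tb)):
        t_gap = int(tb[i][0] - tb[i - 1][1])
        q_gap = int(qb[i][0] - qb[i - 1][1])
        if q_gap > t_gap:
            deletion = max(deletion, q_gap - t_gap)
    return _Hit(int(tb[0][0]) + offset, int(tb[-1][1]) + offset,
                int(qb[0][0]), int(qb[-1][1]), identities, columns,
                identities / columns, deletion)


def _recursive_hits(element: str, feature: str, max_hits: int,
                    min_matches: int, min_identity: float,
                    offset: int = 0, depth: int = 0) -> list[_Hit]:
    """Non-overlapping local placements of the feature, best-first greedy."""
    if depth > 4 or len(element) < 15:
        return []
    hit = _best_local_hit(element, feature, offset)
    if hit is None or hit.matches < min_matches or hit.identity < min_identity:
        return []
    out = [hit]
    if max_hits > 1:
        left = element[: hit.t0 - offset]
        right = element[hit.t1 - offset:]
        out += _recursive_hits(left, feature, max_hits - 1, min_matches,
                               min_identity, offset, depth + 1)
        out += _recursive_hits(right, feature, max_hits - 1, min_matches,
                               min_identity, hit.t1, depth + 1)
    out.sort(key=lambda h: h.t0)
    return out[:max_hits]


def _chain_hits(hits: list[_Hit], max_t_gap: int = 2000,
                overlap_tol: int = 60) -> list[list[_Hit]]:
    """Group collinear hits (advancing in both feature and element) so a gene
    split by an internal deletion yields one chained annotation, while a
    duplicated gene (feature coordinates restarting) yields separate chains."""
    chains: list[list[_Hit]] = []
    for h in sorted(hits, key=lambda h: h.t0):
        placed = False
        for ch in chains:
            prev = ch[-1]
            t_gap = h.t0 - prev.t1
            if (h.q0 >= prev.q1 - overlap_tol and -overlap_tol <= t_gap
                    <= max_t_gap):
                ch.append(h)
                placed = True
                break
        if not placed:
            chains.append([h])
    return chains


# ---------------------------------------------------------------------------
# Operations

def find_ltrs(element_seq: str, reference_ltr: str,
              min_identity: float = 0.70,
              min_span: float = 0.50) -> list[tuple[int, int]]:
    """All non-overlapping occurrences of the reference LTR in the element."""
    min_matches = int(min_span * len(reference_ltr) * min_identity)
    hits = _recursive_hits(element_seq, reference_ltr, max_hits=4,
                           min_matches=min_matches, min_identity=min_identity)
    return sorted((h.t0, h.t1) for h in hits
                  if (h.t1 - h.t0) >= min_span * len(reference_ltr))


def pair_ltrs(intervals: list[tuple[int, int]], element_len: int,
              bounds: tuple[int, int] = (2000, 12_000)) -> tuple | None:
    """Outermost compatible LTR pair, or None.

    Returns ((ltr5, ltr3), internal_intervals); internal_intervals are
    LTR-like hits lying between the chosen pair.
    """
    if len(intervals) < 2:
        return None
    ivs = sorted(intervals)
    first, last = ivs[0], ivs[-1]
    internal = last[0] - first[1]
    if not (bounds[0] <= internal <= bounds[1]):
        return None
    return (first, last), ivs[1:-1]


def extract_signature(flank_up: str, flank_down: str) -> TsdSignature:
    """4-nt genomic signature adjacent to the outermost LTR boundaries."""
    up = flank_up[-4:].rjust(4, "N") if flank_up else "NNNN"
    down = flank_down[:4].ljust(4, "N") if flank_down else "NNNN"
    return TsdSignature(upstream_4mer=up, downstream_4mer=down)


def annotate_genes(element_seq: str, provirus_ref: ProvirusReference,
                   gene_cutoff: float = 0.25, peptide_rescue: bool = True,
                   config: AnnotationConfig | None = None) -> list[GeneAnnotation]:
    """Annotate genes and peptides by alignment against the reference features.

    A feature is emitted when its trimmed alignment keeps >= 50% identity and
    its matching columns cover >= `gene_cutoff` of the reference feature
    length; a gene failing the cutoff is rescued (flagged) when any of its
    peptides passes.
    """
    if config is None:
        config = AnnotationConfig(gene_cutoff=gene_cutoff,
                                  peptide_rescue=peptide_rescue)
    if not provirus_ref.features:
        raise ValueError("reference has no feature table")
    out: list[GeneAnnotation] = []
    for gene in GENES:
        if gene not in provirus_ref.features:
            continue
        gene_anns = _annotate_feature(element_seq, provirus_ref, gene, "gene",
                                      None, config, max_hits=3)
        # peptides are searched inside the annotated gene spans; only when the
        # whole gene failed do they scan the full element (rescue evidence)
        if gene_anns:
            windows = [(max(0, a.start - 200), min(len(element_seq), a.end + 200))
                       for a in gene_anns]
        else:
            windows = [(0, len(element_seq))]
        pep_anns: list[GeneAnnotation] = []
        for pf in provirus_ref.peptide_features(gene):
            best: list[GeneAnnotation] = []
            for w0, w1 in windows:
                found = _annotate_feature(element_seq[w0:w1], provirus_ref,
                                          pf.name, "peptide", gene, config,
                                          max_hits=1, offset=w0)
                if found and (not best or found[0].ref_fraction >
                              best[0].ref_fraction):
                    best = found[:1]
            pep_anns.extend(best)
        if not gene_anns and pep_anns and config.peptide_rescue:
            out.append(GeneAnnotation(
                name=gene, kind="gene", parent=None,
                start=min(p.start for p in pep_anns),
                end=max(p.end for p in pep_anns),
                identity=max(p.identity for p in pep_anns),
                ref_fraction=sum(p.ref_fraction for p in pep_anns) / len(pep_anns),
                rescued=True,
                ref_offset=min(p.ref_offset for p in pep_anns)))
        out.extend(gene_anns)
        out.extend(pep_anns)
    out.sort(key=lambda a: (a.start, a.kind))
    return out


def _annotate_feature(element: str, ref: ProvirusReference, name: str, kind: str,
                      parent: str | None, config: AnnotationConfig,
                      max_hits: int, offset: int = 0) -> list[GeneAnnotation]:
    feature = ref.feature_seq(name)
    flen = len(feature)
    hits = _recursive_hits(element, feature, max_hits,
                           min_matches=config.min_hit_matches,
                           min_identity=config.min_hit_identity, offset=offset)
    anns = []
    for chain in _chain_hits(hits)[:max_hits]:
        matches = sum(h.matches for h in chain)
        columns = sum(h.columns for h in chain)
        deletion = max(h.largest_deletion for h in chain)
        for prev, nxt in zip(chain, chain[1:]):
            q_gap = nxt.q0 - prev.q1
            t_gap = max(0, nxt.t0 - prev.t1)
            if q_gap > t_gap:
                deletion = max(deletion, q_gap - t_gap)
        if matches / flen < config.gene_cutoff:
            continue
        anns.append(GeneAnnotation(
            name=name, kind=kind, parent=parent if kind == "peptide" else None,
            start=chain[0].t0, end=chain[-1].t1,
            identity=100.0 * matches / columns,
            ref_fraction=100.0 * matches / flen,
            largest_deletion=deletion,
            ref_offset=chain[0].q0))
    anns.sort(key=lambda a: a.start)
    return anns


def scan_orfs(element_seq: str, annotations: list[GeneAnnotation],
              big_deletion: int = 1000) -> bool:
    """Mark intact ORFs; returns the copy-level fully-open-ORF flag.

    A gene is intact when no in-frame stop codon occurs within its annotated
    interval; the frame is inferred from the reference alignment offset.
    Deletions larger than `big_deletion` nt remain visible on the annotation
    even when the residual ORF stays open.
    """
    genes = [a for a in annotations if a.kind == "gene"]
    for ann in genes:
        phase = ann.ref_offset % 3
        start = ann.start + ((3 - phase) % 3)
        seg = element_seq[start: ann.end]
        stops = any(seg[i:i + 3] in STOP_CODONS
                    for i in range(0, len(seg) - 2, 3))
        ann.intact_orf = not stops
    return bool(genes) and all(a.intact_orf for a in genes)


def classify(ltr_intervals: list[tuple[int, int]],
             gene_annotations: list[GeneAnnotation],
             element_len: int, clipped: bool,
             config: AnnotationConfig = AnnotationConfig()) -> str:
    """Assign one of the five structural classes (total decision order)."""
    genes = [a for a in gene_annotations if a.kind == "gene"]
    if clipped:
        return "incomplete_segment"
    if len(ltr_intervals) == 1 and not genes:
        return "solo_ltr"
    if len(ltr_intervals) >= 2 and not genes:
        ivs = sorted(ltr_intervals)
        gaps = [ivs[i + 1][0] - ivs[i][1] for i in range(len(ivs) - 1)]
        if min(gaps) < config.paired_solo_gap:
            return "paired_solo_ltr"
    pair = pair_ltrs(ltr_intervals, element_len, config.internal_length_bounds)
    if pair is not None and genes:
        (ltr5, ltr3), internal_ltrs = pair
        names = [g.name for g in sorted(genes, key=lambda g: g.start)]
        ordered = (names == [g for g in GENES if g in names])
        inside = all(ltr5[1] <= g.start and g.end <= ltr3[0] + 50 for g in genes)
        if ordered and inside and len(names) == len(set(names)) and not internal_ltrs:
            return "typical"
    return "atypical"


def annotate_copy(locus: ErvLocus, provirus_ref: ProvirusReference,
                  config: AnnotationConfig = AnnotationConfig()) -> CopyRecord:
    """Full structural annotation of one mined locus."""
    element = locus.element_seq
    ltrs = find_ltrs(element, provirus_ref.ltr_seq,
                     config.ltr_min_identity, config.ltr_min_span)
    anns = annotate_genes(element, provirus_ref, config=config)
    fully_open = scan_orfs(element, anns, config.big_deletion)
    flank_up, flank_down = locus.oriented_flanks()
    sig = extract_signature(flank_up, flank_down)
    scaf_len = locus.scaffold_length
    clipped = (locus.start <= config.end_proximity
               or (scaf_len > 0 and scaf_len - locus.end <= config.end_proximity))
    cls = classify(ltrs, anns, len(element), clipped, config)
    if cls in ("solo_ltr", "paired_solo_ltr"):
        anns = []  # no viral gene regions by definition
        fully_open = False
    pair = pair_ltrs(ltrs, len(element), config.internal_length_bounds)
    ltr_pair = None
    if pair is not None:
        (l5, l3), _ = pair
        ref_ltr = provirus_ref.ltr_seq
        ltr_pair = LtrPair(
            ltr5=l5, ltr3=l3,
            identity5=_global_identity(element[l5[0]:l5[1]], ref_ltr),
            identity3=_global_identity(element[l3[0]:l3[1]], ref_ltr),
            pair_identity=_global_identity(element[l5[0]:l5[1]],
                                           element[l3[0]:l3[1]]),
            internal_length=l3[0] - l5[1])
    return CopyRecord(locus=locus, copy_class=cls, ltr_intervals=ltrs,
                      ltr_pair=ltr_pair, signature=sig, gene_annotations=anns,
                      fully_open_orf=fully_open)
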