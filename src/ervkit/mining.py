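"""Seed-and-extend homology search for ERV loci in host genomes.

The scanning strategy mirrors a multi-query nucleotide BLAST workflow without
calling an external binary: every query (LTR, gag, pol, env, and the whole
provirus) is searched on both strands via exact k-mer seeding, seeds are
clustered by diagonal, and each candidate window is resolved with a gapped
semi-global alignment (edlib) whose ends are trimmed back to anchored match
runs, giving local-alignment-like HSP boundaries. Hits are filtered either on
percent
identity (host-range screening, default cutoff 50%) or on query coverage
(locus mining, default cutoff 50%), then merged into non-overlapping loci and
extracted with flanking sequence for downstream annotation.

Coordinates are 0-based half-open on the forward strand of the subject
scaffold throughout; reverse-strand loci are reported in forward coordinates
with strand '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._edalign import infix_align
from .util import encode, revcomp

__all__ = ["MiningParams", "Hsp", "ErvLocus", "KmerIndex", "search", "filter_hits",
           "merge_to_loci", "extract_with_flanks", "mine_genome", "hits_table"]


@dataclass(frozen=True)
class MiningParams:
    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    diag_band: int = 100          # diagonal tolerance when clustering seeds
    max_seed_gap: int = 1000      # subject-gap splitting clusters
    min_seeds: int = 4            # seeds required to trigger an extension
    window_pad: int = 100
    identity_cutoff: float = 50.0   # host_range mode
    coverage_cutoff: float = 50.0   # locus_mining mode
    max_gap: int = 2000           # locus merging distance
    flank_len: int = 16_000

    def __post_init__(self):
        if self.k < 8:
            raise ValueError("k must be >= 8")


@dataclass(frozen=True)
class Hsp:
    query_id: str
    subject_scaffold: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: float
    identity: float        # matching columns / alignment columns, percent
    query_coverage: float  # aligned query positions / query length, percent

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValueError("bad query interval")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError("bad subject interval")


@dataclass
class ErvLocus:
    locus_id: str
    genome_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    supporting_hsps: list[Hsp] = field(default_factory=list)
    flank_up: str = ""
    flank_down: str = ""
    truncated_flank_up: bool = False
    truncated_flank_down: bool = False
    scaffold_length: int = 0
    element_seq: str = ""    # element orientation (reverse-complemented if '-')

    @property
    def queries(self) -> list[str]:
        return sorted({h.query_id for h in self.supporting_hsps})

    def oriented_flanks(self) -> tuple[str, str]:
        """(upstream, downstream) flanks in element orientation."""
        if self.strand == "-":
            return revcomp(self.flank_down), revcomp(self.flank_up)
        return self.flank_up, self.flank_down


# ---------------------------------------------------------------------------
# k-mer index

def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, kmer codes) of all N-free k-mers on the forward strand."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    m = n - k + 1
    km = np.zeros(m, dtype=np.int64)
    for j in range(k):
        km = km * 4 + np.where(c[j: j + m] < 4, c[j: j + m], 0)
    bad = np.concatenate([[0], np.cumsum(c >= 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return pos, km[pos]


class KmerIndex:
    """Exact-match positions of every N-free k-mer, per scaffold, forward strand."""

    def __init__(self, genome: dict[str, str], k: int = 11):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.k = k
        self.scaffolds = {name: seq.upper() for name, seq in genome.items()}
        self.lengths = {name: len(seq) for name, seq in genome.items()}
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.n_positions = 0
        for name, seq in self.scaffolds.items():
            pos, km = _kmer_codes(encode(seq), k)
            order = np.argsort(km, kind="stable")
            self._index[name] = (km[order], pos[order])
            self.n_positions += pos.size

    def lookup(self, query_kmers: np.ndarray, query_positions: np.ndarray,
               scaffold: str) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, subject_pos) exact k-mer matches on one scaffold."""
        codes, positions = self._index[scaffold]
        left = np.searchsorted(codes, query_kmers, "left")
        right = np.searchsorted(codes, query_kmers, "right")
        counts = right - left
        hit = np.nonzero(counts)[0]
        if hit.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qp = np.repeat(query_positions[hit], counts[hit])
        sp = np.concatenate([positions[left[i]: right[i]] for i in hit])
        return qp, sp


def _clusters(qpos: np.ndarray, spos: np.ndarray, params: MiningParams):
    """Split seed matches into diagonal clusters (sorted by diagonal, then pos)."""
    diag = spos - qpos
    order = np.lexsort((spos, diag))
    d, s, q = diag[order], spos[order], qpos[order]
    breaks = np.nonzero((np.diff(d) > params.diag_band)
                        | (np.abs(np.diff(s)) > params.max_seed_gap))[0] + 1
    for chunk in np.split(np.arange(d.size), breaks):
        if chunk.size >= params.min_seeds:
            yield q[chunk], s[chunk]


def search(query_id: str, query: str, index: KmerIndex,
           params: MiningParams = MiningParams()) -> list[Hsp]:
    """Find HSPs of the query on both strands of every indexed scaffold."""
    if len(query) < index.k:
        raise ValueError("query shorter than k")
    qlen = len(query)
    hsps: list[Hsp] = []
    for strand in "+-":
        qs = query if strand == "+" else revcomp(query)
        qpos_all, qk = _kmer_codes(encode(qs), index.k)
        for scaffold, seq in index.scaffolds.items():
            qp, sp = index.lookup(qk, qpos_all, scaffold)
            if qp.size == 0:
                continue
            windows = []
            for cq, cs in _clusters(qp, sp, params):
                lo = int(cs.min() - cq.min() - params.window_pad)
                hi = int(cs.max() + index.k + (qlen - int(cq.max()) - index.k)
                         + params.window_pad)
                windows.append((max(0, lo), min(len(seq), hi)))
            for lo, hi in sorted(set(windows)):
                aln = infix_align(qs, seq[lo:hi])
                if aln is None:
                    continue
                # trim to the max-scoring segment: the gapped extension is
                # semi-global, so ends must be cut back to local-hit behavior
                c0, c1 = aln.best_local_segment(params.match, params.mismatch,
                                                params.gap_open, params.gap_extend)
                if c1 <= c0:
                    continue
                n_match, n_mismatch, n_qgap, n_tgap = aln.counts(c0, c1)
                columns = n_match + n_mismatch + n_qgap + n_tgap
                s0, s1 = aln.t_range(c0, c1)
                q0, q1 = aln.q_range(c0, c1)
                if strand == "-":
                    q0, q1 = qlen - q1, qlen - q0
                hsps.append(Hsp(
                    query_id=query_id, subject_scaffold=scaffold,
                    q_start=q0, q_end=q1, s_start=s0 + lo, s_end=s1 + lo,
                    strand=strand,
                    score=aln.score(c0, c1, params.match, params.mismatch,
                                    params.gap_open, params.gap_extend),
                    identity=100.0 * n_match / columns,
                    query_coverage=100.0 * (n_match + n_mismatch) / qlen,
                ))
    return _dedup(hsps)


def _dedup(hsps: list[Hsp]) -> list[Hsp]:
    """Drop HSPs mostly contained in a better-scoring HSP of the same query/strand."""
    kept: list[Hsp] = []
    for h in sorted(hsps, key=lambda h: -h.score):
        redundant = False
        for g in kept:
            if (g.subject_scaffold == h.subject_scaffold and g.strand == h.strand
                    and g.query_id == h.query_id):
                ov = min(g.s_end, h.s_end) - max(g.s_start, h.s_start)
                if ov > 0.5 * (h.s_end - h.s_start):
                    redundant = True
                    break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.subject_scaffold, h.s_start, h.s_end))
    return kept


def filter_hits(hsps: list[Hsp], mode: str,
                params: MiningParams = MiningParams()) -> list[Hsp]:
    """Retain hits by identity (host_range) or query coverage (locus_mining)."""
    if mode == "host_range":
        return [h for h in hsps if h.identity >= params.identity_cutoff]
    if mode == "locus_mining":
        return [h for h in hsps if h.query_coverage >= params.coverage_cutoff]
    raise ValueError(f"unknown filter mode {mode!r}")


def merge_to_loci(hsps: list[Hsp], genome_id: str,
                  params: MiningParams = MiningParams()) -> list[ErvLocus]:
    """Merge HSPs (from all queries) within max_gap on a scaffold into loci."""
    loci: list[ErvLocus] = []
    by_scaf: dict[str, list[Hsp]] = {}
    for h in hsps:
        by_scaf.setdefault(h.subject_scaffold, []).append(h)
    for scaffold in sorted(by_scaf):
        group: list[Hsp] = []
        for h in sorted(by_scaf[scaffold], key=lambda h: (h.s_start, h.s_end)):
            if group and h.s_start > max(g.s_end for g in group) + params.max_gap:
                loci.append(_make_locus(group, genome_id, scaffold))
                group = []
            group.append(h)
        if group:
            loci.append(_make_locus(group, genome_id, scaffold))
    for i, loc in enumerate(loci):
        loc.locus_id = f"{genome_id}_L{i:03d}"
    return loci


def _make_locus(group: list[Hsp], genome_id: str, scaffold: str) -> ErvLocus:
    start = min(h.s_start for h in group)
    end = max(h.s_end for h in group)
    plus = sum(h.score for h in group if h.strand == "+")
    minus = sum(h.score for h in group if h.strand == "-")
    return ErvLocus(locus_id="", genome_id=genome_id, scaffold=scaffold,
                    start=start, end=end, strand="+" if plus >= minus else "-",
                    supporting_hsps=list(group))


def extract_with_flanks(locus: ErvLocus, genome: dict[str, str],
                        flank_len: int = 16_000) -> ErvLocus:
    """Fill in element sequence and up/downstream flanks, clipped at scaffold ends."""
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    seq = genome[locus.scaffold]
    if not (0 <= locus.start < locus.end <= len(seq)):
        raise ValueError("locus outside scaffold")
    up0 = max(0, locus.start - flank_len)
    down1 = min(len(seq), locus.end + flank_len)
    locus.flank_up = seq[up0: locus.start]
    locus.flank_down = seq[locus.end: down1]
    locus.truncated_flank_up = len(locus.flank_up) < flank_len
    locus.truncated_flank_down = len(locus.flank_down) < flank_len
    locus.scaffold_length = len(seq)
    element = seq[locus.start: locus.end]
    locus.element_seq = revcomp(element) if locus.strand == "-" else element
    return locus


def mine_genome(genome: dict[str, str], queries: dict[str, str], genome_id: str,
                params: MiningParams = MiningParams()) -> list[ErvLocus]:
    """Index, search all queries, filter on coverage, merge, and extract flanks."""
    index = KmerIndex(genome, params.k)
    all_hits: list[Hsp] = []
    for qid, qseq in queries.items():
        all_hits.extend(search(qid, qseq, index, params))
    kept = filter_hits(all_hits, "locus_mining", params)
    loci = merge_to_loci(kept, genome_id, params)
    for loc in loci:
        extract_with_flanks(loc, genome, params.flank_len)
    return loci


def hits_table(hsps: list[Hsp]) -> pd.DataFrame:
    """Tabular hit report (BLAST outfmt-6-like, plus query coverage)."""
    return pd.DataFrame(
        [{"query_id": h.query_id, "subject": h.subject_scaffold,
          "identity": round(h.identity, 3), "q_start": h.q_start, "q_end": h.q_end,
          "s_start": h.s_start, "s_end": h.s_end, "strand": h.strand,
          "score": h.score, "query_coverage": round(h.query_coverage, 3)}
         for h in hsps])
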