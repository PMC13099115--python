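"""Cross-genome comparison: orthologous loci, count tables, exact tests.

Insertion loci are matched across genomes by their flanking sequence (the
element itself excised): pairs whose upstream and downstream flanks both
align at >= 90% identity over at least 500 bp per side are joined by single
linkage into `flank_match` ortholog groups. Copies that merely share the same
4-nt target-site signature at different loci are reported as `signature_only`
coincidences and never merged — convergent integration-site preference is not
orthology.

Count tables (classes x genomes, gene and peptide presence over
nonrecombinant typical copies, per-scaffold placements) feed two-sided
Fisher's exact tests with Bonferroni correction within each comparison
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .annotation import CopyRecord
from .util import alignment_counts
from .reference import GENES, PEPTIDES

__all__ = ["OrthologGroup", "FisherResult", "match_orthologous_loci",
           "build_count_tables", "fisher_exact", "bonferroni",
           "run_count_comparisons"]


@dataclass
class OrthologGroup:
    group_id: str
    members: list[tuple[str, str]]          # (genome_id, copy_id)
    evidence: str                           # 'flank_match' | 'signature_only'
    shared_signature: str | None = None


@dataclass(frozen=True)
class FisherResult:
    label: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    p_bonferroni: float
    family_size: int


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p (probability-mass criterion, fixed margins)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValueError("table entries must be nonnegative integers")
        arr = arr.astype(np.int64)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def bonferroni(p_values, family_size: int) -> list[float]:
    """Multiply by the family size, capped at 1."""
    ps = list(p_values)
    if family_size < len(ps):
        raise ValueError("family_size must be >= number of tests")
    return [min(1.0, p * family_size) for p in ps]


# ---------------------------------------------------------------------------
# Orthologous loci

def _flank_identity(a: str, b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    gaps, identities, mismatches = alignment_counts(aln)
    return identities / max(1, gaps + identities + mismatches)


def match_orthologous_loci(copies: dict[str, list[CopyRecord]],
                           flank_len: int = 1000,
                           min_flank_identity: float = 0.90,
                           min_flank_len: int = 500) -> list[OrthologGroup]:
    """Group copies across genomes occupying the same (orthologous) locus.

    `copies` maps genome_id -> annotated copy records carrying extracted
    flanks. Pairs are only compared across genomes; linkage is transitive.
    """
    items = []  # (genome, copy_id, up, down, signature)
    for genome, recs in sorted(copies.items()):
        for rec in recs:
            up, down = rec.locus.oriented_flanks()
            if len(up) < min_flank_len or len(down) < min_flank_len:
                continue  # excluded: flanks too short to establish orthology
            sig = rec.signature.upstream_4mer if rec.signature else None
            items.append((genome, rec.copy_id, up[-flank_len:], down[:flank_len], sig))

    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if items[i][0] == items[j][0]:
                continue  # same genome: never orthologous here
            if find(i) == find(j):
                continue
            if (_flank_identity(items[i][2], items[j][2]) >= min_flank_identity and
                    _flank_identity(items[i][3], items[j][3]) >= min_flank_identity):
                parent[find(j)] = find(i)

    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(find(i), []).append(i)
    groups: list[OrthologGroup] = []
    singles: list[int] = []
    for members in clusters.values():
        if len(members) > 1:
            groups.append(OrthologGroup(
                group_id="", members=[(items[i][0], items[i][1]) for i in members],
                evidence="flank_match",
                shared_signature=_common_signature([items[i][4] for i in members])))
        else:
            singles.append(members[0])
    # singletons sharing only a 4-mer signature: reported, never merged
    sig_count: dict[str, int] = {}
    for i in singles:
        if items[i][4]:
            sig_count[items[i][4]] = sig_count.get(items[i][4], 0) + 1
    for i in singles:
        sig = items[i][4]
        convergent = sig is not None and sig_count.get(sig, 0) > 1
        groups.append(OrthologGroup(
            group_id="", members=[(items[i][0], items[i][1])],
            evidence="signature_only" if convergent else "flank_match",
            shared_signature=sig if convergent else None))
    groups.sort(key=lambda g: g.members[0])
    for n, g in enumerate(groups):
        g.group_id = f"OG{n:03d}"
    return groups


def _common_signature(sigs: list[str | None]) -> str | None:
    vals = {s for s in sigs if s}
    return vals.pop() if len(vals) == 1 else None


# ---------------------------------------------------------------------------
# Count tables

CLASSES = ("solo_ltr", "typical", "atypical", "paired_solo_ltr", "incomplete_segment")


def build_count_tables(copies: dict[str, list[CopyRecord]],
                       removed_ids: set[str] = frozenset()) -> dict[str, pd.DataFrame]:
    """Class, gene, peptide and placement count tables.

    Gene/peptide tables count presence over nonrecombinant typical copies
    (copies in `removed_ids` — the recombination screen's removals — are
    excluded).
    """
    genomes = sorted(copies)
    class_tab = pd.DataFrame(0, index=list(CLASSES), columns=genomes)
    gene_tab = pd.DataFrame(0, index=list(GENES), columns=genomes)
    pep_names = [p for g in GENES for p, _, _ in PEPTIDES[g]]
    pep_tab = pd.DataFrame(0, index=pep_names, columns=genomes)
    placements = []
    for genome in genomes:
        for rec in copies[genome]:
            class_tab.loc[rec.copy_class, genome] += 1
            placements.append({"genome": genome, "scaffold": rec.locus.scaffold,
                               "start": rec.locus.start, "end": rec.locus.end,
                               "class": rec.copy_class,
                               "signature": rec.signature.upstream_4mer
                               if rec.signature else "NNNN"})
            if rec.copy_class != "typical" or rec.copy_id in removed_ids:
                continue
            for g in {a.name for a in rec.genes()}:
                gene_tab.loc[g, genome] += 1
            for p in {a.name for a in rec.peptides()}:
                pep_tab.loc[p, genome] += 1
    return {"classes": class_tab, "genes": gene_tab, "peptides": pep_tab,
            "placements": pd.DataFrame(placements)}


def run_count_comparisons(tables: dict[str, pd.DataFrame],
                          n_typical: int | None = None) -> list[FisherResult]:
    """Three Bonferroni-corrected families of two-sided exact tests:

    (a) per genome pair, typical vs solo-LTR counts;
    (b) per gene pair, presence/absence over nonrecombinant typical copies;
    (c) per peptide, presence vs the other peptides of the same polyprotein.
    """
    out: list[FisherResult] = []
    classes, genes, peps = tables["classes"], tables["genes"], tables["peptides"]
    genomes = list(classes.columns)

    fam = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            gi, gj = genomes[i], genomes[j]
            t = ((int(classes.loc["typical", gi]), int(classes.loc["solo_ltr", gi])),
                 (int(classes.loc["typical", gj]), int(classes.loc["solo_ltr", gj])))
            if sum(t[0]) + sum(t[1]) > 0:
                fam.append((f"load:{gi}|{gj}", t))
    out.extend(_family(fam))

    # denominator: nonrecombinant typical copies; defaults to the largest
    # per-gene total (a gene can be present at most once per copy here)
    n_typ = n_typical if n_typical is not None else (
        int(genes.sum(axis=1).max()) if not genes.empty else 0)
    fam = []
    totals = genes.sum(axis=1)
    for i in range(len(GENES)):
        for j in range(i + 1, len(GENES)):
            a, b = GENES[i], GENES[j]
            t = ((int(totals[a]), n_typ - int(totals[a])),
                 (int(totals[b]), n_typ - int(totals[b])))
            if n_typ > 0:
                fam.append((f"gene:{a}|{b}", t))
    out.extend(_family(fam))

    fam = []
    pep_totals = peps.sum(axis=1)
    for g in GENES:
        names = [p for p, _, _ in PEPTIDES[g]]
        for p in names:
            rest = [q for q in names if q != p]
            rest_pres = int(round(pep_totals[rest].mean())) if rest else 0
            t = ((int(pep_totals[p]), max(0, n_typ - int(pep_totals[p]))),
                 (rest_pres, max(0, n_typ - rest_pres)))
            if n_typ > 0:
                fam.append((f"peptide:{g}:{p}", t))
    out.extend(_family(fam))
    return out


def _family(fam: list[tuple[str, tuple]]) -> list[FisherResult]:
    m = len(fam)
    res = []
    for label, t in fam:
        p = fisher_exact(np.asarray(t, dtype=np.int64))
        res.append(FisherResult(label=label, table=t, p_two_sided=p,
                                p_bonferroni=min(1.0, p * m), family_size=m))
    return res


def fisher_results_table(results: list[FisherResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "comparison": r.label, "a": r.table[0][0], "b": r.table[0][1],
        "c": r.table[1][0], "d": r.table[1][1], "p": r.p_two_sided,
        "p_bonferroni": r.p_bonferroni, "family_size": r.family_size}
        for r in results])
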