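"""End-to-end orchestration: simulate -> mine -> annotate -> date ->
recombination-screen -> compare -> tree, with TSV/JSON artifacts and an
optional truth-based evaluation block.

All randomness flows from a single seed, fanned out into named substreams per
stage, so a rerun with the same configuration and seed reproduces every
artifact byte for byte. Stages write their tables under the output directory
as they complete; the machine-readable run report aggregates per-genome class
counts, dating summaries, recombination removals, ortholog group counts and
exact-test results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationConfig, CopyRecord, annotate_copy
from .comparative import (build_count_tables, fisher_results_table,
                          match_orthologous_loci, run_count_comparisons)
from .dating import DEFAULT_RATE, DEFAULT_RATE_INTERVAL, date_ltr_pair
from .mining import MiningParams, hits_table, mine_genome
from .phylogeny import (bootstrap_support, gene_vs_genome_table, k2p_matrix,
                        midpoint_root, neighbor_joining, reference_projected_msa)
from .recombination import consensus_calls, scan_triplets
from .reference import ProvirusReference, synthetic_reference
from .simulate import SimulationConfig, simulate
from .util import read_fasta, write_fasta, write_gff3, write_json

ALL_STAGES = ("simulate", "mine", "annotate", "date", "recomb", "compare", "phylo")


@dataclass
class PipelineConfig:
    outdir: str | Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # inputs: either simulated or loaded from FASTA paths
    simulation: SimulationConfig | None = None
    genome_fastas: dict[str, str] = field(default_factory=dict)
    reference_fasta: str | None = None
    reference_features: str | None = None
    # stage parameters
    mining: MiningParams = field(default_factory=MiningParams)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    rate: float = DEFAULT_RATE
    rate_interval: tuple[float, float] = DEFAULT_RATE_INTERVAL
    min_methods: int = 2
    recomb_alpha: float = 0.05
    max_triplets: int = 200
    # permutation resolution must beat the Bonferroni family size
    n_permutations: int = 999
    bootstrap_replicates: int = 50

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


@dataclass
class PipelineState:
    reference: ProvirusReference
    genomes: dict[str, dict[str, str]]
    truth: pd.DataFrame | None = None
    loci: dict[str, list] = field(default_factory=dict)
    copies: dict[str, list[CopyRecord]] = field(default_factory=dict)
    dating: pd.DataFrame | None = None
    removals: set[str] = field(default_factory=set)
    recomb_calls: pd.DataFrame | None = None
    ortholog_groups: list = field(default_factory=list)
    tables: dict = field(default_factory=dict)
    fisher: pd.DataFrame | None = None
    tree_newick: str | None = None
    msa: object = None


def _load_reference(config: PipelineConfig) -> ProvirusReference:
    if config.reference_fasta:
        if not config.reference_features:
            raise ValueError("reference feature table required with reference FASTA")
        return ProvirusReference.load(config.reference_fasta, config.reference_features)
    return synthetic_reference()


def run_pipeline(config: PipelineConfig,
                 genomes: dict[str, dict[str, str]] | None = None,
                 truth: pd.DataFrame | None = None) -> dict:
    """Execute the configured stages in order; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = _load_reference(config)
    state = PipelineState(reference=ref, genomes=genomes or {}, truth=truth)

    if "simulate" in config.stages and config.simulation is not None:
        ds = simulate(config.simulation, reference=ref, outdir=outdir / "simulated")
        state.genomes = ds.genomes
        state.truth = ds.truth
    elif not state.genomes:
        if not config.genome_fastas:
            raise ValueError("no genomes: provide FASTAs or a simulation config")
        state.genomes = {gid: read_fasta(path)
                         for gid, path in sorted(config.genome_fastas.items())}
    if not state.genomes or all(not g for g in state.genomes.values()):
        raise ValueError("empty genome set")

    if "mine" in config.stages:
        _stage_mine(config, state, outdir)
    if "annotate" in config.stages:
        _stage_annotate(config, state, outdir)
    if "date" in config.stages:
        _stage_date(config, state, outdir)
    if "recomb" in config.stages:
        _stage_recomb(config, state, outdir)
    if "compare" in config.stages:
        _stage_compare(config, state, outdir)
    if "phylo" in config.stages:
        _stage_phylo(config, state, outdir)

    report = _build_report(config, state)
    if state.truth is not None and state.copies:
        report["evaluation"] = evaluate_against_truth(state)
    write_json(outdir / "report.json", report)
    return report


def _stage_mine(config, state, outdir):
    all_hits = []
    for gid in sorted(state.genomes):
        loci = mine_genome(state.genomes[gid], state.reference.query_set(), gid,
                           config.mining)
        state.loci[gid] = loci
        for loc in loci:
            all_hits.extend(loc.supporting_hsps)
        with open(outdir / f"{gid}.loci.bed", "w") as fh:
            for loc in loci:
                fh.write(f"{loc.scaffold}\t{loc.start}\t{loc.end}\t"
                         f"{loc.locus_id}\t0\t{loc.strand}\n")
        write_fasta(outdir / f"{gid}.loci.fasta",
                    [(loc.locus_id, loc.element_seq) for loc in loci])
    hits_table(all_hits).to_csv(outdir / "hits.tsv", sep="\t", index=False)


def _stage_annotate(config, state, outdir):
    rows, gff = [], []
    for gid in sorted(state.loci):
        recs = [annotate_copy(loc, state.reference, config.annotation)
                for loc in state.loci[gid]]
        state.copies[gid] = recs
        for rec in recs:
            sig = rec.signature
            rows.append({
                "genome": gid, "copy_id": rec.copy_id, "class": rec.copy_class,
                "scaffold": rec.locus.scaffold, "start": rec.locus.start,
                "end": rec.locus.end, "strand": rec.locus.strand,
                "signature_up": sig.upstream_4mer if sig else "NNNN",
                "signature_down": sig.downstream_4mer if sig else "NNNN",
                "signature_matching": bool(sig and sig.is_matching),
                "n_ltrs": len(rec.ltr_intervals),
                "genes": ",".join(a.name for a in rec.genes()),
                "fully_open_orf": rec.fully_open_orf,
            })
            gff.append({"seqid": f"{gid}:{rec.locus.scaffold}", "type": "ERV_copy",
                        "start": rec.locus.start, "end": rec.locus.end,
                        "strand": rec.locus.strand,
                        "attributes": {"ID": rec.copy_id, "class": rec.copy_class}})
    pd.DataFrame(rows).to_csv(outdir / "copies.tsv", sep="\t", index=False)
    write_gff3(outdir / "copies.gff3", gff)


def _copy_ltr_seqs(rec: CopyRecord) -> tuple[str, str] | None:
    if rec.ltr_pair is None:
        return None
    e = rec.locus.element_seq
    l5, l3 = rec.ltr_pair.ltr5, rec.ltr_pair.ltr3
    return e[l5[0]:l5[1]], e[l3[0]:l3[1]]


def _stage_date(config, state, outdir):
    rows = []
    for gid in sorted(state.copies):
        for rec in state.copies[gid]:
            if rec.copy_class != "typical":
                continue
            pair = _copy_ltr_seqs(rec)
            if pair is None:
                continue
            res = date_ltr_pair(*pair, copy_id=rec.copy_id, r=config.rate,
                                r_interval=config.rate_interval)
            rows.append({"genome": gid, "copy_id": res.copy_id, "K": res.K,
                         "P": res.P, "Q": res.Q, "n_sites": res.n_sites,
                         "T_years": res.T_years, "T_low": res.T_low,
                         "T_high": res.T_high,
                         "identical_ltrs": res.identical_ltrs,
                         "saturated": res.saturated})
    state.dating = pd.DataFrame(rows)
    state.dating.to_csv(outdir / "dating.tsv", sep="\t", index=False)


def _stage_recomb(config, state, outdir):
    call_rows = []
    removed: set[str] = set()
    for gid in sorted(state.copies):
        typical = [r for r in state.copies[gid] if r.copy_class == "typical"]
        if len(typical) < 3:
            continue
        msa = reference_projected_msa(
            {r.copy_id: r.locus.element_seq for r in typical}, state.reference)
        rows = msa.rows()
        calls = scan_triplets(rows, seed=config.seed,
                              max_triplets=config.max_triplets,
                              n_permutations=config.n_permutations)
        decisions = consensus_calls(calls, config.min_methods, config.recomb_alpha)
        removed |= {d.copy_id for d in decisions if d.removed}
        for c in calls:
            call_rows.append({
                "genome": gid, "candidate": c.triplet[0], "parent_a": c.triplet[1],
                "parent_b": c.triplet[2], "method": c.method,
                "statistic": c.statistic, "breakpoint": c.breakpoint,
                "p_value": c.p_value, "no_call": c.no_call})
    state.removals = removed
    state.recomb_calls = pd.DataFrame(call_rows)
    state.recomb_calls.to_csv(outdir / "recombination_calls.tsv", sep="\t",
                              index=False)
    (outdir / "removed_copies.txt").write_text("\n".join(sorted(removed)) + "\n")


def _stage_compare(config, state, outdir):
    state.ortholog_groups = match_orthologous_loci(state.copies)
    og_rows = [{"group_id": g.group_id, "evidence": g.evidence,
                "shared_signature": g.shared_signature or ".",
                "members": ";".join(f"{a}:{b}" for a, b in g.members)}
               for g in state.ortholog_groups]
    pd.DataFrame(og_rows).to_csv(outdir / "ortholog_groups.tsv", sep="\t",
                                 index=False)
    state.tables = build_count_tables(state.copies, state.removals)
    for name, tab in state.tables.items():
        tab.to_csv(outdir / f"counts_{name}.tsv", sep="\t")
    results = run_count_comparisons(state.tables)
    state.fisher = fisher_results_table(results)
    state.fisher.to_csv(outdir / "fisher_results.tsv", sep="\t", index=False)


def _stage_phylo(config, state, outdir):
    elements = {}
    for gid in sorted(state.copies):
        for rec in state.copies[gid]:
            if rec.copy_class == "typical" and rec.copy_id not in state.removals:
                elements[rec.copy_id] = rec.locus.element_seq
    if len(elements) < 3:
        return
    elements["reference_provirus"] = state.reference.seq
    msa = reference_projected_msa(elements, state.reference)
    state.msa = msa
    tree, _ = bootstrap_support(msa, B=config.bootstrap_replicates,
                                seed=config.seed)
    rooted = midpoint_root(tree)
    state.tree_newick = rooted.as_string(schema="newick")
    (outdir / "copies.nwk").write_text(state.tree_newick)
    gene_vs_genome_table(msa, state.reference).to_csv(
        outdir / "gene_vs_genome_topologies.tsv", sep="\t", index=False)


def _build_report(config, state) -> dict:
    report: dict = {"seed": config.seed, "stages": list(config.stages),
                    "genomes": sorted(state.genomes)}
    if state.copies:
        report["class_counts"] = {
            gid: dict(pd.Series([r.copy_class for r in recs]).value_counts())
            for gid, recs in state.copies.items()}
    if state.dating is not None and len(state.dating):
        d = state.dating
        report["dating"] = {
            "n_dated": int(len(d)),
            "median_T_years": float(d.T_years.median()),
            "identical_ltr_fraction": float(d.identical_ltrs.mean())}
    report["recombination_removed"] = sorted(state.removals)
    if state.ortholog_groups:
        report["ortholog_groups"] = {
            "n_groups": len(state.ortholog_groups),
            "n_shared": sum(1 for g in state.ortholog_groups
                            if len(g.members) > 1),
            "n_signature_only": sum(1 for g in state.ortholog_groups
                                    if g.evidence == "signature_only")}
    if state.fisher is not None and len(state.fisher):
        report["fisher"] = state.fisher.to_dict("records")
    if state.tree_newick:
        report["tree"] = "copies.nwk"
    return report


def evaluate_against_truth(state: PipelineState) -> dict:
    """Locus sensitivity/precision, class confusion, signature accuracy,
    dating bias/RMSE by age, recombination flags vs truth events."""
    truth = state.truth
    matched, confusion = [], {}
    n_truth = n_found = 0
    matched_ids = set()
    for gid, recs in state.copies.items():
        sub = truth[truth.carrier == gid] if "carrier" in truth else \
            truth[truth.genome == gid]
        for _, t in sub.iterrows():
            n_truth += 1
            hits = [r for r in recs if r.locus.scaffold == t.scaffold
                    and r.locus.start < t.end and r.locus.end > t.start]
            if len(hits) == 1:
                n_found += 1
                rec = hits[0]
                matched_ids.add(rec.copy_id)
                key = (t.class_truth if "class_truth" in t else t.kind,
                       rec.copy_class)
                confusion[key] = confusion.get(key, 0) + 1
                matched.append((t, rec))
    n_loci = sum(len(r) for r in state.copies.values())
    sig_ok = sig_n = 0
    for t, rec in matched:
        tsd = t.tsd_up if "tsd_up" in t else t.tsd
        if t.get("truncated", False):
            continue
        sig_n += 1
        sig_ok += int(rec.signature is not None
                      and rec.signature.upstream_4mer == tsd)
    out = {
        "sensitivity": n_found / n_truth if n_truth else float("nan"),
        "precision": n_found / n_loci if n_loci else float("nan"),
        "confusion": {f"{a}->{b}": c for (a, b), c in sorted(confusion.items())},
        "signature_accuracy": sig_ok / sig_n if sig_n else float("nan"),
    }
    if state.dating is not None and len(state.dating) and "age_years" in truth:
        id_age = {}
        for t, rec in matched:
            id_age[rec.copy_id] = float(t.age_years)
        d = state.dating[state.dating.copy_id.isin(id_age)]
        if len(d):
            err = d.T_years.to_numpy() - np.array([id_age[c] for c in d.copy_id])
            out["dating_bias_years"] = float(err.mean())
            out["dating_rmse_years"] = float(np.sqrt((err ** 2).mean()))
    if "events" in (truth.columns if truth is not None else []):
        true_rec = set()
        for _, t in truth.iterrows():
            if "recombination" in str(t.events):
                true_rec.add(t.copy_id)
        out["recombination_truth_n"] = len(true_rec)
        out["recombination_removed_n"] = len(state.removals)
    return out
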