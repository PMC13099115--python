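"""Synthetic host genomes carrying ERV insertions, with machine-readable truth.

The generative model, end to end:

* A host pedigree/species tree with branch durations in years. The default
  topology is (chaus,(nigripes,(catus_1,catus_2,catus_3))) with the earliest
  split at 2.0 My, a second split at 1.2 My and within-species coalescence of
  the domestic-cat individuals at 0.2 My; insertions may also occur on the
  stem above the root back to a 3.5 My horizon, in which case they are
  inherited by every individual.
* Endogenization events arrive as a Poisson process per branch
  (events/branch/My), each event placing one provirus at a uniform position
  in a uniformly chosen scaffold. The 4-nt target site at that position is
  duplicated on both sides of the element (TSD).
* Every copy evolves neutrally under the Kimura two-parameter process at a
  per-site yearly rate r (default 2.3e-9). Substitutions are applied along
  the host tree, so copies shared by several individuals keep diverging
  after speciation and the two LTRs of one copy diverge independently.
* Structural events: solo-LTR collapse (hazard per My), paired-solo collapse,
  internal deletions (sizes can exceed 1000 nt), internal duplication
  (an "atypical" architecture with duplicated genes around an LTR-like
  spacer), and inter-copy recombination (mosaic of two copies at a drawn
  breakpoint).
* Host background divergence: each individual's background (and therefore
  the flanks of every insertion) differs from any other individual's by
  approximately `host_background_divergence` substitutions/site.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kimura import evolve_codes
from .reference import ProvirusReference, synthetic_reference
from .util import decode, encode, revcomp_codes, substream, random_background, \
    write_fasta, write_gff3, write_json


# ---------------------------------------------------------------------------
# Host pedigree

@dataclass
class HostNode:
    name: str
    time: float                       # age (years before present) of this node
    parent: "HostNode | None" = None
    children: list = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass(frozen=True)
class IntrogressionEdge:
    donor: str        # branch (named by its child node) donating copies
    recipient: str    # branch receiving them
    time_years: float
    burst: int = 0    # extra near-identical copies seeded in the recipient


class HostTree:
    """Rooted host tree; each branch is named by its child node and spans
    [node.time, parent-or-horizon time]."""

    def __init__(self, root: HostNode, horizon_years: float,
                 introgression: IntrogressionEdge | None = None):
        self.root = root
        self.horizon_years = float(horizon_years)
        self.nodes: dict[str, HostNode] = {}
        stack = [root]
        while stack:
            n = stack.pop()
            if n.name in self.nodes:
                raise ValueError(f"duplicate node name {n.name}")
            self.nodes[n.name] = n
            stack.extend(n.children)
        self.introgression = introgression
        if introgression is not None:
            for br in (introgression.donor, introgression.recipient):
                if br not in self.nodes:
                    raise ValueError(f"introgression references unknown branch {br}")
            t = introgression.time_years
            for br in (introgression.donor, introgression.recipient):
                lo, hi = self.branch_interval(br)
                if not (lo <= t <= hi):
                    raise ValueError(
                        f"introgression time {t} outside branch {br} interval [{lo},{hi}]")

    def branch_interval(self, name: str) -> tuple[float, float]:
        n = self.nodes[name]
        top = self.horizon_years if n.parent is None else n.parent.time
        return n.time, top

    def branch_duration(self, name: str) -> float:
        lo, hi = self.branch_interval(name)
        return hi - lo

    def tips(self) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.is_tip)

    def tips_below(self, name: str) -> list[str]:
        out, stack = [], [self.nodes[name]]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.name)
            stack.extend(n.children)
        return sorted(out)

    def ancestors_of_branch(self, name: str) -> list[str]:
        """Branch names on the path from `name` up to the root (inclusive)."""
        out, n = [], self.nodes[name]
        while n is not None:
            out.append(n.name)
            n = n.parent
        return out

    def total_branch_length_my(self) -> float:
        return sum(self.branch_duration(n) for n in self.nodes) / 1e6


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class SimulationConfig:
    """All knobs of the provirus-evolution simulator (rates per year or per My)."""

    seed: int = 0
    background_length: int = 1_000_000
    n_scaffolds: int = 1
    gc_content: float = 0.42
    # host tree
    horizon_years: float = 3.5e6
    split_chaus_years: float = 2.0e6
    split_nigripes_years: float = 1.2e6
    coalescence_catus_years: float = 0.2e6
    n_catus: int = 3
    introgression: IntrogressionEdge | None = None
    # molecular evolution
    r: float = 2.3e-9                 # substitutions/site/year
    kappa: float = 2.0                # transition/transversion rate ratio
    host_background_divergence: float = 0.005   # subs/site between individuals
    # insertion process
    endogenization_rate: float = 1.7  # events per branch per My
    min_spacing: int = 40_000         # bp between insertion points
    position_margin: int = 20_000     # keep implants clear of scaffold ends
    # structural events
    solo_collapse_hazard: float = 0.10   # per-copy per-My probability
    paired_solo_prob: float = 0.0
    deletion_prob: float = 0.25
    deletion_size_range: tuple[int, int] = (100, 3000)  # includes sizes > 1000 nt
    duplication_prob: float = 0.05
    recombination_prob: float = 0.05
    minus_strand_prob: float = 0.0
    tsd_length: int = 4
    # truncation at scaffold ends
    truncate_at_end: bool = False
    end_margin: int = 0

    def __post_init__(self):
        for name in ("r", "kappa", "host_background_divergence", "endogenization_rate",
                     "solo_collapse_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("paired_solo_prob", "deletion_prob", "duplication_prob",
                     "recombination_prob", "minus_strand_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.tsd_length != 4:
            raise ValueError("tsd_length must be 4 (retroviral integrase signature)")
        if self.background_length <= 0:
            raise ValueError("background_length must be positive")
        lo, hi = self.deletion_size_range
        if not (0 < lo <= hi):
            raise ValueError("bad deletion_size_range")


@dataclass
class TruthRecord:
    """Ground truth for one implanted copy (positions in root-background coords)."""

    copy_id: str
    scaffold: int
    insertion_position: int
    age_years: float
    tsd: str                               # ancestral 4-mer at the target site
    class_truth: str
    events: list = field(default_factory=list)
    carriers: list = field(default_factory=list)
    parent_copy_ids: list = field(default_factory=list)
    branch: str = ""
    minus_strand: bool = False


def build_host_pedigree(config: SimulationConfig) -> HostTree:
    """Default felid-like pedigree; see module docstring for the topology."""
    if config.split_chaus_years > config.horizon_years:
        raise ValueError("oldest split beyond simulation horizon")
    catus = [HostNode(f"catus_{i+1}", 0.0) for i in range(config.n_catus)]
    if config.n_catus > 1:
        anc_catus = HostNode("anc_catus", config.coalescence_catus_years, children=catus)
        for c in catus:
            c.parent = anc_catus
        felis_child = anc_catus
    elif config.n_catus == 1:
        felis_child = catus[0]
    else:
        felis_child = None
    nigripes = HostNode("nigripes", 0.0)
    inner = [nigripes] + ([felis_child] if felis_child is not None else [])
    anc_felis = HostNode("anc_felis", config.split_nigripes_years, children=inner)
    for c in inner:
        c.parent = anc_felis
    chaus = HostNode("chaus", 0.0)
    root = HostNode("root", config.split_chaus_years, children=[chaus, anc_felis])
    chaus.parent = root
    anc_felis.parent = root
    return HostTree(root, config.horizon_years, config.introgression)


def single_tip_tree(name: str = "ind", duration_years: float = 0.0) -> HostTree:
    """Degenerate one-individual pedigree (no inherited copies possible)."""
    return HostTree(HostNode(name, 0.0), horizon_years=duration_years)


# ---------------------------------------------------------------------------
# Endogenization

def root_backgrounds(config: SimulationConfig) -> list[np.ndarray]:
    rng = substream(config.seed, "background")
    return [random_background(config.background_length, rng, config.gc_content)
            for _ in range(config.n_scaffolds)]


def _draw_events(truth: TruthRecord, ref: ProvirusReference, config: SimulationConfig,
                 rng: np.random.Generator, existing: list[TruthRecord]) -> None:
    """Draw structural events for a copy; sets truth.events and class_truth."""
    age_my = truth.age_years / 1e6
    i0, i1 = ref.internal_interval
    p_solo = 1.0 - (1.0 - config.solo_collapse_hazard) ** age_my
    if rng.random() < p_solo:
        keep = "5" if rng.random() < 0.5 else "3"
        truth.events.append({"type": "solo_collapse", "keep_ltr": keep})
        truth.class_truth = "solo_ltr"
        return
    if rng.random() < config.paired_solo_prob:
        truth.events.append({"type": "paired_solo", "gap": 50})
        truth.class_truth = "paired_solo_ltr"
        return
    if rng.random() < config.recombination_prob:
        shared = [t for t in existing
                  if set(t.carriers) & set(truth.carriers) and not t.events]
        if shared:
            parent = shared[int(rng.integers(len(shared)))]
            bp = int(rng.integers(i0 + 200, i1 - 200))
            truth.events.append({"type": "recombination", "breakpoint": bp,
                                 "parent": parent.copy_id})
            truth.parent_copy_ids = [parent.copy_id]
    if rng.random() < config.deletion_prob:
        lo, hi = config.deletion_size_range
        size = int(rng.integers(lo, hi + 1))
        size = min(size, i1 - i0 - 200)
        start = int(rng.integers(i0, i1 - size))
        truth.events.append({"type": "deletion", "start": start, "end": start + size,
                             "size": size})
    if rng.random() < config.duplication_prob:
        truth.events.append({"type": "internal_duplication"})
        truth.class_truth = "atypical"
        return
    truth.class_truth = "typical"


def simulate_endogenization(host_tree: HostTree, provirus_ref: ProvirusReference,
                            config: SimulationConfig) -> list[TruthRecord]:
    """Poisson insertion events on every branch, inherited by descendant tips."""
    if config.background_length <= 2 * config.position_margin:
        raise ValueError("background too short for the configured position margin")
    rng = substream(config.seed, "endogenization")
    bgs = root_backgrounds(config)
    truths: list[TruthRecord] = []
    used_positions: dict[int, list[int]] = {i: [] for i in range(config.n_scaffolds)}
    intro = host_tree.introgression
    for branch in sorted(host_tree.nodes):
        dur_my = host_tree.branch_duration(branch) / 1e6
        if dur_my <= 0:
            continue
        n = rng.poisson(config.endogenization_rate * dur_my)
        lo, hi = host_tree.branch_interval(branch)
        for _ in range(n):
            age = float(rng.uniform(lo, hi))
            scaf = int(rng.integers(config.n_scaffolds))
            pos = _draw_position(rng, config, used_positions[scaf])
            if pos is None:
                continue  # no room left on this scaffold; logged via count
            used_positions[scaf].append(pos)
            carriers = host_tree.tips_below(branch)
            if (intro is not None and age > intro.time_years
                    and branch in host_tree.ancestors_of_branch(intro.donor)
                    and not set(host_tree.tips_below(intro.recipient)) <= set(carriers)):
                carriers = sorted(set(carriers) | set(host_tree.tips_below(intro.recipient)))
            tsd = decode(bgs[scaf][pos:pos + config.tsd_length])
            truth = TruthRecord(
                copy_id=f"copy{len(truths):03d}", scaffold=scaf, insertion_position=pos,
                age_years=age, tsd=tsd, class_truth="typical", carriers=carriers,
                branch=branch,
                minus_strand=bool(rng.random() < config.minus_strand_prob),
            )
            _draw_events(truth, provirus_ref, config, rng, truths)
            truths.append(truth)
    truths.sort(key=lambda t: (t.scaffold, t.insertion_position))
    return truths


def _draw_position(rng, config, used: list[int]) -> int | None:
    for _ in range(200):
        pos = int(rng.integers(config.position_margin,
                               config.background_length - config.position_margin))
        if all(abs(pos - u) >= config.min_spacing for u in used):
            return pos
    return None


# ---------------------------------------------------------------------------
# Copy evolution

def apply_structural_events(codes: np.ndarray, truth: TruthRecord,
                            ref: ProvirusReference,
                            parent_codes: np.ndarray | None = None) -> np.ndarray:
    """Apply the copy's recorded structural events, in recorded order."""
    ltr5, ltr3 = ref.ltr5, ref.ltr3
    for ev in truth.events:
        kind = ev["type"]
        if kind == "recombination":
            if parent_codes is None:
                raise ValueError("recombination event requires parent sequence")
            bp = ev["breakpoint"]
            codes = np.concatenate([codes[:bp], parent_codes[bp:]])
        elif kind == "deletion":
            codes = np.concatenate([codes[: ev["start"]], codes[ev["end"]:]])
        elif kind == "internal_duplication":
            internal = codes[ltr5.end: ltr3.start]
            mid_ltr = codes[ltr5.start: ltr5.end]
            codes = np.concatenate([codes[: ltr3.start], mid_ltr, internal,
                                    codes[ltr3.start:]])
        elif kind == "solo_collapse":
            f = ltr5 if ev["keep_ltr"] == "5" else ltr3
            codes = codes[f.start: f.end].copy()
        elif kind == "paired_solo":
            gap = ev["gap"]
            codes = np.concatenate([codes[ltr5.start: ltr5.end],
                                    codes[ltr5.end: ltr5.end + gap],
                                    codes[ltr3.start: ltr3.end]])
        else:
            raise ValueError(f"unknown structural event {kind}")
    return codes


def evolve_copy(provirus_ref: ProvirusReference, truth: TruthRecord,
                config: SimulationConfig,
                rng: np.random.Generator | None = None,
                parent_seq: str | None = None) -> str:
    """Evolve one copy for its age on a single lineage and apply its events.

    Substitutions hit every site independently (the two LTRs therefore
    diverge independently); structural events are applied afterwards in
    recorded order. When the copy is a recombinant and no parent sequence is
    supplied, a parent lineage of the same age is evolved from the reference.
    """
    if rng is None:
        rng = substream(config.seed, "evolve", int(truth.copy_id.lstrip("copy") or 0))
    codes = evolve_codes(encode(provirus_ref.seq), config.r * truth.age_years,
                         config.kappa, rng)
    parent_codes = None
    if any(ev["type"] == "recombination" for ev in truth.events):
        if parent_seq is not None:
            parent_codes = encode(parent_seq)
        else:
            parent_codes = evolve_codes(encode(provirus_ref.seq),
                                        config.r * truth.age_years, config.kappa, rng)
    return decode(apply_structural_events(codes, truth, provirus_ref, parent_codes))


def _evolve_copy_on_tree(truth: TruthRecord, ref: ProvirusReference,
                         config: SimulationConfig, tree: HostTree) -> dict[str, np.ndarray]:
    """Per-carrier pre-event sequences, with substitutions shared until speciation."""
    rng = substream(config.seed, "copyevo", int(truth.copy_id[4:]))
    out: dict[str, np.ndarray] = {}
    intro = tree.introgression
    start = tree.nodes[truth.branch] if truth.branch else tree.root
    needs_transfer = (
        intro is not None
        and any(c in truth.carriers for c in tree.tips_below(intro.recipient))
        and intro.recipient not in {n for n in tree.nodes
                                    if start.name in tree.ancestors_of_branch(n)}
    )

    def descend(codes: np.ndarray, node: HostNode, t_from: float) -> None:
        snapshot = None
        if (needs_transfer and node.name == intro.donor
                and t_from >= intro.time_years >= node.time):
            codes = evolve_codes(codes, config.r * (t_from - intro.time_years),
                                 config.kappa, rng)
            snapshot = codes.copy()
            t_from = intro.time_years
        codes = evolve_codes(codes, config.r * (t_from - node.time), config.kappa, rng)
        if node.is_tip:
            if node.name in truth.carriers:
                out[node.name] = codes
        else:
            for child in sorted(node.children, key=lambda c: c.name):
                descend(codes.copy(), child, node.time)
        if snapshot is not None:
            descend(snapshot, tree.nodes[intro.recipient], intro.time_years)

    descend(encode(ref.seq), start, truth.age_years)
    # introgressed carriers not reachable from the insertion branch
    missing = [c for c in truth.carriers if c not in out]
    if missing and intro is not None:
        base = next(iter(out.values()))
        for c in sorted(missing):
            out[c] = evolve_codes(base.copy(), config.r * intro.time_years,
                                  config.kappa, rng)
    return out


# ---------------------------------------------------------------------------
# Genome emission

@dataclass
class SimulatedDataset:
    genomes: dict[str, dict[str, str]]      # individual -> scaffold -> sequence
    truth: pd.DataFrame                     # one row per copy per carrier
    truths: list[TruthRecord]
    reference: ProvirusReference
    config: SimulationConfig
    redraws: int = 0


def emit_genomes(truths: list[TruthRecord], provirus_ref: ProvirusReference,
                 config: SimulationConfig, host_tree: HostTree | None = None,
                 outdir: str | Path | None = None) -> SimulatedDataset:
    """Implant evolved copies into per-individual backgrounds and emit truth.

    Final genome length per scaffold is background + Σ(element + 4) over the
    carried copies (the 4-nt target site is duplicated at each implant).
    """
    if config.background_length == 0:
        raise ValueError("zero-length background")
    if host_tree is None:
        host_tree = build_host_pedigree(config)
    bgs = root_backgrounds(config)
    tips = host_tree.tips()

    tip_bg: dict[str, list[np.ndarray]] = {}
    for i, tip in enumerate(tips):
        rng = substream(config.seed, "hostbg", i)
        d = config.host_background_divergence / 2.0
        tip_bg[tip] = [evolve_codes(bg, d, config.kappa, rng) for bg in bgs]

    # per-carrier evolved sequences (pre-structural-events), then events applied
    carrier_seqs: dict[str, dict[str, np.ndarray]] = {}
    by_id = {t.copy_id: t for t in truths}
    for t in truths:
        carrier_seqs[t.copy_id] = _evolve_copy_on_tree(t, provirus_ref, config, host_tree)
    final_seqs: dict[str, dict[str, np.ndarray]] = {}
    for t in truths:
        final_seqs[t.copy_id] = {}
        for carrier, codes in carrier_seqs[t.copy_id].items():
            parent_codes = None
            rec = [ev for ev in t.events if ev["type"] == "recombination"]
            if rec:
                p = by_id[rec[0]["parent"]]
                psc = carrier_seqs[p.copy_id]
                parent_codes = psc.get(carrier, next(iter(psc.values())))
            ele = apply_structural_events(codes, t, provirus_ref, parent_codes)
            if t.minus_strand:
                ele = revcomp_codes(ele)
            final_seqs[t.copy_id][carrier] = ele

    genomes: dict[str, dict[str, str]] = {}
    rows = []
    L = config.background_length
    for tip in tips:
        genomes[tip] = {}
        for scaf in range(config.n_scaffolds):
            carried = [t for t in truths if tip in t.carriers and t.scaffold == scaf]
            carried.sort(key=lambda t: t.insertion_position)
            segments, shift, prev = [], 0, 0
            bg = tip_bg[tip][scaf]
            scaffold_name = f"scaffold_{scaf}"
            truncated_tail = False
            for t in carried:
                pos = t.insertion_position
                ele = final_seqs[t.copy_id][tip]
                tsd_up = bg[pos: pos + 4]
                rng_tsd = substream(config.seed, "tsd", int(t.copy_id[4:]),
                                    tips.index(tip))
                tsd_down = evolve_codes(tsd_up, config.r * t.age_years,
                                        config.kappa, rng_tsd)
                truncate = (config.truncate_at_end
                            and pos >= L - config.end_margin)
                segments.append(bg[prev: pos + 4])
                start = pos + 4 + shift
                if truncate:
                    keep = max(0, L - pos - 4)
                    ele = ele[:keep]
                    segments.append(ele)
                    cls = "incomplete_segment"
                    t.class_truth = cls
                    rows.append(_row(t, tip, scaffold_name, start, start + len(ele),
                                     tsd_up, None, truncated=True))
                    truncated_tail = True
                    prev = len(bg)  # drop downstream background
                    break
                segments.append(ele)
                segments.append(tsd_down)
                rows.append(_row(t, tip, scaffold_name, start, start + len(ele),
                                 tsd_up, tsd_down, truncated=False))
                shift += len(ele) + 4
                prev = pos + 4
            if not truncated_tail:
                segments.append(bg[prev:])
            genomes[tip][scaffold_name] = decode(np.concatenate(
                [s for s in segments if len(s)] or [np.empty(0, dtype=np.uint8)]))

    truth_df = pd.DataFrame(rows, columns=[
        "copy_id", "carrier", "scaffold", "start", "end", "strand", "age_years",
        "class_truth", "tsd_truth", "tsd_up", "tsd_down", "events",
        "parent_copy_ids", "truncated"])
    ds = SimulatedDataset(genomes=genomes, truth=truth_df, truths=truths,
                          reference=provirus_ref, config=config)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def _row(t: TruthRecord, carrier, scaffold_name, start, end, tsd_up, tsd_down,
         truncated):
    return {
        "copy_id": t.copy_id, "carrier": carrier, "scaffold": scaffold_name,
        "start": int(start), "end": int(end),
        "strand": "-" if t.minus_strand else "+",
        "age_years": t.age_years, "class_truth": t.class_truth, "tsd_truth": t.tsd,
        "tsd_up": decode(tsd_up),
        "tsd_down": decode(tsd_down) if tsd_down is not None else "NNNN",
        "events": json.dumps(t.events), "parent_copy_ids": ",".join(t.parent_copy_ids),
        "truncated": truncated,
    }


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ind, scafs in ds.genomes.items():
        write_fasta(outdir / f"{ind}.fasta", sorted(scafs.items()))
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    gff_rows = []
    for _, r in ds.truth.iterrows():
        gff_rows.append({"seqid": f"{r.carrier}:{r.scaffold}", "type": "ERV_copy",
                         "start": r.start, "end": r.end, "strand": r.strand,
                         "attributes": {"ID": f"{r.copy_id}.{r.carrier}",
                                        "class": r.class_truth, "tsd": r.tsd_up}})
    write_gff3(outdir / "truth.gff3", gff_rows)
    write_json(outdir / "run_log.json",
               {"seed": ds.config.seed, "config": _config_dict(ds.config),
                "n_copies": len(ds.truths)})


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    return d


def simulate(config: SimulationConfig, reference: ProvirusReference | None = None,
             outdir: str | Path | None = None) -> SimulatedDataset:
    """Convenience: pedigree -> endogenization -> evolution -> emitted genomes."""
    ref = reference if reference is not None else synthetic_reference()
    tree = build_host_pedigree(config)
    truths = simulate_endogenization(tree, ref, config)
    return emit_genomes(truths, ref, config, host_tree=tree, outdir=outdir)
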