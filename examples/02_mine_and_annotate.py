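"""Mine ERV loci from a genome and annotate their structure.

Runs the seed-and-extend search with the standard multi-query set (LTR, gag,
pol, env, whole provirus), merges hits into loci, and classifies each copy
(typical / solo LTR / atypical / paired solo LTRs / incomplete segment).
"""

from ervkit import MiningParams, annotate_copy, mine_genome, simulate
from ervkit.simulate import SimulationConfig

ds = simulate(SimulationConfig(seed=7, background_length=300_000,
                               min_spacing=30_000, position_margin=20_000))
genome_id = "catus_1"
loci = mine_genome(ds.genomes[genome_id], ds.reference.query_set(), genome_id,
                   MiningParams(flank_len=4000))
print(f"{genome_id}: {len(loci)} loci mined")
for locus in loci:
    rec = annotate_copy(locus, ds.reference)
    sig = rec.signature
    print(f"  {rec.copy_id}  [{locus.start:,}-{locus.end:,}] {locus.strand} "
          f"class={rec.copy_class} genes={[a.name for a in rec.genes()]} "
          f"signature={sig.upstream_4mer}/{sig.downstream_4mer} "
          f"matching={sig.is_matching} open_orf={rec.fully_open_orf}")
# A matching 4-mer signature is the target-site duplication left by
# integration; it decays with insertion age as the two copies accumulate
# independent substitutions.
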