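"""Simulate host genomes carrying ERV insertions, with ground truth.

Builds a five-individual felid-like pedigree (one jungle-cat-like early
divergence at 2 My, one black-footed-cat-like split at 1.2 My, three
domestic-cat individuals), drops proviral insertions on its branches as a
Poisson process, evolves every copy neutrally at 2.3e-9 subs/site/year, and
implants the copies with 4-nt target-site duplications.
"""

from ervkit import SimulationConfig, simulate

config = SimulationConfig(seed=7, background_length=300_000,
                          min_spacing=30_000, position_margin=20_000)
ds = simulate(config, outdir="example_out/simulated")

print(f"individuals: {sorted(ds.genomes)}")
print(f"implanted copies (unique loci): {len(ds.truths)}")
print(ds.truth[["copy_id", "carrier", "start", "end", "age_years",
                "class_truth", "tsd_up"]].to_string(index=False))
# Each row is one copy in one carrier: a locus inserted on an ancestral
# branch appears in every descendant individual at orthologous coordinates,
# and tsd_up is the 4-mer duplicated on both sides of the element.
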