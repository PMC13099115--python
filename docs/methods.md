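# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `ervkit`, in the order the pipeline runs them.

## Substitution model and simulator

All sequence evolution uses the Kimura two-parameter (K2P) continuous-time
process: each site receives a Poisson number of substitution events with mean
`r · t` (r in substitutions/site/year, t in years), and each event is a
transition with probability `kappa / (kappa + 2)` (default `kappa = 2`),
otherwise one of the two transversions. Defaults: `r = 2.3e-9` (a neutral
rate measured in the domestic cat and consistent with endogenous LTRs of
primates), with an uncertainty interval `[2.0e-9, 2.5e-9]` used for dating
bounds. Using the same two-parameter model in the simulator and in the K2P
estimator makes dating a genuine parameter-recovery experiment rather than a
model-mismatch benchmark.

The host pedigree defaults to five individuals:
`(chaus,(nigripes,(catus_1,catus_2,catus_3)))` with splits at 2.0 My and
1.2 My and within-species coalescence at 0.2 My, plus a stem reaching back to
a 3.5 My horizon (insertions on the stem are carried by everyone). These
times reflect the published minimum divergence of the earliest *Felis* split
(2 My) and the observed insertion-age range (≤ 3.5 My). Endogenization is a
Poisson process per branch (default 1.7 events/branch/My, chosen to yield
roughly a dozen loci over the default tree's 7.1 My of total branch length —
a copy number comparable to per-individual loads reported for recently
endogenized gammaretroviruses). Each event gets a uniform position (with a
minimum spacing of 40 kb so loci never merge), a 4-nt target site read from
the background and duplicated at implant, and inheritance by all tips below
its branch. An optional introgression edge transfers copies existing at the
transfer time from a donor branch to a recipient branch.

Structural events per copy: solo-LTR collapse with per-My hazard 0.10 (the
surviving LTR is drawn at random — which LTR persists is not modelled in the
source data); internal deletion with probability 0.25 and uniform size
100–3000 nt (so sizes > 1000 nt occur); internal duplication (probability
0.05) producing the "atypical" architecture `LTR–internal–LTR-like–internal–
LTR`; recombination (probability 0.05) splicing the copy with another copy
sharing a carrier at a uniform internal breakpoint; paired-solo collapse is
available (default probability 0) for class benchmarking.

Host background divergence uses a star approximation: each individual's
background receives independent substitutions at half the configured
pairwise divergence (default 0.005), so any two individuals differ by about
that amount in their flanks. Inherited ERV copies, in contrast, evolve
properly along the tree (shared substitutions until speciation, independent
afterwards), which reproduces the pattern of one shared locus dating
differently in different carriers. The duplicated target site accrues
substitutions with copy age at rate `r`, so signatures of old copies can
stop matching while age-0 signatures always match exactly.

What the simulator does **not** model: chromosome-scale synteny, repeats and
low-complexity background (the background is i.i.d. nucleotides with
configurable GC), selection on copies, epigenetic silencing, and assembly
artifacts. Passing benchmarks on this background therefore demonstrates
algorithmic correctness, not robustness to repeat-rich real assemblies — a
repeat-rich background would mostly stress the miner's seeding stage.

## Mining

Queries (LTR, gag, pol, env, whole provirus) are searched on both strands:
exact k-mer seeding (k = 11) against a sorted k-mer index, clustering of
seeds by diagonal (tolerance 100 bp, split at subject gaps > 1 kb, minimum 4
seeds), and a gapped semi-global alignment of the query inside each candidate
window (edlib's bit-parallel aligner). Because the semi-global placement
forces terminal noise, each alignment is trimmed to its maximal-scoring
column interval (match +1, mismatch −2, gap open −5, extend −2), which
restores local-alignment semantics: flanking noise has negative expected
score and is cut, while internal deletions are bridged only when both sides
outweigh the gap cost. Filters follow the two published cutoffs: percent
identity ≥ 50 for host-range screening and query coverage ≥ 50 for locus
mining. HSPs within 2 kb on a scaffold are merged into loci (strand by
score-weighted majority); flanks (default 16 kb) are clipped at scaffold ends
and flagged. The minimum-seed rule and the coverage filter together keep the
false-locus rate at zero on ERV-free megabase backgrounds while recovering
implants up to at least 15% divergence with boundary errors well inside
±50 bp.

E-value statistics are deliberately absent: the published workflow filters
on identity/coverage, not significance, so none are needed.

## Annotation

LTR occurrences are found by repeated affine-gap local alignment
(match +1, mismatch −2, open −5, extend −2) with greedy masking; hits must
reach 70% identity over at least half the reference LTR. The outermost pair
with internal length in [2, 12] kb is the dating pair.

Genes and peptides are annotated the same way, then collinear hits (advancing
in both feature and element coordinates) are chained, so a gene split by an
internal deletion yields one annotation whose largest deletion is read off
the chain junction; a duplicated gene (feature coordinates restarting) yields
separate annotations. Local alignment performs the "trim to high-identity
regions" step deterministically — terminal columns with negative score
contribution are excluded by construction. A feature is emitted when its
matches cover ≥ 25% of the reference feature length (each hit must also hold
≥ 80% column identity with ≥ 35 matches, which separates true homology from
the ~50–60% match density that optimal alignments achieve on random DNA).
The manual curation step in the source workflow — adding a gene whose overall
identity fails while an individual peptide passes — is automated as "peptide
rescue" and flagged per annotation.

ORF integrity: the reading frame is inferred from the feature alignment
offset; a gene is intact when no in-frame stop codon occurs in its annotated
interval, and a copy is "fully open" when all annotated genes are intact.
In-frame deletions keep ORFs open; deletions > 1000 nt stay visible on the
annotation regardless.

Classification is a total decision order: (1) element clipped at a scaffold
end (locus within 500 bp of a scaffold boundary) → incomplete segment;
(2) one LTR, no genes → solo LTR; (3) ≥ 2 LTRs < 200 bp apart with no genes →
paired solo LTRs; (4) LTR pair with genes in reference order, each at most
once, no internal LTR-like segment → typical (whole-gene deletions allowed);
(5) otherwise atypical. The 200 bp paired-solo gap, the 70% LTR identity and
the 500 bp end proximity are package choices (the source analyses state no
values) and are all configurable.

## Dating

LTR pairs are globally aligned (affine gaps) and the K2P distance
`K = -½ ln((1-2P-Q)√(1-2Q))` is computed over non-gap, non-N columns
(`n_sites` reported). Ages are `T = K/(2r)` with bounds from the rate
interval (a larger rate gives the younger bound). `K = 0` is flagged
`identical_ltrs` and reported as an age-0 lower bound; saturation
(`1-2P-Q ≤ 0` or `1-2Q ≤ 0`) is flagged and left undated — no fallback
estimator is substituted, mirroring the reliance on recent, unsaturated
LTRs. With 600-bp LTRs a 1 My age implies only ~2.8 expected differences, so
single-copy ages are Poisson-noisy; the estimator is unbiased in expectation
(mean recovery within a few percent over 200 pairs).

## Recombination screen

Three triplet statistics are implemented natively: MaxChi (maximal
chi-square contrast of pairwise match proportions in windows of w = 20
variable sites left/right of a candidate breakpoint), a Chimaera variant
(the same contrast on the candidate-vs-parent match vector restricted to
sites where the parents differ), and a sliding-window identity method (the
longest run of windows whose locally closest parent differs from the
globally closest one). Significance uses seeded permutations of the
informative-site order; p = (1 + #{perm ≥ obs}) / (B + 1).

Triplet enumeration defaults to one triplet per candidate, with the two most
similar other copies as putative parents. An exhaustive mode (every member
of every 3-subset as candidate) exists, but Bonferroni over an O(n³) family
destroys the resolution of permutation p-values — with B permutations no
call can clear α once the family exceeds αB — so the per-candidate scan is
the default and the pipeline's permutation count (999) is chosen to keep
the corrected floor below α for realistic copy numbers. A copy flagged by at
least `min_methods` methods (default 2 of the 3 implemented, proportional to
the published 3-of-7 rule; 3-of-3 available) is removed from phylogeny
input. MaxChi is pair-based, so parents of a strong mosaic can be flagged
along with it; this removal of mixed signal is conservative by design.
Under clonal simulation the empirical type-I error at α = 0.05 sits within
[0.02, 0.08], and 50/50 mosaics of parents at 5% divergence are flagged
essentially always.

## Comparative analyses

Orthologous loci are matched by their flanks with the element excised: the
1 kb of flank adjacent to each side is globally aligned pairwise across
genomes, and pairs with ≥ 90% identity on both sides (≥ 500 bp per side
required) are joined by single linkage. Copies sharing only a 4-mer
signature at different loci are reported as `signature_only` coincidences
and never merged — identical signatures arise convergently at ~1/256 per
pair of insertions.

Count tables (classes × genomes; gene and peptide presence over
nonrecombinant typical copies; per-scaffold placements) feed three families
of two-sided Fisher exact tests, each Bonferroni-corrected by the number of
tests actually run in the family: (a) typical-vs-solo load per genome pair,
(b) gene presence/absence per gene pair, (c) each peptide against the mean
of the other peptides of its polyprotein. The exact 2×2 constructions are
package choices (the source analyses do not print theirs); the two published
bounds this package reproduces — preferential `pol` loss (p < 0.001 over 65
gag / 50 pol / 65 env in 65 typical copies) and the early-diverging host's
copy-load excess (27 typical / 0 solo vs every other long-read individual,
p < 0.001) — hold under these constructions.

## Phylogenetics

Copies are projected onto reference coordinates by semi-global alignment
(free end gaps only for unaligned reference tails; gap extension −0.5 so
kilobase structural deletions beat shifted noisy alignments; copy insertions
relative to the reference are dropped and counted). Maximum-likelihood
inference is deliberately out of scope: at the low divergences of recently
endogenized copies, neighbor joining on K2P distances recovers the same
topological observables, and it is exact on additive matrices (verified to
1e-9). Ties in the NJ Q-matrix and in cluster joins break lexicographically
on tip labels; negative branch lengths are clamped to zero. Support is a
nonparametric bootstrap over alignment columns; rooting is at the midpoint
of the longest tip-to-tip path; monophyly tests reroot at a designated
outgroup. Saturated pairwise distances (absent in practice here) are set to
a finite ceiling of 5 substitutions/site rather than propagating NaN.
Per-gene trees are slices of the projected alignment at the reference gene
intervals; gene-vs-genome topologies are compared descriptively by shared
and unique bipartitions (no AU test).

## Pipeline and reproducibility

All randomness flows from one seed through named CRC32-keyed substreams, so
every stage is independently reproducible and a rerun with the same config
is byte-identical. Each stage writes TSV/GFF3/BED/Newick artifacts as it
completes, and the JSON report aggregates class counts, dating summaries,
removals, ortholog groups and exact-test results; for simulated inputs an
evaluation block reports locus sensitivity/precision, the class confusion
matrix, signature accuracy, dating bias/RMSE and recombination removals
against truth.

Benchmark problem sizes — 3 × 1 Mb genomes for mining, 30 copies across six
genomes for classification, 200 LTR pairs per age for dating, 500 clonal
triplets for screen calibration, 100 replicate simulations for monophyly —
were chosen as the smallest sizes at which the Monte-Carlo error of each
metric is well below its acceptance margin, and they keep the full benchmark
suite to a few minutes on one CPU.

## Known limitations

* The miner is untuned for repeat-rich or low-complexity backgrounds; a
  repeat toggle exists in the background generator for stress testing, but
  masking/repeat libraries are out of scope.
* Edit-distance window alignment (mining) and affine local alignment
  (annotation) can disagree by a few base pairs at hit boundaries; boundary
  accuracy is validated to ±50 bp, not to the base.
* Dating assumes rate constancy and neutrality; both are approximations for
  elements that still interact with their exogenous counterparts.
* The recombination screen implements 3 of the 7 methods of the reference
  screening suite; only the consensus-removal semantics, not per-method
  counts, are comparable.
* The star model of background divergence does not produce
  phylogenetically structured flank similarity between individuals; it is
  sufficient for ortholog matching at the default 0.5% divergence.
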