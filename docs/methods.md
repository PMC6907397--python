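# Methods

This note records the models, parameter choices and numerical decisions
behind `paleoscaf`, and what the synthetic benchmarks do and do not show
about real data.

## Synthetic genomes and planted truth

`synthetic_data.simulate_wgd_genome` builds a multi-chromosome genome of
single-exon genes (default 13 chromosomes, 100 genes each, 300 bp CDS)
separated by random intergenic sequence. WGD events are applied in list
order (oldest first): each event duplicates every chromosome, each gene
surviving on the copy with probability `retention_rate` with local gene
order preserved, so duplicated segments are collinear by construction.
Each surviving pair receives a true Ks drawn from a normal distribution
truncated at zero; the default two-event configuration uses means 0.61
and 1.71 (SDs 0.15 and 0.35, retention 0.7 each), the two duplication
depths the package is designed to resolve. Mixture component weights and
SDs are package defaults chosen to give clearly separated but
realistically overlapping peaks; only the means are anchored to reported
duplication ages.

Synonymous divergence is *realized*, not just recorded: the duplicate
CDS is mutated only at codons with a one-step synonymous neighbor, one
substitution per codon, until the synonymous-difference count implied by
the inverted Jukes–Cantor relation pS = 3/4·(1 − e^(−4/3·Ks)) is reached
(the fractional remainder is realized stochastically). This makes the
planted Ks recoverable by the NG86 estimator without a full codon-
evolution simulator: on simulated pairs the estimator's mean absolute
error is well under 0.1 for Ks ≤ 1 and grows toward saturation, as the
counting method's own error does. One consequence worth knowing: because
substitutions accumulate along each lineage, Ks between *cousin* genes
of nested WGDs exceeds the older event's depth, so the old peak of a
deduplicated paranome sits slightly above the generating mean — the same
upward drift real paranome distributions show for old events.

Assembly corruption plants exactly `chimera_count` chimeric joins by
concatenating scaffold pairs from different chromosomes with a single N
at the junction; the splitting rule targets lone N's, so truth is
recoverable by that rule (the package's own diagnostic convention: a
lone N marks a join no read pair supported). Proximity orderings cluster
scaffolds by true chromosome, order them by true position, and reverse
`inversion_count` disjoint runs of ≥ 2 scaffolds (orientations flipped),
mimicking the large-scale inversion errors contact-map ordering is prone
to. Crossovers are a Poisson process on map distance — no interference —
which is exactly the model under which Haldane's map function is the
correct distance transform; the default missing-call rate of 5%
exercises the 90% call-rate filter without dominating it.

What the simulator does *not* emulate: repeats and repeat-driven
misassembly, heterozygosity, read-level error, selection on duplicates,
fractionation bias, or rate variation among lineages. Passing the
planted-truth suites therefore demonstrates the algorithms' correctness
under their stated models, not robustness to every artifact of real
assemblies.

## Linkage mapping

Markers are pseudo-testcross (heterozygous in one parent, 1:1
segregation, phase unknown), so the recombination fraction of a pair is
r = min(m, n−m)/n over pairwise-complete progeny, and completely linked
markers (r = 0) collapse into blocks. Grouping links two markers when
r ≤ 0.35 and the binomial likelihood-ratio LOD against independence
reaches 3.0 — but the LOD threshold is applied *family-wise* by default:
with M markers there are M(M−1)/2 tests, and at M ≈ 650 a per-test LOD
of 3 admits dozens of spurious cross-chromosome edges, any one of which
fuses two linkage groups. The threshold is therefore raised by
log10(number of pairs) (a Bonferroni correction on the likelihood-ratio
scale). Genuine adjacent-marker linkage in a mapping population of 110
carries LOD ≈ 20, so group connectivity is untouched; with the
correction the expected spurious-edge count is ≪ 1 and 13 planted
chromosomes are recovered as exactly 13 groups in every tested seed.
Set `familywise=False` to recover the raw per-test rule.

Block ordering minimizes the sum of adjacent recombination fractions —
an exact Held–Karp dynamic program for ≤ 10 blocks, greedy
nearest-neighbor with 2-opt refinement beyond — with positions as
cumulative Haldane distances. This is a deliberate simplification of
maximum-likelihood map ordering: downstream reconciliation consumes only
block *order*, which the seriation recovers on planted data, and for
≤ 10 blocks the result provably equals the exhaustive-permutation
optimum. A linkage group's order and its reversal are equivalent; all
consumers treat them as such.

## Reconciliation

Scaffolds inherit the linkage group of their markers; a scaffold whose
markers hit more than one group is a chimera candidate, reported with
per-group marker coordinate ranges. Splitting cuts each boundary
interval at a lone N (neighbors not N) when one exists, else at the
midpoint of the first N-run; the cut base is removed from both parts,
which are named `<id>_1`, `<id>_2`, … left to right. An interval with no
N is left unsplit and flagged unresolved. Whether real misassemblies are
always marked by a lone N rather than an N-run is not knowable in
general; the lone-N preference is a documented package choice.

Proximity clusters map one-to-one onto linkage groups by maximizing
shared bp (Hungarian assignment) — deterministic and optimal, with
per-pair purity reported. Ordering concordance uses Kendall tau-b with
scaffolds of one linkage block order-tied. Inversion detection aligns
the map's direction to the proximity order (the map's own orientation is
arbitrary), then finds maximal runs of ≥ 2 scaffolds with non-increasing
linkage rank containing at least one strict decrease; rank ties
(co-segregating scaffolds) never break a run but are never evidence on
their own. A run is accepted only if reversing it strictly increases the
number of concordant adjacent pairs — this guards against flip-flopping
on noise and makes reconciliation idempotent. `min_segment = 2` because
the map cannot resolve a single-scaffold order swap. When a segment is
reversed, orientations inside flip and "?" stays "?". After chimera
splitting, the parent's proximity slot passes to its largest subscaffold
(which dominates the contact signal); other parts enter as
proximity-unplaced scaffolds.

Tiers: `both_consistent` (ordered by both methods, no residual adjacent
discordance), `proximity_only` (ordered by proximity but absent from the
map, or residually discordant with it), `clustered_unordered`,
`unclustered`; the accounting conserves scaffold count and total bp.

## Synteny

Chaining is sparse dynamic programming on gene order per chromosome pair
and orientation sign: chain score = Σ anchor scores − g·(gap_a + gap_b),
adjacent anchors may skip at most 40 genes per side, chains are
extracted greedily by descending score with used anchors removed, and
blocks need ≥ 5 anchors. The gap penalty g = 1 per skipped gene per side
and flat anchor score 10 are package defaults (chaining-threshold
behavior, not these constants, is what the benchmarks depend on). The
5-anchor minimum is applied to every block. Tandem duplicate anchors
(same chromosome, ≤ 5 order positions apart) are dropped before chaining
to avoid inflating the self-diagonal. Syntenic depth uses
non-overlapping 20-gene windows — the same scale as the anchor minimum —
counting blocks whose span overlaps the window, both block sides for
self-synteny. Coverage is the length fraction of genes in ≥ 1 block.

## Ks estimation

NG86 with Jukes–Cantor correction replaces maximum-likelihood codon
models: closed-form, dependency-free, and adequate at these divergences;
the implementation agrees with an independent NG86 implementation to
1e-9 on test pairs and is validated against the saturation boundary
pS < 3/4. Site counts weight each codon position by its fraction of
synonymous one-step changes (changes to stops count as nonsynonymous);
multi-hit codons average over all minimal mutational pathways, excluding
pathways through stop codons (falling back to all pathways when every
ordering is blocked). Gene families are connected components of the
filtered hit graph — on clean similarity graphs this matches dedicated
clustering engines, with no external binary. Within a family, redundant
Ks values are removed by average-linkage clustering of the pairwise Ks
matrix: each merge height is the mean of the pairwise values first
joined there, giving exactly n − 1 node values per n-gene family.
Saturated entries are imputed as the family maximum for clustering and
excluded from samples (counted). Ks values above 3.0 are excluded from
distribution analysis by default — beyond that the correction is
hopelessly noisy — and the cap is configurable. Ortholog samples use
reciprocal best hits by score; ties drop the gene.

## Peaks and WGD calls

The KDE and SiZer grid is 401 positions over [0, 3]; bandwidths are 15
log-spaced values spanning [0.5×, 4×] the Silverman rule-of-thumb.
Significance of the density derivative uses the Gaussian derivative
kernel's empirical standard error and a simultaneous level from the
effective-independent-blocks adjustment (m = grid width / 2h; row-wise
quantile Φ⁻¹((1 + (1−α)^(1/m))/2)), α = 0.05 by default. Cells with
effective local sample size < 5 are coded sparse. A peak is a
significant rise followed by a significant fall at some bandwidth,
required to persist (by interval overlap) across ≥ 2 adjacent
bandwidths to suppress single-bandwidth artifacts.

Mixtures are fit by a hand-rolled 1-D EM (log-likelihood verified
non-decreasing every iteration; degenerate components with sd < 1e-4 or
weight < 1e-3 reject the start): 20 random + 5 k-means starts per k with
a 100-iteration burn-in, then full convergence (tolerance 1e-8, cap
2,000 iterations) from the best start — the standard multi-start
economy; the convergence basin for well-separated 1-D mixtures is wide,
and results are checked by tolerance, not optimum identity. BIC uses
p = 3k − 1. Only components whose mean falls inside a SiZer peak
interval are reported as WGD candidates (a minimum-BIC model often
spends extra components on skew and tails); calls with pooled mean below
0.25 are flagged as likely background duplication rather than WGD — a
configurable recency threshold, not a hard biological claim. Shared
calls across genomes form by single-linkage grouping of reported
component means at tolerance 0.25 (about the spacing resolvable given
rate variation among lineages). Placement against a speciation compares
the WGD mean to the mode of the ortholog Ks density, with dead-band δ =
half the larger of the two peak half-widths (half-maximum widths), so
"before"/"after" is only asserted when the peaks genuinely separate.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
every stage completes in seconds to a few minutes on one CPU: mixture
recovery and SiZer at n = 20,000; crosses with 110 progeny and 50
markers on each of 13 chromosomes of 100 cM; planted-error recovery with
23 chimeras and 3 inversions per genome aggregated over 20 seeds;
genomes of 13 × 20–100 genes (gene count changes chromosome length, not
the mapping statistics, so recovery tests use the smaller size); the
syntenic-depth benchmark plants a 30-gene segment on five chromosomes at
80% retention. Statistics that depend on real read data (true assembly
contiguity, repeat content, real gene counts) are out of reach of these
benchmarks by construction.

## Known limitations

- NG86 underestimates Ks at high divergence relative to ML codon
  models; peak *positions* near saturation inherit that bias.
- Connected-component families over-merge if the hit table is noisy at
  scale; the e-value cutoff (1e-4) is doing real work there.
- The linkage simplification has no ML ordering and no interference
  model; it is not a general-purpose mapping tool.
- Absolute dating (Ma) is out of scope; all ages are Ks.
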