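# Methods

`mamutspec` re-implements, as a reusable pipeline, the analysis of a
mutation-accumulation (MA) experiment in mismatch-repair-impaired,
obligately outcrossing *Caenorhabditis elegans*: 19 *fog-2(q71)*;
*msh-2*(RNAi) knockdown lines bottlenecked for a mean of 40.3 generations
and whole-genome sequenced together with their unmutated ancestor. The
package covers variant acceptance (hard thresholds plus a cross-line
binomial consensus test), repeat and sequence-complexity annotation,
partitioned mutation-rate and spectrum estimation, mitochondrial
heteroplasmy rates, and a penalized-logistic model of site mutability.
Because the raw sequencing data are not an input, a first-class synthetic
generator produces complete MA experiments with known ground truth, and
the experiment's published summary tables are carried as fixtures from
which every derived Results statistic is recomputed.

## Rate model

For line *i* with `F` accepted mutations, `G_i` generations and `B`
callable bases in the queried genomic partition,

    mu_i = F_i / (G_i * B),

and the experiment-wide rate is the arithmetic mean of line rates with a
95% CI of `t_{0.975, n-1} * SEM` (the CI method is a package choice; with
n = 19–20 lines the *t* quantile matters). Per-line generation numbers are
first-class inputs; pooled statistics always weight by line. Substitutions
are strand-collapsed into six classes; transitions are A/T→G/C and
G/C→A/T. Trinucleotide contexts are collapsed with their reverse
complements into 32 keys (`AAT` and `ATT` around a focal A→T / T→A
mutation share one key).

The composition-normalized AT bias divides each direction's count by the
fraction of genomic sites able to produce it: AT-ward changes arise at
G/C sites, GC-ward changes at A/T sites. With uniform composition it
reduces exactly to the raw count fraction. The composition source
(genome-wide vs callable-site GC) is a parameter; the defaults use the
genome-wide value (0.36 for *C. elegans*).

Mitochondrial rates weight each heteroplasmic variant by its fraction of
quality reads, so a variant at 5% heteroplasmy contributes 0.05 events; a
multi-bp deletion counts once at its frequency. The per-line rate is
`sum(f) / (L_mt * G_i)` and the overall rate averages over *all*
sequenced lines, including the (many) lines without a mitochondrial
variant. `L_mt` defaults to 13,794 bp (the *C. elegans* mtDNA length) and
is overridable by a callable-site count — the published 2.18e-7 value
depends on this denominator; recomputing from the variant table with
L_mt = 13,794 and the per-line generation numbers gives 2.14e-7, within
rounding/denominator uncertainty of the printed value.

## Variant acceptance

Hard thresholds reproduce the study's pipeline: minimum RMS mapping
quality 30 (SNPs) / 40 (indels), at least 3 / 5 supporting reads, at
least 80% of high-quality calls supporting the variant, concordance of at
least two callers (represented as a caller-count on each call record; the
callers themselves are out of scope), and removal of any variant with
ancestral support.

The consensus stage estimates, at each candidate position, the
probability that a read calls the variant by chance as
`P = sum(K) / sum(N)` pooled over all sequenced lines (carriers
included), then scores each carrier line's evidence with the binomial
point mass `C(N,K) P^K (1-P)^(N-K)`, computed in log space. A
Holm–Bonferroni step-down over all candidate p-values at alpha = 0.05
(alpha is a parameter; the original analysis does not state one) decides
retention experiment-wide. Polarity: *significant means retained* — the
read support is inconsistent with shared noise. A fixed variant private
to one line of twenty (K ≈ N ≈ 30, P ≈ 0.05) scores ~1e-39 and is always
kept; a systematic artifact present at K ≈ N/2 in every line has P ≈ 0.5
and unremarkable per-line evidence, and is removed. The point mass is
implemented as printed; it is not a conventional tail p-value, so an
upper-tail mode `P(X >= K)` is available and flagged in outputs when
used. Undefined-P candidates (no coverage anywhere) go to a quarantine
list, never silently dropped.

## Repeats and complexity

The repeat catalog uses IMEX-style criteria: homopolymers ≥ 6 bp,
di-/tri-nucleotide motifs with ≥ 4 whole repetitions, tetra- to
hexa-nucleotide motifs with ≥ 3. Runs are maximal perfect whole-unit
runs; an interruption splits a region into sub-runs evaluated
independently; motifs must be aperiodic so poly-A is a homopolymer, not
(AA)n; N splits runs. A variant is `in_repeat` when inside a run and
`adjacent` within a 1 bp flank (the adjacency distance is configurable;
no numeric rule is stated in the source analysis, and only in-run or
within-flank positions are counted — imperfect spacer bases are not).
The detector is validated against a brute-force enumerator of all
(start, unit, copies) triples.

Sequence complexity of a window of length n with overlapping-triplet
counts `c_t` (l = n−2) is `S = sum_t c_t(c_t−1) / (2(l−1))`: zero when
all triplets are distinct, maximal for homopolymers. Note the polarity:
larger S means *more repetitive* sequence, while reports about "lower
complexity" near indels are directional claims on the complement; reports
therefore expose both raw S and the normalized complement
`1 − sum c_t(c_t−1)/(l(l−1))`. Windows are 41 bp centered on the site,
truncated at contig edges (flagged below 21 bp); windows containing N are
flagged unavailable.

## Mutability model

Training data are the unique substitution sites (response 1) plus a large
uniform sample of non-mutated callable sites (response 0; collisions
redrawn). The ~100:1 to ~320:1 class imbalance is preserved, not
reweighted: predicted probabilities are meaningful in relative terms
only. Predictors: chromosome, functional class, collapsed trinucleotide
context and chromatin state as indicator blocks; recombination rate,
41-bp GC and 41-bp S as numerics; germline expression, repeat membership
and A/T-cluster membership as binaries.

The fit is elastic-net-penalized logistic regression in the glmnet
parameterization (per-observation mean log-loss plus
`lambda [(1−alpha)/2 ||c||² + alpha ||c||₁]`), features standardized
internally, coefficients reported on the original scale, odds ratios
`OR = e^c`. Defaults lambda = 6.83e-5 and alpha = 0.01 follow the
reference analysis, but lambda is dataset-specific and can be re-selected
as the minimizer of 10-fold cross-validated deviance
(`select_lambda_cv`). With lambda = 0 the fit reproduces the unpenalized
MLE (checked against `statsmodels` to <1%); with lambda → ∞ all
coefficients vanish.

Predicted mutabilities over [0, 0.12] are combined into bins of width
0.015 (eight bins) and the per-bin rate `SNP_b / (B_b G)` is regressed on
the bin midpoint. The regression weights bins by their site count `B_b`:
under Poisson counts the variance of a bin's rate scales as `1/B_b`, and
on megabase-scale simulated genomes the top bins hold only tens of sites,
so an unweighted fit would be driven by the noisiest bins. At genome
scale every bin is huge and the weighted and unweighted fits coincide;
`weight_by_sites=False` restores the plain regression.

## Synthetic experiments: what they emulate, and what they do not

The generator's defaults are the study conditions. The genome is 1 Mb
across two autosomes and an X (scaled down from 100 Mb), GC 0.36, with
tip/arm/core recombination domains (7/26/47 proportions, normalized, with
domain-level cM/Mb values), gene models with frame-consistent exons,
chromatin-state blocks, A/T-clusters, and planted homopolymers (6–16 bp,
AT-rich), dinucleotide microsatellites of the four motif families and a
few longer-unit repeats, at per-Mb densities chosen once to resemble an
AT-rich nematode genome while giving every run length a usable census.

Mutations are planted per line as fixed (homozygous) events — matching
the post-MA inbreeding design; heterozygosity is out of scope — at class
rates derived from the observed knockdown spectrum (total SNP rate
0.42e-7, indel 2.23e-7, deletion:insertion 1.94), with the transition
share adjusted so the planted Ts/Tv equals the per-line mean of 1.15.
Indel events are allocated 80% to homopolymer runs (per-run weight given
by length-multiplier tables peaking at 11 bp for A/T and 8 bp for G/C
runs — the observed hotspot structure), 4% to dinucleotide runs (with
family-specific insertion/deletion tendencies: AT/TA insertion-biased
2:1, CG/GC deletion-only), and the rest to background sites with a
96%-1-bp size distribution. 80% of A/T→T/A transversions are placed at
A/T homopolymer boundaries with run choice proportional to length,
emulating the observed boundary concentration and its length correlation.
The X chromosome receives a 0.86x substitution and 1.15x indel factor
(site-selection weights are renormalized so genome-wide class rates stay
exactly as configured). At most one hit per (line, site); run events
slide to the next unit-aligned slot within the run so hotspot runs can
take several events per line without biasing totals, and the generator
warns if the per-site hit probability exceeds 10%.

Read evidence: carrier support `K ~ Binom(N, 1−e)` with
`N ~ Poisson(depth)`; non-carrier lines see scattered errors toward the
specific allele at rate e/3 per read; error-only noise sites put
`K ~ Binom(N, e)` in every line, emulating the shared systematic noise
the consensus test targets; the ancestral control is an extra library
with no planted variants whose lenient caller reports a putative call at
K ≥ 2 and K/N ≥ 0.2.

Not emulated: mapping/alignment artifacts, indel realignment ambiguity,
coverage heterogeneity along the genome, length-dependent direction
switching within G/C runs (net gain below ~9 bp), mitochondrial variant
calling (heteroplasmy rates are exercised on the published variant table
and constructed cases), CNV and rDNA copy-number dynamics (out of scope),
and selection/fitness effects. Passing recovery tests therefore shows the
estimators and filters are correct and unbiased under the stated
generative model, not that the pipeline is robust to every artifact of
real short-read data.

## Problem sizes and numerical choices

The recovery suite uses a 1 Mb genome, 20 lines, G = 40 and class rates
scaled 100x above the study values — about 21,000 planted mutations and
10,000 noise sites — sizes chosen so every class has enough events for
3-SE comparisons while a full run stays in seconds. The mutability
recovery uses 1e5 sites with a planted repeat log-odds of 1.5. Binomial
masses are computed via log-space `scipy.stats.binom` (checked against
exact rational arithmetic to 12 significant digits for N ≤ 30, stable to
N = 1e5). Ties in Holm–Bonferroni keep stable original order. Repeat
association returns the longest overlapping run on ties. Indel partition
assignment uses the left-aligned VCF anchor base; an indel spanning a
boundary is assigned by its anchor. Exon label takes precedence over
intron for overlapping gene models. Ka/Ks site counting is
Nei–Gojobori-style fractional counting, isolated behind
`synonymous_site_counts` so the counting scheme can be swapped.

## Known limitations

Recombination-domain boundaries are an input layer (BED), not re-derived
by segmentation. The binomial verification uses the point mass as
printed; users wanting a conventional test should enable the tail mode.
Per-line and pooled summary statistics (e.g. Ts/Tv 1.15 vs 1.12) are both
reported and neither is forced to match the other. The published
raw-data-scale results (3,125 SNPs, 10,861 indels, the fitted lambda and
variance explained) require the original sequencing data and are covered
here only by the scaled-down property suites.
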