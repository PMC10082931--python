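# Methods

This note documents the models implemented in `ponet`, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Polysome occupancy and the noise filter

Expression values are log2 intensities for two fractions, total (T) and
polysomal (P), on a shared (stage, replicate) grid. Polysome occupancy is
the difference of log2 values, `PO = log2 P − log2 T`; no re-normalisation
is applied, so any additive artefact common to both fractions cancels.

Two noise-filter variants are provided, matching the two uses upstream of
differential calling and network construction respectively:

- `all-samples` removes a gene only when *every* value in both fractions is
  below the threshold (default 4.0 log2 units);
- `any-stage-either-level` keeps a gene whose per-stage replicate mean
  exceeds the threshold at one or more stages in either fraction.

## Moderated differential PO

Per gene and consecutive-stage contrast, an ordinary two-sample comparison
of replicate PO values is moderated by empirical-Bayes variance shrinkage.
The prior `(d0, s0²)` of the scaled inverse-chi-square model is estimated by
matching the mean and variance of `log s²` to their theoretical values
(digamma/trigamma identities; the trigamma equation is inverted by Newton
iteration). The posterior variance is `s̃² = (d0·s0² + d·s²)/(d0 + d)` and
the moderated t uses `d + d0` degrees of freedom. When the observed spread
of `log s²` does not exceed the chi-square contribution — as happens when
all true variances are equal, the case in the synthetic data — `d0 = ∞` is
used, i.e. complete pooling, with a warning. Calls require
`|log2 FC| > 1` **and** BH FDR `< 0.05`; both thresholds are configurable.

The implementation is self-contained rather than delegating to an external
fitting package: the statistic is the contract, and its two limits
(`d0 = 0` → ordinary t; `d0 = ∞` → pooled variance z) anchor the tests.

## Clustering, PCA, absorbance traces

PO stage means (replicate mode available) are clustered by average-linkage
hierarchical clustering on Euclidean distance; the cluster number maximises
the mean silhouette width over k = 2…20, ties resolved toward smaller k,
with a degenerate flag when all profiles coincide. Sample PCA is a
gene-centred SVD. Ribosome abundance from an A254 gradient trace is the
trapezoidal area of the blank-subtracted signal (negatives clipped — 
absorbance below the blank is noise) over a region, normalised by the total
area.

## The inference crowd

All scorers consume the replicated PO matrix (replicates as columns, never
averaged) and emit non-negative dependence scores; signs are kept as
metadata. Defaults:

| method | definition | default parameters |
|---|---|---|
| pearson / spearman | absolute correlation | — |
| anova | η² of target grouped by quantile bins of the source; asymmetric | 4 bins |
| clr | MI z-scored against each gene's off-diagonal row background, combined as √(z_i⁺² + z_j⁺²) | MI: equal-frequency binning, ⌈√n⌉ bins, plug-in estimator (bits) |
| aracne | data-processing-inequality pruning of the MI matrix, `MI_ij < min(MI_ik, MI_jk)·(1−ε)` against the original matrix | ε = 0 |
| pcor | partial correlation from a correlation matrix shrunk toward the identity with the analytic (Ledoit–Wolf/Schäfer–Strimmer) intensity | — |
| genie3 | per-target extremely-randomised-trees importance, normalised to sum 1 | 100 trees, √p features, seeded |

CLR row statistics exclude the diagonal (which stores H(X)). NARROMI and
TIGRESS are accepted as names but are explicit plugin slots without
implementations; the aggregation is defined for any method subset.

## Top1 consensus, directionality, threshold

Each method's pair scores become descending **competition ranks**: ties
share the smallest applicable rank and the next distinct score resumes at
its positional rank, so `rank/n_pairs` is a quantile on any problem size.
A zero score is an *abstention* — the method reports no dependence (an
ARACNE-pruned edge, a rectified-zero CLR value) — and takes the worst rank
instead of a tied block rank; without this rule a method with a large zero
block would hand nearly every pair a top rank. Asymmetric methods are
reduced to pair level by their better orientation before ranking;
orientation-resolved ranks are retained separately.

Top1 keeps each pair's best rank across methods;
`score = 1 − (best − 1)/(n_pairs − 1)`. The supporting methods are those
achieving the best rank, and the emitted edge order is fixed by
(best, second-best, pair id). An edge is *orientable* when an asymmetric
method is among its supporters; it is *oriented* only when every supplied
asymmetric table prefers the same direction strictly (unanimity; margin
configurable, default 0). This conservative rule yields a small directional
fraction, and the agreement requirement filters out coin-flip orientations.

The threshold scan evaluates node/edge counts, the log–log degree-histogram
R² (OLS of log10 frequency on log10 degree over nonzero-count bins; three
distinct degrees required) and global transitivity on the nested
subnetworks; the selected threshold maximises R² among candidates retaining
a minimum node count, ties resolved toward the larger network. The
library-level scan default is the published-style extreme window
[0.9999, 1] step 1e-5, which targets the top ~1e-4 quantile of a ~3·10⁷-pair
ranking; the pipeline default widens it to [0.90, 1] step 5e-4 because its
network stage ranks ~1.1·10⁴ pairs, where the equivalent top-fraction window
is broader. The "ACC 0.4" reported alongside the published threshold
conflates an information criterion with average clustering; this package
reports transitivity along the whole scan and computes no AIC.

## Map-equation modules

Undirected flow: node visit rates are `strength/(2W)`; directed mode uses
PageRank with teleportation 0.15. The two-level map equation

`L(M) = q·H(Q) + Σ_i p_i·H(P_i)`

is evaluated in bits with module exit rates `q_i = cut_i/(2W)`. The
optimiser performs seeded greedy single-node moves with incremental
codelength bookkeeping, followed by Louvain-style module-aggregation passes
(self-loops from aggregation carry no cut flow), best of 10 restarts. The
hierarchy re-partitions each module's induced subnetwork recursively while
the split lowers that subnetwork's own codelength — a nesting-guaranteed
simplification relative to optimising a full multilevel map equation, and a
documented deviation from the reference implementation. Hubs are module
nodes with induced-subnetwork degree ≥ 4 (the cutoff is a parameter), and
GLIs are the directed edges, optionally restricted to one module.

## Sequence, structure and motif features

GC3 is the GC fraction at third codon positions. Nc uses Wright's formula
`Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6` with the **plain plug-in**
homozygosity `F = Σ p̂²`, so uniform synonymous usage gives exactly 61 and
single-codon usage exactly 20 (the bias-corrected estimator is available by
flag). CDSs must start with ATG, contain no internal stop and have ≥ 100
codons; UTRs count as present only when longer than 1 nt. Distribution
comparisons use the two-sample rank-sum test (exact for tie-free samples of
n ≤ 10, else normal approximation with tie correction): the compared sets
are unpaired and of unequal size, so a signed-rank (paired) test cannot
apply.

Structure tracks are resampled per region onto 100 relative bins (bin b
averages the nucleotides overlapping [b/n, (b+1)/n); short regions share
nucleotides so every bin is populated), then averaged across genes with
standard errors; set contrasts are per-bin two-sample t tests.

PWM scanning is forward-strand (mRNA is single-stranded) with log-odds
scores against a 0-order background (default: composition of the scanned
sequences; pseudocount 1e-4 where the background is zero under a nonzero
column). P-values are exact: scores are integer-scaled (factor 1000) and
the null score distribution is built by dynamic-programming convolution
over the PWM columns; hits require p < 0.001. Motif enrichment is the
one-tailed Fisher exact test on (in set / not) × (≥1 hit / none).
Positional profiles map each hit to `offset/(L − w + 1)` and bin into 100
relative positions, normalised by set size.

Ontology enrichment is the parent–child test (union variant by default,
intersection by flag): each term's hypergeometric draw is restricted to the
genes annotated to the union of its parents (roots use the whole universe),
with BH correction and an FDR ≤ 0.05 report threshold. When a term's parent
union equals the universe the test reduces exactly to the classic
hypergeometric test.

## The synthetic generator

The generator emulates the *statistical shape* of a two-fraction microarray
time course: 9 ordered stages (4 maturation + 5 germination), 3 replicates,
log2 intensities with a noise floor near 4.

- **Total signal**: per-gene random walk over stages (step sd 0.3, start
  uniform on [5, 11] log2 units) — the walk gives realistic stage
  autocorrelation without modelling transcription.
- **PO signal** is additive on the log2 scale so `compute_po` recovers it
  exactly in expectation: a signed step (effect ~ N(1.5, 0.25²)) at the
  designated transition for 200 up / 100 down genes; a shared standardised
  template (amplitude 1.0) for each of 3 co-trajectory modules of 20 genes;
  and for cascades, `target(s) = 0.8·regulator(s − 1) + N(0, 0.1)` for 10
  regulators with 3 targets each.
- **Regulator trajectories** are moving-average-smoothed random walks
  (window 3, sd 1.5). Smoothness matters: the scorers see contemporaneous
  samples only, so a 1-stage-lagged dependence is detectable and orientable
  only when the driving trajectory is autocorrelated — which is also what a
  developmental regulator looks like. With an unsmoothed (white-step) walk
  the planted cascade is statistically invisible by construction.
- **Replicate noise** sd 0.2 (log2), independent in both fractions; 5% of
  background genes sit entirely below the noise floor to exercise the
  filter.
- **Transcripts**: UTR5 (150 nt) + CDS (450 nt incl. stop) + UTR3 (200 nt)
  from a 0-order composition (A/C/G/T = 0.3/0.2/0.2/0.3); module genes
  receive a PWM-*sampled* (not consensus) insert in the 5ʹUTR with
  probability 0.6 vs 0.05 elsewhere; a designated set can get a CDS GC
  shift. Structure tracks are N(0.35, 0.1²) per nucleotide clipped to
  [0, 1], with +δ over the CDS of a designated set.

What it does **not** emulate: probe-level hybridisation or normalisation
artefacts, stage-dependent variance, correlated replicate noise, realistic
codon usage or UTR length distributions, tissue mixtures. Passing recovery
tests therefore demonstrates the *algorithmic* correctness and calibration
of the pipeline under its stated assumptions, not performance on real
arrays.

## Problem sizes and determinism

The pipeline default analyses 1,000 synthetic genes; the quadratic network
stage runs on the 150 most PO-variable genes (11,175 pairs), a standard
variance pre-filter that keeps the crowd inexpensive while retaining the
planted structure. Recovery statistics in the acceptance script are pooled
over 3 simulated replicates. All randomness flows from one master seed;
per-stage seeds are derived by stable hashing so stages are independently
reproducible, and identical seeds give byte-identical artifacts.

## Known limitations

- The η² scorer conditions on quantile bins of the putative source, a
  simplification of variance-decomposition scoring against experimental
  groupings; it is documented as an approximation.
- Orientation rests on weak asymmetries (prediction-residual asymmetry of a
  lagged linear link); accuracy is measured on recovered planted edges and
  is meaningful only in aggregate.
- Plug-in MI and η² are biased upward at small sample counts; the null
  calibration tests quantify rather than remove this bias.
- The two-level-recursive hierarchy need not match a true multilevel
  map-equation optimum.
- `GeneNet`-style shrinkage partial correlation is weak in the p ≫ n regime
  of the default problem size; it participates in the crowd regardless.
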