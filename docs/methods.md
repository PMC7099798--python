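# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each stage of the package. It describes what the code
computes; every empirical figure quoted here is one the test suite or
`scripts/acceptance.py` recomputes.

## Coordinates, symbols and inputs

All genomic coordinates are 0-based half-open, the native convention of BED
and refFlat; readers for any 1-based dialect would convert at the boundary.
Gene symbols are whitespace-trimmed and upper-cased before any comparison;
no alias or identifier mapping is attempted, so two catalogues naming the
same gene differently stay distinct members. Chromosome names are matched
with the `chr` prefix stripped and written back as read. Rows sharing a
gene id collapse to the widest span (min start, max end) with a logged
warning; cytogenetic arms split at the start of the lexicographically first
q-band, and a chromosome with no q-band is treated as a single p arm.

## Sliding-window co-distribution

Windows start at 0, s, 2s, … while start < L, with end = min(start + w, L);
defaults w = s = 1 Mb. A gene is assigned to the window(s) containing its
start coordinate — with s = w exactly one window per gene, so window tallies
conserve the gene count (a midpoint rule is available via `by='midpoint'`).
Per window, ratios r_A = n_A/n_ref and r_B = n_B/n_ref are formed where
n_ref > 0.

The co-distribution statistic defaults to Pearson correlation of
(log10 r_A, log10 r_B); the log transform is undefined at zero counts, so
windows with any of n_ref, n_A, n_B at zero are excluded and their number
always reported. Spearman and an untransformed variant are flags, because
the summary correlation of this kind of analysis is reported in the
literature without the estimator being named; the choice is exposed rather
than guessed. A zero-variance ratio track yields r = 0 with a warning.

Significance comes from a membership permutation: set B is redrawn
uniformly from the annotated genes (size preserved), the correlation
recomputed, and p = (1 + #{r_null ≥ r_obs}) / (1 + n_perm). Permuting
memberships rather than positions preserves the reference density
landscape. Seeds are mandatory.

Chromosome/arm over-representation uses the hypergeometric distribution
with N annotated genes, K in the category, n query genes and overlap x:
expected = n·K/N, p doubles the upper tail when x ≥ expected and the lower
tail otherwise, capped at 1. The tie x = expected is deterministically
labelled "up" with the upper-tail p. A generic two-sided Fisher 2×2 test is
provided; the pipeline documents one construction (set membership × on/off
chromosome) without claiming it is canonical.

## Over-representation analysis

p = P(X ≥ x) = Σ_{k=x}^{min(K,n)} C(K,k)·C(N−K,n−k)/C(N,n), evaluated via
the scipy hypergeometric survival function (log-space internally). Study
genes outside the background are dropped with a logged count; terms with
fewer than 2 background members are skipped to avoid degenerate p = x/N
artifacts. Adjustment is Benjamini–Hochberg step-up by default (the
convention of the standard enrichment tooling; Bonferroni by flag), and
rows carry GeneRatio x/n and BgRatio K/N.

## Expression preprocessing

Probe input is a positive intensity matrix (TSV) with a probe→gene map and
sample metadata; binary chip formats are out of scope. The fixed order is
background correction → quantile normalization → log2 → median polish.

**Background (normexp).** Observed o = s + n with signal s ~ Exp(α) and
background n ~ N(μ, σ²). Per chip, μ is estimated as the histogram mode
(√n bins), σ as the RMS deviation of values below μ, α as the reciprocal
mean excess above μ; known parameters can be injected. The corrected value
is the posterior mean E[s | o]: a normal with mean a = o − μ − σ²α and sd σ
truncated to (0, o), evaluated in closed form
a + σ·(φ(−a/σ) − φ((o−a)/σ))/(Φ((o−a)/σ) − Φ(−a/σ)). (o−a)/σ > 0 always,
so the only degenerate regime is a ≪ 0, where the exact tail limit σ²/(−a)
replaces the ratio. The output is strictly positive and monotone in o; the
parameter estimators are deliberately simple and rough — the tests
demonstrate that the posterior mean beats naive subtraction o − μ in mean
absolute error, not that the estimates are efficient.

**Quantile normalization.** The reference distribution is the across-chip
mean of each order statistic; each chip's values map to the reference value
at their rank, ties taking the mean of the tied reference values (average
ranks with linear interpolation). The operation is idempotent and preserves
within-chip ranks; a single chip passes through with a warning.

**Median polish.** Per gene, log2 intensities fit overall + probe + sample
effects by alternating row/column median sweeps; the summarized expression
is overall + sample effect. The stop rule watches the magnitude of the
sweep medians (< 1e-6, max 10 sweeps by default) rather than the change in
the sum of absolute residuals: on even-sized tables that sum stalls while
the medians still oscillate (decaying), and the magnitude rule is what
guarantees residual row/column medians vanish at convergence. Genes with
equal probe counts are polished together as a 3-D stack for speed; results
are identical to gene-at-a-time polishing and invariant to probe order.

## Differential expression

Contrasts follow the two axes of the sample design: the same region at
adjacent stages (s vs s+1, hemisphere-stratified — the two hemispheres are
reported separately in this kind of design) and any two regions at the same
stage (hemispheres pooled). Comparisons with an empty group are dropped and
logged; donors are treated as independent samples, mirroring the design
description this analysis follows rather than "fixing" it.

Per comparison and gene: log2FC = mean(group2) − mean(group1); pooled
variance s²_g with d_g = n₁+n₂−2 df; moderated t as in the README with the
prior (d₀, s₀²) estimated across genes by moment matching on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): ψ′(d₀/2) equals the excess of the
empirical variance of e over the mean sampling term ψ′(d_g/2) (solved by
bracketed root-finding on the strictly decreasing trigamma; d₀ = ∞ when the
excess is non-positive, in which case the reference distribution is normal
and s̃² = s₀² = exp(ē)). d₀ = 0 recovers the ordinary pooled t exactly. The
implementation agrees with the limma reference implementation (lmFit +
eBayes) to ~1e-5 on a shared fixture, verified through Rscript in the test
suite. p-values are two-sided from t with d_g + d₀ df; BH adjustment is
applied within each comparison (a global-adjustment flag exists, off by
default). Genes with zero posterior variance at d₀ = 0 are flagged
undefined and excluded from adjustment. The screen is pass ⇔ adj.P < α
(strict) AND |log2FC| ≥ log2(FC) (inclusive), defaults α = 0.05, FC = 2.

Counts of passing genes are arranged as a symmetric region × region matrix
per stage and as per-(stage-pair, hemisphere, region) vectors for the
adjacent-stage axis. The gene set entering the three-way intersection is
the union of passing genes over all comparisons (restrictable by kind);
trajectories report the arithmetic mean log2 expression per (gene, region,
stage) with hemispheres and donors pooled.

## Synthetic data

**Genome.** Defaults mirror the study shape at desk size: 22 autosomes + X
with hg38-proportional lengths scaled to 100 Mb, 20,000 reference genes,
|A| = 1905, |B| = 244. Cluster centers follow a Neyman–Scott model (uniform
centers, Gaussian offspring, σ = 300 kb, 25 clusters) with lognormal(0, 1)
cluster weights. Set A keeps a 50% genome-wide uniform backbone with the
other half drawn by the centers' Gaussian-kernel weights — matching a large
disease catalogue that is broadly distributed with hotspots — while set B
is the strongly clustered set: a fraction ρ of its members is drawn with
the same cluster weights (co-clustering), the rest uniformly. ρ = 0.9 is
the default planted condition; ρ = 0 gives independent sets. The backbone
also keeps enough usable windows (~90 of 100) for the null correlation to
concentrate: E|r| ≈ √(2/(πn)) for independent tracks, so a fully clustered
A (~40 usable windows) could not satisfy a |r| < 0.1 null on average no
matter the implementation. Both sets are subsets of the annotation, so set
tallies are bounded by reference tallies and a three-way intersection with
DE genes is well-defined.

**Expression.** Defaults are a fast desk-scale design: 2000 genes × 4
probes, 3 regions × 4 stages × 2 hemispheres × 2 samples per cell (the full
16 × 15 × 2 layout is a config away). True log2 expression is
baseline ~ N(8, 1) plus planted additive effects on samples matching a
(region, stage, hemisphere) selector. Per-gene residual sd is either drawn
from the scaled-inverse-χ² prior (d₀ = 4, s₀² = 0.25 by default — the
condition for the prior-recovery experiment) or fixed via `gene_sigma` (the
condition for the power experiment, which specifies a common σ = 0.5).
Probe intensity is 2^(expression + affinity), affinity ~ N(0, 0.5),
plus N(50, 10) background on the linear scale, then a per-chip monotone
distortion o → c·o^γ (c lognormal(0, 0.1), γ ∈ [0.97, 1.03]) so quantile
normalization has real work to do. Generators are pure functions of their
config and seed; emitted files are byte-identical across reruns and pass
the package's own readers.

What the synthetic data does **not** emulate: realistic gene catalogues or
inter-gene correlation, linkage or recombination structure, donor pairing
across stages, probe GC effects or batch structure. Passing tests
demonstrate the estimators recover structure they were told to plant under
the model's assumptions — they say nothing about annotation quality,
curation or batch pathology in real data.

## Problem sizes and runtime choices

The suite's recovery experiments use the default desk scale: 50 seeded
genome replicates per co-clustering condition with 199-permutation nulls;
variance-prior recovery at G = 10,000; one probe-to-screen run at
G = 2000 × 4 probes with 100 planted 4-fold effects and n = 5 per group;
100 all-null replicates for BH family calibration. These sizes keep each
experiment's Monte-Carlo error well inside the asserted margins while the
whole suite completes in well under a minute of compute per experiment.

## Known limitations

- The normexp parameter estimators (mode/RMS/mean-excess) are crude; for
  data near the background they bias μ upward. The injected-parameter path
  is exact.
- The moderated-t model assumes independent genes and equal within-group
  variances; the BH guarantee is on expectation over replicates, not on a
  single screen's realized false-discovery proportion.
- Arm-level enrichment assigns genes by start coordinate; genes straddling
  the centromere boundary count toward the arm of their start.
- The permutation null preserves set sizes and the reference landscape but
  not any within-set spatial autocorrelation beyond it.
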