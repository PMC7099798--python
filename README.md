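# imprintscape

Tools for asking whether two gene catalogues — for example a disease gene
list and the genomically imprinted genes — occupy the same neighbourhoods of
the genome, and whether those genes are the ones that switch expression
across brain regions and developmental stages.

The package bundles four analyses behind one pipeline:

1. **Sliding-window co-distribution.** Windows of width *w* advance by step
   *s* along each chromosome; per window the reference annotation, set A and
   set B are tallied and the ratios r_A = n_A/n_ref, r_B = n_B/n_ref formed.
   Their correlation across windows (Pearson on log10 ratios by default,
   windows with any zero count excluded) summarizes co-localization, with a
   membership-permutation null for significance and hypergeometric
   chromosome/arm over- and under-representation alongside (plus a plain
   Fisher 2×2 test).
2. **Over-representation analysis (ORA).** For a study set of n genes from a
   background of N, a term with K members and overlap x has
   p = P(X ≥ x) under X ~ Hypergeometric(N, K, n); Benjamini–Hochberg
   adjustment across terms.
3. **Microarray-style expression preprocessing.** Background correction
   under the normal + exponential convolution model (the corrected value is
   the posterior mean of the signal), quantile normalization (all chips share
   the mean empirical distribution) and median-polish summarization of
   probes into gene-level log2 expression. The three steps are
   sklearn-compatible transformers and compose in a `sklearn` Pipeline.
4. **Spatio-temporal differential expression.** Two-group contrasts between
   adjacent stages within a region and between region pairs within a stage,
   tested with the moderated t-statistic: the gene-wise variance s²_g (d_g
   df) is shrunk toward a moment-estimated prior s²_0 (d_0 df),

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t_g = log2FC_g / (s̃_g·√(1/n₁+1/n₂)),  df = d_g + d₀,

   and a gene passes the screen when adj.P < 0.05 and |FC| ≥ 2. Passing
   genes feed a three-way set intersection and per-(region, stage)
   expression trajectories.

Everything runs on synthetic data with planted truth: a genome generator
places cluster-seeded gene sets with a tunable co-clustering level ρ, and an
expression generator plants log2 effects with known variance structure, so
recovery and calibration are testable end to end.

## Worked example

Simulate a desk-scale genome (22 autosomes + X scaled to 100 Mb, 20,000
reference genes, |A| = 1905, |B| = 244, co-clustering ρ = 0.9) and measure
the co-distribution of the two sets at 1 Mb windows:

```
$ imprintscape simulate-genome --seed 11 --outdir demo
20000 genes, |A|=1905, |B|=244 -> demo

$ imprintscape coloc --annotation demo/genes.bed --chrom-sizes demo/chrom.sizes \
    --set-a demo/set_a.txt --set-b demo/set_b.txt \
    --permutations 199 --seed 11 --out demo/windows.tsv
r=0.908828	n_windows=46	perm_p=0.005
```

The two planted-together sets correlate strongly (r = 0.91 over the 46
windows where all three tallies are positive) and no permutation of set B's
membership reaches the observed correlation (p = 0.005 with 199
permutations). `demo/windows.tsv` holds the per-window tallies and ratios:

```
chrom	start	end	n_ref	n_a	r_a	n_b	r_b
chr1	0	1000000	179	4	0.0223464	0	0
chr1	1000000	2000000	213	23	0.107981	0	0
```

The full pipeline — genome, co-distribution, enrichment, preprocessing,
differential expression, intersection, trajectories — runs from one YAML
config with a single seed:

```
imprintscape run --config analysis.yaml
```

and writes every intermediate table plus a manifest with per-artifact
checksums; rerunning the same config reproduces the checksums byte for byte.
Library use mirrors the CLI (`simulate_genome`, `count_in_windows`,
`ora_test`, `rma_preprocess`, `ModeratedTTest`, `run_pipeline`, ...); see
`docs/methods.md` for the statistical details and design choices.

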