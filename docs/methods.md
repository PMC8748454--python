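# Methods

## Differential expression

Each drug is contrasted against the pooled vehicle controls of the same
cell line. Expression values are assumed to be log-scale and already
normalized; normalization is a documented precondition, not a pipeline
stage. For gene g with treated/control group sizes n₁, n₂ and residual
degrees of freedom d = n₁ + n₂ − 2, the pooled variance s²_g is shrunk
toward a prior:

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),
    t_g  = (x̄₁ − x̄₂) / sqrt(s̃²_g (1/n₁ + 1/n₂)),   t_g ~ t(d₀ + d).

The prior (d₀, s₀²) is fitted by method of moments on z_g = log s²_g:
under the scaled-F sampling model, E[z] and Var[z] are digamma/trigamma
expressions in d and d₀, so matching the sample mean and variance of z
and inverting the trigamma function (Newton iteration) yields d₀ and s₀².
When the observed log-variances are underdispersed relative to pure
sampling noise the prior is effectively infinite; d₀ is capped at 10⁶,
which only guards floating-point overflow. Treated groups of size one are
permitted (variance is then estimated from controls alone and moderated)
and flagged in the contrast metadata.

Degenerate inputs: with `prior_df=0` requested explicitly, zero-variance
genes raise an error rather than dividing by zero. Under the default
empirical-Bayes path, data with *no* positive-variance genes (an exactly
noise-free dataset) take the analytical limit instead: genes with a
nonzero mean difference get p = 0, flat genes p = 1. This keeps the exact
zero-noise regime — useful for planted-truth validation — flowing through
the same code path as real data.

P-values are Benjamini–Hochberg adjusted (statsmodels). Up/down lists are
`p_adj < alpha` split by the sign of the log-fold-change with an optional
magnitude floor `lfc_min`; defaults alpha = 0.05, lfc_min = 0, always
recorded in the output. A drug is *analysable* when its combined list has
at least `min_list_size` (default 1) genes; the rule is explicit because
on real compendium data it determines how many of the assayed compounds
survive to the screen.

## Enrichment and rank integration

All libraries are scored with a single one-sided hypergeometric
(Fisher-exact) overlap test against the measured gene universe (the
expression matrix's genes by default, configurable). Real multi-resource
TF-enrichment tools use a different internal statistic per resource; a
uniform test was chosen deliberately for reproducibility and testability
— the integration layer (MeanRank over per-library ranks) is agnostic to
the per-library statistic.

Within a library, TFs are ranked by ascending p with deterministic
tie-breaks (larger overlap, then lexicographic TF id). MeanRank averages
a TF's rank over libraries; a TF absent from a library is assigned rank
(library size + 1) — absence is evidence against, but finite — with a
config switch to average over present libraries only.

Mean ranks have no analytic p-value, so significance is empirical: in
each library, the deepest rank position whose enrichment p is strictly
below alpha (0 if none); the average of these positions over libraries is
the threshold; TFs with mean rank ≤ threshold are significant. The
boundary is closed because a TF sitting exactly at the threshold position
is deemed significant; a strict-inequality flag is provided. "Deeper rank"
is well defined since rankings are p-ascending. Note the direction: rank 1
is the *strongest* enrichment, so "above the threshold position" means
numerically smaller mean rank.

A TF significant for both the up- and the down-list of the same drug is
excluded (its target evidence is contradictory); excluded cells are
carried as their own state and contribute nothing to scoring, exactly
like unchanged TFs.

## Scoring and ranking

The pro-differentiation score of a drug over a TF panel is
#(activated panel TFs) − #(repressed panel TFs), an integer in
[−|panel|, +|panel|]. Drugs are ranked by descending score; ties break by
more activated TFs, then lexicographic drug id, making the ranking a
deterministic function of the activation matrix. Panel filtering can drop
drugs with no nonzero panel state ("inert" drugs), mirroring the
reduction of a full compound screen to the panel-active subset.

## Robustness analysis

Profiles are one vector per (drug, cell line): in expression space the
mean treated expression across replicates; in TF space the signed
activation states (excluded → 0), or optionally negated mean ranks.
Both sets are embedded with tSNE (2-D, seeded random initialization,
exact gradient for small n; default perplexity min(30, (n−1)/3 − ε)).
For every drug profiled in ≥2 cell lines, Euclidean distances between its
cross-cell-line point pairs are collected.

Because tSNE coordinates have no intrinsic scale — two separately fitted
maps are only defined up to their own spread — same-drug distances are
expressed by default in units of the map's mean pairwise distance over
all points. Without this normalization the comparison between the
observed map and the randomized-data map measures overall map scale, not
same-drug similarity; a flag restores raw distances.

The null model randomizes each profile by permuting its feature values
within the profile (seeded), preserving every profile's value
distribution while destroying gene/TF identity. The observed and
randomized same-drug distance distributions are compared with a
two-sample Kolmogorov–Smirnov test: D = sup |ECDF₁ − ECDF₂| evaluated at
the pooled sample points; p from the asymptotic Kolmogorov distribution
by default, or by group-label permutation — exhaustive enumeration when
C(n₁+n₂, n₁) is small enough, otherwise a seeded Monte-Carlo sample.

One property of this design worth knowing: the randomization preserves
per-profile value multisets, so under a true null the observed and
re-randomized distance samples are positively dependent and the
observed-vs-random KS test is *conservative* (its null p-values are
stochastically larger than uniform). The test therefore controls the
type-I error rate but understates significance; the test suite checks
the one-sided control and, separately, exact calibration of the
permutation machinery on independent samples.

## Synthetic data

The generator emulates the structure of a perturbation compendium:

- **Libraries.** The gene universe is partitioned into one candidate pool
  per TF; each library draws that TF's target set from the pool, sharing
  a core fraction `overlap_frac` (default 0.8) across libraries and
  filling the rest with library-specific picks. Partially concordant
  libraries give MeanRank something nontrivial to integrate. Disjoint
  pools are a deliberate idealization — real regulons overlap — chosen so
  planted regulons are identifiable and exact recovery is a meaningful
  target; consequences: cross-TF enrichment leakage is absent, so
  precision estimates on synthetic data are optimistic relative to real
  libraries.
- **Expression.** Per-gene baselines ~ N(7, 1) on the log scale;
  per-(cell line, gene) offsets ~ N(0, `cell_line_offset_sd`²), default
  2.0, which produces the cluster-by-cell-type behaviour of real
  compendia in expression space; i.i.d. Gaussian noise with sd
  `noise_sd`, default 0.5. Optionally, per-gene noise variances are drawn
  from a scaled inverse chi-square (`gene_noise_df`), the heteroscedastic
  regime under which variance moderation is exactly calibrated; the
  default is homoscedastic, under which the moderated test is measurably
  but mildly conservative (≈4.8% rejections at nominal 5% with 500 genes
  and 3v3 groups), because the estimated prior df is finite while the
  true variance distribution is degenerate.
- **Programs.** A drug program assigns ±1 to a few TFs and shifts every
  target of those TFs (union over libraries) by ±`effect_size` in all
  cell lines — the "shared transcriptional circuit" that TF profiles are
  supposed to recover across cell lines.
- **Common random numbers.** Standard-normal deviates depend only on
  (seed, shape) and are scaled by `noise_sd` afterwards, so recovery
  across an effect × noise grid at a fixed seed is monotone by
  construction rather than confounded by resampling.

What the generator does **not** model: probe-level microarray artifacts,
batch structure, correlated gene–gene noise, overlapping regulons,
cell-line-specific drug response programs, and dose effects. Passing
planted-truth tests therefore demonstrates correctness of the inference
machinery, not performance guarantees on real compendium data.

## Study sizes used in validation

The validation suite and `scripts/acceptance.py` use: 7 libraries ×
50 TFs × 2000 genes × 100 drugs × 3 cell lines for exact zero-noise
recovery; a 3 × 3 effect (0.3/1.0/3.0) × noise (0.2/0.6/1.8) grid with
3 libraries, 20 TFs, 600 genes, 15 drugs for monotonicity; 5 libraries,
20 TFs, 800 genes, 20 drugs × 3 cell lines at noise 0.5 / offset 2.0 for
the robustness comparison; and 200 replicates of a 500-gene, 25-TF,
single-null-drug configuration (full-coverage regulons with per-library
target fraction 0.04 < alpha, heteroscedastic gene noise, df 10) for null
calibration. These sizes were chosen as the smallest configurations at
which each property is comfortably resolved.

## Known limitations

- The uniform hypergeometric statistic ignores per-resource evidence
  types (binding proximity, co-expression strength).
- The empirical threshold couples significance to library size and list
  length; very small libraries make the threshold coarse.
- With `missing="penalize"`, TFs annotated in few libraries are hard to
  call significant even with strong evidence in those libraries.
- tSNE-based distances depend on perplexity and seed; both are recorded,
  and a feature-space distance flag bypasses the embedding entirely.
- The conservative null of the robustness comparison (see above) means
  reported KS p-values are lower bounds on the true null tail
  probability.
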