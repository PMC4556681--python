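# Methods

## Model and estimation

A reaction-chamber measurement on a parallel qPCR array is modeled as an
additive composition on the Ct (cycle) scale,

    Y = ε_P:A + ε̃ + ε_S + Δ_T + Δ_T:G + ε,

with probe-per-array, batch, and sample errors removed and the treatment
signal (global shift Δ_T, per-gene effect Δ_T:G) plus the residual retained.
The additive scale is natural for Ct: one cycle is one doubling, so additive
cycle effects are multiplicative abundance effects.

All effects are estimated as arithmetic group means (a median variant sits
behind `LemOptions(robust=True)` but is not the default, because the model
is defined through means and the mean keeps the decomposition exactly
additive). Estimation is sequential, each step on the previous step's
residuals, in a fixed order:

1. **Probe per array** — per-(gene, array) mean. On a single array this also
   absorbs the gene's baseline level, which is deliberate: only contrasts
   between conditions are of interest, and the per-gene constant cancels in
   the −ΔCt output.
2. **Batch effects** — per batch factor. A factor nested inside the
   biological replicate (e.g. repeated cDNA conversions of one RNA sample)
   is estimated as within-replicate level means, which are orthogonal to the
   treatment by construction. A factor that cuts across treatment groups but
   is not confounded with them is estimated from group-centred level means.
   A factor whose levels coincide with treatment groups is skipped with a
   warning: a group-wise offset and the treatment are indistinguishable from
   chip data. The escape hatch is an external measurement: with
   `use_ssdna_covariate=True` the per-sample mean residual is regressed on
   centred log2 single-stranded cDNA quantity and the fitted values are
   removed, which restores the treatment contrast when the apparent shift is
   a loading artifact.
3. **Global treatment shift** — per-group mean over all genes and records
   (record-weighted; with unequal missingness per gene a gene-weighted mean
   would differ, and the record-weighted choice keeps the decomposition
   exact).
4. **Sample error** — per-sample mean of the *step-2* residuals minus the
   sample group's Δ_T. Doing step 3 before step 4 is essential: per-sample
   means soak up whatever group structure is still present, so estimating
   them first drives Δ_T to zero and silently removes a real global
   response. The package exposes the wrong order behind a diagnostic flag
   (`fit_lem(..., sample_error_first=True)`) so the failure is demonstrable.
5. **Per-gene treatment effect** — per-(gene, group) mean of what remains.

The residual is the remainder, so the identity
`Ct = ε_P:A + ε̃ + ε_S + Δ_T + Δ_T:G + ε` holds to machine precision for
every record (tested at 1e-9 cycles over a thousand random datasets).
Technical qPCR replicates enter as individual records, never pre-averaged,
preserving residual degrees of freedom for the variance decomposition.
Missing chambers are simply ignored by every mean; the model never imputes.

Identifiability caveats, reflected in how recovery is scored: the absolute
level of each component is not identified (constants move freely between
components), and the global shift is only identified jointly with the
all-gene average of the per-gene effects. Recovery is therefore always
measured on contrasts against the reference group, and per-gene effects as
the total shift Δ_T + Δ_T:G.

`LemFit` stores Δ_T as the raw per-group means from step 3 so the additive
identity is exact; the reference-relative convention (reference = 0) is
available as `global_treatment_contrast()`. The −ΔCt output recenters per
gene, so the convention does not affect results.

## Comparators

**ΔΔCt** follows the efficiency-corrected ratio
`E_TG^(Ct_c − Ct_s) / E_RG^(Ct_c − Ct_s)` with both efficiencies defaulting
to 2 (assay efficiencies of 100% are assumed throughout; per-assay
efficiency calibration is out of scope). The control Ct is the
reference-group mean.

**geNorm** is implemented in full: relative quantities
`Q = base^(minCt − Ct)` (the per-gene min-Ct anchor is the standard
convention and cancels in every ratio), stability M as the mean pairwise
log2-ratio sd with iterative elimination of the highest-M gene, NF_n as the
geometric mean of the n most stable genes, pairwise variation
`V(n, n+1) = sd log2(NF_n / NF_{n+1})`, and `selected_n` as the smallest
n ≥ 2 with V strictly below the cutoff (default 0.15). Strict `<` is a
deliberate choice: at exact equality the gene is *not* added, which matches
the documented behaviour of excluding a candidate whose inclusion yields
V = 0.15. Ties in elimination and in the final best pair are broken
lexicographically for determinism.

The back-transform to the Ct scale is this package's reconstruction: NF is
rescaled to geometric mean 1 across samples and added as `log_base NF`
cycles. The rescaling is the unique constant choice that preserves each
gene's all-sample average Ct, which is what makes geNorm output directly
comparable with raw and model-processed values; its validation is that
property (tested), not an external reference.

geNorm and ΔΔCt need complete matrices, so missing cells are KNN-imputed
first (k = 10 by default, gene neighbours by Euclidean distance over
mutually observed samples rescaled by `sqrt(n_total/n_observed)`, backed by
scikit-learn's imputer which implements exactly this convention). Imputation
happens on per-cell mean Ct and is broadcast back with a provenance flag;
the error model ignores imputed records.

## Evaluation statistics

* **sd reduction**: per-(gene, group) sample sd (n−1) of raw vs processed
  per-sample values; percent reduction summarized per group.
* **Mean displacement**: change of the per-(gene, group) mean introduced by
  a normalization, relative to the same change in the reference group (so
  per-gene constants cancel). Zero displacement iff the normalization factor
  is constant within condition groups — the diagnostic that exposes
  coexpressed RGs.
* **Variance decomposition**: per-gene sequential (type-I) sums of squares
  over the declared replicate hierarchy (treatment → biological → cDNA
  conversion → residual/qPCR), computed by incremental least squares on
  cumulative dummy designs. Sequential SS is appropriate because the chip
  designs are balanced; for balanced nested chains it equals the classical
  nested-ANOVA SS (tested against an explicit cell-mean oracle).
* **Differential expression**: Welch's unequal-variance t, and an
  empirical-Bayes moderated t with the prior (d0, s0²) from moment matching
  of log variances and posterior variance `(d0·s0² + d_g·s_g²)/(d0 + d_g)`
  on d0 + d_g degrees of freedom. The "robust" flavour winsorizes per-gene
  variances at the 1st/99th percentile before prior estimation — an
  approximation to the published robust hyperparameter machinery, default
  on, toggleable. Bonferroni multiplies by the number of tests performed
  unless a fixed denominator is configured.
* **Paired sd tests**: Wilcoxon signed-rank (exact null for n ≤ 25, normal
  approximation with continuity correction above) and the exact binomial
  sign test; zero differences dropped and counted.
* **Residual distribution**: maximum-likelihood location-scale-df Student-t
  fit; Kolmogorov–Smirnov and Kuiper (V = D⁺ + D⁻) statistics against the
  fitted CDF. Because parameters are estimated from the same sample, default
  p-values come from a parametric bootstrap (999 replicates, refitting on
  each) that avoids the Lilliefors bias; asymptotic formulas are available
  as a fast, anti-conservative option. The Kuiper statistic weights both
  tails equally and is invariant under cyclic shifts of a circular sample
  (tested); it is the more sensitive tail diagnostic here.

## Synthetic data

The generator draws every model component with known truth: gene baselines
uniform on [−4, +8] cycles around a 22-cycle chip baseline (spanning the
dynamic range), normal probe/array, batch (cDNA conversion) and sample
effects, configurable global shifts and per-gene effects for a configurable
DE fraction, and Student-t residuals (df 5 by default, matching the heavy
tails seen in chip residuals) whose scale grows linearly with the gene's
mean Ct (slope 0.02 sd-cycles per cycle, floored at 10% of the base scale).
Default sizes mirror a two-condition 48×48 experiment: 2 groups × 4
biological replicates × 3 cDNA conversions × 2 qPCR replicates, 48 genes,
one array. Default noise scales (probe/array 0.3, sample 0.2, cDNA batch
0.5, residual scale 0.3 cycles) follow the variance budget such experiments
show, with the reverse-transcription step as the dominant technical source.
Designated "reference" genes can be forced stable, or given a shared
group-dependent shift to reproduce the coexpressed-RG failure mode.

What the generator does *not* emulate: biological variation shared across
the technical replicates of one biological sample (the residual carries
biological plus qPCR noise independently per record), per-chamber spatial
effects, amplification-efficiency differences between assays, and
missingness mechanisms (no-calls are injected by tests, not the generator).
Passing tests therefore demonstrate correctness of the estimators and the
comparative behaviour of the methods under the stated error structure, not
robustness to effects outside it.

## Numerical and design choices

* Conservation is tested at 1e-9 cycles; in practice the float error is
  ~1e-14 because each residual is defined as an explicit remainder.
* Sd-dominance of the error model over single-RG ΔΔCt is a statement about
  expected sds; single-dataset sd estimates at 12 samples per group flip
  sign in a few percent of cells from estimator noise alone, so the
  dominance check averages each cell's sd over 200 replicate datasets.
* KNN imputation requires k available donor genes; k is capped with an
  error, and genes missing everywhere are reported and left missing.
* The Welch null-calibration check uses near-normal residuals (t with
  df = 200): with df = 5 residuals the t-test is visibly conservative,
  which is precisely why the moderated/robust route is recommended.
* Problem sizes in tests and the acceptance script (48 genes, 12 samples
  per group, 200 Monte-Carlo replicates) are the package's chosen study
  conditions: large enough for the claims to be stable, small enough to run
  interactively.

## Known limitations

* A group-wise systematic error is fundamentally indistinguishable from the
  global treatment effect without an external covariate; the package warns
  and leaves the confound in Δ_T unless ssDNA quantification is provided.
* The moderated-t "robust" option approximates, rather than reimplements,
  the published robust empirical-Bayes hyperparameter estimation.
* Bootstrap p-values for the residual fit are Monte-Carlo estimates with
  resolution 1/(n_boot + 1).
* Only Bonferroni correction is provided, matching the evaluation design
  this package reproduces; FDR procedures are out of scope.
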