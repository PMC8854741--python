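# Methods

This note documents the statistical model behind `seedomics`, the
design choices that were genuinely open, the numerical machinery, and
what the synthetic-data generator does and does not emulate.

## Experimental layout

The analysis targets a two-treatment (tau-seeded vs control) by
three-time-point (DIV 3, 7, 14) factorial with three independent
biological replicates per treatment × DIV cell, 18 samples per assay.
Samples are distributed round-robin over a small number of culture
plates (default 4), so treatment and plate are partially confounded —
as they generally are in real plate layouts. Tau-inclusion load grows
roughly exponentially over the culture period; the pathology proxy is
`100·exp(k·(DIV − DIV_max))` anchored at 100% on the final DIV, with
`k` set so the first DIV evaluates to a configurable fraction
(default 1%). Only the ranks of this curve matter downstream
(Spearman), so its exact shape is immaterial to trend calls.

## Per-gene inference

Each gene is fit independently with cell-mean coding (equivalent to
`treatment + DIV + treatment:DIV`). The reported effect at each DIV is
the seed − control difference of model-predicted cell means; in the
balanced fixed-effects case this is exactly the difference of observed
cell means, with pooled-variance SE and residual df = N − 6.

**Plate screening.** A plate random intercept is tested per gene by a
likelihood-ratio test (ML) of the variance component. Under the null
the LRT statistic is pivotal given the design — its distribution
depends only on (X, Z), not on the fixed effects or noise scale — so
the null is simulated exactly once per design (2,000 standard-normal
draws, internal seed 0, cached) and the p-value is the add-one
empirical tail probability. The conventional asymptotic
½χ²₀ + ½χ²₁ mixture is kept as an option (`null="mixture"`) but is
measurably anticonservative here: at N = 18 it selects ~8.5% of null
genes at nominal 5%, while the exact null holds the 5% rate.

**Mixed fit.** Genes where the LRT rejects at α = 0.05 are refit by
REML with the plate random intercept. The fit profiles the variance
ratio λ = σ²_plate/σ²_resid through an eigendecomposition of ZZᵀ
shared across genes, reducing each evaluation to a small weighted
least-squares solve; estimates agree with `statsmodels` MixedLM and
`lme4` to numerical precision. Contrast t statistics use per-contrast
**Satterthwaite degrees of freedom** computed from the curvature of
the REML criterion in (σ²_resid, σ²_plate) — the approach of
`lmerTest`/`emmeans`, reproduced here to 0.01 df. The simpler
residual-df convention was tried first and rejected: conditioning on a
plate-LRT rejection shrinks the residual variance estimate, and with
residual df the detect-then-model pipeline loses false-discovery
control on null data (mean realized FDP ~0.3 at the 0.05 FDR level in
a 4-plate, zero-plate-variance simulation; ~0.05 with the exact LRT
null plus Satterthwaite df). This pretest selection effect is a real
property of "mixed model when detected" pipelines and is worth knowing
about; the calibrated detection and honest df bring it under control
but do not remove it in principle.

**Multiplicity.** Within a gene, the three contrasts are adjusted by
the Tukey studentized-range tail `P(Q(6, df) ≥ √2|t|)` over the six
cell means — conservative for a three-contrast family, matching the
full pairwise family a Tukey procedure protects; a Šidák adjustment
with m = 3 is available (`family="sidak3"`). Across genes the minimum
FWER p per gene enters Benjamini–Hochberg at α = 0.05 (delegated to
`statsmodels.multipletests`; an independent step-up loop serves as the
test oracle). Under the global null the min-FWER-p is sub-uniform
(the k = 6 family covers 15 comparisons, only 3 are used), so the
realized probability of any false discovery sits below the nominal
0.05.

**p\* resolution.** p\* is the largest per-gene minimum FWER p among
FDR-significant genes; a contrast is significant iff its FWER p ≤ p\*.
The ≤ convention is deliberate: with strict `<`, the gene(s) whose
minimum p defines p\* would themselves end up with zero significant
contrasts, breaking the coherence property "FDR-significant ⇒ at least
one significant contrast". The strict variant is exposed
(`--pstar-strict`) and the test suite demonstrates that switching it
breaks exactly the p\*-defining gene(s). If no gene passes the FDR
cut, p\* is undefined and no contrast is significant.

Genes with zero residual variance are dropped with a logged warning
rather than failing a genome-scale run; the single-gene API raises
instead, so degenerate input is never silently averaged over.

## Normalization

RNA matrices (log2 gene-level abundances) are quantile-normalized:
every sample receives the across-sample mean of the order statistics;
ties within a sample get the mean of the reference values over the
tied rank span. Protein matrices arrive on linear scale and are
processed complete-case filter → total-abundance normalization (each
sample scaled so its non-missing total equals the mean total) → log2.
The log2 modelling scale for protein is a package choice for symmetry
with RNA. The imaging readout divides per-well inclusion counts by
live-nuclei counts, averages per DIV and rescales to percent of the
reference DIV (the final time point reads exactly 100).

Both distribution-matching normalizers assume most features are
unchanged between samples. Synthetic configurations that violate this
(e.g. half the genes responsive, used in stress tests to produce large
selected sets) visibly distort null genes — an inherent property of
quantile/total normalization, not an implementation artifact — so such
tests analyse the generated matrices on their native scale.

## Trends and concordance

A feature's profile is its per-DIV seed − control log2FC from the
contrast table (raw-mean profiles are available through
`empirical_log2fc`, which also covers noise-free data where the model
fit is degenerate). Spearman ρ against the strictly-increasing
pathology ranks is +1/−1 exactly when the profile is strictly
monotone; classification is implemented by exact rank comparison
(equivalent, but immune to float-equality fragility), and any tie
forces non-monotone. With three time points the attainable ρ values
for tie-free profiles are {−1, −½, ½, 1}.

Concordance restricts to transcript-significant genes; each is
reported with a reason code (`ok`, `unmapped`, `unquantified`,
`non_monotone`), and genes monotone in both layers are *selected* and
classified into the four direction quadrants, which partition the
selected set by construction.

## Enrichment and qPCR

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k) with the quantified genes as background, BH correction
across tested sets, and a minimum in-background set size (default 3)
below which sets are skipped and logged. The hypergeometric is the
standard stand-in for proprietary ontology-enrichment statistics and
is labelled as such. ΔΔCt quantification aggregates replicate Ct by
arithmetic mean (median available), assumes amplification efficiency
2, flags arms whose replicate SD exceeds 0.5 cycles, and returns
log2FC = −ΔΔCt.

## Synthetic data generator

The generator emulates: the 2 × 3 × 3-replicate layout per assay;
gene-specific plate offsets (N(0, plate_sd) per gene × plate — a
shared per-plate scalar would be erased by quantile normalization and
would make the per-gene LRT degenerate across genes); i.i.d. Gaussian
residual noise on log2 scale; five response archetypes (null,
monotone up/down following the pathology curve to ±effect_size at the
final DIV, and single-time-point late/early effects with random sign);
a protein layer covering a random gene subset on linear scale whose
direction agrees with the transcript with probability
`concordant_fraction`; and completely-at-random protein missingness.

Defaults mirror the study conditions: 18,049 genes, ~6% responsive
(split to echo the observed preponderance of late, monotone
responses), effect_size 2, residual_sd 0.25, plate_sd 0.1 over 4
plates, protein_fraction 0.2, concordant_fraction 0.6,
protein_missing_rate 0.035 (≈52% complete-case retention over 18
samples). Baselines are drawn on a 0.25-log2-unit grid so noise-free
cell-mean differences reproduce the true log2FC without floating-point
residue.

Not emulated: gene–gene correlation, variance heterogeneity across
genes, count-level sampling noise, informative protein missingness,
isoform/peptide-level structure. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to those real-data features.

## Numerical choices

- Studentized-range tail: own Gauss–Legendre quadrature (120 nodes per
  axis, outer variable s = √(χ²_df/df) truncated at the 1e-16
  quantiles, inner variable over ±9 SD), with the difference of CDF
  powers evaluated via `expm1`/`log1p` to preserve relative accuracy in
  small tails; agrees with `scipy.stats.studentized_range` to ~1e-14
  absolute at about a tenth of the per-value cost. Adjusted p is floored at
  the raw p to guard round-off at p ≈ 1.
- Profile optimization over λ: bounded scalar minimization on log λ in
  [−12, 10], xatol 1e-8; λ̂ = 0 when the boundary fits no worse.
- Satterthwaite df: central finite differences (step 1e-5 relative) of
  the REML criterion and contrast variance in (σ²_resid, σ²_plate);
  df clamped to [1, N − 6]; falls back to residual df when λ̂ = 0 or
  the information matrix is singular.
- Quantile-normalization ties: mean of reference values over the tied
  rank span, computed from cumulative sums (exact, O(n log n)).
- Reproducibility: a single `numpy` Generator seeded from
  `rng_seed` drives the generator; identical configs reproduce
  bitwise-identical matrices.

## Problem sizes used in the validation suite

The packaged checks run at desk scale chosen to keep the suite quick
while giving stable Monte-Carlo estimates: FDR control on 20 all-null
replicates of 2,000 genes; power and p\*-coherence on 1,000-gene
simulations with 20% monotone spikes; cross-omics truth recovery on
400 genes with a fully concordant protein layer; oracle equivalence on
200 randomized instances of up to 200 genes. The acceptance script
additionally runs the full pipeline once at the study-scale default of
18,049 genes.

## Known limitations

- The detect-then-model plate strategy remains slightly liberal in
  principle for genes selected by chance clustering, even with exact
  detection calibration and Satterthwaite df (measured mean null FDP
  ≈ 0.05 at α = 0.05 under the worst case of plates with zero true
  variance).
- Containment-style df and Kenward–Roger are not implemented; at this
  design size Satterthwaite and containment nearly coincide.
- The mixed model supports a single random intercept (plate); nested
  or crossed batch structures are out of scope.
- Trend calls on three points are coarse by nature: a monotone class
  asserts only a strict ordering, not a fitted slope.
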