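# Methods

This note documents the statistical model behind `abcompare`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Compartment scores

For one chromosome of one sample, let `C` be the raw binned cis contact
map (no ICE/KR balancing is applied by default; balanced matrices may be
supplied instead, since the pipeline is agnostic to the normalization of
its input counts).

1. **Masking.** Bins with zero marginal count, or with fewer than
   `min_coverage_frac` (default 1%) nonzero cis entries, are excluded.
   Chromosomes with fewer than 20 usable bins are skipped with a warning —
   correlation PCA is meaningless on tiny systems.
2. **O/E.** The expected count at distance `d` is the mean of `C[i, i+d]`
   over pairs of unmasked bins; entries are divided by it. Diagonals with
   no unmasked pair get expected 0 and O/E 0 — excluding masked bins from
   the expectation avoids deflating it.
3. **Correlation.** Pearson correlation of O/E rows over unmasked columns;
   zero-variance rows are masked at this point.
4. **Partial SVD.** The top-k (default k=2) singular triplets of the
   correlation matrix, computed by dense symmetric eigendecomposition for
   small systems and ARPACK (`eigsh`, fixed start vector) for large ones.
   A deterministic sign convention (largest-magnitude loading positive) is
   applied before any orientation, so repeated runs are bit-identical.
   The principal components are the projections `PC = X·V`.
5. **Selection and orientation.** Each retained PC is correlated against
   per-bin GC content and gene density; the PC maximizing
   `|r_GC| + |r_gene|` wins (ties go to the lower index). Absolute values
   are used because the PC sign is arbitrary before orientation — a
   sign-flipped but perfectly informative PC must not lose the selection.
   The selected PC is negated when `r_GC < 0`, so positive score = A
   (GC-rich). If `r_GC` is exactly 0 the gene-density correlation decides;
   if both covariates are constant the chromosome cannot be oriented and
   an error is raised.

The score is invariant to positive scaling of the map (O/E cancels
sequencing depth) and equivariant under bin permutation; both properties
are tested numerically.

## Normalization

Raw scores from different samples are principal components of different
matrices and live on arbitrary scales. Quantile normalization (QN) is
applied per chromosome, jointly across *all* replicate columns of all
samples: each column is mapped onto the across-column mean of order
statistics by rank, ties receiving the average of the tied reference
values (the standard tie policy of the common QN implementations).
Replicate columns are then averaged per sample. Bins masked in any one
column are dropped from the QN pool for every column rather than imputed —
imputation would fabricate scores in exactly the bins where the data are
least trustworthy.

QN forces identical marginal distributions by construction. It is
therefore only appropriate when compartment composition is broadly
comparable across samples; a condition that globally gains A compartment
will have part of that signal absorbed (and neighboring quantiles
distorted) by QN. This is a real limitation of the approach, shared by any
QN-based pipeline, and is visible in simulation when planted flips are
strongly unbalanced between directions.

## Differential compartments

Let `s_i ∈ R^M` be the per-bin vector of normalized sample scores pooled
genome-wide (the covariance is better estimated on all chromosomes
jointly; QN has already removed per-chromosome scale differences).

- **Disagreement weight.** `d_N^i = sqrt(Σ_t (q_t^i − q_N^i)²)/(M−1)` per
  sample, standardized across bins within each sample to `z_N^i`, and
  `w_i = Φ(max_N z_N^i) ∈ (0, 1)`. Bins where samples disagree get
  `w → 1`. If a sample's distances have zero spread (identical columns —
  degenerate), its z is set to 0 with a warning, which keeps `w`
  well-defined and NaN-free.
- **Weighted center.** The default center is `μ_i = s_i (1 − w_i)`, so the
  deviation entering the quadratic form is `s_i w_i`: bins with high
  cross-sample disagreement deviate most, as intended for an outlier
  statistic. The alternative `μ_i = s_i w_i` (`weight_mode="verbatim"`) is
  kept behind a flag; it shrinks the deviation to zero exactly where
  disagreement is largest and consequently cannot detect differential
  bins, which the recovery tests confirm — hence it is not the default.
- **Robust covariance.** `Σ` is the MCD estimate over bins. The MCD
  support fraction defaults to 0.9, not the estimator's usual ≈0.5:
  compartment scores are *bimodal* (A and B clouds along the diagonal),
  and a half-sample MCD can collapse onto a single mode, underestimating
  the covariance by an order of magnitude and destroying the χ²
  calibration. A 0.9 support keeps both modes in the subset while still
  resisting up to 10% gross outliers — matching the χ²₀.₉₀ trim of the
  next step. The MCD subset search is seeded (`random_state`) for
  reproducibility. Exactly collinear score columns are reported by index
  before the singular fit is attempted.
- **Two passes.** Pass 1 computes `MD_i = (s_i−μ_i)ᵀ Σ⁻¹ (s_i−μ_i)` for
  all bins; bins with `MD > χ²_{0.90, df}` are excluded and Σ is refit on
  the survivors; pass 2 re-scores *all* bins (outliers are excluded from
  covariance estimation but still tested). Removing genuine differential
  bins from Σ sharpens the null and strictly increases their second-pass
  distance. If more than half the bins are removed in pass 1 a warning is
  emitted — the null model is then suspect.
- **Significance.** `p_i = 1 − F_{χ², df}(MD_i)` with `df = M` by default.
  The reference df of a Mahalanobis outlier test equals the dimension of
  the score vector; since other conventions exist, df is exposed as a
  parameter. Note the weighted statistic is stochastically *smaller* than
  χ²_M under the null (the `w² ≤ 1` factor), so the test is conservative;
  the unweighted quadratic form with known covariance is exactly χ²
  calibrated, which is the tested contract.
- **Replicate covariate and FDR.** With ≥ 2 replicates per sample, a
  replicate-variability distance is computed over the R pooled replicate
  columns: within-sample distances only, weights `srw = Φ(max z)`, centers
  `r_i (1 − srw_i)`, and a *diagonal-masked* inverse covariance (cross-
  replicate covariance terms are noise at this level). Bins with noisy
  replicates score high. P-values are then adjusted by covariate-weighted
  BH: bins are stratified into covariate quantile groups (default 5), a
  per-group null proportion π₀ is estimated by Storey's method on held-out
  cross-validation folds, weights `∝ 1/π₀` are normalized to mean 1, and
  BH is applied to `p/weight`. This approximates independent hypothesis
  weighting with the same contract — FDR control under a covariate-
  informed weighting that degenerates to plain BH when the covariate is
  uninformative (a constant covariate yields exactly plain BH). Adjusted
  p-values are floored at the raw p-value, which weighted BH does not
  guarantee by itself; the floor is conservative. Without replicates,
  plain BH is used.
- **Labels.** Two-sample transitions: `A->B`/`B->A` on sign change,
  `sA->wA` etc. for strength changes within a compartment (strong/weak by
  strict |score| comparison — the significance filter already gates which
  bins are labeled, so no minimum-gap threshold is imposed). A score of
  exactly 0 counts as A, and an exact |score| tie is labeled `A->A`/`B->B`
  (measure-zero on continuous scores). Multi-sample labels are the
  per-sample A/B string plus the max-|score| sample.

## Differential interactions

Significant cis interactions (FitHiC2-style TSV; the union over
samples/replicates of calls passing the caller's threshold) are filtered
to those with at least one anchor in a significant differential bin.
Replicate maps are pooled per sample, and each record gets per-sample
`log2((O + c)/(E + c))` values under the same per-diagonal expectation
used for compartment O/E, with pseudocount `c = 1` so interactions absent
in one sample stay finite. The test is the same quadratic form with a
*fixed* center — the per-sample mean (optionally 10%-trimmed) of the
tested set, the simplest center consistent with "distance-normalized
interaction" values — MCD covariance (classical available by flag, since
a robust choice is not forced here; no two-pass refinement, which belongs
to the compartment-level null), χ² survival p-values and BH. Fewer than
10 qualifying records is refused outright: no usable covariance.

## Synthetic data

`SimulationSpec` defines one simulated chromosome: `n_bins` (default
2,000) bins of `resolution` (100 kb), expected intensity
`λ_ij ∝ |i−j|^(−α) (1 + δ a_i a_j)` with decay exponent α = 1 and
compartment affinity δ = 1, scaled to a sequencing depth of 5·10⁶ expected
read pairs per replicate map, with independent Poisson counts per bin pair
(symmetrized; the diagonal uses the offset-1 decay intensity). Two
conditions with two replicates each are the default design.

The compartment track `a ∈ [−0.97, 0.97]` is blockwise (blocks of 10–40
bins, magnitudes uniform in [0.5, 0.9]) with two realism ingredients that
matter for the pipeline: per-bin magnitude jitter (σ = 0.1) and a short
taper at block boundaries. Real compartment scores vary continuously
within blocks and pass through zero at boundaries; a piecewise-constant
track would produce a plateaued, gappy score distribution whose quantile
map amplifies rank noise into large value changes, an artifact of the
generator rather than a property of the method. Differential truth is
planted as disjoint ≥5-bin blocks: sign flips (`flip_fraction` of bins,
balanced between A→B and B→A so the marginal composition respects QN's
assumption — see the QN limitation above) and strength shifts (|a| scaled
by `shift_factor` in the non-reference conditions). GC content is a noisy
increasing function of the condition-average track and gene density a
Poisson with track-dependent rate, so PC selection and orientation are
genuinely exercised. Everything is deterministic given `seed`.

The simulator does **not** emulate TADs or loops, trans contacts,
restriction-fragment or mappability biases, copy-number variation, or
overdispersed (beyond-Poisson) replicate noise. Passing tests therefore
demonstrate the statistical machinery under a clean plaid-plus-decay
model, not robustness to every artifact of real Hi-C; on real data the
coverage filter and the robust covariance carry more of the load.

## Problem sizes and numerical choices

The simulation-based tests and the acceptance script use one chromosome
of 2,000 × 100 kb bins (a typical large chromosome at this resolution) at
5·10⁶ reads per map for end-to-end contracts, 500 bins for score-accuracy
checks, and 300–400 bins for algebraic invariances — sizes chosen so the
whole suite reflects realistic per-chromosome dimensions. Tolerances:
quadratic forms match loop oracles to 1e-8; QN idempotence to 1e-12;
depth invariance to 1e-8; χ² calibration by KS distance < 0.05 at
n = 5,000. Degenerate inputs (all-masked chromosomes, constant columns,
identical replicates, zero-spread distances) either raise typed errors or
degrade to well-defined values with warnings, as listed per function.

## Known limitations

- QN assumes comparable score composition across samples; large,
  directionally unbalanced compartment reorganizations are partially
  absorbed and can distort neighboring quantiles (worse on chromosomes
  with few usable bins, where the quantile grid is coarse).
- The weighted statistic is conservative rather than exactly χ²
  calibrated; FDR is controlled but the raw p-values are not uniform
  under the null.
- The MCD needs bins ≥ 5 × samples; very small chromosomes should be
  pooled (the default genome-wide pooling does this automatically).
- Interactions are tested only within differential compartments, as
  designed; it is a focused follow-up test, not a genome-wide loop
  caller.
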