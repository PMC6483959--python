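# Methods

## Model and estimation

`AMMI.fit` estimates the two-way fixed-effects decomposition of a balanced
genotype x environment table of cell means. Main effects are the row/column
mean deviations; the interaction residual `Z = Y - rowmean - colmean +
grandmean` is doubly centered by construction, and its SVD supplies the
multiplicative terms. All `M = min(G-1, E-1)` axes are computed and kept on
the fitted object; `n_components_` only marks how many belong to the
"adjusted" model (significant Gollob axes when an error term is available,
else two, always overridable).

Scale conventions, fixed throughout:

* **Scores** are symmetrically scaled, `sqrt(lambda_n) * gamma_gn` and
  `sqrt(lambda_n) * delta_en`, so each axis's genotype and environment
  score vectors both have squared norm `lambda_n`. This is the scaling
  under which the bundled trial's published-style score magnitudes are
  reproduced, and it makes genotype-by-environment products reconstruct
  `Z` directly.
* **Sums of squares** are on the replicate-total scale: means-scale SS
  times `r` (`GEMatrix.replicates`). The axis SS is therefore
  `r * lambda_n^2`.
* **Signs** of each axis pair are arbitrary in any SVD; we flip each axis
  so its largest-magnitude environment score is positive. ASV and GSI are
  sign-invariant; comparisons of individual scores across software should
  be made on magnitudes or after aligning one axis sign.
* **Ties** in singular values are ordered by descending `lambda`, then by
  the sign of the first environment loading, then original SVD order —
  deterministic, if cosmetic.

Axis tests use Gollob's approximation: axis *n* has
`df = G + E - 1 - 2n` (equal to the number of free parameters a rank-*n*
centered bilinear term adds, which the test suite verifies by a numeric
Jacobian-rank count), `MS = SS/df`, and `F = MS / MS_error` against a
replicate-level error mean square supplied by the user or computed by
`anova_two_way` from replicate records. Gollob tests are liberal; users
wanting resampling-based axis tests should look elsewhere — they are out
of scope here.

`anova_from_means` reports percent-of-total explained using the total over
the rows it lists (G, E, GE, and Error when given). If a trial's original
analysis carried additional strata (e.g. blocks), percentages computed
here will differ from that analysis even when every listed SS matches;
the bundled barley trial shows exactly this: its published shares imply a
blocks stratum of roughly 1050 g² that the table itself does not list, and
its environments F-statistic was evidently tested against that stratum
rather than the pooled error. We recompute percentages from listed rows
only and test environment effects against the pooled error, documenting
rather than guessing the missing stratum.

## Stability

ASV weights the IPCA1 score by `SS_IPCA1/SS_IPCA2`; the ratio is invariant
to the SS scale, so means-only input (r unknown) gives identical ASV. ASV
uses exactly the first two axes even when more are significant — that is
the statistic's definition. A rank-1 interaction (SS_IPCA2 = 0) leaves ASV
undefined and raises.

GSI ranks: mean descending, ASV ascending, average ranks for ties (GSI can
then be non-integer). With 2-decimal published inputs, pairs of genotypes
whose true ASVs differ by less than the rounding error can swap adjacent
ranks relative to a published table; the bundled trial has one such
adjacent swap, which moves two GSI values by 1 without affecting the
selection order at the top.

## Genetic effects

Empirical quantiles use linear interpolation of order statistics (numpy
default). With 30 lines and quantiles 0.03/0.97 the extreme groups are
singletons (the 0.03 quantile falls between the two smallest order
statistics), and the global minimum/maximum line is always included so the
groups are never empty. Overlapping groups — possible with near-constant
means or an aggressive quantile pair — raise a configuration error rather
than silently producing a meaningless contrast. Subset analyses (hulled /
hull-less) re-identify extremes within the subset; parents are excluded
from every DH group. The better-scoring parent is decided per context
(per environment or per mean column), so `a_Parents` is nonnegative by
definition.

The F-tests treat each effect as a single-df linear contrast `c'ybar` of
line means with `sum(c^2)` equal to `1/(4 n_min) + 1/(4 n_max)` for
`a_DH`, the analogous three-group expression for `aa_DH`, and `1/2` for
`a_Parents`; `MS = estimate^2 * m / sum(c^2)` with `m` observations behind
each mean (r per environment; r·E for cross-environment means), and
`F = MS / MS_e` on (1, error_df) df. This contrast construction is this
package's documented interpretation — the method literature the statistic
descends from does not print the mean-square formulas.

**Caveat — selection effect.** The contrast machinery assumes the groups
are fixed in advance. The quantile method *selects* the extreme lines from
the same data, so under a pure-noise null the realised `F_a` is inflated
well above its nominal distribution (the expected squared range of n line
means greatly exceeds the fixed-contrast variance). The test suite
therefore verifies the 5% type-I calibration with pre-specified groups,
and the noisy-recovery test quantifies the (small, positive) selection
inflation of `a_DH` at trial-realistic noise. Stars on quantile-selected
effects should be read as descriptive, as they are in the source analyses
that use this method.

## Synthetic data

`simulate_ammi_trial` generates `y_ger = mu + alpha_g + beta_e +
sum_k lambda_k gamma_gk delta_ek + eps` with `eps ~ N(0, error_sd^2)`.
Interaction score vectors are random orthonormal vectors orthogonalised
against the all-ones vector, so planted axes satisfy the double-centering
identities exactly and `lambda` recovery is exact at zero noise. Defaults
are the bundled trial's conditions: G=32, E=6, r=3, mu=44.8 g, main-effect
sds 4.9/3.8 g and lambdas (39.3, 26.2, 24.9) back-solved from its sums of
squares, error sd sqrt(26.4) g. What the generator does *not* emulate:
block effects, heteroscedastic or correlated errors, missing plots, and
year-to-year meteorological structure — so passing recovery tests show
correctness of the estimators under the model's own assumptions, not
robustness to field realities.

`simulate_dh_population` is an idealised test scaffold: lines are ±1
allele vectors, genotypic value = base + sum of additive effects + pairwise
additive-by-additive terms; `force_extremes` plants the all-plus and
all-minus lines the quantile estimators theoretically assume. With it and
zero noise, `a_DH` equals the summed per-locus effects exactly.

## Numerical choices and problem sizes

* Reconstruction/SS-conservation tolerances: 1e-8 absolute on the data
  scale, 1e-6 relative on SS.
* A fitted interaction whose total SS is below `1e-12 * max(|Y|)^2` is
  treated as exactly zero (purely additive input leaves only
  floating-point residue); scores are zeroed and axis percentages reported
  as 0 with a warning.
* Monte-Carlo test sizes: 2000 replicates for type-I calibration, 400
  simulated trials for error-MS recovery (mean within 2% of truth), 200
  trials for leading-axis recovery. At full trial noise the leading
  singular value is inflated ~11% by noise absorption; the 5% recovery
  property is demonstrated at half that noise (sd 2.5 g), with the
  inflation at full noise left as a documented bias, not a defect.
* The brute-force rank-1 oracle (alternating least squares with 2000
  sweeps) matches SVD axis SS to 1e-6 relative on 4x4 problems.

## Limitations

Fixed-effects only (no REML/BLUP shrinkage of interactions); balanced
complete designs only — unbalanced input is refused, not imputed; no GGE
biplot, no cross-validation axis selection, no alternative stability
measures (ecovalence, Shukla, joint regression); DH populations only for
the genetic estimators (no dominance is estimable, and none is modelled).
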