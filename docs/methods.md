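# Methods

## The measurement model

The unit of analysis is a grid cell on a nested equal-area grid. The world
is a flat `width x height` rectangle of unit-square base cells (a planar
stand-in for an equal-area projection; distances are Euclidean in
cell widths). Four grain levels double the cell edge successively, so
every coarse cell contains exactly four children and extents must be
divisible by 8. Cells are half-open `[x0, x1) x [y0, y1)`, ids row-major
and 0-based from the lower-left origin, which makes boundary assignment
unambiguous: a point on an interior boundary belongs to the
higher-indexed cell.

Species ranges are sets of base cells. Expected richness of a cell is the
number of ranges overlapping it; at coarse grains the expected set is by
construction the union over children. A record documents a (species,
cell) pair if it falls in the cell *and* the species is expected there.
Records of species outside their mapped range are tallied separately and
never enter completeness — this keeps C = S_doc/S_exp a true binomial
fraction (0 ≤ C ≤ 1 by construction), which the inference stage relies
on. Records outside the grid are flagged invalid and dropped with a
logged count. Cells with S_exp = 0 have undefined completeness and are
excluded from every statistic.

Endemism richness (the per-cell sum of inverse range sizes, range size in
base cells) is computed at the base grain and aggregated to coarser
grains by the mean over children, keeping it on a per-area scale
comparable across grains.

## The synthetic worlds

The generator exists so that every downstream stage can be tested against
known ground truth; its defaults define the package's study conditions.

* Grid 32x32; 250 species in three taxa (120 birds, 60 mammals, 70
  amphibians — birds deliberately the most speciose, as in real vertebrate
  data); range sizes lognormal (median 30 cells, sigma_log 1.1, truncated
  to the grid), grown as 4-connected sets by a spreading-dye process so
  ranges are cohesive and realized sizes are exact.
* Eight contiguous countries (nearest-seed partition) carrying
  socio-economic covariates: a security score on a Global-Peace-Index-like
  scale (higher = less peaceful), an ecology H-index and international
  collaboration share, per-capita research funding and wealth (lognormal,
  positively correlated — rich countries fund more research), and a
  data-network membership flag (p = 0.6, forced non-degenerate).
* Environmental surfaces are Gaussian random fields (iid noise convolved
  with an isotropic Gaussian kernel of the configured range, default 4
  cells, then z-scored): elevation on a 2x finer subgrid (four DEM samples
  per base cell, so within-cell relief exists at the base grain), a
  right-skewed travel-time surface (exp-transformed, hours), and a
  protected mask (top 15% of a field, matching the real global
  protected-area share). Twelve airports and twenty publishers are point
  facilities; publishers concentrate in wealthy countries (50% wealth
  weighting) to emulate the concentration of data holders.
* Records: per-cell intensity log λ = Σ β_k z_k − d/s + ε over the
  standardized *exogenous* predictors, the distance d to the nearest
  publisher (decay scale s = 8 cells — "distance to researchers" is a
  built-in driver), and Gaussian noise (sd 0.25, optionally spatially
  autocorrelated). Cells without species are excluded from the
  multinomial; species are uniform among those present (no abundance
  model); publishers are chosen with inverse-distance weights
  1/(d + 0.5). Record coordinates are uniform within the cell. Default
  effects: national funding +0.7, network participation +0.7, endemism
  +0.4, travel time −0.3, protected fraction +0.2, security −0.2.

Only exogenous predictors (those computable before any record exists) may
carry true effects; the three record-derived predictors (institution
proximity, publisher funding, publisher size) would be circular as causes
and act solely as candidate confounders in recovery experiments.

What the generator does **not** emulate: temporal dynamics of collection,
taxonomic noise (misidentification, synonymy), spherical geometry,
abundance-dependent detectability, or realistic country shapes. Passing
tests therefore demonstrate that the *machinery* recovers known structure
under the stated sampling model, not that real-world inference is
unbiased under violations of it.

## The driver models

Completeness enters a binomial GLM as a composite response — S_doc
successes out of S_exp trials, logit link — so richer cells carry more
information automatically. Predictors are standardized over analyzed
cells only (S_exp ≥ 1), with log10(x+1) first for the right-skewed ones
(travel time, fundings, publisher size, endemism, airport proximity; the
list is a config option). The publisher-derived predictors weight each
publisher by its records within radius R of the cell centroid (default:
two cell widths at the analysis grain, config key); cells with no
surrounding records receive the global minimum of the index so the design
stays complete, and are flagged for sensitivity checks. Proximity kernels
are exp(−d/scale) with scale 4 base-cell widths by default.

The in-package IRLS solver implements a strict convergence contract
(max |score| < 1e-8 or relative deviance change < 1e-10; 100 iterations
without convergence reported as likely separation, as is a pooled rate of
0 or 1). Two robustness measures matter in practice: step-halving keeps
the deviance monotone on ill-conditioned designs, and a minimum-norm SVD
step handles exactly collinear columns (e.g. four country-level
covariates over few countries), where fitted values — hence deviance,
AIC, D² — remain well defined even though individual coefficients are
not. The full likelihood (including binomial coefficients) is used, so
AIC = −2 logL + 2k with k counting the intercept and, in spatial models,
the RAC term.

All 2^p subsets are fitted (p ≤ 16 enforced; p = 12 in the standard
analysis → 4096 models) and ranked by AIC, ties broken by fewer
predictors then lexicographic order. Subsets within ΔAIC < 10 of the best
are refitted with a residuals autocovariate built from *that subset's own*
non-spatial working residuals: RAC_i(r) = mean residual of neighbours
within radius r, focal cell excluded, isolated cells 0; r is chosen by
AIC over {1, 2, 3, 4, 6, 8} cell widths. The spatial fit with the lowest
AIC is the minimum adequate model.

Importance has two faces. β are the MAM's coefficients on the z-scored
predictors (predictors not selected are reported as absent, not zero; the
RAC coefficient is reported raw, not rescaled). %SS comes from an ANOVA
whose response is the AIC of every model in the subset space and whose
factors are sum-to-zero presence codes; because the 2^p design is
balanced and orthogonal, type III equals type I sums of squares (asserted
in tests to 1e-8), and each %SS is a share of the total SS including the
residual. The intercept-only model is included in the ANOVA (config
option), and failed subset fits are imputed at the worst observed AIC so
the design stays complete (excluded from the ranking itself).

Auxiliary quantities: the density model regresses the composite response
on standardized log10(N_rec + 1) and reports its d². The shared-deviance
fraction between the MAM and the density model is computed by deviance
decomposition over the union model — (ED_density + ED_MAM − ED_union) /
ED_MAM, clipped to [0, 1] — because explained-deviance inclusion–
exclusion is the only formulation that is exact for both the
"density explains nothing" and "MAM is the density model" limits. The
country-identity test adds country dummies to the MAM's covariates
(including its RAC column) and reports ΔD² with a likelihood-ratio
p-value; dummies exactly aliased with country-level covariates already in
the model are dropped and the test runs on the surviving degrees of
freedom.

## Spatially effective degrees of freedom

Autocorrelated surfaces make naive tests anti-conservative. For a
correlation r between two surfaces, distance-class autocorrelation
profiles of both variables are estimated (12 equal-width classes spanning
the full range of pairwise distances) and assembled into correlation
matrices R_x, R_y; then var(r) ≈ trace(R_x R_y)/n², the effective sample
size is n_eff = 1 + 1/var(r) (clipped to (2, n]), and r is t-tested on
n_eff − 2 df. Spearman tests apply the same machinery to ranks.

Two numerical choices deserve emphasis. First, the distance classes span
*all* pairwise distances: truncating the profile (say, at half the grid
diagonal) zeroes genuine long-range correlation and in simulation made
the adjusted test badly liberal (empirical size 0.38 at α = 0.05 under
range-8 fields on a 20x20 grid, versus 0.06 with full-range classes; the
naive test rejects at 0.96 there). Second, the two-sample region contrast
computes its adjusted p through the identity between the two-sample t and
the point-biserial correlation — the values are correlated with the 0/1
region indicator and tested with the machinery above. Direct plug-in
estimates of per-group effective sizes are unusable here because
group-mean centering forces the empirical correlogram to sum to zero,
cancelling the variance inflation exactly; the point-biserial route is
calibrated (size ≤ 0.02 under iid and strongly autocorrelated nulls,
power 1.0 at a 2-sd shift with 200 cells per group). Multi-group
comparisons test paired per-cell differences with a conservative
floor-at-zero correlogram for the effective size and a studentized-range
(Tukey) adjustment; a Sidak-form max-t adjustment is available for
families of region contrasts. The across-grain comparison is a plain
Kruskal–Wallis test, deliberately without spatial adjustment.

## Country summaries

Countries partition base cells; at coarser analysis grains a cell belongs
wholly to the majority country of its base cells, ties broken to the
lexicographically smallest id (deterministic). Required combinations per
country are the sum of S_exp over its cells; completeness is
documented/required; the missing share normalizes each country's gap by
the world total (shares sum to 1; a fully documented world yields zeros
with a warning). The wealth regression is OLS of country completeness on
log10 per-capita wealth — the log because wealth is lognormal-ish and the
relation is expected to be roughly linear per decade of wealth.

## Problem sizes and numerical defaults

The standard analysis grain is the base grain of a 32x32 world
(1024 cells, ~50k records); the all-subsets sweep over 12 predictors plus
spatial refits completes in well under a minute. Test-suite simulations
use 10 seeds for recovery and RAC-efficacy properties, 50 seeds for test
calibration at n = 400, and 16x16 worlds for bit-exact oracle
comparisons. Default tolerances: IRLS as above; GLM oracle agreement
asserted at 1e-6; ANOVA type III/type I identity at 1e-8.

## Known limitations

* Planar geometry only; no projections, no great-circle distances.
* The RAC approach absorbs residual autocorrelation but, like all
  autocovariate methods, can shrink covariate effects when the radius
  search overfits; under pure noise the AIC-selected radius buys a
  best-of-6 selection bonus (about half of null replicates gain > 2 AIC),
  so spatial-vs-nonspatial AIC gains should not be read as evidence of
  spatial structure on their own.
* The Dutilleul-type corrections are approximations; with autocorrelation
  ranges comparable to the domain (a handful of independent patches) they
  are honest but conservative, and no test can fully rescue such designs.
* Country covariates are piecewise constant within countries, so with few
  countries they are collinear with country identity; the country-identity
  test drops aliased dummies rather than pretending to separate them.
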