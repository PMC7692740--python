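# Methods

`seedpref` implements a distance-matrix workflow for multi-choice seed
predation (cafeteria) assays: which properties of weed seeds explain the
preferences of granivorous carabid beetles?

## Data model

The unit of analysis is the seed species. One **response** table records
consumption of each seed species by each predator species; several
**explanatory** blocks record seed properties:

* morphology — principal dimensions `A >= B >= C` (mm, calliper, replicate
  seeds averaged per species), 100-seed mass (g),
* derived shape descriptors — shape variance
  `Vs = var(A/A, B/A, C/A)` (population variance, n = 3; 0 for a sphere,
  supremum 2/9), flatness `FI = (A+B)/(2C)` (>= 1), eccentricity
  `EI = A/B` (>= 1), volume `V = A·B·C` (mm³). Note: `Vs` is often quoted
  with a maximum of 0.2 for discs and spindles; the formula's actual
  supremum is 2/9 ≈ 0.222, attained only in the degenerate limit. We
  implement the formula and report its true range.
* structural defence — seed-coat thickness (mm) and crush strength (N),
* chemistry — wide compositional blocks (total and surface fatty-acid
  methyl esters, volatiles from dry and imbibed seeds, other surface
  compounds), typically with more columns than species,
* ecology/taxonomy — plant family and life strategy
  (annual / biennial / annual-biennial / perennial).

Consumption is standardized per predator to the proportion of that
predator's most consumed seed (removes body-size effects; values in
[0, 1], column maximum exactly 1). All-zero predator columns are dropped
with a warning rather than erroring, so the pipeline runs on subsets.

## Distance matrices

Each block becomes a seed × seed dissimilarity matrix:

| data type | metric |
|---|---|
| standardized preferences | Bray–Curtis, `Σ|x_i−x_j| / Σ(x_i+x_j)` |
| multivariate continuous block | Mahalanobis, covariance with `n−1` denominator |
| single continuous trait (mass) | absolute difference |
| categorical attribute | simple matching (0 same / 1 different) |

The mass and categorical metrics are the package's own choices: the
simplest measures consistent with one continuous variable and with
unweighted category membership, respectively.

Every matrix is validated (symmetry to 1e-10, zero diagonal,
non-negativity) and canonicalized to lexicographic species order, so block
alignment is bit-reproducible.

**Singular covariance.** For a block with `p >= n−1` columns the
covariance `S` of `n` species has rank at most `n−1`. Whitening with the
Moore–Penrose pseudo-inverse then projects the species onto a regular
simplex: *all* pairwise distances equal `sqrt(2(n−1))` exactly, and the
matrix carries no information. A vanishing ridge (e.g. 1e-6) does not help,
because the pairwise differences lie entirely in the row space of `S`.
`mahalanobis_matrix` therefore exposes both the pseudo-inverse default
(correct for blocks that are merely ill-conditioned) and a ridge
`S + λ·diag(S)`; the pipeline applies `λ = 1` to blocks that are singular
by dimension, which interpolates the metric toward Euclidean distance on
per-column-standardized data while retaining covariance weighting among the
well-resolved directions. Chemistry blocks are not otherwise rescaled
before the metric; the ridge term makes the result scale-aware through
`diag(S)`.

## Mantel screening

Redundancy among explanatory matrices is screened with one-sided
(positive-association) Mantel permutation tests, 999 permutations by
default: Pearson correlation of lower-triangle vectors, null distribution
by simultaneous row/column relabeling of one matrix. The observed statistic
counts as its own permutation (`p = (1+k)/(1+B)`), keeping p valid; when
`n! <= B` the permutation group is enumerated and p is exact. A constant
distance vector (possible for degenerate categorical matrices) yields
`r = 0, p = 1` with a warning instead of an error.

The screen is iterative: while any retained pair is correlated at
`p <= threshold`, the pair with the smallest p is resolved by excluding the
member with the weaker marginal Mantel correlation to the response (ties
broken by label order, the later name dropped). The rule is logged
decision-by-decision; the threshold (library default 0.05; the worked
analysis uses 0.01 because 55 candidate pairs over-prune at 5%) and the
rule are configuration, not science — with real data the excluded set
should be reviewed, not trusted blindly.

## MRM and inference

Multiple regression on distance matrices: OLS of the response distance
vector (length `n(n−1)/2`) on the explanatory distance vectors plus an
intercept. Raw distances are regressed by default; `use_ranks` substitutes
ranks. Because distance entries sharing a species are dependent,
significance comes from object relabelings of the *response* matrix only
(9999 permutations by default, explanatory matrices fixed): term p-values
are two-sided on |coefficient|, the model p is the upper tail of R².
Under independence of response and predictors this permutation scheme is
exact, which the calibration test verifies empirically. Exhaustive
enumeration again replaces sampling for small `n`. Comparisons use an
absolute tolerance of 1e-12 so exhaustive p-values are reproducible across
BLAS round-off. Significance is flagged at `alpha = 0.1`, with stars at
p < 0.1 / 0.05 / 0.001 in reports.

**Variance partitioning.** The unique contribution of term *k* is the
leave-one-out drop `R²(full) − R²(without k)`; the model R² minus the sum
of uniques is reported as the shared ("collinearity") portion that cannot
be attributed to any single block. This is the leave-one-out interpretation
of commonality analysis, not the full `2^k` decomposition; uniques can be
numerically negative with suppressor structure and are reported as
computed, with a warning. The intercept is excluded from the partition.

## The three models

The pipeline fits one model per predator set — all predators, Harpalini
only, Zabrini only — rebuilding the Bray–Curtis response from each subset's
columns while reusing the single retained explanatory set from the screen
on the full response. Sub-seeds for the screen and each model fit are
spawned deterministically from the configured seed; identical config +
seed gives byte-identical JSON reports.

## Synthetic studies

The generator emulates the study's shapes: 28 seed species, 37 predators
(15 Harpalini, 18 Zabrini, 4 other), 13 plant families, 4 life strategies,
35-column fatty-acid blocks (exercising the singular-covariance path),
30-column volatile blocks and a 20-column surface-compound block.
Dimensions are sorted log-normal draws (so `A >= B >= C` by construction);
mass is volume × log-normal density (rank correlation with volume ≈ 0.8);
coat thickness and strength share a latent defence factor; chemistry blocks
are exponentiated rank-4 factor models. Two redundancies are built in
deliberately — imbibed volatiles echo dry volatiles, surface fatty acids
echo other surface compounds (latent carryover 0.85) — so the screen has
realistic work.

Consumption follows a trait-level generative story rather than the MRM
model itself: each predator draws standard-normal weights over the
standardized columns of every block, block scores are scaled by effect
sizes `tau_k`, Gaussian noise (sd `noise_sd`, default 1.0) is added, and
consumption is `exp(latent)` rescaled so each predator's maximum is 100.
Default effects make morphology and coat strong drivers (`tau = 1`), mass,
taxonomy and strategy moderate (`tau = 0.5`) and chemistry inert, echoing
the qualitative findings the workflow is designed to detect.

What the generator does *not* emulate: behavioural foraging (encounter and
handling), day-by-day count accumulation and dish replication, phylogenetic
signal beyond the family label, compositional closure of chemistry tables,
and measurement error structure. Passing tests therefore demonstrate that
the statistical machinery is correct and calibrated under a plausible
trait-driven world, not that any particular biological conclusion holds.

## Verification at a glance

* Shape indices, Bray–Curtis, Mahalanobis and the OLS core are checked
  against closed forms and independent brute-force oracles (explicit
  summation, normal equations, affine-invariance).
* Mantel and MRM permutation p-values match exhaustive enumeration exactly
  on 4–5 species instances; the Mantel r is cross-checked against
  scikit-bio.
* Type-I calibration: with all `tau_k = 0` (28 seeds, 300 replicates,
  199 permutations — sizes chosen to make the binomial check sharp while
  the suite stays quick), MRM term rejection at α = 0.05 stays inside the
  binomial 99% interval; the analogous Mantel check uses 500 replicates.
* Recovery: with `tau_dimensions = 2`, `noise_sd = 0.5` and all other
  blocks inert (200 replicates), the dimensions term is significant at
  α = 0.1 in ≥ 90% of replicates, carries the largest median unique R²,
  and inert blocks stay near nominal rejection.

## Limitations

* The exclusion rule and threshold of the screen, the mass/categorical
  metrics, the ridge for singular covariance and the leave-one-out
  partition are all reasonable conventions, not uniquely determined by the
  method; alternative choices change which blocks survive screening.
* MRM term tests permute the whole response, so partial-coefficient
  p-values are exact only under the global null; with strong inter-block
  correlation they are approximate.
* Bray–Curtis pairs of entirely unconsumed seeds are defined as distance 0,
  a convention that matters only for pathological subsets.
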