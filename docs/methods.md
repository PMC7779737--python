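# Methods

This note documents the models, conventions and numerical choices behind
`clusterbench`, in the order of the pipeline.

## Study design

The benchmark emulates district-level surveillance of a rare childhood
cancer.  A geography of H districts with under-15 populations u_i (total N)
hosts a single connected high-risk cluster; 10-year case counts are drawn
per district; three detection methods label districts high-risk; labels are
scored against the truth.  Default conditions mirror the German
nephroblastoma setting: H = 402, λ = 7 per million children per year
(all-malignancies variant: 140 per million), aggregation window T = 10
years, cluster sizes {1, 2, 3, 5, 10, 20, 50}, relative risks
{1, 1.1, 1.2, 1.3, 1.4, 1.5, 2, 5, 10, 100}, 2,000 iterations per cell.

## Synthetic geography

`make_lattice_map` builds a rook-adjacency lattice (edge-sharing neighbors,
matching the notion of administrative districts sharing borders).  The
German-like default is a 21×20 lattice trimmed to 402 cells by shortening
the last row, which preserves connectivity.  Populations are i.i.d.
truncated log-normal, sampled by rejection: `log_mean = ln 20,000`,
`log_sd = 1`, truncated to the observed German range [3,594, 492,448].
These values reproduce the scale and right skew of the real district
populations (median ≈ 20k, total within a factor ~1.2 of 11.05 million);
they do **not** reproduce spatial autocorrelation of population density,
irregular district shapes, or the real adjacency structure, so absolute
performance numbers on the lattice are indicative rather than identical to
those on the real map.  Real geographies can be supplied as CSV bundles.

## Cluster generation

A cluster of target size k grows from a uniformly random start district by
repeatedly adding a uniformly random member of the frontier (non-members
adjacent to the current set).  The expansion distribution is not prescribed
beyond adjacency in the source design; uniform-over-frontier is the
simplest faithful rule.  Growth stuck in a too-small component restarts
from a new random seed district (default 100 attempts, then an error).
"Donut" holes — districts all of whose neighbors are members — are filled
to a fixed point; enclosure is defined graph-theoretically, which coincides
with polygon containment for genuine donuts on planar district maps.
Filled clusters can therefore exceed the target size; scoring always uses
the realized member set.

## Case simulation

Expected counts are e_i = λ u_i T with the population held at one snapshot
(the real study uses 31 Dec 2017).  Counts are one Poisson draw with mean
RR_i e_i (RR_i = cluster RR inside, 1 outside); a single draw with the
T-year mean is distributionally identical to summing T annual draws and
halves the RNG work.  The per-district estimand is the cumulative relative
risk c_i / e_i.  Seeding is counter-based: every (role, size, RR,
iteration) tuple indexes an independent substream of the master seed, so
any cell or single iteration is reproducible in isolation, and the cluster
stream for a given size is shared across RR levels by default
(`paired_clusters`), which matches storing one cluster list per size and
lowers the variance of RR contrasts.

## Besag–Newell test

For center i, districts are ranked by centroid distance (Euclidean on
projected coordinates, great-circle on lon/lat; only the ranking matters),
ties broken by district id.  m_i is the smallest number of neighbors whose
accumulated cases D_{m_i}(i) reach the threshold k; the p-value is the
Poisson tail P(X ≥ k) for the circle's null mean μ.  The default
accumulation rule is the standard `D ≥ k`; a `plus_one` flag reproduces the
`D + 1 ≥ k` dialect.  Two conventions for μ exist in circulation and both
are implemented: the default is the sum of the supplied expected counts
over the circle, μ = E_{m_i}(i) — what reference implementations use when
per-district expected cases are provided, and the deposited benchmark data
ship exactly those; `population_based_mu` instead uses the population share
scaled by the observed total, μ = U_{m_i}(i)·C/N.  The distinction matters:
conditioning on the observed C makes the test lose power once a strong
cluster inflates the overall count (sensitivity becomes non-monotone in RR
at RR ≈ 100), whereas the expected-count mean keeps power monotone and
matches the benchmark's reported behavior.  k defaults to 5
(nephroblastoma; ≈ the 75th percentile of expected district counts) and 50
for the all-malignancies scenario.  The global statistic R counts
significant circles at α = 0.05.  High-risk labels default to the union of
all significant circles; `label_center_only` restricts labels to
significant centers.  In either μ convention, k must be tuned to the
scenario's expected district counts for the test to have power.

## Spatial scan statistic

Zones are nested circles per center, grown by centroid distance while zone
population stays within `max_frac` (default 10%) of N.  The Poisson
log-likelihood ratio D ln(D/E) + (C−D) ln((C−D)/(C−E)), E = U C/N, is
scored only for zones with D > E.  Significance is conditional Monte
Carlo: C cases are redistributed multinomially with probabilities u_i/N
(999 replicates by default), and p = (1 + #{T* ≥ T}) / (1 + n_mc), which
cannot be zero.  The replicate scan is a numba-compiled kernel; the
observed scan is plain numpy and doubles as the cross-check path in tests.
Secondary clusters are on by default: zones disjoint from already-reported
clusters whose own LLR exceeds the (1−α) replicate quantile are also
labeled.  This is needed for true clusters larger than the population cap
allows a single circle to cover (a 50-district cluster cannot fit in one
10% circle); a flag restores the strict most-likely-only reading.  n_mc and
the secondary rule are recorded in result metadata since the reference
study does not state them.

## BYM disease mapping

The model is c_i ~ Poisson(e_i RR_i), log RR_i = μ + s_i + ν_i, with
ν_i ~ N(0, 1/τ_ν) exchangeable and s carrying the intrinsic CAR prior
(conditional mean = neighbor average, conditional variance = 1/(τ_s f_i)
with f_i the neighbor count).  The ICAR density is invariant to constant
shifts, so s is constrained to sum to zero per graph component (per
component on disconnected maps, with a warning); the intercept absorbs the
overall level.  Priors: Gamma(1, 0.001) on each precision — the log-gamma
(1, 0.001) prior on the log-precision written in shape/rate order, matching
the convention of the Laplace-approximation engine such models are usually
fit with — and a near-flat normal on μ (precision 10⁻⁴).

Inference is a deterministic own-authored Gaussian approximation:

* for fixed (τ_s, τ_ν) the latent posterior is log-concave; its mode is
  found by constrained Newton iteration with sparse factorizations,
  projecting onto the sum-to-zero subspace each step (conditioning by
  kriging);
* the two log-precisions maximize the Laplace approximation to their
  marginal posterior (coarse 3×3 grid in log τ, then Nelder–Mead polish;
  generalized ICAR determinant from the cached Laplacian spectrum,
  subspace determinants via the constraint correction);
* district summaries use the Gaussian approximation at that mode:
  RR_i is log-normal, median exp(η_i*), equal-tailed interval
  exp(η_i* ± z σ_i) with σ_i from the constrained marginal variances.

The hyperparameters are plug-in (empirical Bayes), so interval widths
ignore hyperparameter uncertainty; on the benchmark's null fixtures this
still yields label rates far below α, and full-Bayes mixing over a
hyperparameter grid would only widen intervals.  The backend is
deterministic — repeat fits agree exactly, which trivially satisfies the
seed-stability contract — and is validated two ways in the tests: against
an independent MCMC route (emcee on the identical fixed-precision
posterior, small lattice) and through parameter-recovery and
data-dominant-limit checks.  A district is classified high-risk when the
lower 95% equal-tailed bound of RR_i exceeds 1.  Note the identifiability
convention: scaling all e_i by a constant shifts μ by minus its log and
leaves the district-specific pattern unchanged.

## Performance measures

Each iteration yields a district-level 2×2 table against the realized true
cluster.  Per-iteration measures (percent scale): sensitivity, specificity,
correct classification, PPV, NPV; minimum power = 1{TP ≥ 1}; exact power =
1{TP = |truth| and FP = 0}.  Cell aggregates are means with SD across
iterations and normal CIs (mean ± 1.96 SD/√n).  Conventions:

* PPV/NPV iterations with empty denominators are excluded and counted
  (`n_undefined_*`); an `averaging: pooled` mode instead sums counts before
  dividing (binomial SEs on pooled denominators).
* PDL = sens/(100−spec) and NDL = (100−sens)/spec are formed from the cell
  means, because per-iteration ratios are mostly undefined at the null.
* FPR/FNR are the per-iteration complements of PPV/NPV on the same
  iteration subsets.
* The Monte Carlo error of the estimand is the SD across iterations of the
  mean cumulative RR over true-cluster districts.
* A "correct proportion" column is emitted as NaN: the deposited summary
  spreadsheet carries it without a published definition, and guessing one
  would be worse than leaving it empty.

## Pipeline

`run_experiment` iterates (size, RR) cells, checkpointing each cell's
metric rows to CSV (a rerun skips finished cells and recomputes partial
ones); per-iteration raw draws (cluster member ids + case vectors) can be
archived as JSON and re-scored later with different method settings
(`score_archive`, `clusterbench score`).  Method failures are logged and
excluded from that method's cell only.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run scaled-down versions of the
study grid chosen to exercise every code path with stable statistics: null
calibration of the scan uses 500 iterations at n_mc = 999; Bayesian
recovery uses 50 replicates; power monotonicity uses 200 iterations per RR
at cluster size 5 (scan at n_mc = 199 there, a valid Monte Carlo test at
α = 0.05); the acceptance script runs 100 iterations per cell for sizes
{2, 5} × RR {1, 5, 10, 100} with all three methods.  The full 2,000 ×
7 × 10 grid is what `clusterbench run` executes given the study's own
configuration.

## Known limitations

* The lattice geography reproduces population scale and skew, not the real
  adjacency graph; headline numbers on the real German map require the
  deposited adjacency/population data and GADM centroids.
* The BYM backend is an empirical-Bayes Laplace approximation, not a full
  posterior; its credible intervals are slightly narrow in principle.
* No multiple-testing correction is applied in the Besag–Newell test
  (matching the benchmarked convention), and the scan's secondary-cluster
  rule is one of several in circulation (quantile-of-max).
* Overdispersion, covariates, age–period structure and population dynamics
  are out of scope; counts are pure Poisson against a fixed snapshot.
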