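# Methods

## The synchrony statistic

Community synchrony is the variance ratio
φ = Var(Σᵢ xᵢ(t)) / (Σᵢ SD(xᵢ))², computed on a site's *annual* community
matrix (years × taxa of mean densities). By the Cauchy–Schwarz
inequality the numerator never exceeds the squared sum of SDs, so
φ ∈ [0, 1]. φ = 1 iff all taxa are perfectly (positively) linearly
related; φ → 0 under perfect compensation. Useful identities used in
tests: for N equal-variance series with common pairwise correlation ρ,
φ = (1 + (N−1)ρ)/N — hence 1/N under independence and 1 at ρ = 1.

Numerical choices:

- **Variance divisor.** Sample variance (T−1) in numerator and
  denominator. φ is exactly invariant to the divisor as long as it is
  used consistently; a property test asserts this.
- **Zero-variance taxa** stay in the community and contribute 0 to the
  denominator sum (dropping them would change φ).
- **Degenerate input.** If every taxon is constant, φ is 0/0 and a
  `DegenerateCommunityError` is raised rather than returning NaN.
- φ is computed on annualized matrices only; there is deliberately no
  option to compute it on raw event-level series, because within-year
  events are replicate samples of the same population state, not
  dynamics.

## Annualization

Sampling happens in up to E discrete events per year. A taxon absent
from a *sampled* event is an observed zero (monitoring programs record
presences), so the annual value is (sum of recorded densities) /
(number of events sampled in that site-year). Years with no sampling at
a site are absent from the matrix — no interpolation. Duplicate
(site, year, event, taxon) rows are an error rather than being summed:
genus-level aggregation must be done explicitly upstream, where
taxonomy mistakes are visible. Taxon order is lexicographic so matrices
are independent of file row order.

## Monte Carlo null and contributions

The null model permutes each taxon's annual values independently across
years, preserving species marginals while destroying cross-species
correlation. The community test permutes **all** columns in each of
n (default 999) randomizations and reports the one-tailed add-one
p-value (1 + #{φ_null ≥ φ_obs})/(n + 1); the smallest attainable p is
therefore 1/(n+1), and on exchangeable (independent-taxon) data the
test is calibrated: the measured type-I rate at α = 0.05 over 2000
simulated communities is 0.051.

A taxon's contribution permutes **only its own column** (default 100
times). Permutation leaves that column's SD unchanged, so only the
variance of the community total moves; the implementation exploits this
(the denominator is constant across the null) and a test verifies the
fast path equals literally permuting and recomputing. The z-score
(φ_obs − mean null)/SD(null) is classified at ±1.96. A constant column
cannot be changed by permutation — the null is a point mass — so such
taxa are flagged `degenerate` with z = 0 rather than raising, because
real data do contain constant columns. The null SD uses divisor n−1
(at 100 replicates the divisor choice is a ~0.5 % effect).

On independent-taxon data the z-scores are approximately standard
normal (measured mean ≈ 0, SD ≈ 1.0, |z| > 1.96 in ≈ 4–5 % of taxa).
The *positive*-tail rate of a pure-noise taxon embedded in a
synchronous community is ≈ 4–6 % rather than the naive one-tailed
2.5 %, because the single-column null distribution of φ is
right-skewed; the calibration tests use a 5 % ± 3-point band for this
quantity.

Reproducibility: every routine takes a seed; `all_contributions` gives
each taxon its own `SeedSequence` substream keyed by column index, so
results do not depend on evaluation order.

## Turnover, diversity, environmental variability

Turnover uses annualized presence (annual mean density > 0) and
consecutive observed-year pairs: (gains + losses) / union richness of
the pair, averaged across pairs. It is symmetric within a pair and
bounded in [0, 1]. Simpson diversity is the complement form 1 − Σpᵢ².
Environmental variability is the sample SD of the full series at its
native measurement resolution (daily, in the synthetic data) in the
series' own units — no resampling to a common grid, since any
aggregation choice (e.g. SD of means vs mean of SDs) changes the value;
the package states its definition and applies it uniformly.

## Association screens

Spearman correlations use midranks and the two-sided t approximation
with n−2 df (standard at n = 18 sites; exact permutation with ties is
not). **A caveat worth stating**: rank correlations computed from a
*printed, rounded* summary table can differ noticeably from those
computed on the underlying data, because rounding creates ties — on the
published 18-site table the discharge column (3 d.p.) has three sites
tied at 0.015 and two pairs more, which moves φ~discharge from the
0.28 reported on unrounded data to 0.43 on the printed values, and
φ~turnover from 0.03 to 0.05; the temperature screen (−0.26) is
insensitive. The package computes honestly from whatever table it is
given.

Moran's I uses inverse great-circle (haversine) distance weights, zero
diagonal, row-standardized — a declared default, reported in the
result's `weight_spec`, since no single weighting convention is
canonical. p-values come from random permutation of values over
locations (999 by default), two-sided around the exchangeability
expectation −1/(n−1). Coincident coordinates are a hard error naming
the offending pair (infinite weight). The implementation is verified
against a brute-force O(n²) double sum.

## Feeding-group model

Contribution z-scores are modelled as
`z ~ group + (1|site) + (1|genus)`, Gaussian, fitted by REML
(statsmodels `MixedLM` with variance components on a single constant
top-level group, which yields genuinely crossed site and genus
intercepts). Treatment coding with the alphabetically first group
present as reference (`filterer` for the standard five) — declared
because group contrasts are meaningless without a stated baseline.
The optimizer tries lbfgs, then bfgs, then powell; non-convergence is
flagged in the result (and the pipeline manifest) rather than raised.
Proportions of positive/negative contributors per group count
degenerate taxa in the denominator; taxa without a group assignment are
counted, logged and excluded.

## Synthetic studies

The generator emulates the *shape* of a standardized multi-site stream
monitoring design: 18 sites, 8 years, 3 sampling events per year,
100–230 genera per site, daily temperature and discharge series, and a
five-group feeding-group table over a shared 400-genus pool (shared so
genera recur across sites, which the crossed-effects model requires).

Synchrony is controlled on the log scale by a factor model: log-density
anomalies are √ρ_b·s(t) + √(ρ_w−ρ_b)·g_f(t) + λ_f·e(t) + √(1−ρ_w)·ε,
with a shared driver s, per-group drivers g, an optional standardized
environmental driver e (loadings λ default 0) and independent noise.
With λ = 0 this gives exact pairwise log-correlations ρ_within within a
group and ρ_between across groups, so the compound-symmetry closed form
is an oracle for the whole chain. Turnover masks latent abundances to
zero through a symmetric extinction/colonization Markov chain (rate
0.3/yr by default, matching typical observed annual turnover ≈ 0.2–0.6)
— masking, not regeneration, keeps persisting taxa's correlations
intact. Event-level densities multiply the annual value by lognormal
noise (SD 0.5 on the log scale). Mean log densities spread with SD 1
across taxa (a lognormal rank-abundance profile); density scale 50
individuals per unit area. Environmental series are a seasonal sinusoid
plus noise (temperature) and lognormal base flow with rare spate spikes
(discharge), each rescaled — additively for temperature, multiplicatively
(positivity-preserving) for discharge — so the realized series SD equals
a target drawn from the configured range (defaults 1–18 °C and
0.002–0.44 m³/s, the observed cross-site ranges); variability is thus a
control parameter, not an emergent quantity.

What the generator does **not** emulate: mechanistic density dependence
or species interactions (no Ricker/Lotka–Volterra), dispersal between
sites, observation effort beyond event noise, seasonality in community
composition, or environmental forcing of abundances unless λ ≠ 0 is
requested. Passing tests therefore demonstrate statistical correctness
and calibration of the estimators on data with known structure — not
that real communities satisfy the factor-model assumptions.

## Problem sizes in the standard checks

The validation suite uses sizes at which Monte Carlo error is small but
runtimes stay in seconds-to-minutes: compound-symmetry recovery at
N = 10, T = 200 with 1000 replicates (3 MC-SE band; replicates chosen
so the band, not the check's own false-alarm rate, binds); null
calibration on 1000 communities of 20 taxa × 10 years with 999-rep
nulls; contribution calibration over 400 seeds; mixed-model recovery
over 20 simulated datasets (5 groups × 12 genera × 10 sites, ~70 %
site occupancy) plus 100 genus-level label permutations. The end-to-end
synthetic pipeline example runs 18 sites with 40–60 genera per site
from a 150-genus pool.

## Known limitations

- The variance-ratio φ is scale-free but not richness-free; comparisons
  across communities of very different N should lean on the null test
  and z-scores rather than raw φ.
- The permutation null destroys temporal autocorrelation within taxa as
  well as cross-correlation; strongly autocorrelated series make the
  test anti-conservative for the question "more synchronous than
  independent", as with all within-series permutation nulls.
- The mixed model assumes Gaussian z-scores; heavy-tailed contribution
  distributions (few dominant taxa) are better screened with the
  per-group proportions it accompanies.
- Spearman p-values use the t approximation; at n < 10 sites treat them
  as descriptive.
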