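# streamsync

Community synchrony analysis for multi-site abundance time series, built
around the questions ecologists ask of long-term stream macroinvertebrate
monitoring data (e.g. NEON's wadeable-stream sites): do the taxa of a
community fluctuate together or compensate for one another, which taxa
drive that pattern, and is the pattern related to environmental
variability, species turnover, or functional feeding group?

## The statistic

For a community of $N$ taxa with annual density series $x_i(t)$,
community synchrony is the variance ratio

$$
\varphi = \frac{\operatorname{Var}\!\left(\sum_i x_i(t)\right)}
               {\left(\sum_i \operatorname{SD}(x_i)\right)^2}
\in [0, 1],
$$

where $\varphi = 1$ means all taxa fluctuate in perfect proportion and
$\varphi \to 0$ means fluctuations cancel (compensatory dynamics).
Around it the package provides:

- **Monte Carlo null test** — within-taxon permutation across years
  (999 randomizations by default) destroys cross-taxon correlation while
  preserving each taxon's marginal distribution; a one-tailed add-one
  p-value asks whether the observed community is more synchronous than
  the null.
- **Per-taxon contributions** — one taxon's series is permuted (100
  times by default) while all others stay fixed; the z-score of observed
  $\varphi$ against that taxon-specific null classifies the taxon as
  contributing to synchrony ($z > 1.96$), to asynchrony ($z < -1.96$),
  or neither.
- **Community metrics** — year-to-year species turnover
  ((gains + losses) / union richness), richness, Simpson diversity
  $1 - \sum p_i^2$, and environmental variability (sample SD of the full
  temperature or discharge series).
- **Association screens** — Spearman rank correlations of site-level
  $\varphi$ against environmental variability and turnover; Moran's I
  with inverse great-circle-distance weights and a permutation test for
  spatial autocorrelation.
- **Functional feeding groups** — per-group proportions of positively /
  negatively contributing taxa, and a Gaussian mixed model
  `z ~ group + (1|site) + (1|genus)` (REML, crossed random intercepts)
  testing whether feeding groups differ in their contributions.
- **Synthetic studies** — a seeded generator of NEON-shaped multi-site
  bundles (community long table, daily temperature and discharge series,
  feeding-group table, coordinates) with controllable synchrony,
  turnover and environmental variability, so every stage runs and is
  testable offline.

## Worked example

Simulate a four-site study, test synchrony per site, and score every
taxon's contribution:

```bash
$ streamsync simulate --seed 4 --sites 4 --out demo
wrote 5 tables to demo

$ streamsync synchrony demo/community.csv --reps 999 --seed 0
S01: phi=0.1497 p=0.001
S02: phi=0.0843 p=0.001
S03: phi=0.0790 p=0.001
S04: phi=0.2220 p=0.001

$ streamsync contributions demo/community.csv --reps 100 --seed 0 --out contrib.csv
737 taxa: {'nonsignificant': 621, 'positive': 114, 'negative': 2}
```

Each site's $\varphi$ is low (0.08–0.22) but far above its permutation
null — p = 0.001 is the smallest value attainable with 999
randomizations — i.e. these communities are weakly yet significantly
synchronous, which is the typical regime in real stream data. Most taxa
do not individually move the community statistic; the 114 positive taxa
are the ones whose series track the community total.

The package ships the published site-level summary table for the 18
NEON wadeable streams (2014–2022) as reference data; the association
screen applied to those printed values gives

```bash
$ streamsync associate ref.csv     # ref.csv = streamsync.load_reference_site_table()
phi ~ temp_sd: rho=-0.2553 p=0.3066 (n=18)
phi ~ turnover_mean: rho=0.0456 p=0.8575 (n=18)
phi ~ discharge_sd: rho=0.4292 p=0.0755 (n=18)
```

— no significant association between synchrony and temperature
variability, turnover, or discharge variability at these 18 sites.
(Coefficients computed from a printed, rounded table can differ from
ones computed on the underlying data, because rounding creates rank
ties; see `docs/methods.md`.)

`streamsync pipeline --config cfg.yaml` runs everything end to end —
site summaries, contributions, feeding-group proportions, correlation
and Moran's I screens, the mixed model, and a JSON manifest — and is
byte-for-byte reproducible for a fixed config and seed.

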