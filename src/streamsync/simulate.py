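"""Synthetic multi-site study generator.

Emulates the shape of a NEON-style stream macroinvertebrate study —
many sites, ~8 years, 3 sampling events per year, 100–230 genera per
site — with controllable community synchrony, year-to-year turnover,
functional-group structure and environmental variability, so the whole
pipeline is testable without any download.

The synchrony control is a Gaussian factor model on log densities:

    y_i(t) = sqrt(rho_between) * s(t)
           + sqrt(rho_within - rho_between) * g_{f(i)}(t)
           + loading_{f(i)} * e(t)
           + sqrt(1 - rho_within) * eps_i(t)

with a shared site driver s, one driver g per feeding group, an
optional standardized environmental driver e, and independent noise.
With zero environmental loadings every pair of taxa in the same group
has log-scale correlation ``rho_within`` and pairs in different groups
``rho_between``, giving exact compound-symmetry targets with a
closed-form synchrony oracle.  Turnover is imposed by masking latent
abundances to zero through a symmetric presence/absence Markov chain,
which leaves the correlation structure of persisting taxa intact.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    FFG_GROUPS,
    CommunityTable,
    EnvSeries,
    FFGTable,
    SiteCoords,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study.

    Defaults mirror the sampling design they emulate: 18 sites, 8 years,
    3 events per year, 100–230 genera per site, turnover around 0.3 and
    temperature/discharge variability spanning the observed site ranges
    (roughly 1–18 degC and 0.002–0.44 m³/s).
    """

    n_sites: int = 18
    n_years: int = 8
    events_per_year: int = 3
    n_taxa_range: tuple[int, int] = (100, 230)
    #: proportion of the taxon pool in each group, FFG_GROUPS order
    #: (filterer, gatherer, predator, scraper, shredder); gatherers are
    #: the most taxon-rich group in these streams.
    ffg_weights: tuple[float, ...] = (0.10, 0.40, 0.20, 0.15, 0.15)
    rho_within: float = 0.3
    rho_between: float = 0.1
    #: per-group loading on the standardized environmental driver,
    #: FFG_GROUPS order; zero keeps the compound-symmetry targets exact.
    env_loading: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    turnover_rate: float = 0.3
    event_noise_sd: float = 0.5
    #: spread of log mean densities across taxa (lognormal rank-abundance).
    abundance_sigma: float = 1.0
    density_scale: float = 50.0
    temp_sd_range: tuple[float, float] = (1.0, 18.0)
    discharge_sd_range: tuple[float, float] = (0.002, 0.44)
    taxon_pool: int = 400
    start_year: int = 2014
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_years < 2 or self.events_per_year < 1:
            raise ConfigError("need n_sites >= 1, n_years >= 2, events_per_year >= 1")
        lo, hi = self.n_taxa_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad n_taxa_range {self.n_taxa_range}")
        if hi > self.taxon_pool:
            raise ConfigError("n_taxa_range exceeds the taxon pool size")
        w = np.asarray(self.ffg_weights, dtype=float)
        if len(w) != len(FFG_GROUPS) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ConfigError("ffg_weights must be 5 non-negative proportions summing to 1")
        if not (0.0 <= self.rho_between <= self.rho_within <= 1.0):
            raise ConfigError("need 0 <= rho_between <= rho_within <= 1")
        if not (0.0 <= self.turnover_rate <= 1.0):
            raise ConfigError("turnover_rate must be in [0, 1]")
        if self.event_noise_sd < 0 or self.abundance_sigma < 0:
            raise ConfigError("noise SDs must be non-negative")
        if len(self.env_loading) != len(FFG_GROUPS):
            raise ConfigError("env_loading needs one value per feeding group")
        for name in ("temp_sd_range", "discharge_sd_range"):
            lo_, hi_ = getattr(self, name)
            if lo_ > hi_ or lo_ < 0:
                raise ConfigError(f"degenerate {name}: ({lo_}, {hi_})")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        kwargs = dict(d)
        for key in (
            "n_taxa_range",
            "ffg_weights",
            "env_loading",
            "temp_sd_range",
            "discharge_sd_range",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StudyBundle:
    """A mutually consistent synthetic study: all pipeline inputs."""

    community: CommunityTable
    temperature: dict[str, EnvSeries]
    discharge: dict[str, EnvSeries]
    ffg: FFGTable
    coords: SiteCoords
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the four input CSVs in the dialect the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "community": outdir / "community.csv",
            "temperature": outdir / "temperature.csv",
            "discharge": outdir / "discharge.csv",
            "ffg": outdir / "ffg.csv",
            "coords": outdir / "coords.csv",
        }
        self.community.df.to_csv(paths["community"], index=False)
        for name, table in (("temperature", self.temperature), ("discharge", self.discharge)):
            frames = [
                pd.DataFrame(
                    {"site": s.site_id, "timestamp": s.timestamps, "value": s.values}
                )
                for s in table.values()
            ]
            pd.concat(frames, ignore_index=True).to_csv(paths[name], index=False)
        pd.DataFrame(
            sorted(self.ffg.mapping.items()), columns=["taxon", "group"]
        ).to_csv(paths["ffg"], index=False)
        self.coords.df.to_csv(paths["coords"], index=False)
        return paths


def _site_rngs(config: SyntheticConfig) -> tuple[np.random.Generator, list]:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_sites + 1)
    return np.random.default_rng(children[0]), children[1:]


def _scale_to_sd(anomalies: np.ndarray, target_sd: float) -> np.ndarray:
    """Rescale zero-ish-mean anomalies so the sample SD equals target_sd."""
    sd = anomalies.std(ddof=1)
    if sd == 0 or target_sd == 0:
        return np.zeros_like(anomalies)
    return anomalies * (target_sd / sd)


def generate_env(
    config: SyntheticConfig, site_id: str, rng: np.random.Generator
) -> tuple[EnvSeries, EnvSeries]:
    """Daily temperature and discharge series for one site.

    Temperature is a seasonal sinusoid plus Gaussian noise whose
    anomalies are rescaled so the series SD hits a target drawn from
    ``temp_sd_range``.  Discharge is lognormal base flow with rare
    Bernoulli spate spikes, scaled multiplicatively (preserving
    positivity) to a target SD from ``discharge_sd_range``.
    """
    config.validate()
    n_days = config.n_years * 365
    dates = pd.date_range(f"{config.start_year}-01-01", periods=n_days, freq="D")
    doy = np.arange(n_days) % 365

    t_target = rng.uniform(*config.temp_sd_range)
    seasonal = np.sin(2 * np.pi * doy / 365.0)
    noise = rng.normal(0.0, 0.3, n_days)
    anomalies = _scale_to_sd(seasonal + noise, t_target)
    temp = EnvSeries(site_id, "temperature", dates.to_numpy(), 10.0 + anomalies)

    q_target = rng.uniform(*config.discharge_sd_range)
    base = np.exp(rng.normal(0.0, 0.8, n_days))
    spikes = rng.random(n_days) < 0.02
    base = base + spikes * rng.exponential(5.0, n_days)
    sd = base.std(ddof=1)
    values = base * (q_target / sd) if sd > 0 and q_target > 0 else np.full(n_days, base.mean())
    disch = EnvSeries(site_id, "discharge", dates.to_numpy(), values)
    return temp, disch


def _latent_log_densities(
    config: SyntheticConfig,
    groups_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(T, N) latent log-density anomalies with compound-symmetry structure."""
    T, N = config.n_years, len(groups_idx)
    a = np.sqrt(config.rho_between)
    b = np.sqrt(config.rho_within - config.rho_between)
    c = np.sqrt(1.0 - config.rho_within)
    shared = rng.normal(size=T)
    group_drivers = rng.normal(size=(len(FFG_GROUPS), T))
    env_driver = rng.normal(size=T)
    eps = rng.normal(size=(T, N))
    loadings = np.asarray(config.env_loading, dtype=float)[groups_idx]
    y = (
        a * shared[:, None]
        + b * group_drivers[groups_idx, :].T
        + loadings[None, :] * env_driver[:, None]
        + c * eps
    )
    return y


def _presence_mask(
    config: SyntheticConfig, n_taxa: int, rng: np.random.Generator
) -> np.ndarray:
    """(T, N) boolean presence via a symmetric extinction/colonization chain.

    All taxa start present in year 1; each year a present taxon goes
    locally extinct with probability ``turnover_rate`` and an absent one
    recolonizes with the same probability.
    """
    T = config.n_years
    mask = np.ones((T, n_taxa), dtype=bool)
    for t in range(1, T):
        flip = rng.random(n_taxa) < config.turnover_rate
        mask[t] = np.where(flip, ~mask[t - 1], mask[t - 1])
    return mask


def generate_community(
    config: SyntheticConfig,
    site_id: str,
    rng: np.random.Generator,
    taxa: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format observation rows for one site (only observed taxa).

    ``taxa``/``groups`` may be passed to draw the site's assemblage from
    a shared study-wide pool; otherwise a standalone pool is created.
    """
    config.validate()
    if taxa is None:
        n = int(rng.integers(config.n_taxa_range[0], config.n_taxa_range[1] + 1))
        taxa = np.array([f"Genus{i + 1:04d}" for i in range(n)])
        groups = rng.choice(len(FFG_GROUPS), size=n, p=config.ffg_weights)
    n = len(taxa)
    groups_idx = np.asarray(groups, dtype=int)

    mu = rng.normal(0.0, config.abundance_sigma, n)
    latent = _latent_log_densities(config, groups_idx, rng)
    annual = config.density_scale * np.exp(mu[None, :] + latent)  # (T, N)
    mask = _presence_mask(config, n, rng)
    annual = annual * mask

    years = config.start_year + np.arange(config.n_years)
    E = config.events_per_year
    rows = []
    for t, year in enumerate(years):
        present = np.flatnonzero(mask[t])
        if present.size == 0:
            continue
        noise = (
            np.exp(rng.normal(0.0, config.event_noise_sd, (E, present.size)))
            if config.event_noise_sd > 0
            else np.ones((E, present.size))
        )
        dens = annual[t, present][None, :] * noise  # (E, n_present)
        for e in range(E):
            rows.append(
                pd.DataFrame(
                    {
                        "site": site_id,
                        "year": int(year),
                        "event": e + 1,
                        "taxon": taxa[present],
                        "density": dens[e],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_study(config: SyntheticConfig) -> StudyBundle:
    """Generate a full mutually-consistent study bundle.

    Sites draw their assemblages from a shared taxon pool with a single
    study-wide feeding-group assignment, so genera recur across sites
    (which the crossed random-effects model needs).  The same seed
    always yields a bitwise-identical bundle.
    """
    config.validate()
    master, site_seeds = _site_rngs(config)

    pool = np.array([f"Genus{i + 1:04d}" for i in range(config.taxon_pool)])
    pool_groups = master.choice(len(FFG_GROUPS), size=config.taxon_pool, p=config.ffg_weights)
    ffg = FFGTable({t: FFG_GROUPS[g] for t, g in zip(pool, pool_groups)})

    site_ids = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    lats = master.uniform(33.0, 46.0, config.n_sites)
    lons = master.uniform(-122.0, -72.0, config.n_sites)
    coords = SiteCoords(
        pd.DataFrame({"site": site_ids, "lat": np.round(lats, 4), "lon": np.round(lons, 4)})
    )

    community_frames = []
    temperature: dict[str, EnvSeries] = {}
    discharge: dict[str, EnvSeries] = {}
    for site_id, seed in zip(site_ids, site_seeds):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(config.n_taxa_range[0], config.n_taxa_range[1] + 1))
        chosen = np.sort(rng.choice(config.taxon_pool, size=n, replace=False))
        frame = generate_community(
            config, site_id, rng, taxa=pool[chosen], groups=pool_groups[chosen]
        )
        community_frames.append(frame)
        temperature[site_id], discharge[site_id] = generate_env(config, site_id, rng)

    community = CommunityTable.from_frame(
        pd.concat(community_frames, ignore_index=True)
    )
    return StudyBundle(
        community=community,
        temperature=temperature,
        discharge=discharge,
        ffg=ffg,
        coords=coords,
        config=config,
    )
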