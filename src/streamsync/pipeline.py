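"""End-to-end orchestration.

Runs, per site: annualization, community synchrony with its Monte Carlo
null, per-taxon contribution z-scores, turnover and environmental
variability — then the study-level association screens (Spearman,
Moran's I), feeding-group aggregation, and the crossed random-effects
model.  Writes all artifacts as CSV plus a JSON run manifest; the same
config and seed always reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    ffg_proportions,
    fit_ffg_mixed_model,
    morans_i,
    spearman,
)
from .errors import ConfigError, StreamSyncError
from .io import (
    read_community_long,
    read_env_table,
    read_ffg_table,
    read_site_coords,
    to_site_matrix,
    write_site_summary,
)
from .metrics import build_site_summary, temporal_turnover
from .resampling import all_contributions, community_null_test
from .simulate import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, Monte Carlo settings and output location for a full run.

    Either the four input paths are given, or ``synthetic`` holds a
    generator config and the study is simulated in memory.
    """

    outdir: str
    community_path: str | None = None
    temperature_path: str | None = None
    discharge_path: str | None = None
    ffg_path: str | None = None
    coords_path: str | None = None
    synthetic: SyntheticConfig | None = None
    n_reps_community: int = 999
    n_reps_taxon: int = 100
    n_perm_moran: int = 999
    alpha: float = 0.05
    z_crit: float = 1.96
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if min(self.n_reps_community, self.n_reps_taxon, self.n_perm_moran) < 1:
            raise ConfigError("replicate counts must be >= 1")
        file_inputs = (
            self.community_path,
            self.temperature_path,
            self.discharge_path,
            self.ffg_path,
            self.coords_path,
        )
        if self.synthetic is None and any(p is None for p in file_inputs):
            raise ConfigError(
                "provide either all five input paths or a synthetic block"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig.from_dict(syn)
        return cls(synthetic=syn, **raw)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        bundle = generate_study(config.synthetic)
        return (
            bundle.community,
            bundle.temperature,
            bundle.discharge,
            bundle.ffg,
            bundle.coords,
        )
    community = read_community_long(config.community_path)
    temperature = read_env_table(config.temperature_path, "temperature")
    discharge = read_env_table(config.discharge_path, "discharge")
    ffg = read_ffg_table(config.ffg_path)
    coords = read_site_coords(config.coords_path)
    return community, temperature, discharge, ffg, coords


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact set to ``config.outdir``.

    Artifacts: site_summary.csv, contributions.csv, ffg_summary.csv,
    correlations.csv, morans_i.csv, mixed_model.csv, manifest.json.
    On any stage failure the partially written directory is removed and
    the error re-raised with the failing stage and site in its message.
    """
    outdir = Path(config.outdir)
    staging = Path(tempfile.mkdtemp(prefix="streamsync_", dir=outdir.parent if outdir.parent.exists() else None))
    warnings_log: list[str] = []
    try:
        community, temperature, discharge, ffg, coords = _load_inputs(config)
        sites = community.sites
        rng_seeds = {
            site: s
            for site, s in zip(sites, np.random.SeedSequence(config.seed).spawn(len(sites)))
        }

        summaries = []
        contrib_rows = []
        all_contribs = []
        turnover_rows = []
        for site in sites:
            logger.info("site %s: annualizing and testing synchrony", site)
            try:
                matrix = to_site_matrix(community, site)
                child = rng_seeds[site].spawn(2)
                sync = community_null_test(
                    matrix, n_reps=config.n_reps_community, seed=child[0]
                )
                contribs = all_contributions(
                    matrix,
                    n_reps=config.n_reps_taxon,
                    seed=child[1],
                    z_crit=config.z_crit,
                )
                summaries.append(
                    build_site_summary(
                        matrix, temperature[site], discharge[site], coords, sync
                    )
                )
                for y0, y1, tv in temporal_turnover(matrix).per_interval:
                    turnover_rows.append(
                        {"site": site, "year_from": y0, "year_to": y1, "turnover": tv}
                    )
            except StreamSyncError as exc:
                raise type(exc)(f"[site {site}] {exc}") from exc
            n_degenerate = sum(c.classification == "degenerate" for c in contribs)
            if n_degenerate:
                warnings_log.append(
                    f"site {site}: {n_degenerate} degenerate (constant) taxa"
                )
            for c in contribs:
                all_contribs.append((site, c))
                contrib_rows.append(
                    {
                        "site": site,
                        "taxon": c.taxon,
                        "ffg": ffg.group_of(c.taxon) or "",
                        "z": c.z,
                        "phi_obs": c.phi_obs,
                        "null_mean": c.null_mean,
                        "null_sd": c.null_sd,
                        "n_reps": c.n_reps,
                        "classification": c.classification,
                    }
                )

        summary_df = pd.DataFrame(
            {
                "site": [s.site_id for s in summaries],
                "phi": [s.phi for s in summaries],
                "temp_sd": [s.temp_sd for s in summaries],
                "turnover_mean": [s.mean_turnover for s in summaries],
                "discharge_sd": [s.discharge_sd for s in summaries],
            }
        )

        # --- association screens -----------------------------------------
        corr_rows = []
        for var in ("temp_sd", "turnover_mean", "discharge_sd"):
            r = spearman(summary_df["phi"], summary_df[var])
            corr_rows.append(
                {"variable_pair": f"phi~{var}", "rho": r.rho, "p": r.p_value, "n": r.n}
            )

        moran_rows = []
        moran_seed = np.random.SeedSequence([config.seed, 7]).spawn(4)
        for (var, child) in zip(("phi", "temp_sd", "turnover_mean", "discharge_sd"), moran_seed):
            m = morans_i(
                summary_df[var].to_numpy(),
                coords,
                sites=list(summary_df["site"]),
                n_perm=config.n_perm_moran,
                seed=child,
            )
            moran_rows.append(
                {
                    "variable": var,
                    "I": m.I,
                    "expected_I": m.expected_I,
                    "p": m.p_value,
                    "n": m.n,
                    "weight_spec": m.weight_spec,
                }
            )

        # --- feeding-group stage ------------------------------------------
        contribs_flat = [c for _, c in all_contribs]
        groups = ffg_proportions(contribs_flat, ffg)
        n_unassigned = sum(ffg.group_of(c.taxon) is None for c in contribs_flat)
        if n_unassigned:
            warnings_log.append(
                f"{n_unassigned} contribution rows without FFG assignment excluded "
                "from group analyses"
            )
        ffg_df = pd.DataFrame(
            {
                "group": [g.group for g in groups],
                "n_taxa": [g.n_taxa for g in groups],
                "prop_positive": [g.prop_positive for g in groups],
                "prop_negative": [g.prop_negative for g in groups],
            }
        )

        model_df = pd.DataFrame(
            {
                "z": [c.z for site, c in all_contribs],
                "site": [site for site, c in all_contribs],
                "genus": [c.taxon for site, c in all_contribs],
                "group": [ffg.group_of(c.taxon) for site, c in all_contribs],
            }
        ).dropna(subset=["group"])
        model = fit_ffg_mixed_model(model_df)
        if not model.converged:
            warnings_log.append(f"mixed model: {model.message}")
        fe = model.fixed_effects.reset_index()
        vc_rows = [
            {"term": f"var({k})", "estimate": v, "std_error": np.nan, "t_value": np.nan}
            for k, v in model.variance_components.items()
        ]
        model_out = pd.concat([fe, pd.DataFrame(vc_rows)], ignore_index=True)

        # --- write artifacts ----------------------------------------------
        write_site_summary(summaries, staging / "site_summary.csv")
        pd.DataFrame(contrib_rows).to_csv(staging / "contributions.csv", index=False)
        pd.DataFrame(turnover_rows).to_csv(staging / "turnover_intervals.csv", index=False)
        ffg_df.to_csv(staging / "ffg_summary.csv", index=False)
        pd.DataFrame(corr_rows).to_csv(staging / "correlations.csv", index=False)
        pd.DataFrame(moran_rows).to_csv(staging / "morans_i.csv", index=False)
        model_out.to_csv(staging / "mixed_model.csv", index=False)

        manifest = {
            "streamsync_version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "z_crit": config.z_crit,
            "n_reps_community": config.n_reps_community,
            "n_reps_taxon": config.n_reps_taxon,
            "n_perm_moran": config.n_perm_moran,
            "n_sites": len(sites),
            "synthetic": (
                config.synthetic.to_dict() if config.synthetic is not None else None
            ),
            "inputs": {
                "community": config.community_path,
                "temperature": config.temperature_path,
                "discharge": config.discharge_path,
                "ffg": config.ffg_path,
                "coords": config.coords_path,
            },
            "mixed_model_reference_level": model.reference_level,
            "mixed_model_converged": model.converged,
            "warnings": warnings_log,
            "versions": _versions(),
        }
        with open(staging / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise

    if outdir.exists():
        shutil.rmtree(outdir)
    shutil.move(str(staging), str(outdir))
    return outdir


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
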