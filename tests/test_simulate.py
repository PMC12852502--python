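"""Synthetic study generator: determinism, integrity, statistical targets."""

import numpy as np
import pandas as pd
import pytest

from streamsync import (
    ConfigError,
    SyntheticConfig,
    community_synchrony,
    env_variability,
    expected_phi_compound_symmetry,
    generate_study,
    temporal_turnover,
    to_site_matrix,
)
from streamsync.simulate import generate_community, generate_env


def small_config(**kw):
    base = dict(
        n_sites=3, n_years=8, events_per_year=3, n_taxa_range=(15, 25),
        taxon_pool=60, seed=42,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SyntheticConfig().validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"ffg_weights": (0.5, 0.5, 0.0, 0.0, 0.5)},
            {"rho_within": 0.2, "rho_between": 0.5},
            {"turnover_rate": 1.5},
            {"temp_sd_range": (5.0, 1.0)},
            {"n_taxa_range": (0, 10)},
            {"n_years": 1},
        ],
    )
    def test_invariant_violations_rejected(self, kw):
        with pytest.raises(ConfigError):
            small_config(**kw).validate()


class TestDeterminism:
    def test_same_seed_bitwise_identical_bundle(self):
        b1 = generate_study(small_config())
        b2 = generate_study(small_config())
        pd.testing.assert_frame_equal(b1.community.df, b2.community.df)
        pd.testing.assert_frame_equal(b1.coords.df, b2.coords.df)
        assert b1.ffg.mapping == b2.ffg.mapping
        for s in b1.temperature:
            np.testing.assert_array_equal(
                b1.temperature[s].values, b2.temperature[s].values
            )
            np.testing.assert_array_equal(
                b1.discharge[s].values, b2.discharge[s].values
            )

    def test_different_seed_differs(self):
        b1 = generate_study(small_config(seed=1))
        b2 = generate_study(small_config(seed=2))
        assert not b1.community.df.equals(b2.community.df)


@pytest.fixture(scope="module")
def bundle():
    return generate_study(small_config())


class TestBundleIntegrity:
    def test_densities_positive_where_recorded(self, bundle):
        assert (bundle.community.df["density"] > 0).all()

    def test_every_taxon_has_ffg_row(self, bundle):
        taxa = set(bundle.community.df["taxon"])
        assert all(bundle.ffg.group_of(t) is not None for t in taxa)

    def test_site_tables_mutually_consistent(self, bundle):
        sites = set(bundle.community.sites)
        assert sites == set(bundle.temperature)
        assert sites == set(bundle.discharge)
        assert sites == set(bundle.coords.sites)

    def test_shape_matches_config(self, bundle):
        cfg = bundle.config
        assert len(bundle.community.sites) == cfg.n_sites
        for s in bundle.community.sites:
            sub = bundle.community.df[bundle.community.df["site"] == s]
            assert sub["year"].nunique() <= cfg.n_years
            assert sub["event"].max() <= cfg.events_per_year
            m = to_site_matrix(bundle.community, s)
            assert cfg.n_taxa_range[0] <= m.n_taxa <= cfg.n_taxa_range[1]

    def test_round_trip_through_files(self, bundle, tmp_path):
        from streamsync import read_community_long, read_env_table, read_ffg_table

        paths = bundle.write(tmp_path)
        table = read_community_long(paths["community"])
        pd.testing.assert_frame_equal(table.df, bundle.community.df)
        temps = read_env_table(paths["temperature"], "temperature")
        assert set(temps) == set(bundle.temperature)
        assert len(read_ffg_table(paths["ffg"])) == len(bundle.ffg)


class TestStatisticalTargets:
    def test_no_turnover_means_zero_turnover(self):
        b = generate_study(small_config(turnover_rate=0.0))
        for s in b.community.sites:
            m = to_site_matrix(b.community, s)
            assert temporal_turnover(m).mean_turnover == 0.0

    def test_turnover_monotone_in_rate(self):
        means = []
        for rate in (0.0, 0.2, 0.5):
            b = generate_study(small_config(turnover_rate=rate, seed=3))
            vals = [
                temporal_turnover(to_site_matrix(b.community, s)).mean_turnover
                for s in b.community.sites
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_perfect_correlation_gives_phi_one(self):
        cfg = small_config(
            rho_within=1.0, rho_between=1.0, turnover_rate=0.0, event_noise_sd=0.0
        )
        b = generate_study(cfg)
        for s in b.community.sites:
            phi = community_synchrony(to_site_matrix(b.community, s)).phi
            assert phi == pytest.approx(1.0, abs=1e-9)

    def test_independent_taxa_phi_near_one_over_n(self):
        # equal-abundance independent taxa: phi should approach 1/N
        cfg = small_config(
            n_years=40, n_taxa_range=(20, 20), rho_within=0.0, rho_between=0.0,
            turnover_rate=0.0, event_noise_sd=0.0, abundance_sigma=0.0, seed=9,
        )
        b = generate_study(cfg)
        phis = [
            community_synchrony(to_site_matrix(b.community, s)).phi
            for s in b.community.sites
        ]
        assert np.mean(phis) == pytest.approx(
            expected_phi_compound_symmetry(20, 0.0), abs=0.04
        )

    def test_log_density_correlations_match_targets(self):
        cfg = small_config(
            n_years=150, n_taxa_range=(24, 24), rho_within=0.5, rho_between=0.2,
            turnover_rate=0.0, event_noise_sd=0.0, n_sites=1, seed=11,
        )
        b = generate_study(cfg)
        m = to_site_matrix(b.community, b.community.sites[0])
        logX = np.log(m.X)
        groups = np.array([b.ffg.group_of(t) for t in m.taxa])
        C = np.corrcoef(logX.T)
        same = np.equal.outer(groups, groups) & ~np.eye(len(groups), dtype=bool)
        diff = ~np.equal.outer(groups, groups)
        assert C[same].mean() == pytest.approx(0.5, abs=0.08)
        assert C[diff].mean() == pytest.approx(0.2, abs=0.08)

    def test_env_series_hit_requested_variability(self):
        cfg = small_config(temp_sd_range=(4.0, 4.0), discharge_sd_range=(0.05, 0.05))
        rng = np.random.default_rng(0)
        temp, disch = generate_env(cfg, "X", rng)
        assert env_variability(temp) == pytest.approx(4.0, rel=1e-6)
        assert env_variability(disch) == pytest.approx(0.05, rel=1e-6)
        assert (disch.values >= 0).all()

    def test_zero_variability_gives_flat_series(self):
        cfg = small_config(temp_sd_range=(0.0, 0.0))
        temp, _ = generate_env(cfg, "X", np.random.default_rng(0))
        assert env_variability(temp) == 0.0

    def test_high_vs_low_rho_separates_phi(self):
        lo = generate_study(small_config(rho_within=0.05, rho_between=0.05, seed=21))
        hi = generate_study(small_config(rho_within=0.8, rho_between=0.8, seed=21))
        phi_lo = np.mean(
            [community_synchrony(to_site_matrix(lo.community, s)).phi for s in lo.community.sites]
        )
        phi_hi = np.mean(
            [community_synchrony(to_site_matrix(hi.community, s)).phi for s in hi.community.sites]
        )
        assert phi_hi > phi_lo + 0.2
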