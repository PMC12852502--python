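"""Correlation screens, Moran's I, FFG aggregation and the mixed model."""

import numpy as np
import pandas as pd
import pytest

from streamsync import (
    ValidationError,
    ffg_proportions,
    fit_ffg_mixed_model,
    morans_i,
    spearman,
)
from streamsync.associations import haversine_matrix
from streamsync.io import FFG_GROUPS, FFGTable, SiteCoords
from streamsync.resampling import TaxonContribution


def contribution(taxon, z, classification=None):
    if classification is None:
        classification = "positive" if z > 1.96 else "negative" if z < -1.96 else "nonsignificant"
    return TaxonContribution(
        taxon=taxon, z=z, phi_obs=0.2, null_mean=0.1, null_sd=0.05,
        n_reps=100, classification=classification,
    )


def random_coords(rng, n):
    return SiteCoords(
        pd.DataFrame(
            {
                "site": [f"s{i:02d}" for i in range(n)],
                "lat": rng.uniform(33, 46, n),
                "lon": rng.uniform(-120, -75, n),
            }
        )
    )


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(size=10)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self, rng):
        x = rng.normal(size=10)
        assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_symmetry_and_monotone_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        r = spearman(x, y).rho
        assert spearman(y, x).rho == pytest.approx(r)
        assert spearman(np.exp(x), y).rho == pytest.approx(r)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman(np.ones(5), np.arange(5.0))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            spearman(np.arange(4.0), np.arange(5.0))


class TestMoransI:
    def brute_force(self, values, coords, sites):
        latlon = np.array([coords.latlon(s) for s in sites])
        d = haversine_matrix(latlon[:, 0], latlon[:, 1])
        n = len(values)
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    W[i, j] = 1.0 / d[i, j]
        W = W / W.sum(axis=1, keepdims=True)
        z = values - values.mean()
        num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        return (n / W.sum()) * num / (z @ z)

    def test_matches_brute_force_double_sum(self, rng):
        for _ in range(5):
            coords = random_coords(rng, 10)
            vals = rng.normal(size=10)
            res = morans_i(vals, coords, n_perm=19, seed=0)
            assert res.I == pytest.approx(
                self.brute_force(vals, coords, coords.sites), rel=1e-10
            )

    def test_permutation_null_mean_near_expectation(self, rng):
        coords = random_coords(rng, 12)
        # average observed I over many exchangeable value draws
        vals = [morans_i(rng.normal(size=12), coords, n_perm=19, seed=i).I for i in range(300)]
        assert np.mean(vals) == pytest.approx(-1 / 11, abs=0.03)

    def test_longitude_gradient_detected(self, rng):
        coords = random_coords(rng, 15)
        vals = np.asarray(coords.df["lon"]) / 10.0
        res = morans_i(vals, coords, n_perm=999, seed=4)
        assert res.I > res.expected_I
        assert res.p_value < 0.05

    def test_coincident_coordinates_reported(self, rng):
        df = random_coords(rng, 5).df.copy()
        df.loc[1, ["lat", "lon"]] = df.loc[0, ["lat", "lon"]]
        with pytest.raises(ValidationError, match="coincident"):
            morans_i(rng.normal(size=5), SiteCoords(df), n_perm=9, seed=0)

    def test_constant_values_rejected(self, rng):
        with pytest.raises(ValidationError):
            morans_i(np.ones(6), random_coords(rng, 6), n_perm=9, seed=0)


class TestFFGProportions:
    def test_all_positive_group(self):
        ffg = FFGTable({f"t{i}": "scraper" for i in range(4)})
        out = ffg_proportions([contribution(f"t{i}", 3.0) for i in range(4)], ffg)
        scr = next(g for g in out if g.group == "scraper")
        assert scr.n_taxa == 4 and scr.prop_positive == 1.0 and scr.prop_negative == 0.0

    def test_mixed_counts_with_degenerate_in_denominator(self):
        ffg = FFGTable({f"t{i}": "gatherer" for i in range(4)})
        cons = [
            contribution("t0", 3.0),
            contribution("t1", -3.0),
            contribution("t2", 0.0, "degenerate"),
            contribution("t3", 0.0, "degenerate"),
        ]
        g = next(x for x in ffg_proportions(cons, ffg) if x.group == "gatherer")
        assert g.n_taxa == 4
        assert g.prop_positive == pytest.approx(0.25)
        assert g.prop_negative == pytest.approx(0.25)

    def test_count_conservation_and_unassigned_excluded(self):
        ffg = FFGTable({"a": "filterer", "b": "shredder"})
        cons = [contribution("a", 0.0), contribution("b", 0.0), contribution("zz", 5.0)]
        out = ffg_proportions(cons, ffg)
        assert sum(g.n_taxa for g in out) == 2
        assert {g.group for g in out} == set(FFG_GROUPS)

    def test_empty_group_flagged_with_nan(self):
        ffg = FFGTable({"a": "filterer"})
        out = ffg_proportions([contribution("a", 0.0)], ffg)
        pred = next(g for g in out if g.group == "predator")
        assert pred.n_taxa == 0 and np.isnan(pred.prop_positive)


def simulate_mixed_data(
    rng,
    group_effects,
    site_sd=0.3,
    genus_sd=0.5,
    resid_sd=1.0,
    n_sites=10,
    genera_per_group=12,
    presence=0.7,
):
    """z-scores with known group effects and crossed site/genus intercepts."""
    rows = []
    for g, effect in zip(FFG_GROUPS, group_effects):
        for k in range(genera_per_group):
            genus = f"{g}_gen{k:02d}"
            u_genus = rng.normal(0, genus_sd)
            for s in range(n_sites):
                if rng.random() > presence:
                    continue
                rows.append(
                    {
                        "z": effect + u_genus + rng.normal(0, resid_sd),
                        "site": f"site{s:02d}",
                        "genus": genus,
                        "group": g,
                        "_site_idx": s,
                    }
                )
    df = pd.DataFrame(rows)
    site_effects = rng.normal(0, site_sd, n_sites)
    df["z"] += site_effects[df["_site_idx"]]
    return df.drop(columns="_site_idx")


class TestMixedModel:
    def test_degenerate_balanced_case_recovers_group_means(self):
        rows = []
        for gi, g in enumerate(FFG_GROUPS):
            for s in range(4):
                for k in range(6):
                    rows.append(
                        {"z": float(gi), "site": f"site{s}", "genus": f"{g}_g{k}", "group": g}
                    )
        res = fit_ffg_mixed_model(pd.DataFrame(rows))
        assert res.reference_level == "filterer"
        est = res.fixed_effects["estimate"]
        assert est["Intercept"] == pytest.approx(0.0, abs=1e-6)
        for i, g in enumerate(FFG_GROUPS[1:], start=1):
            assert est[g] == pytest.approx(float(i), abs=1e-6)

    def test_recovers_known_effects_and_components(self, rng):
        df = simulate_mixed_data(rng, group_effects=(0.0, 0.8, -0.8, 1.5, -1.5))
        res = fit_ffg_mixed_model(df)
        assert res.converged
        est = res.fixed_effects["estimate"]
        # contrasts against the filterer reference
        for g, truth in zip(("gatherer", "predator", "scraper", "shredder"),
                            (0.8, -0.8, 1.5, -1.5)):
            assert est[g] == pytest.approx(truth, abs=0.6)
        assert res.variance_components["residual"] == pytest.approx(1.0, abs=0.3)

    def test_single_group_rejected(self):
        df = pd.DataFrame(
            {"z": [0.1, 0.2, 0.3], "site": ["a", "b", "a"],
             "genus": ["g1", "g1", "g2"], "group": ["scraper"] * 3}
        )
        with pytest.raises(ValidationError, match="one feeding group"):
            fit_ffg_mixed_model(df)

    def test_t_is_estimate_over_se(self, rng):
        df = simulate_mixed_data(rng, group_effects=(0, 0.5, 1, 1.5, 2), n_sites=6)
        res = fit_ffg_mixed_model(df)
        fe = res.fixed_effects
        np.testing.assert_allclose(
            fe["t_value"], fe["estimate"] / fe["std_error"], rtol=1e-12
        )
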