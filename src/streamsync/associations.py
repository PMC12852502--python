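"""Association screens and group-level models.

Spearman rank correlations between site-level synchrony and candidate
drivers, Moran's I spatial autocorrelation with inverse great-circle
distance weights, aggregation of contribution z-scores by functional
feeding group, and a Gaussian linear mixed model with crossed random
intercepts for site and genus testing whether feeding groups differ in
their contributions to synchrony.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io import FFG_GROUPS, FFGTable, SiteCoords
from .resampling import TaxonContribution

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its two-sided p-value."""

    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class SpatialAutocorrResult:
    """Moran's I with permutation p-value.

    ``expected_I`` is −1/(n−1), the expectation under spatial
    exchangeability; the permutation test is two-sided around it.
    """

    I: float
    expected_I: float
    p_value: float
    n: int
    weight_spec: str
    n_perm: int


@dataclass(frozen=True)
class FFGSummary:
    """Contribution tallies for one functional feeding group."""

    group: str
    n_taxa: int
    prop_positive: float  # NaN when n_taxa == 0
    prop_negative: float


@dataclass(frozen=True)
class MixedModelResult:
    """Fixed effects and variance components of the group-contrast model.

    ``fixed_effects`` has one row per fixed-effect term (intercept =
    reference group; remaining rows are treatment contrasts against it)
    with columns estimate, std_error, t_value.  Variance components are
    the site and genus random-intercept variances plus the residual.
    """

    fixed_effects: pd.DataFrame
    variance_components: dict[str, float]
    n_obs: int
    reference_level: str
    converged: bool
    message: str = ""


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (midranks for ties, t-approximation p).

    Two-sided p with n−2 degrees of freedom; requires n >= 3 and
    non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 for a rank correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=n)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between coordinate vectors."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _inverse_distance_weights(coords: SiteCoords, sites: Sequence[str]) -> np.ndarray:
    latlon = np.array([coords.latlon(s) for s in sites])
    d = haversine_matrix(latlon[:, 0], latlon[:, 1])
    off = ~np.eye(len(sites), dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValidationError(
            f"coincident coordinates for sites {sites[i]!r} and {sites[j]!r}: "
            "inverse-distance weight is infinite"
        )
    W = np.zeros_like(d)
    W[off] = 1.0 / d[off]
    W /= W.sum(axis=1, keepdims=True)  # row-standardize
    return W


def _moran_stat(z: np.ndarray, W: np.ndarray) -> float:
    # row-standardized weights: S0 = sum(W) = n, so I = z'Wz / z'z
    n = len(z)
    s0 = W.sum()
    return float((n / s0) * (z @ W @ z) / (z @ z))


def morans_i(
    values: Sequence[float],
    coords: SiteCoords,
    sites: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> SpatialAutocorrResult:
    """Moran's I with inverse great-circle-distance, row-standardized weights.

    I = (n / ΣΣ w_ij) · ΣΣ w_ij (v_i − v̄)(v_j − v̄) / Σ (v_i − v̄)².
    The p-value comes from ``n_perm`` random permutations of values over
    locations, two-sided around the exchangeability expectation −1/(n−1).
    """
    values = np.asarray(values, dtype=float)
    if sites is None:
        sites = coords.sites
    if len(values) != len(sites):
        raise ValidationError("values and sites differ in length")
    n = len(values)
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 sites for Moran's I, got {n}")
    if np.ptp(values) == 0:
        raise ValidationError("Moran's I undefined for constant values")
    W = _inverse_distance_weights(coords, sites)
    z = values - values.mean()
    i_obs = _moran_stat(z, W)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(z, (n_perm, n)), axis=1)
    i_null = np.einsum("ri,ij,rj->r", perms, W, perms) * (n / W.sum())
    i_null /= z @ z
    extreme = np.abs(i_null - expected) >= np.abs(i_obs - expected) - 1e-12
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)
    return SpatialAutocorrResult(
        I=i_obs,
        expected_I=expected,
        p_value=float(p),
        n=n,
        weight_spec="inverse great-circle distance, row-standardized",
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Functional feeding group aggregation
# ---------------------------------------------------------------------------


def ffg_proportions(
    contributions: Iterable[TaxonContribution],
    ffg: FFGTable,
) -> list[FFGSummary]:
    """Per-group share of taxa with significant positive/negative contributions.

    Degenerate taxa count in the denominator (they are observed taxa that
    simply cannot move the statistic).  Taxa without an FFG assignment are
    excluded after being counted and logged; groups with no taxa get NaN
    proportions.
    """
    contribs = list(contributions)
    unassigned = [c.taxon for c in contribs if ffg.group_of(c.taxon) is None]
    if unassigned:
        logger.warning(
            "%d taxa without a feeding-group assignment excluded: %s",
            len(unassigned),
            ", ".join(sorted(set(unassigned))[:10]),
        )
    out = []
    for group in FFG_GROUPS:
        members = [c for c in contribs if ffg.group_of(c.taxon) == group]
        n = len(members)
        if n == 0:
            out.append(FFGSummary(group, 0, float("nan"), float("nan")))
            continue
        pos = sum(c.classification == "positive" for c in members)
        neg = sum(c.classification == "negative" for c in members)
        out.append(FFGSummary(group, n, pos / n, neg / n))
    return out


def count_unassigned(
    contributions: Iterable[TaxonContribution], ffg: FFGTable
) -> int:
    return sum(ffg.group_of(c.taxon) is None for c in contributions)


# ---------------------------------------------------------------------------
# Crossed random-effects model
# ---------------------------------------------------------------------------


def fit_ffg_mixed_model(
    data: pd.DataFrame,
    response: str = "z",
    group_col: str = "group",
    site_col: str = "site",
    genus_col: str = "genus",
) -> MixedModelResult:
    """Gaussian mixed model: z ~ feeding group + (1|site) + (1|genus).

    Fit by REML with treatment coding; the reference level is the
    alphabetically first group present (``filterer`` for the standard
    five).  Site and genus enter as crossed random intercepts via
    variance components.  Non-convergence is reported in the result, not
    raised, so a pipeline run over real data survives hard fits.
    """
    import statsmodels.formula.api as smf

    df = data[[response, group_col, site_col, genus_col]].dropna().copy()
    df[group_col] = df[group_col].astype(str)
    groups_present = sorted(df[group_col].unique())
    if len(groups_present) < 2:
        raise ValidationError(
            "only one feeding group present; compare group means directly "
            "instead of fitting a group-contrast model"
        )
    if df[site_col].nunique() < 2:
        raise ValidationError("need >= 2 sites for a site random effect")
    if not np.all(np.isfinite(df[response].to_numpy(dtype=float))):
        raise ValidationError("non-finite response values")

    df["_all"] = 1  # single top-level group; crossed effects via vc_formula
    vc = {
        "site": f"0 + C({site_col})",
        "genus": f"0 + C({genus_col})",
    }
    model = smf.mixedlm(
        f"{response} ~ C({group_col})",
        data=df,
        groups="_all",
        vc_formula=vc,
        re_formula="0",
    )
    fit = None
    converged = False
    message = ""
    # lbfgs is fast but fragile near variance boundaries; fall back to
    # slower, more robust optimizers before declaring non-convergence
    for method in ("lbfgs", "bfgs", "powell"):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                candidate = model.fit(reml=True, method=method, maxiter=500)
            except Exception as exc:  # hard numerical failure
                message = f"fit failed ({method}): {exc}"
                continue
            conv_msgs = [
                str(w.message) for w in caught if "converge" in str(w.message).lower()
            ]
        fit = candidate
        if getattr(candidate, "converged", True) and not conv_msgs:
            converged = True
            message = ""
            break
        message = "; ".join(conv_msgs) or "optimizer did not converge"
    if fit is None:
        return MixedModelResult(
            fixed_effects=pd.DataFrame(columns=["estimate", "std_error", "t_value"]),
            variance_components={},
            n_obs=len(df),
            reference_level=groups_present[0],
            converged=False,
            message=message,
        )

    fe = pd.DataFrame(
        {
            "estimate": fit.fe_params,
            "std_error": fit.bse_fe,
        }
    )
    fe["t_value"] = fe["estimate"] / fe["std_error"]
    fe.index = [_clean_term(ix, group_col) for ix in fe.index]
    fe.index.name = "term"

    vcomp = {
        name: float(v) for name, v in zip(model.exog_vc.names, fit.vcomp)
    }
    vcomp["residual"] = float(fit.scale)
    return MixedModelResult(
        fixed_effects=fe,
        variance_components=vcomp,
        n_obs=len(df),
        reference_level=groups_present[0],
        converged=converged,
        message=message,
    )


def _clean_term(term: str, group_col: str) -> str:
    """'C(group)[T.scraper]' -> 'scraper'; 'Intercept' kept as is."""
    prefix = f"C({group_col})[T."
    if term.startswith(prefix) and term.endswith("]"):
        return term[len(prefix) : -1]
    return term
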