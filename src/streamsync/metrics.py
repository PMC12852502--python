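"""Community and environmental summary metrics.

Temporal turnover, richness, Simpson diversity, environmental
variability, and the assembly of the per-site summary row that the
pipeline writes (one row per site: coordinates, richness, temperature
and discharge variability, mean turnover, synchrony and its p-value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError, InsufficientDataError, ValidationError
from .io import CommunityMatrix, EnvSeries, SiteCoords
from .synchrony import SynchronyResult


@dataclass(frozen=True)
class TurnoverResult:
    """Per-interval temporal turnover and its mean for one site.

    For each consecutive pair of observed years, turnover is
    (gains + losses) / richness of the union of taxa present in either
    year — 0 for identical assemblages, 1 for complete replacement.
    """

    site_id: str
    per_interval: tuple[tuple[int, int, float], ...]  # (year_from, year_to, turnover)
    mean_turnover: float


@dataclass(frozen=True)
class SiteSummary:
    """One site's row of the study-level summary table."""

    site_id: str
    lat: float
    lon: float
    richness: int
    temp_sd: float
    discharge_sd: float
    mean_turnover: float
    phi: float
    p_value: float | None


def temporal_turnover(matrix: CommunityMatrix) -> TurnoverResult:
    """Year-to-year species turnover from annualized presence (density > 0)."""
    pres = matrix.presence()
    if matrix.n_years < 2:
        raise InsufficientDataError(
            f"site {matrix.site_id!r}: turnover needs >= 2 years"
        )
    intervals = []
    for t in range(matrix.n_years - 1):
        a, b = pres[t], pres[t + 1]
        union = np.sum(a | b)
        if union == 0:
            # both years empty of taxa; no turnover information
            tv = 0.0
        else:
            gains = np.sum(b & ~a)
            losses = np.sum(a & ~b)
            tv = float((gains + losses) / union)
        intervals.append((int(matrix.years[t]), int(matrix.years[t + 1]), tv))
    mean = float(np.mean([tv for _, _, tv in intervals]))
    return TurnoverResult(matrix.site_id, tuple(intervals), mean)


def richness(matrix: CommunityMatrix) -> int:
    """Number of taxa ever observed at the site."""
    return matrix.n_taxa


def simpson_diversity(abundances: np.ndarray) -> float:
    """Simpson diversity 1 − Σ p_i² (probability of an interspecific draw).

    Ranges from 0 (single taxon) to 1 − 1/N (perfectly even community).
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D abundance vector")
    if np.any(x < 0):
        raise ValidationError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValidationError("all-zero abundance vector: diversity undefined")
    p = x / total
    return float(1.0 - np.sum(p**2))


def env_variability(series: EnvSeries) -> float:
    """Environmental variability: sample SD (divisor n−1) of the full series.

    Computed on the native resolution of the input, in the series' own
    units (degC or m³/s); no resampling to a common grid.
    """
    vals = series.values
    if len(vals) < 2:
        raise InsufficientDataError(
            f"{series.site_id}/{series.variable}: need >= 2 values for an SD"
        )
    return float(np.std(vals, ddof=1))


def build_site_summary(
    matrix: CommunityMatrix,
    temp: EnvSeries,
    discharge: EnvSeries,
    coords: SiteCoords,
    synchrony: SynchronyResult,
) -> SiteSummary:
    """Assemble one site's summary row from the component results."""
    for series, expected_var in ((temp, "temperature"), (discharge, "discharge")):
        if series.site_id != matrix.site_id:
            raise ConsistencyError(
                f"{expected_var} series is for site {series.site_id!r}, "
                f"community matrix for {matrix.site_id!r}"
            )
        if series.variable != expected_var:
            raise ConsistencyError(
                f"expected a {expected_var} series, got {series.variable!r}"
            )
    lat, lon = coords.latlon(matrix.site_id)
    return SiteSummary(
        site_id=matrix.site_id,
        lat=lat,
        lon=lon,
        richness=richness(matrix),
        temp_sd=env_variability(temp),
        discharge_sd=env_variability(discharge),
        mean_turnover=temporal_turnover(matrix).mean_turnover,
        phi=synchrony.phi,
        p_value=synchrony.p_value,
    )
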