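"""Data model and tabular I/O.

The pipeline works from four plain-CSV inputs — a long-format community
abundance table, per-site environmental time series, a taxon-to-
functional-feeding-group assignment table, and site coordinates — and
produces CSV outputs.  This module defines the validated in-memory
containers for those tables and the readers/writers that enforce their
invariants at the boundary.

Column names in input files are adapted through a ``dialect`` mapping
(canonical name -> actual file column), so exports that use other field
names (e.g. NEON download column names) can be ingested without editing
the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InsufficientDataError,
    UnknownKeyError,
    ValidationError,
)

#: The five functional feeding groups of stream macroinvertebrates,
#: in alphabetical order (which is also the modelling reference order).
FFG_GROUPS: tuple[str, ...] = (
    "filterer",
    "gatherer",
    "predator",
    "scraper",
    "shredder",
)

_COMMUNITY_COLUMNS = ("site", "year", "event", "taxon", "density")


def _apply_dialect(
    df: pd.DataFrame,
    required: Sequence[str],
    dialect: Mapping[str, str] | None,
    path: Path,
) -> pd.DataFrame:
    """Rename file columns to canonical names and check presence."""
    dialect = dict(dialect or {})
    rename = {dialect.get(name, name): name for name in required}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"present columns are {list(df.columns)}"
        )
    return df.rename(columns=rename)[list(required)]


# ---------------------------------------------------------------------------
# CommunityTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityTable:
    """Long-format community observations.

    One row per (site, year, sampling event, taxon) with a non-negative
    density (individuals per unit area).  Rows record *observed* taxa;
    a taxon missing from a sampled event is an observed zero and is
    imputed during annualization, not stored.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if list(df.columns) != list(_COMMUNITY_COLUMNS):
            raise FormatError(
                f"community table must have columns {_COMMUNITY_COLUMNS}, "
                f"got {list(df.columns)}"
            )
        dens = df["density"].to_numpy()
        if not np.issubdtype(dens.dtype, np.number):
            raise FormatError("density column is not numeric")
        bad = np.flatnonzero(~(dens >= 0))  # catches negatives and NaN
        if bad.size:
            raise ValidationError(
                f"negative or missing density at row index {bad[0]} "
                f"(value {dens[bad[0]]!r})"
            )
        dup = df.duplicated(subset=["site", "year", "event", "taxon"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            key = df.iloc[i][["site", "year", "event", "taxon"]].tolist()
            raise ValidationError(
                f"duplicate (site, year, event, taxon) row: {key}; aggregate "
                "duplicates explicitly upstream before ingestion"
            )
        years_per_site = df.groupby("site")["year"].nunique()
        single = years_per_site[years_per_site < 2]
        if len(single):
            raise ValidationError(
                f"site(s) {list(single.index)} have fewer than 2 distinct "
                "years and cannot enter a temporal analysis"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityTable":
        """Validate an in-memory frame (canonical column names required)."""
        out = df.loc[:, list(_COMMUNITY_COLUMNS)].copy()
        out["site"] = out["site"].astype(str)
        out["taxon"] = out["taxon"].astype(str)
        out["year"] = out["year"].astype(int)
        out["event"] = out["event"].astype(int)
        out["density"] = out["density"].astype(float)
        return cls(out.reset_index(drop=True))

    @property
    def sites(self) -> list[str]:
        return sorted(self.df["site"].unique())


def read_community_long(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> CommunityTable:
    """Read a long-format community CSV into a validated table.

    Duplicate keys and negative densities are hard errors — silent
    aggregation would hide upstream taxonomy mistakes.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df = _apply_dialect(df, _COMMUNITY_COLUMNS, dialect, path)
    return CommunityTable.from_frame(df)


def write_community(table: CommunityTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityMatrix:
    """Per-site annual community matrix: years x taxa of mean densities.

    This is the unit on which synchrony, turnover and contribution
    statistics operate.  Taxa never observed at the site are dropped at
    construction; taxon order is lexicographic so the matrix does not
    depend on input row order.
    """

    site_id: str
    years: np.ndarray  # (T,) int, strictly increasing
    taxa: tuple[str, ...]  # (N,) lexicographically sorted
    X: np.ndarray  # (T, N) float, non-negative annual mean densities

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "X", X)
        if years.ndim != 1 or len(years) < 2:
            raise InsufficientDataError(
                f"site {self.site_id!r}: need >= 2 years, got {len(years)}"
            )
        if np.any(np.diff(years) <= 0):
            raise ValidationError(f"site {self.site_id!r}: years not increasing")
        if X.shape != (len(years), len(self.taxa)):
            raise ValidationError(
                f"site {self.site_id!r}: matrix shape {X.shape} does not match "
                f"{len(years)} years x {len(self.taxa)} taxa"
            )
        if X.shape[1] < 1:
            raise ValidationError(f"site {self.site_id!r}: no taxa")
        if np.any(X < 0):
            raise ValidationError(f"site {self.site_id!r}: negative density")
        if np.any(X.sum(axis=0) == 0):
            raise ValidationError(
                f"site {self.site_id!r}: all-zero taxon column present"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def column(self, taxon: str) -> int:
        """Index of a taxon's column; UnknownKeyError if absent."""
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise UnknownKeyError(
                f"taxon {taxon!r} not present at site {self.site_id!r}"
            ) from None

    def presence(self) -> np.ndarray:
        """Boolean (T, N) presence matrix (annual mean density > 0)."""
        return self.X > 0

    def with_X(self, X: np.ndarray) -> "CommunityMatrix":
        """Copy of this matrix with a replaced value array (same axes)."""
        return CommunityMatrix(self.site_id, self.years, self.taxa, X)


def to_site_matrix(table: CommunityTable, site: str) -> CommunityMatrix:
    """Annualize one site: mean density across sampling events per year.

    A taxon absent from a sampled event is an observed zero for that
    event, so the annual value is (sum of recorded densities) / (number
    of events sampled in that site-year).  Years with no events at the
    site are simply absent; taxa never observed are dropped.
    """
    sub = table.df[table.df["site"] == site]
    if sub.empty:
        raise UnknownKeyError(f"site {site!r} not present in community table")
    years = np.sort(sub["year"].unique())
    if len(years) < 2:
        raise InsufficientDataError(
            f"site {site!r}: need >= 2 years for a community matrix"
        )
    # events actually sampled per year at this site
    n_events = sub.groupby("year")["event"].nunique()
    totals = sub.pivot_table(
        index="year", columns="taxon", values="density", aggfunc="sum", fill_value=0.0
    )
    X = totals.div(n_events, axis=0)
    X = X.reindex(index=years).sort_index(axis=1)
    keep = X.sum(axis=0) > 0
    X = X.loc[:, keep]
    return CommunityMatrix(
        site_id=site,
        years=years,
        taxa=tuple(X.columns),
        X=X.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# EnvSeries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvSeries:
    """A single site's environmental time series (temperature or discharge)."""

    site_id: str
    variable: str  # "temperature" (degC) or "discharge" (m3/s)
    timestamps: np.ndarray  # strictly increasing; datetime64 or numeric
    values: np.ndarray  # float

    def __post_init__(self) -> None:
        if self.variable not in ("temperature", "discharge"):
            raise ValidationError(
                f"variable must be 'temperature' or 'discharge', got "
                f"{self.variable!r}"
            )
        ts = np.asarray(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise InsufficientDataError(
                f"{self.site_id}/{self.variable}: need >= 2 values"
            )
        if len(ts) != len(vals):
            raise ValidationError("timestamps and values differ in length")
        if np.any(np.diff(ts) <= np.zeros(1, dtype=np.diff(ts).dtype)):
            raise ValidationError(
                f"{self.site_id}/{self.variable}: timestamps not strictly increasing"
            )
        if np.any(~np.isfinite(vals)):
            raise ValidationError(f"{self.site_id}/{self.variable}: non-finite value")


def read_env_series(
    path: str | Path,
    variable: str,
    dialect: Mapping[str, str] | None = None,
    site: str | None = None,
) -> EnvSeries:
    """Read one site's environmental series from a CSV.

    Expects canonical columns ``site, timestamp, value`` (remappable via
    ``dialect``).  If the file holds several sites, ``site`` selects one.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df = _apply_dialect(df, ("site", "timestamp", "value"), dialect, path)
    df["site"] = df["site"].astype(str)
    sites = df["site"].unique()
    if site is None:
        if len(sites) != 1:
            raise FormatError(
                f"{path}: multiple sites present {sorted(sites)}; pass site="
            )
        site = str(sites[0])
    sub = df[df["site"] == site]
    if sub.empty:
        raise UnknownKeyError(f"site {site!r} not present in {path}")
    ts = pd.to_datetime(sub["timestamp"]).to_numpy()
    return EnvSeries(site, variable, ts, sub["value"].to_numpy(dtype=float))


def read_env_table(
    path: str | Path,
    variable: str,
    dialect: Mapping[str, str] | None = None,
) -> dict[str, EnvSeries]:
    """Read a multi-site environmental CSV into one EnvSeries per site."""
    path = Path(path)
    df = pd.read_csv(path)
    df = _apply_dialect(df, ("site", "timestamp", "value"), dialect, path)
    df["site"] = df["site"].astype(str)
    return {
        s: EnvSeries(
            s,
            variable,
            pd.to_datetime(g["timestamp"]).to_numpy(),
            g["value"].to_numpy(dtype=float),
        )
        for s, g in df.groupby("site")
    }


# ---------------------------------------------------------------------------
# FFGTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FFGTable:
    """Taxon -> functional feeding group assignment."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {t: g for t, g in self.mapping.items() if g not in FFG_GROUPS}
        if bad:
            taxon, group = next(iter(bad.items()))
            raise ValidationError(
                f"taxon {taxon!r} has unknown feeding group {group!r}; "
                f"allowed groups are {list(FFG_GROUPS)}"
            )

    def group_of(self, taxon: str) -> str | None:
        return self.mapping.get(taxon)

    def __len__(self) -> int:
        return len(self.mapping)


def read_ffg_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> FFGTable:
    path = Path(path)
    df = pd.read_csv(path)
    df = _apply_dialect(df, ("taxon", "group"), dialect, path)
    df["taxon"] = df["taxon"].astype(str)
    df["group"] = df["group"].astype(str).str.strip().str.lower()
    conflicts = df.groupby("taxon")["group"].nunique()
    if (conflicts > 1).any():
        taxon = conflicts[conflicts > 1].index[0]
        raise ValidationError(f"taxon {taxon!r} mapped to more than one group")
    return FFGTable(dict(zip(df["taxon"], df["group"])))


def write_ffg_table(ffg: FFGTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(ffg.mapping.items()), columns=["taxon", "group"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SiteCoords
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteCoords:
    """Site geographic coordinates in decimal degrees."""

    df: pd.DataFrame  # columns: site, lat, lon

    def __post_init__(self) -> None:
        df = self.df
        if list(df.columns) != ["site", "lat", "lon"]:
            raise FormatError("site coordinates need columns (site, lat, lon)")
        if df["site"].duplicated().any():
            dup = df.loc[df["site"].duplicated(), "site"].iloc[0]
            raise ValidationError(f"duplicate site id {dup!r} in coordinates")
        if np.any(np.abs(df["lat"].to_numpy()) > 90):
            i = int(np.argmax(np.abs(df["lat"].to_numpy()) > 90))
            raise ValidationError(
                f"latitude out of range at row {i}: {df['lat'].iloc[i]}"
            )
        if np.any(np.abs(df["lon"].to_numpy()) > 180):
            i = int(np.argmax(np.abs(df["lon"].to_numpy()) > 180))
            raise ValidationError(
                f"longitude out of range at row {i}: {df['lon'].iloc[i]}"
            )

    def latlon(self, site: str) -> tuple[float, float]:
        row = self.df[self.df["site"] == site]
        if row.empty:
            raise UnknownKeyError(f"site {site!r} has no coordinates")
        return float(row["lat"].iloc[0]), float(row["lon"].iloc[0])

    @property
    def sites(self) -> list[str]:
        return list(self.df["site"])


def read_site_coords(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> SiteCoords:
    path = Path(path)
    df = pd.read_csv(path)
    df = _apply_dialect(df, ("site", "lat", "lon"), dialect, path)
    df["site"] = df["site"].astype(str)
    df["lat"] = df["lat"].astype(float)
    df["lon"] = df["lon"].astype(float)
    return SiteCoords(df.reset_index(drop=True))


def write_site_coords(coords: SiteCoords, path: str | Path) -> None:
    coords.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Site summary output
# ---------------------------------------------------------------------------

SITE_SUMMARY_COLUMNS = (
    "site",
    "lat",
    "lon",
    "S",
    "temp_sd",
    "turnover_mean",
    "discharge_sd",
    "phi",
    "p_value",
)


def write_site_summary(summaries: Iterable, path: str | Path) -> None:
    """Write per-site summaries (one row per site) to CSV.

    Accepts any iterable of objects exposing the SiteSummary fields
    (see :mod:`streamsync.metrics`).
    """
    rows = [
        {
            "site": s.site_id,
            "lat": s.lat,
            "lon": s.lon,
            "S": s.richness,
            "temp_sd": s.temp_sd,
            "turnover_mean": s.mean_turnover,
            "discharge_sd": s.discharge_sd,
            "phi": s.phi,
            "p_value": s.p_value,
        }
        for s in summaries
    ]
    if not rows:
        raise ValidationError("no site summaries to write")
    pd.DataFrame(rows, columns=list(SITE_SUMMARY_COLUMNS)).to_csv(path, index=False)


def read_site_summary(path: str | Path) -> pd.DataFrame:
    """Read a site-summary CSV back into a frame (schema-checked)."""
    df = pd.read_csv(path)
    missing = [c for c in SITE_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: site summary missing column(s) {missing}")
    return df[list(SITE_SUMMARY_COLUMNS)]


def load_reference_site_table() -> pd.DataFrame:
    """Published site-level summaries for the 18 NEON wadeable-stream sites.

    Columns follow the site-summary schema: taxonomic richness S,
    temperature variability (SD, degC), mean annual turnover, discharge
    variability (SD, m3/s), community synchrony phi and its Monte Carlo
    p-value, for macroinvertebrate communities sampled 2014-2022.
    P-values reported below the 0.001 resolution are stored as 0.001.

    These printed values are inputs for worked examples and consistency
    checks; they are not produced by this package.
    """
    with resources.files("streamsync.data").joinpath(
        "neon_site_summary.csv"
    ).open("r") as fh:
        return pd.read_csv(fh)
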