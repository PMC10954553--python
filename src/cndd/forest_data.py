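"""Ingest and clean stem-level census tables into focal-sapling observations.

The canonical in-memory representation is a pandas DataFrame with one row
per stem (or tree) per census and the columns

    tree_id, stem_id, species, x, y, dbh, status, census_index, date

Statuses are the strings ``alive`` / ``dead`` / ``missing``.  The analysis
table produced by :func:`build_observations` has one row per living focal
sapling (1 <= DBH < 10 cm) per consecutive census pair:

    site, tree_id, species, j, Y, dt, dbh, x, y, edge_excluded
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlotMetadata",
    "STEM_COLUMNS",
    "OBSERVATION_COLUMNS",
    "read_census_tables",
    "consolidate_stems",
    "clean_statuses",
    "build_observations",
    "classify_growth_form",
    "compute_abundance",
    "group_abundance",
    "write_observations",
    "read_observations",
]

STEM_COLUMNS = ["tree_id", "stem_id", "species", "x", "y", "dbh",
                "status", "census_index", "date"]
OBSERVATION_COLUMNS = ["site", "tree_id", "species", "j", "Y", "dt",
                       "dbh", "x", "y", "edge_excluded"]

VALID_STATUSES = ("alive", "dead", "missing")


@dataclass
class PlotMetadata:
    site_name: str
    width: float                       # metres
    height: float                      # metres
    absolute_latitude: float           # degrees >= 0
    census_dates: list = field(default_factory=list)   # decimal years, increasing
    stems_as_individuals: bool = False  # sites where each stem is an individual: skip consolidation

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.absolute_latitude < 0:
            raise ValueError("absolute latitude must be >= 0")
        if list(self.census_dates) != sorted(self.census_dates) or \
                len(set(self.census_dates)) != len(self.census_dates):
            raise ValueError("census dates must be strictly increasing")

    @property
    def area_ha(self) -> float:
        return self.width * self.height / 10_000.0


def read_census_tables(paths, schema_config: dict | None = None,
                       on_unknown_status: str = "drop"):
    """Read delimited census tables, one file per census.

    ``schema_config`` maps canonical column names to file column names
    (key ``columns``) and raw status codes to canonical statuses (key
    ``status_codes``, e.g. ``{"A": "alive", "D": "dead"}``).  Rows missing
    coordinates, species, status or measurement date are dropped and
    counted.

    Returns ``(tables, drop_counts)``: a list of canonical DataFrames and
    a list of per-file dropped-row counts.
    """
    schema_config = schema_config or {}
    colmap = schema_config.get("columns", {})
    status_codes = schema_config.get("status_codes", {})
    tables, drops = [], []
    for path in paths:
        try:
            raw = pd.read_csv(path, sep=schema_config.get("sep", ","))
        except Exception as exc:  # unparseable file is fatal
            raise ValueError(f"cannot parse census table {path}: {exc}") from exc
        df = raw.rename(columns={v: k for k, v in colmap.items()})
        if len(df) == 0:
            warnings.warn(f"census table {path} is empty")
            tables.append(pd.DataFrame(columns=STEM_COLUMNS))
            drops.append(0)
            continue
        missing_cols = [c for c in STEM_COLUMNS if c not in df.columns]
        for c in missing_cols:
            if c == "stem_id":
                df["stem_id"] = df["tree_id"]
            else:
                raise ValueError(f"{path}: required column {c!r} absent")
        if status_codes:
            df["status"] = df["status"].map(lambda s: status_codes.get(s, s))
        unknown = ~df["status"].isin(VALID_STATUSES)
        if unknown.any():
            if on_unknown_status == "fail":
                raise ValueError(f"{path}: unknown status codes "
                                 f"{sorted(df.loc[unknown, 'status'].unique())}")
            df = df[~unknown]
        for c in ("x", "y", "dbh", "date"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        before = len(df)
        df = df.dropna(subset=["x", "y", "species", "status", "date"])
        drops.append(before - len(df) + int(unknown.sum()))
        tables.append(df[STEM_COLUMNS].reset_index(drop=True))
    return tables, drops


def consolidate_stems(stems: pd.DataFrame, plot: PlotMetadata) -> pd.DataFrame:
    """Collapse multi-stem records to one row per tree per census.

    A tree is alive iff at least one stem is alive; its DBH equivalent
    comes from the summed basal area of live stems (all stems when none
    is alive), i.e. sqrt(sum dbh_i^2); coordinates are those of the main
    stem, taken as the largest-DBH living stem.  When the plot treats
    every stem as an individual (``plot.stems_as_individuals``) stems pass
    through untouched.
    """
    if len(stems) == 0:
        raise ValueError("no stems to consolidate")
    if plot.stems_as_individuals:
        out = stems.copy()
        out["tree_id"] = out["stem_id"]
        return out

    def one(group: pd.DataFrame) -> pd.Series:
        alive = group[group["status"] == "alive"]
        basis = alive if len(alive) else group
        dbh_eq = float(np.sqrt(np.sum(basis["dbh"].to_numpy(dtype=float) ** 2)))
        main = basis.loc[basis["dbh"].idxmax()]
        status = "alive" if len(alive) else (
            "dead" if (group["status"] == "dead").any() else "missing")
        return pd.Series({"species": main["species"], "x": main["x"], "y": main["y"],
                          "dbh": dbh_eq, "status": status, "date": main["date"]})

    out = (stems.groupby(["tree_id", "census_index"])
           .apply(one, include_groups=False).reset_index())
    return out


def clean_statuses(trees: pd.DataFrame) -> pd.DataFrame:
    """Plausibility corrections across a tree's census history.

    Any 'dead' record followed by a later 'alive' record is rewritten to
    'alive' (resurrection rule); species and coordinates that conflict
    across censuses are replaced by the most recent value.  Never converts
    an alive record to dead.
    """
    df = trees.sort_values(["tree_id", "census_index"]).reset_index(drop=True)
    is_alive = (df["status"] == "alive").astype(int)
    # reversed cummax per tree: 1 iff alive at this census or any later one
    alive_here_or_later = (is_alive.iloc[::-1]
                           .groupby(df["tree_id"].iloc[::-1], sort=False)
                           .cummax().iloc[::-1])
    resurrect = (df["status"] == "dead") & (alive_here_or_later == 1)
    df.loc[resurrect, "status"] = "alive"
    grp = df.groupby("tree_id", sort=False)
    for col in ("species", "x", "y"):
        df[col] = grp[col].transform("last")
    return df


def build_observations(trees: pd.DataFrame, plot: PlotMetadata,
                       buffer_m: float = 30.0,
                       fern_palm_species=frozenset()) -> pd.DataFrame:
    """Focal-sapling observations for every consecutive census pair.

    Keeps living non-fern, non-palm trees with 1 <= DBH < 10 cm in census
    c that have a known alive/dead status in census c + 1.  ``Y`` is 1
    for death, ``dt`` the per-tree interval in years (census-level dates
    as fallback), and ``edge_excluded`` marks focal trees within
    ``buffer_m`` of any plot boundary.
    """
    censuses = sorted(trees["census_index"].unique())
    if len(censuses) < 2:
        raise ValueError("at least two censuses are required")
    by_census = {c: trees[trees["census_index"] == c].set_index("tree_id")
                 for c in censuses}
    rows = []
    n_nonpositive_dt = 0
    for j, (c0, c1) in enumerate(zip(censuses[:-1], censuses[1:]), start=1):
        t0, t1 = by_census[c0], by_census[c1]
        focal = t0[(t0["status"] == "alive")
                   & (t0["dbh"] >= 1.0) & (t0["dbh"] < 10.0)
                   & ~t0["species"].isin(fern_palm_species)]
        followed = focal.index.intersection(
            t1.index[t1["status"].isin(["alive", "dead"])])
        f0 = focal.loc[followed]
        f1 = t1.loc[followed]
        if f0["date"].notna().all() and f1["date"].notna().all():
            dt = (f1["date"] - f0["date"]).to_numpy(dtype=float)
        else:
            dates = plot.census_dates
            dt = np.full(len(f0), dates[c1 - 1] - dates[c0 - 1] if len(dates) >= c1
                         else np.nan)
        ok = dt > 0
        n_nonpositive_dt += int((~ok).sum())
        f0, f1, dt = f0[ok], f1[ok], dt[ok]
        x = f0["x"].to_numpy(dtype=float)
        y = f0["y"].to_numpy(dtype=float)
        edge = ((x < buffer_m) | (x > plot.width - buffer_m)
                | (y < buffer_m) | (y > plot.height - buffer_m))
        rows.append(pd.DataFrame({
            "site": plot.site_name, "tree_id": f0.index, "species": f0["species"].to_numpy(),
            "j": j, "Y": (f1["status"] == "dead").astype(int).to_numpy(),
            "dt": dt, "dbh": f0["dbh"].to_numpy(dtype=float),
            "x": x, "y": y, "edge_excluded": edge,
        }))
    if n_nonpositive_dt:
        warnings.warn(f"dropped {n_nonpositive_dt} observations with non-positive dt")
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=OBSERVATION_COLUMNS)
    out.attrs["n_nonpositive_dt"] = n_nonpositive_dt
    return out[OBSERVATION_COLUMNS]


def classify_growth_form(trees: pd.DataFrame) -> dict:
    """Growth form per species from maximum tree size.

    Per census, the mean DBH of the six largest individuals (all, when
    fewer than six); a species is a tree iff the maximum of these means
    exceeds 10 cm (strictly), otherwise a shrub.  Species with no measured
    individual map to 'unknown'.
    """
    forms = {}
    for species, sub in trees.groupby("species"):
        sub = sub.dropna(subset=["dbh"])
        if len(sub) == 0:
            forms[species] = "unknown"
            continue
        means = sub.groupby("census_index")["dbh"].apply(
            lambda d: d.nlargest(6).mean())
        forms[species] = "tree" if means.max() > 10.0 else "shrub"
    return forms


def compute_abundance(census: pd.DataFrame, plot: PlotMetadata,
                      species: str | None = None) -> float:
    """Living individuals with DBH >= 1 cm per hectare on the entire plot."""
    if plot.area_ha <= 0:
        raise ValueError("plot area must be positive")
    live = census[(census["status"] == "alive") & (census["dbh"] >= 1.0)]
    if species is not None:
        live = live[live["species"] == species]
    return len(live) / plot.area_ha


def group_abundance(member_abundances) -> float:
    """Abundance of a pooled rare group: mean of member-species abundances."""
    values = list(member_abundances)
    if not values:
        raise ValueError("empty rare group")
    return float(np.mean(values))


def read_species_attributes(path) -> tuple[frozenset, dict]:
    """Species-attribute CSV with columns ``species``,
    ``growth_form_override`` (optional values tree/shrub) and
    ``is_fern_or_palm`` (truthy).  Returns (fern/palm species set,
    growth-form override mapping)."""
    df = pd.read_csv(path)
    ferns = frozenset(df.loc[df.get("is_fern_or_palm", False).astype(bool), "species"])
    overrides = {}
    if "growth_form_override" in df.columns:
        sub = df.dropna(subset=["growth_form_override"])
        overrides = dict(zip(sub["species"], sub["growth_form_override"]))
    return ferns, overrides


def write_observations(observations: pd.DataFrame, path) -> None:
    observations[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["edge_excluded"] = df["edge_excluded"].astype(bool)
    return df[OBSERVATION_COLUMNS]
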