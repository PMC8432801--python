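"""Standardize checklist and route-stop streams into detection tables.

Checklists are filtered to a standardized effort envelope (party size,
duration, distance, protocol, completeness, breeding-season window, minimum
list length), group duplicates are collapsed, surveys are restricted to the
focal species' observed range, zero-filled into one presence/absence row per
survey unit, and finally spatiotemporally subsampled to balance detections
against non-detections and sample sizes across years.

Route-stop data are filtered on the run quality flag and expanded into one
row per (run, stop) with explicit zeros for stops where the species was not
recorded, either as 0/1 detections or as counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from birdindex.synthetic import ChecklistTable, StopTable

__all__ = [
    "FilterConfig",
    "filter_checklists",
    "collapse_groups",
    "compute_list_length",
    "restrict_to_range",
    "restrict_stops_to_range",
    "zero_fill",
    "balance_checklists",
    "build_stop_detections",
]

ALLOWED_PROTOCOLS = ("stationary", "traveling", "random")

DETECTION_COLUMNS = [
    "unit_id", "source", "species_id", "response", "town", "year",
    "observer_id", "location_id", "doy", "doy_c", "start_time", "start_c",
    "list_length", "protocol",
]


@dataclass
class FilterConfig:
    """Effort-standardization envelope for checklists."""

    max_party: int = 10
    max_duration: float = 5.0   # hours
    max_distance: float = 5.0   # km
    protocols: tuple = ("stationary", "traveling")
    min_species: int = 5
    season_start: tuple = (5, 1)    # May 1
    season_end: tuple = (7, 15)     # Jul 15
    years: tuple | None = None      # (first, last) inclusive; None = all

    def __post_init__(self):
        if self.max_party <= 0 or self.max_duration <= 0 or self.max_distance <= 0:
            raise ValueError("filter bounds must be positive")
        if self.season_start >= self.season_end:
            raise ValueError("season window start must precede end")


def _season_mask(dates: pd.Series, cfg: FilterConfig) -> np.ndarray:
    d = pd.to_datetime(dates)
    md = list(zip(d.dt.month, d.dt.day))
    return np.array([cfg.season_start <= x <= cfg.season_end for x in md])


def filter_checklists(raw: ChecklistTable, cfg: FilterConfig | None = None):
    """Apply the effort filters; returns (filtered table, per-rule tally).

    The 'random' protocol is reclassified before protocol filtering:
    'traveling' when distance > 0 km, 'stationary' when distance is 0.
    A checklist is counted in the tally under every rule it violates.
    """
    cfg = cfg or FilterConfig()
    meta = raw.meta.copy()
    unknown = ~meta["protocol"].isin(ALLOWED_PROTOCOLS)
    if unknown.any():
        bad = sorted(meta.loc[unknown, "protocol"].unique())
        raise ValueError(f"unknown protocol value(s): {bad}")

    is_random = meta["protocol"] == "random"
    meta.loc[is_random & (meta["distance_km"] > 0), "protocol"] = "traveling"
    meta.loc[is_random & (meta["distance_km"] <= 0), "protocol"] = "stationary"

    ll = compute_list_length(ChecklistTable(meta, raw.obs))
    ll = meta["checklist_id"].map(ll).fillna(0).astype(int)

    rules = {
        "incomplete": ~meta["complete"].astype(bool),
        "party_size": meta["party_size"] > cfg.max_party,
        "duration": meta["duration_hours"] > cfg.max_duration,
        "distance": meta["distance_km"] > cfg.max_distance,
        "protocol": ~meta["protocol"].isin(cfg.protocols),
        "season": ~_season_mask(meta["date"], cfg),
        "min_species": ll < cfg.min_species,
    }
    if cfg.years is not None:
        yr = pd.to_datetime(meta["date"]).dt.year
        rules["years"] = (yr < cfg.years[0]) | (yr > cfg.years[1])
    tally = {k: int(v.sum()) for k, v in rules.items()}
    bad = np.logical_or.reduce(list(rules.values()))
    keep = meta.loc[~bad].reset_index(drop=True)
    obs = raw.obs[raw.obs["checklist_id"].isin(set(keep["checklist_id"]))].reset_index(drop=True)
    return ChecklistTable(keep, obs), tally


def collapse_groups(cl: ChecklistTable) -> ChecklistTable:
    """Merge checklists sharing a group id into one survey unit.

    The unit keeps the first member's metadata; its species rows are the
    union over members (duplicate observations from shared group surveys).
    """
    meta = cl.meta
    if "group_id" not in meta.columns or meta["group_id"].isna().all():
        return cl
    grouped = meta[meta["group_id"].notna()]
    keep_rows, drop_ids, remap = [], set(), {}
    for gid, sub in grouped.groupby("group_id", sort=False):
        rep = sub["checklist_id"].iloc[0]
        for cid in sub["checklist_id"]:
            remap[cid] = rep
        drop_ids.update(sub["checklist_id"].iloc[1:])
    meta2 = meta[~meta["checklist_id"].isin(drop_ids)].reset_index(drop=True)
    obs2 = cl.obs.copy()
    obs2["checklist_id"] = obs2["checklist_id"].map(lambda c: remap.get(c, c))
    obs2 = (
        obs2.groupby(["checklist_id", "species_id"], as_index=False, sort=False)
        .agg(count=("count", "max"))
    )
    return ChecklistTable(meta2, obs2)


def compute_list_length(cl: ChecklistTable) -> pd.Series:
    """List length per survey unit: distinct species on the (group-collapsed)
    checklist.  Units with no species rows get 0 (removed later by the
    minimum-species rule)."""
    merged = collapse_groups(cl)
    ll = merged.obs.groupby("checklist_id")["species_id"].nunique()
    ll = merged.meta["checklist_id"].map(ll).fillna(0).astype(int)
    ll.index = merged.meta["checklist_id"]
    return ll


def restrict_to_range(cl: ChecklistTable, species_id: str) -> ChecklistTable:
    """Keep only checklists at locations with >= 1 detection of the species
    across the study period."""
    det = cl.obs[(cl.obs["species_id"] == species_id) & (cl.obs["count"] > 0)]
    locs = set(cl.meta.set_index("checklist_id").loc[det["checklist_id"], "location_id"])
    if not locs:
        warnings.warn(f"species {species_id} never detected; range restriction empty")
    keep = cl.meta[cl.meta["location_id"].isin(locs)].reset_index(drop=True)
    obs = cl.obs[cl.obs["checklist_id"].isin(set(keep["checklist_id"]))].reset_index(drop=True)
    return ChecklistTable(keep, obs)


def restrict_stops_to_range(stops: StopTable, species_id: str) -> StopTable:
    """Keep only routes with >= 1 detection of the species across the period."""
    det_runs = set(stops.counts.loc[stops.counts["species_id"] == species_id, "run_id"])
    routes = set(stops.runs.loc[stops.runs["run_id"].isin(det_runs), "route_id"])
    if not routes:
        warnings.warn(f"species {species_id} never detected on any route")
    runs = stops.runs[stops.runs["route_id"].isin(routes)].reset_index(drop=True)
    counts = stops.counts[stops.counts["run_id"].isin(set(runs["run_id"]))].reset_index(drop=True)
    return StopTable(runs, counts, stops.stops_per_route)


def _center(x: np.ndarray):
    m = float(np.mean(x)) if len(x) else 0.0
    return x - m, m


def zero_fill(cl: ChecklistTable, species_id: str) -> pd.DataFrame:
    """One presence/absence row per survey unit for the focal species.

    Groups are collapsed first; covariates (day of year and start time,
    centered over this table; list length; protocol; town; year; observer)
    are attached.  Centering means are stored in ``.attrs`` so prediction
    grids use identical centering.
    """
    merged = collapse_groups(cl)
    meta = merged.meta
    det = merged.obs[(merged.obs["species_id"] == species_id) & (merged.obs["count"] > 0)]
    detected = set(det["checklist_id"])
    ll = compute_list_length(merged)
    d = pd.to_datetime(meta["date"])
    doy = d.dt.dayofyear.to_numpy(dtype=float)
    start = meta["start_time"].to_numpy(dtype=float)
    doy_c, doy_mean = _center(doy)
    start_c, start_mean = _center(start)
    out = pd.DataFrame(
        {
            "unit_id": meta["checklist_id"].to_numpy(),
            "source": "checklist",
            "species_id": species_id,
            "response": meta["checklist_id"].isin(detected).astype(int).to_numpy(),
            "town": meta["town"].to_numpy(),
            "year": d.dt.year.to_numpy(),
            "observer_id": meta["observer_id"].to_numpy(),
            "location_id": meta["location_id"].to_numpy(),
            "doy": doy,
            "doy_c": doy_c,
            "start_time": start,
            "start_c": start_c,
            "list_length": ll.to_numpy(),
            "protocol": meta["protocol"].to_numpy(),
        }
    )
    out.attrs["doy_mean"] = doy_mean
    out.attrs["start_mean"] = start_mean
    return out


def recenter(det: pd.DataFrame) -> pd.DataFrame:
    """Re-center doy/start covariates over the current table (after
    subsetting); idempotent on already-centered tables."""
    out = det.copy()
    out["doy_c"], out.attrs["doy_mean"] = _center(out["doy"].to_numpy(dtype=float))
    out["start_c"], out.attrs["start_mean"] = _center(out["start_time"].to_numpy(dtype=float))
    return out


def balance_checklists(
    det: pd.DataFrame,
    seed: int,
    target_ratio: float = 4.0,
    year_tolerance: float = 0.25,
    cell_col: str = "town",
) -> pd.DataFrame:
    """Spatiotemporal subsampling of a zero-filled checklist table.

    Three stages, detections always kept preferentially:

    1. *stratum dedup* — within each (spatial cell, year, ISO week, response)
       stratum keep one row, chosen uniformly at random: at most one
       detection and one non-detection survive per cell-week;
    2. *class balance* — non-detections subsampled so that their count is at
       most ``target_ratio`` times the detection count;
    3. *year balance* — each year's non-detections downsampled toward the
       minimum annual total within ``(1 + year_tolerance)``.

    Deterministic for a fixed seed.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    rng = np.random.default_rng(seed)
    d = det.sort_values("unit_id", kind="stable").reset_index(drop=True)
    dates_week = (
        (d["doy"].to_numpy(dtype=float) - 1) // 7
    ).astype(int)  # season-relative week index
    d = d.assign(_week=dates_week)

    # stage 1: one row per (cell, year, week, response) stratum
    def _pick(idx: np.ndarray) -> int:
        return idx[rng.integers(0, len(idx))] if len(idx) > 1 else idx[0]

    keep = [
        _pick(sub.to_numpy())
        for _, sub in d.groupby([cell_col, "year", "_week", "response"], sort=True).groups.items()
    ]
    d = d.loc[sorted(keep)].reset_index(drop=True)

    # stage 2: subsample non-detections to the target ratio
    n_det = int((d["response"] == 1).sum())
    nondet_idx = d.index[d["response"] == 0].to_numpy()
    max_nondet = int(np.floor(target_ratio * n_det))
    if len(nondet_idx) > max_nondet:
        drop = rng.choice(nondet_idx, size=len(nondet_idx) - max_nondet, replace=False)
        d = d.drop(index=drop).reset_index(drop=True)

    # stage 3: downsample each year's non-detections toward the min-year size
    sizes = d.groupby("year").size()
    cap = int(np.ceil(sizes.min() * (1.0 + year_tolerance)))
    for yr, n_yr in sizes.items():
        if n_yr <= cap:
            continue
        sub = d[(d["year"] == yr) & (d["response"] == 0)]
        excess = min(n_yr - cap, len(sub))
        if excess > 0:
            drop = rng.choice(sub.index.to_numpy(), size=excess, replace=False)
            d = d.drop(index=drop)
    d = d.drop(columns="_week").reset_index(drop=True)
    d = recenter(d)
    d.attrs["balanced"] = True
    return d


def build_stop_detections(
    stops: StopTable, species_id: str, mode: str = "detection"
) -> pd.DataFrame:
    """One row per (route run, stop) for the focal species.

    Low-quality runs are removed via the quality flag; absent
    (run, stop, species) combinations are materialized as explicit zeros.
    ``mode='detection'`` thresholds counts to 0/1; ``mode='count'`` keeps the
    nonnegative counts.
    """
    if mode not in ("detection", "count"):
        raise ValueError("mode must be 'detection' or 'count'")
    runs = stops.runs[stops.runs["quality"] == "good"].reset_index(drop=True)
    counts = stops.counts[stops.counts["species_id"] == species_id]
    dup = counts.duplicated(subset=["run_id", "stop"])
    if dup.any():
        raise ValueError("duplicate (run, stop, species) rows in stop table")
    lookup = counts.set_index(["run_id", "stop"])["count"]

    n_stops = stops.stops_per_route
    run_rep = runs.loc[runs.index.repeat(n_stops)].reset_index(drop=True)
    stop_no = np.tile(np.arange(1, n_stops + 1), len(runs))
    key = pd.MultiIndex.from_arrays([run_rep["run_id"], stop_no])
    c = lookup.reindex(key).fillna(0).to_numpy(dtype=int)
    response = (c > 0).astype(int) if mode == "detection" else c
    out = pd.DataFrame(
        {
            "unit_id": run_rep["run_id"].to_numpy() + "-s" + pd.Series(stop_no).astype(str),
            "source": "stop",
            "species_id": species_id,
            "response": response,
            "town": run_rep["town"].to_numpy(),
            "year": run_rep["year"].to_numpy(),
            "observer_id": run_rep["observer_id"].to_numpy(),
            "location_id": run_rep["route_id"].to_numpy(),
            "doy": 0.0,
            "doy_c": 0.0,
            "start_time": 0.0,
            "start_c": 0.0,
            "list_length": 0,
            "protocol": "stop",
        }
    )
    out.attrs["doy_mean"] = 0.0
    out.attrs["start_mean"] = 0.0
    return out
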