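"""Assemble annual indices, aggregate towns to the state, and difference years.

The pipeline's central product is the (species, index, town, year) estimate
with its standard error.  State-level series are inverse-SE-weighted
averages of town estimates (weights 1/SE, not 1/SE^2 — the weighting the
aggregation is defined with), with the aggregate SE propagated as
sqrt(sum w^2 SE^2) / sum w.  Inter-annual change is the proportional change
relative to the previous year's estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_IDS",
    "IndexSeries",
    "ChangeSeries",
    "aggregate_state",
    "interannual_change",
    "assemble_frame",
]

INDEX_IDS = ("BBS-DP", "BBS-RA", "eBird-GLMM-DP", "eBird-RF-DP")

ESTIMATE_COLUMNS = ["species_id", "index_id", "town", "year", "estimate", "se"]


@dataclass
class IndexSeries:
    """Ordered annual series of one index at one scale."""

    species_id: str
    index_id: str
    scale: str              # "state" or "town:<id>"
    years: np.ndarray
    estimates: np.ndarray
    ses: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years)
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if not (len(self.years) == len(self.estimates) == len(self.ses)):
            raise ValueError("years/estimates/ses must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if not np.all(np.isfinite(self.ses)) or np.any(self.ses <= 0):
            raise ValueError("SEs must be finite and positive")

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.ses

    def __len__(self):
        return len(self.years)


@dataclass
class ChangeSeries:
    species_id: str
    index_id: str
    scale: str
    years: np.ndarray       # years 2..T
    changes: np.ndarray     # proportional change vs previous year (NaN if undefined)


def aggregate_state(town_rows: pd.DataFrame):
    """Inverse-SE weighted state aggregate of one species/index/year.

    Returns (estimate, se) with estimate = sum(w x) / sum(w), w = 1/SE, and
    se = sqrt(sum w^2 SE^2) / sum w (which reduces to sqrt(n) / sum w).
    """
    se = town_rows["se"].to_numpy(dtype=float)
    x = town_rows["estimate"].to_numpy(dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one town estimate")
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("all SEs must be positive and finite")
    w = 1.0 / se
    est = float(np.sum(w * x) / np.sum(w))
    agg_se = float(np.sqrt(np.sum(w**2 * se**2)) / np.sum(w))
    return est, agg_se


def state_series(est: pd.DataFrame, species_id: str, index_id: str) -> IndexSeries:
    """Aggregate a species/index estimate table to the state-level series."""
    sub = est[(est["species_id"] == species_id) & (est["index_id"] == index_id)]
    rows = []
    for yr, g in sub.groupby("year"):
        e, s = aggregate_state(g)
        rows.append((yr, e, s))
    rows.sort()
    yrs, es, ss = zip(*rows)
    return IndexSeries(species_id, index_id, "state", np.array(yrs), np.array(es), np.array(ss))


def town_series(est: pd.DataFrame, species_id: str, index_id: str, town: str) -> IndexSeries:
    sub = est[
        (est["species_id"] == species_id)
        & (est["index_id"] == index_id)
        & (est["town"] == town)
    ].sort_values("year")
    return IndexSeries(
        species_id, index_id, f"town:{town}",
        sub["year"].to_numpy(), sub["estimate"].to_numpy(), sub["se"].to_numpy(),
    )


def interannual_change(series: IndexSeries) -> ChangeSeries:
    """Proportional year-over-year change: (x_t - x_{t-1}) / x_{t-1}.

    A zero previous-year estimate makes the change undefined (NaN, logged).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 years")
    x = series.estimates
    prev = x[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(prev != 0, (x[1:] - prev) / np.where(prev != 0, prev, 1.0), np.nan)
    n_undef = int(np.sum(prev == 0))
    if n_undef:
        warnings.warn(f"{n_undef} inter-annual change(s) undefined (zero previous estimate)")
    return ChangeSeries(series.species_id, series.index_id, series.scale,
                        series.years[1:], delta)


def assemble_frame(est: pd.DataFrame, scale: str = "state"):
    """Align the four indices per species on their common years.

    Returns ``(frames, report)`` where ``frames[species] = {index_id:
    IndexSeries}`` aligned on the intersection of years, and ``report`` notes
    per-index missing years and species excluded for <2 common years.
    """
    frames, report = {}, {"missing": {}, "excluded": []}
    for sp, g in est.groupby("species_id"):
        series = {}
        for idx in INDEX_IDS:
            gi = g[g["index_id"] == idx]
            if gi.empty:
                continue
            if scale == "state":
                series[idx] = state_series(est, sp, idx)
            else:
                town = scale.split(":", 1)[1]
                gt = gi[gi["town"] == town]
                if gt.empty:
                    continue
                series[idx] = town_series(est, sp, idx, town)
        if not series:
            report["excluded"].append(sp)
            continue
        common = sorted(set.intersection(*(set(s.years.tolist()) for s in series.values())))
        all_years = sorted(set.union(*(set(s.years.tolist()) for s in series.values())))
        report["missing"][sp] = {
            idx: sorted(set(all_years) - set(s.years.tolist())) for idx, s in series.items()
        }
        if len(common) < 2:
            warnings.warn(f"species {sp}: fewer than 2 common years; excluded")
            report["excluded"].append(sp)
            continue
        aligned = {}
        for idx, s in series.items():
            mask = np.isin(s.years, common)
            aligned[idx] = IndexSeries(
                sp, idx, s.scale, s.years[mask], s.estimates[mask], s.ses[mask]
            )
        frames[sp] = aligned
    return frames, report
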