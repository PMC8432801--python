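"""Synthetic checklist and route-stop surveys over a known abundance surface.

The generator produces the two survey streams the pipeline consumes:

* semi-structured *checklists* — opportunistic surveys with heterogeneous
  effort (duration, distance, party size, start time), an observer pool with
  varying skill, spatially clustered locations, and a configurable fraction of
  records that violate the standard effort filters;
* structured *route-stop* surveys — fixed routes run once per year, each with
  a fixed number of point-count stops and per-stop counts.

Both are driven by a shared latent abundance surface ``lambda[s, g, t]``
(species, town, year) built from a species base rate, a log-linear annual
trend, and town-level offsets, so every downstream estimate can be scored
against known truth.

Detection on a checklist follows a Poisson-thinning link:
``p = 1 - exp(-lambda * E(effort) * exp(skill))`` with ``E`` a log-linear
multiplier in the effort covariates.  Stop counts are Poisson (optionally
negative-binomial to produce overdispersion) with mean proportional to the
town-year lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticTruth",
    "EffortConfig",
    "PoissonThinningLink",
    "generate_truth",
    "simulate_checklists",
    "simulate_routes",
    "make_town_attributes",
    "ChecklistTable",
    "StopTable",
]

HABITAT_CLASSES = ("developed", "wetland", "herbaceous", "deciduous", "shrub")


# ---------------------------------------------------------------------------
# containers


@dataclass
class SyntheticTruth:
    """Latent abundance surface with known per-species trends.

    ``lam[s, g, t] = exp(base[s] + town_effect[s, g] + trend[s] * (t - t_bar))``
    where ``t_bar`` is the mid-point of the study years, so ``trend`` is the
    exact log-scale annual rate of change in every town.
    """

    towns: list
    years: np.ndarray
    species: list
    base: np.ndarray          # (S,) log base rate
    trend: np.ndarray         # (S,) log-scale annual trend
    town_effect: np.ndarray   # (S, G)
    hotspot_weight: np.ndarray  # (G,) relative sampling intensity, sums to 1
    lam: np.ndarray           # (S, G, T)

    def lam_at(self, species_id, town, year) -> float:
        s = self.species.index(species_id)
        g = self.towns.index(town)
        t = int(np.where(self.years == year)[0][0])
        return float(self.lam[s, g, t])

    def to_frame(self) -> pd.DataFrame:
        """Long truth table (species, town, year, lambda) for recovery scoring."""
        s_idx, g_idx, t_idx = np.meshgrid(
            np.arange(len(self.species)),
            np.arange(len(self.towns)),
            np.arange(len(self.years)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "species_id": np.asarray(self.species)[s_idx.ravel()],
                "town": np.asarray(self.towns)[g_idx.ravel()],
                "year": self.years[t_idx.ravel()],
                "lam": self.lam.ravel(),
            }
        )


@dataclass
class ChecklistTable:
    """Checklist survey stream: per-checklist metadata + long species rows."""

    meta: pd.DataFrame  # one row per checklist_id
    obs: pd.DataFrame   # (checklist_id, species_id, count)

    def to_long(self) -> pd.DataFrame:
        return self.obs.merge(self.meta, on="checklist_id", how="left")

    def write(self, meta_path, obs_path) -> None:
        self.meta.to_csv(meta_path, index=False)
        self.obs.to_csv(obs_path, index=False)

    @classmethod
    def read(cls, meta_path, obs_path) -> "ChecklistTable":
        return cls(pd.read_csv(meta_path), pd.read_csv(obs_path))


@dataclass
class StopTable:
    """Route-stop survey stream: run metadata + positive per-stop counts."""

    runs: pd.DataFrame    # one row per run_id (route, year)
    counts: pd.DataFrame  # (run_id, stop, species_id, count) with count > 0
    stops_per_route: int = 50

    def write(self, runs_path, counts_path) -> None:
        self.runs.to_csv(runs_path, index=False)
        self.counts.to_csv(counts_path, index=False)

    @classmethod
    def read(cls, runs_path, counts_path, stops_per_route: int = 50) -> "StopTable":
        return cls(pd.read_csv(runs_path), pd.read_csv(counts_path), stops_per_route)


@dataclass
class EffortConfig:
    """Scenario parameters for checklist effort and sampling design.

    Defaults aim at a realistic community-science mix: ~1 h surveys of a few
    km with small parties, morning-biased start times, mostly traveling
    protocol, and a modest observer pool with log-odds-scale skill spread.
    Violation rates inject records that the standard filters must remove.
    """

    duration_meanlog: float = math.log(0.9)   # hours
    duration_sdlog: float = 0.6
    distance_meanlog: float = math.log(1.5)   # km (traveling lists)
    distance_sdlog: float = 0.8
    party_geom_p: float = 0.6                 # party size ~ 1 + Geometric
    start_beta: tuple = (2.0, 4.0)            # fraction of day, morning-biased
    protocol_mix: dict = field(
        default_factory=lambda: {"stationary": 0.30, "traveling": 0.62, "random": 0.08}
    )
    n_observers: int = 60
    skill_sd: float = 0.4                     # log-scale observer skill spread
    doy_window: tuple = (121, 196)            # May 1 - Jul 15 (non-leap)
    checklists_per_year: int | np.ndarray = 200
    locations_per_town: int = 8
    background_pool: int = 80
    richness_base: float = 12.0               # mean background list length at E=1
    richness_effort_exp: float = 0.4
    # filter-violation injection rates
    frac_incomplete: float = 0.04
    frac_overlong: float = 0.03
    frac_overdistance: float = 0.03
    frac_bigparty: float = 0.02
    frac_out_of_season: float = 0.02

    def per_year_counts(self, n_years: int, rng: np.random.Generator) -> np.ndarray:
        c = self.checklists_per_year
        if np.isscalar(c):
            return np.full(n_years, int(c))
        c = np.asarray(c, dtype=int)
        if len(c) != n_years:
            raise ValueError("checklists_per_year length must match n_years")
        return c


@dataclass
class PoissonThinningLink:
    """Detection link p = 1 - exp(-lambda * E * exp(skill)).

    ``E = (duration/1h)^a * (1 + distance)^b * party^c`` is a log-linear
    effort multiplier; p is monotone non-decreasing in lambda and in every
    effort covariate (for nonnegative exponents).
    """

    a_duration: float = 0.7
    b_distance: float = 0.3
    c_party: float = 0.2

    def effort_multiplier(self, duration, distance, party) -> np.ndarray:
        dur = np.clip(np.asarray(duration, dtype=float), 1e-3, None)
        dist = np.clip(np.asarray(distance, dtype=float), 0.0, None)
        par = np.clip(np.asarray(party, dtype=float), 1.0, None)
        return (
            dur ** self.a_duration
            * (1.0 + dist) ** self.b_distance
            * par ** self.c_party
        )

    def __call__(self, lam, duration, distance, party, skill) -> np.ndarray:
        e = self.effort_multiplier(duration, distance, party)
        return 1.0 - np.exp(-np.asarray(lam) * e * np.exp(np.asarray(skill)))


# ---------------------------------------------------------------------------
# operations


def generate_truth(
    n_towns: int,
    n_years: int,
    species_specs: list,
    seed: int,
    start_year: int = 2005,
    hotspot_concentration: float = 1.0,
) -> SyntheticTruth:
    """Build the latent abundance surface.

    Parameters
    ----------
    species_specs
        One ``(base_rate, trend, town_sd)`` triple per species: expected count
        per standardized survey unit at the centered year in an average town,
        the log-scale annual trend, and the sd of town-level log offsets.
    hotspot_concentration
        Dirichlet concentration for town sampling weights; values < 1 give
        strongly clustered ("hotspot") checklist sampling.
    """
    if n_towns < 1:
        raise ValueError("n_towns must be >= 1")
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    rng = np.random.default_rng(seed)
    S = len(species_specs)
    base = np.empty(S)
    trend = np.empty(S)
    town_sd = np.empty(S)
    for i, (b, tr, sd) in enumerate(species_specs):
        if b <= 0:
            raise ValueError(f"base rate must be positive, got {b!r}")
        base[i] = math.log(b)
        trend[i] = tr
        town_sd[i] = sd
    towns = [f"T{g+1:02d}" for g in range(n_towns)]
    years = np.arange(start_year, start_year + n_years)
    town_effect = rng.normal(0.0, town_sd[:, None], size=(S, n_towns))
    yc = years - years.mean()
    lam = np.exp(base[:, None, None] + town_effect[:, :, None] + trend[:, None, None] * yc)
    w = rng.dirichlet(np.full(n_towns, hotspot_concentration))
    species = [f"SP{i+1:02d}" for i in range(S)]
    return SyntheticTruth(towns, years, species, base, trend, town_effect, w, lam)


def _doy_to_date(year: int, doy: int) -> str:
    return (pd.Timestamp(year=int(year), month=1, day=1) + pd.Timedelta(days=int(doy) - 1)).strftime(
        "%Y-%m-%d"
    )


def simulate_checklists(
    truth: SyntheticTruth,
    effort: EffortConfig,
    detection_link=None,
    seed: int = 0,
) -> ChecklistTable:
    """Simulate the checklist stream from the latent surface.

    Each checklist draws a town (proportional to hotspot weight), a location
    within the town, an observer, a date, and effort covariates; each focal
    species is detected with probability given by ``detection_link``; a
    background community (filler species) sets the list length, correlated
    with effort through the same multiplier.
    """
    if not truth.species:
        raise ValueError("truth has no species")
    link = detection_link if detection_link is not None else PoissonThinningLink()
    rng = np.random.default_rng(seed)
    n_years = len(truth.years)
    per_year = effort.per_year_counts(n_years, rng)
    n = int(per_year.sum())

    year_idx = np.repeat(np.arange(n_years), per_year)
    town_idx = rng.choice(len(truth.towns), size=n, p=truth.hotspot_weight)

    # clustered locations within towns
    loc_weights = rng.dirichlet(np.full(effort.locations_per_town, 0.8), size=len(truth.towns))
    loc_idx = np.array(
        [rng.choice(effort.locations_per_town, p=loc_weights[g]) for g in town_idx]
    )
    location = np.array(
        [f"{truth.towns[g]}-L{j+1}" for g, j in zip(town_idx, loc_idx)]
    )

    obs_idx = rng.integers(0, effort.n_observers, size=n)
    skill = rng.normal(0.0, effort.skill_sd, size=effort.n_observers)[obs_idx]

    protocols = np.array(list(effort.protocol_mix))
    proto = rng.choice(protocols, size=n, p=np.array(list(effort.protocol_mix.values())))
    duration = np.minimum(
        rng.lognormal(effort.duration_meanlog, effort.duration_sdlog, size=n), 5.0
    )
    distance = np.minimum(
        rng.lognormal(effort.distance_meanlog, effort.distance_sdlog, size=n), 5.0
    )
    distance[proto == "stationary"] = 0.0
    # half of the 'random' protocol lists are stationary in practice
    distance[(proto == "random") & (rng.random(n) < 0.5)] = 0.0
    party = 1 + rng.geometric(effort.party_geom_p, size=n) - 1
    party = np.minimum(party + 1, 10)
    start = rng.beta(*effort.start_beta, size=n)
    lo, hi = effort.doy_window
    doy = rng.integers(lo, hi + 1, size=n)
    complete = np.ones(n, dtype=bool)

    # inject filter violations at configured rates
    def _mask(frac):
        return rng.random(n) < frac

    complete[_mask(effort.frac_incomplete)] = False
    m = _mask(effort.frac_overlong)
    duration[m] = 5.0 + rng.lognormal(0.0, 0.5, size=int(m.sum()))
    m = _mask(effort.frac_overdistance) & (distance > 0)
    distance[m] = 5.0 + rng.lognormal(0.5, 0.5, size=int(m.sum()))
    m = _mask(effort.frac_bigparty)
    party[m] = 11 + rng.integers(0, 10, size=int(m.sum()))
    m = _mask(effort.frac_out_of_season)
    doy[m] = np.where(rng.random(int(m.sum())) < 0.5, lo - rng.integers(5, 40, int(m.sum())), hi + rng.integers(5, 40, int(m.sum())))

    years = truth.years[year_idx]
    cl_ids = np.array([f"C{i+1:06d}" for i in range(n)])
    meta = pd.DataFrame(
        {
            "checklist_id": cl_ids,
            "location_id": location,
            "town": np.asarray(truth.towns)[town_idx],
            "observer_id": np.array([f"obs{j+1:03d}" for j in obs_idx]),
            "date": [_doy_to_date(y, d) for y, d in zip(years, doy)],
            "year": years,
            "start_time": start,
            "protocol": proto,
            "distance_km": distance,
            "duration_hours": duration,
            "party_size": party,
            "complete": complete,
            "group_id": pd.array([pd.NA] * n),
        }
    )

    base_link = link if isinstance(link, PoissonThinningLink) else PoissonThinningLink()
    e_mult = base_link.effort_multiplier(duration, distance, party)

    # focal species detections
    rows_cl, rows_sp, rows_ct = [], [], []
    for s, sp in enumerate(truth.species):
        lam = truth.lam[s, town_idx, year_idx]
        p = np.clip(link(lam, duration, distance, party, skill), 0.0, 1.0)
        det = rng.random(n) < p
        rows_cl.append(cl_ids[det])
        rows_sp.append(np.full(int(det.sum()), sp))
        rows_ct.append(np.ones(int(det.sum()), dtype=int))

    # background community sets the list length, correlated with effort
    richness = rng.poisson(effort.richness_base * e_mult**effort.richness_effort_exp)
    richness = np.clip(richness, 1, effort.background_pool)
    bg_ids = np.array([f"BG{k+1:03d}" for k in range(effort.background_pool)])
    for i in range(n):
        picks = rng.choice(effort.background_pool, size=richness[i], replace=False)
        rows_cl.append(np.full(richness[i], cl_ids[i]))
        rows_sp.append(bg_ids[picks])
        rows_ct.append(np.ones(richness[i], dtype=int))

    obs = pd.DataFrame(
        {
            "checklist_id": np.concatenate(rows_cl),
            "species_id": np.concatenate(rows_sp),
            "count": np.concatenate(rows_ct),
        }
    ).sort_values(["checklist_id", "species_id"], kind="stable", ignore_index=True)
    return ChecklistTable(meta, obs)


def simulate_routes(
    truth: SyntheticTruth,
    n_routes: int,
    stops_per_route: int = 50,
    seed: int = 0,
    stop_scale: float = 0.2,
    nb_dispersion: float | None = None,
    bad_run_rate: float = 0.05,
) -> StopTable:
    """Simulate the structured route-stop stream.

    Each route is assigned to one town and run once per year by a (mostly)
    persistent observer.  Per-stop counts are Poisson with mean
    ``stop_scale * lambda[s, g, t]`` (a stop samples a smaller area than a
    standardized checklist), or negative-binomial with shape ``nb_dispersion``
    when overdispersion is requested.  A configurable fraction of runs is
    flagged low-quality.
    """
    if stops_per_route < 1:
        raise ValueError("stops_per_route must be >= 1")
    rng = np.random.default_rng(seed)
    route_town = rng.integers(0, len(truth.towns), size=n_routes)
    # ensure coverage of all towns when possible
    if n_routes >= len(truth.towns):
        route_town[: len(truth.towns)] = np.arange(len(truth.towns))
    route_obs = rng.integers(0, max(2, n_routes), size=n_routes)

    runs = []
    crl, cst, csp, cct = [], [], [], []
    for r in range(n_routes):
        obs_id = f"bbsobs{route_obs[r]+1:03d}"
        for t, year in enumerate(truth.years):
            if rng.random() < 0.1:  # occasional observer turnover
                obs_id = f"bbsobs{rng.integers(0, max(2, n_routes))+1:03d}"
            run_id = f"R{r+1:03d}-{year}"
            quality = "good" if rng.random() >= bad_run_rate else "bad"
            runs.append(
                {
                    "route_id": f"R{r+1:03d}",
                    "run_id": run_id,
                    "year": int(year),
                    "town": truth.towns[route_town[r]],
                    "observer_id": obs_id,
                    "quality": quality,
                }
            )
            for s, sp in enumerate(truth.species):
                mu = stop_scale * truth.lam[s, route_town[r], t]
                if nb_dispersion is None:
                    counts = rng.poisson(mu, size=stops_per_route)
                else:
                    k = nb_dispersion
                    counts = rng.negative_binomial(k, k / (k + mu), size=stops_per_route)
                nz = np.nonzero(counts)[0]
                crl.extend([run_id] * len(nz))
                cst.extend((nz + 1).tolist())
                csp.extend([sp] * len(nz))
                cct.extend(counts[nz].tolist())

    counts = pd.DataFrame(
        {"run_id": crl, "stop": cst, "species_id": csp, "count": cct}
    )
    return StopTable(pd.DataFrame(runs), counts, stops_per_route)


def make_town_attributes(truth: SyntheticTruth, seed: int = 0) -> pd.DataFrame:
    """Per-town attribute table: area, habitat-class proportions, survey density.

    Habitat proportions are Dirichlet over the aggregated land-cover classes
    (plus an 'other' remainder); checklist-location density reflects the
    hotspot sampling weights per unit area.
    """
    rng = np.random.default_rng(seed)
    G = len(truth.towns)
    area = rng.lognormal(math.log(60.0), 0.4, size=G)  # km^2
    props = rng.dirichlet(np.array([3.0, 1.0, 1.0, 3.0, 1.0, 2.0]), size=G)
    out = pd.DataFrame({"town": truth.towns, "area_km2": area})
    for j, h in enumerate(HABITAT_CLASSES):
        out[h] = props[:, j]
    out["survey_density"] = truth.hotspot_weight * 100.0 / area
    return out
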