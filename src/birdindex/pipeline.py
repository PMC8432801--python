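"""End-to-end drivers: simulate -> preprocess -> fit four indices -> compare.

These helpers chain the module surface into the study design: for each
species, the checklist stream yields a mixed-model detection-probability
index and a balanced-random-forest detection-probability index, and the
route-stop stream yields detection-probability and count relative-abundance
indices; all four are placed on a common (species, town, year) frame with
bootstrap (or tree-vote) SEs attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from birdindex import comparison as cmp
from birdindex import glmm, indices, preprocess, rf, synthetic

__all__ = ["Scenario", "simulate_scenario", "fit_species_indices", "run_scenario"]


@dataclass
class Scenario:
    """Study conditions for a synthetic run.

    Defaults mirror the study design the pipeline targets: 5 towns observed
    over 14 years, ~3,000 checklists in total (unequal across years), and 10
    routes of 50 stops run once per year.  Species alternate between
    increasing and decreasing log-linear trends of the stated magnitude.
    """

    n_species: int = 20
    n_towns: int = 5
    n_years: int = 14
    start_year: int = 2005
    trend: float = 0.2
    base_rate: float = 0.6       # expected focal count per standardized checklist
    town_sd: float = 0.3
    checklists_total: int = 3000
    n_routes: int = 10
    stops_per_route: int = 50
    stop_scale: float = 0.2
    skill_sd: float = 0.4
    equal_effort: bool = False   # equal checklist counts across years
    bootstrap_B: int = 40
    rf_trees: int = 300

    def species_specs(self):
        return [
            (self.base_rate, self.trend if i % 2 == 0 else -self.trend, self.town_sd)
            for i in range(self.n_species)
        ]


def simulate_scenario(sc: Scenario, seed: int):
    """Generate truth plus both survey streams for a scenario."""
    rng = np.random.default_rng(seed)
    truth = synthetic.generate_truth(
        sc.n_towns, sc.n_years, sc.species_specs(), seed=int(rng.integers(2**31 - 1)),
        start_year=sc.start_year,
    )
    if sc.equal_effort:
        per_year = np.full(sc.n_years, sc.checklists_total // sc.n_years)
    else:
        per_year = rng.multinomial(
            sc.checklists_total, rng.dirichlet(np.full(sc.n_years, 8.0))
        )
        per_year = np.maximum(per_year, 20)
    effort = synthetic.EffortConfig(
        checklists_per_year=per_year, skill_sd=sc.skill_sd
    )
    checklists = synthetic.simulate_checklists(
        truth, effort, seed=int(rng.integers(2**31 - 1))
    )
    stops = synthetic.simulate_routes(
        truth, sc.n_routes, sc.stops_per_route, seed=int(rng.integers(2**31 - 1)),
        stop_scale=sc.stop_scale,
    )
    return truth, checklists, stops


def _glmm_index(det, spec, grid, B, seed, refit_theta=False):
    fit = glmm.fit_glmm(det, spec)
    est = glmm.predict_standardized(fit, grid)
    se = glmm.bootstrap_se(fit, det, grid, B=B, seed=seed, refit_theta=refit_theta)
    out = est.merge(se[["town", "year", "se"]], on=["town", "year"])
    out["se"] = np.maximum(out["se"], 1e-5)  # floor keeps 1/SE weights finite
    return out, fit


def fit_species_indices(
    checklists: synthetic.ChecklistTable,
    stops: synthetic.StopTable,
    species_id: str,
    seed: int = 0,
    B: int = 40,
    rf_trees: int = 300,
    balance: bool = True,
    select_effort: bool = False,
) -> pd.DataFrame:
    """Compute all four index estimates for one species.

    Returns tidy rows (species_id, index_id, town, year, estimate, se).
    Bootstrap SEs for the mixed-model indices use ``B`` replicates with
    variance parameters held at their fitted values (the batch default).
    """
    rng = np.random.default_rng(seed)
    rows = []

    # --- checklist stream ----------------------------------------------
    filtered, _ = preprocess.filter_checklists(checklists)
    ranged = preprocess.restrict_to_range(filtered, species_id)
    det = preprocess.zero_fill(ranged, species_id)
    if balance:
        det_glmm = preprocess.balance_checklists(det, seed=int(rng.integers(2**31 - 1)))
    else:
        det_glmm = det
    grid_cl = glmm.make_prediction_grid(det_glmm)

    if select_effort:
        _, fit = glmm.select_effort_form(det_glmm)
        spec = fit.spec
        est = glmm.predict_standardized(fit, grid_cl)
        se = glmm.bootstrap_se(fit, det_glmm, grid_cl, B=B,
                               seed=int(rng.integers(2**31 - 1)), refit_theta=False)
        out = est.merge(se[["town", "year", "se"]], on=["town", "year"])
        out["se"] = np.maximum(out["se"], 1e-5)
    else:
        out, fit = _glmm_index(
            det_glmm, glmm.GlmmSpec(family="binomial", effort="L"), grid_cl,
            B, int(rng.integers(2**31 - 1)),
        )
    out["species_id"], out["index_id"] = species_id, "eBird-GLMM-DP"
    rows.append(out)

    # balanced random forest on the same (unbalanced) zero-filled table
    train, test = rf.split_train_test(det, frac=0.2, seed=int(rng.integers(2**31 - 1)))
    forest = rf.fit_rf(train, rf.RfSpec(n_trees=rf_trees, seed=int(rng.integers(2**31 - 1))))
    curve = rf.calibrate(forest, train)
    evaluation = rf.evaluate_rf(forest, curve, test)
    grid_rf = glmm.make_prediction_grid(det)
    out = rf.predict_rf_standardized(forest, curve, grid_rf)
    out["species_id"], out["index_id"] = species_id, "eBird-RF-DP"
    rows.append(out)

    # --- route-stop stream ---------------------------------------------
    ranged_stops = preprocess.restrict_stops_to_range(stops, species_id)
    det_dp = preprocess.build_stop_detections(ranged_stops, species_id, mode="detection")
    det_ra = preprocess.build_stop_detections(ranged_stops, species_id, mode="count")
    grid_bbs = glmm.make_prediction_grid(det_dp)
    for name, d, fam in (
        ("BBS-DP", det_dp, "binomial"),
        ("BBS-RA", det_ra, "quasipoisson"),
    ):
        out, _ = _glmm_index(
            d, glmm.GlmmSpec(family=fam, effort=None), grid_bbs,
            B, int(rng.integers(2**31 - 1)),
        )
        out["species_id"], out["index_id"] = species_id, name
        rows.append(out)

    result = pd.concat(rows, ignore_index=True)[indices.ESTIMATE_COLUMNS]
    result.attrs["rf_evaluation"] = evaluation.to_dict()
    return result


def run_scenario(sc: Scenario, seed: int, species=None) -> dict:
    """Simulate a scenario and fit all indices for the requested species.

    Returns a dict with the truth, the estimate table, per-species RF
    evaluations, and the state-level aligned frames.
    """
    truth, checklists, stops = simulate_scenario(sc, seed)
    species = species if species is not None else truth.species
    rng = np.random.default_rng(seed + 10_000)
    all_rows, rf_evals = [], {}
    for sp in species:
        est = fit_species_indices(
            checklists, stops, sp, seed=int(rng.integers(2**31 - 1)),
            B=sc.bootstrap_B, rf_trees=sc.rf_trees,
        )
        rf_evals[sp] = est.attrs.get("rf_evaluation")
        all_rows.append(est)
    est = pd.concat(all_rows, ignore_index=True)
    frames, report = indices.assemble_frame(est, scale="state")
    return {
        "truth": truth,
        "estimates": est,
        "frames": frames,
        "alignment_report": report,
        "rf_evaluations": rf_evals,
    }


def trend_sign_recovery(result: dict) -> pd.DataFrame:
    """Score trend-direction recovery against truth for every species/index.

    A species/index counts as recovered when the fitted linear trend
    coefficient is directional (95% CI excludes zero) with the sign of the
    true log-linear trend.
    """
    truth = result["truth"]
    rows = []
    for sp, frame in result["frames"].items():
        true_trend = truth.trend[truth.species.index(sp)]
        for idx, series in frame.items():
            tf = cmp.fit_trend(series)
            ok = tf.directional and np.sign(tf.linear) == np.sign(true_trend)
            rows.append({
                "species_id": sp, "index_id": idx, "true_trend": true_trend,
                "linear": tf.linear, "ci_low": tf.linear_ci[0],
                "ci_high": tf.linear_ci[1], "recovered": bool(ok),
            })
    return pd.DataFrame(rows)


BETWEEN_DATASET_PAIRS = (
    ("BBS-DP", "eBird-GLMM-DP"),
    ("BBS-DP", "eBird-RF-DP"),
    ("BBS-RA", "eBird-GLMM-DP"),
    ("BBS-RA", "eBird-RF-DP"),
)


def pairwise_state_correlations(result: dict, pairs=None) -> pd.DataFrame:
    """Annual and inter-annual correlations for index pairs, per species."""
    pairs = pairs if pairs is not None else BETWEEN_DATASET_PAIRS
    rows = []
    for sp, frame in result["frames"].items():
        for a, b in pairs:
            if a not in frame or b not in frame:
                continue
            ann = cmp.correlate_state(frame[a], frame[b], sp, (a, b), "annual")
            ca = indices.interannual_change(frame[a])
            cb = indices.interannual_change(frame[b])
            inter = cmp.correlate_state(ca, cb, sp, (a, b), "interannual")
            for res in (ann, inter):
                rows.append({
                    "species_id": sp, "pair": f"{a}~{b}",
                    "resolution": res.resolution, "method": res.method,
                    "r": res.r, "p": res.p, "n": res.n,
                })
    return pd.DataFrame(rows)
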