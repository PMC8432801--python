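"""Balanced random-forest detection model with GAM calibration.

The second checklist index: detection is modeled as a function of year, day
of year, start time, list length, and town.  Each tree is grown on a
balanced bootstrap (the majority class downsampled to the minority count) to
counter detection/non-detection imbalance; the forest score is the fraction
of trees voting detection.  Scores are then calibrated against observed
detection rates with a binomial spline GAM, and evaluated on a held-out 20%
split (AUC by the rank formulation, Cohen's kappa maximized over a threshold
grid, and Brier-type MSE before and after calibration).

Standardized town x year predictions take the calibrated score at the
species' modal detection day/time and mean list length; the prediction SE
is the standard error of the per-tree vote mean, floored at a small epsilon
so inverse-SE aggregation weights stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "RfSpec",
    "BalancedForest",
    "CalibrationCurve",
    "RfEvaluation",
    "split_train_test",
    "fit_rf",
    "calibrate",
    "evaluate_rf",
    "predict_rf_standardized",
    "rank_auc",
    "max_kappa",
]

SE_FLOOR = 1e-4
PREDICTORS = ("year", "doy", "start_time", "list_length", "town")


@dataclass
class RfSpec:
    n_trees: int = 500
    test_frac: float = 0.2
    predictors: tuple = PREDICTORS
    max_features: str | int = "sqrt"
    min_samples_leaf: int = 5
    seed: int = 0


@dataclass
class BalancedForest:
    trees: list
    town_codes: dict
    predictors: tuple
    importance: pd.Series
    inbag: list = field(default_factory=list)  # per-tree in-bag row indices
    n_train: int = 0

    def _design(self, det: pd.DataFrame) -> np.ndarray:
        cols = []
        for p in self.predictors:
            if p == "town":
                unseen = set(det["town"]) - set(self.town_codes)
                if unseen:
                    raise KeyError(f"towns absent from training data: {sorted(unseen)}")
                cols.append(det["town"].map(self.town_codes).to_numpy(dtype=float))
            else:
                cols.append(det[p].to_numpy(dtype=float))
        return np.column_stack(cols)

    def votes(self, det: pd.DataFrame) -> np.ndarray:
        """(n_rows, n_trees) matrix of per-tree 0/1 votes."""
        X = self._design(det)
        return np.column_stack([t.predict(X) for t in self.trees])

    def score(self, det: pd.DataFrame) -> np.ndarray:
        return self.votes(det).mean(axis=1)

    def oob_score(self, train: pd.DataFrame) -> np.ndarray:
        """Per-row vote mean over trees whose bootstrap excluded the row.

        Rows that are in-bag for every tree (rare) fall back to the full
        vote mean.
        """
        if len(train) != self.n_train or not self.inbag:
            raise ValueError("oob_score requires the original training table")
        V = self.votes(train)
        mask = np.ones_like(V, dtype=bool)
        for t, idx in enumerate(self.inbag):
            mask[np.unique(idx), t] = False
        cnt = mask.sum(axis=1)
        s = np.where(cnt > 0, (V * mask).sum(axis=1) / np.maximum(cnt, 1), V.mean(axis=1))
        return s


@dataclass
class CalibrationCurve:
    """Smooth monotone-capable map from raw scores to observed rates."""

    _gam_result: object
    lo: float
    hi: float
    identity: bool = False

    def __call__(self, scores) -> np.ndarray:
        s = np.clip(np.asarray(scores, dtype=float), self.lo, self.hi)
        if self.identity:
            return np.clip(s, 0.0, 1.0)
        out = self._gam_result.predict(
            exog=np.ones((len(s), 1)), exog_smooth=s[:, None]
        )
        return np.clip(np.asarray(out), 0.0, 1.0)


@dataclass
class RfEvaluation:
    auc: float | None
    kappa_max: float | None
    mse_raw: float
    mse_calibrated: float

    def to_dict(self):
        return {
            "auc": self.auc,
            "kappa_max": self.kappa_max,
            "mse_raw": self.mse_raw,
            "mse_calibrated": self.mse_calibrated,
        }


def split_train_test(det: pd.DataFrame, frac: float = 0.2, seed: int = 0):
    """Disjoint, exhaustive train/test partition by survey unit."""
    if not 0.0 < frac < 1.0:
        raise ValueError("test fraction must be in (0, 1)")
    if det.empty:
        raise ValueError("empty detection table")
    rng = np.random.default_rng(seed)
    n = len(det)
    n_test = int(round(frac * n))
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    train = det.iloc[train_idx].reset_index(drop=True)
    test = det.iloc[test_idx].reset_index(drop=True)
    for d in (train, test):
        d.attrs.update(det.attrs)
    return train, test


def fit_rf(train: pd.DataFrame, spec: RfSpec | None = None) -> BalancedForest:
    """Grow the balanced forest.

    Each tree is trained on a bootstrap with equal numbers of detections and
    non-detections (sampling ``n_min`` with replacement from each class).
    Variable importance is the mean impurity importance across trees.
    """
    spec = spec or RfSpec()
    y = train["response"].to_numpy(dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contain a single class")
    town_codes = {t: i for i, t in enumerate(sorted(train["town"].unique()))}
    forest = BalancedForest([], town_codes, spec.predictors, None)
    X = forest._design(train)

    idx_pos = np.nonzero(y == 1)[0]
    idx_neg = np.nonzero(y == 0)[0]
    n_min = min(len(idx_pos), len(idx_neg))
    rng = np.random.default_rng(spec.seed)
    importances = np.zeros(len(spec.predictors))
    for b in range(spec.n_trees):
        take = np.concatenate(
            [rng.choice(idx_pos, n_min, replace=True), rng.choice(idx_neg, n_min, replace=True)]
        )
        tree = DecisionTreeClassifier(
            max_features=spec.max_features,
            min_samples_leaf=spec.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[take], y[take])
        forest.trees.append(tree)
        forest.inbag.append(take)
        importances += tree.feature_importances_
    forest.importance = pd.Series(importances / spec.n_trees, index=list(spec.predictors))
    forest.n_train = len(train)
    return forest


def calibrate(
    forest: BalancedForest | None,
    train: pd.DataFrame,
    df: int = 10,
    scores: np.ndarray | None = None,
) -> CalibrationCurve:
    """Fit the calibration GAM: observed 0/1 detection regressed on the
    predicted score with a binomial spline smoother.

    Scores are out-of-bag vote means by default (in-sample tree votes are
    overfit and would separate the GAM); the resulting curve is clamped to
    [0, 1] and to the trained score range.  ``scores`` can be supplied
    directly to calibrate an external score vector.
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if scores is None:
        scores = forest.oob_score(train)
    scores = np.asarray(scores, dtype=float)
    y = train["response"].to_numpy(dtype=float)
    lo, hi = float(scores.min()), float(scores.max())
    if np.unique(np.round(scores, 6)).size < 2:
        warnings.warn("degenerate forest scores; using identity calibration")
        return CalibrationCurve(None, 0.0, 1.0, identity=True)
    bs = BSplines(scores[:, None], df=[df], degree=[3])
    gam = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = gam.fit()
        except PerfectSeparationError:
            # ridge-penalize the smoother when scores separate the response
            gam.alpha = [10.0]
            res = gam.fit()
    return CalibrationCurve(res, lo, hi)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """AUC by the Mann-Whitney rank formulation with tie correction."""
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        return None
    r = rankdata(scores)  # average ranks handle ties
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def max_kappa(scores: np.ndarray, labels: np.ndarray, n_grid: int = 101):
    """Cohen's kappa maximized over an evenly spaced threshold grid."""
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if labels.min() == labels.max():
        return None
    best = -1.0
    for thr in np.linspace(0.0, 1.0, n_grid):
        pred = (scores >= thr).astype(int)
        tp = int(((pred == 1) & (labels == 1)).sum())
        tn = int(((pred == 0) & (labels == 0)).sum())
        fp = int(((pred == 1) & (labels == 0)).sum())
        fn = int(((pred == 0) & (labels == 1)).sum())
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        if pe < 1.0:
            best = max(best, (po - pe) / (1 - pe))
    return float(best)


def evaluate_rf(
    forest: BalancedForest, curve: CalibrationCurve, test: pd.DataFrame
) -> RfEvaluation:
    """Held-out evaluation: AUC, maximized kappa, MSE before/after calibration.

    With a one-class test set AUC and kappa are undefined and reported as
    missing; the MSEs are still computed.
    """
    y = test["response"].to_numpy(dtype=int)
    raw = forest.score(test)
    cal = curve(raw)
    return RfEvaluation(
        auc=rank_auc(raw, y),
        kappa_max=max_kappa(raw, y),
        mse_raw=float(np.mean((raw - y) ** 2)),
        mse_calibrated=float(np.mean((cal - y) ** 2)),
    )


def predict_rf_standardized(
    forest: BalancedForest, curve: CalibrationCurve, grid: pd.DataFrame
) -> pd.DataFrame:
    """Calibrated town x year estimates with per-tree vote SEs.

    estimate = curve(mean tree vote); se = sd(votes) / sqrt(n_trees),
    floored at a small epsilon so unanimous forests keep finite weight.
    """
    votes = forest.votes(grid)
    score = votes.mean(axis=1)
    se = votes.std(axis=1, ddof=1) / np.sqrt(votes.shape[1])
    out = grid[["town", "year"]].copy()
    out["estimate"] = curve(score)
    out["se"] = np.maximum(se, SE_FLOOR)
    return out
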