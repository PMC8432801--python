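"""Generalized linear mixed models in the nAGQ=0 regime.

Binomial (logit) and quasi-Poisson (log) models with crossed random
intercepts (town, observer), fitted by penalized iteratively reweighted
least squares (PIRLS): for a candidate value of the random-effect standard
deviations, the fixed effects ``beta`` and spherical random effects ``u``
are optimized *jointly* inside the penalized weighted least-squares step —
the nAGQ=0 contract, with no full Laplace refinement of ``beta`` — and the
profiled Laplace deviance

    dev(y, mu) + |u|^2 + log det(Lambda' Z' W Z Lambda + I)

is minimized over the log standard deviations by a derivative-free outer
loop.  Quasi-Poisson fits run Poisson PIRLS and then estimate the dispersion
``phi`` as Pearson chi^2 / (n - p), scaling all fixed-effect SEs by
sqrt(phi).

Standardized prediction evaluates the fitted model on a (town, year) grid at
species-standardized covariates with the observer effect set to zero, and a
parametric bootstrap (simulate -> refit -> re-predict) supplies standard
errors for every grid cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from patsy import build_design_matrices, dmatrix
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "GlmmSpec",
    "GlmmFit",
    "fit_glmm",
    "select_effort_form",
    "make_prediction_grid",
    "predict_standardized",
    "bootstrap_se",
    "ConvergenceError",
]

_SIGMA_FLOOR = 1e-4  # sds below this are treated as exactly zero
_ETA_CLIP = 30.0


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class GlmmSpec:
    """Model specification.

    ``family`` is 'binomial' or 'quasipoisson'.  ``effort`` selects the
    checklist effort block: None (no effort terms; used for the stop-survey
    models), 'L' (list length) or 'logL' (natural log of list length); when
    present the block is list length + protocol + their interaction, plus
    centered day-of-year (linear + quadratic) and centered start time.
    Year always enters as a factor.  Random intercepts: town and observer.
    """

    family: str = "binomial"
    effort: str | None = "L"
    response: str = "response"
    re_factors: tuple = ("town", "observer_id")
    formula_override: str | None = None  # e.g. "1" for an intercept-only model

    def __post_init__(self):
        if self.family not in ("binomial", "quasipoisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.effort not in (None, "L", "logL"):
            raise ValueError(f"unknown effort form {self.effort!r}")

    def formula(self) -> str:
        if self.formula_override is not None:
            return self.formula_override
        terms = ["C(year)"]
        if self.effort is not None:
            lterm = "list_length" if self.effort == "L" else "np.log(list_length)"
            terms += [
                "doy_c", "I(doy_c**2)", "start_c",
                lterm, "C(protocol)", f"{lterm}:C(protocol)",
            ]
        return " + ".join(terms)


@dataclass
class GlmmFit:
    spec: GlmmSpec
    design_info: object
    beta: pd.Series
    vcov_beta: np.ndarray
    sigma: dict                 # factor -> random-intercept sd
    u: dict                     # factor -> Series of spherical conditional modes
    phi: float
    centering: dict
    deviance: float             # profiled Laplace objective (-2 logLik approx)
    loglik: float
    converged: bool
    n_iter: int
    message: str = ""

    @property
    def re_variances(self) -> dict:
        return {k: v**2 for k, v in self.sigma.items()}

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "family": self.spec.family,
            "effort": self.spec.effort,
            "beta": self.beta.to_dict(),
            "beta_se": dict(zip(self.beta.index, np.sqrt(np.diag(self.vcov_beta)))),
            "sigma": self.sigma,
            "phi": self.phi,
            "centering": self.centering,
            "deviance": self.deviance,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


# ---------------------------------------------------------------------------
# families


class _Binomial:
    name = "binomial"

    @staticmethod
    def linkinv(eta):
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))

    @staticmethod
    def mu_eta(eta):
        p = _Binomial.linkinv(eta)
        return p * (1.0 - p)

    @staticmethod
    def variance(mu):
        return np.clip(mu * (1.0 - mu), 1e-10, None)

    @staticmethod
    def deviance(y, mu):
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

    @staticmethod
    def initialize(y):
        return np.log((np.clip(np.mean(y), 0.02, 0.98)) / (1 - np.clip(np.mean(y), 0.02, 0.98))) * np.ones(len(y))


class _Poisson:
    name = "poisson"

    @staticmethod
    def linkinv(eta):
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    @staticmethod
    def mu_eta(eta):
        return _Poisson.linkinv(eta)

    @staticmethod
    def variance(mu):
        return np.clip(mu, 1e-10, None)

    @staticmethod
    def deviance(y, mu):
        mu = np.clip(mu, 1e-12, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * np.sum(term - (y - mu))

    @staticmethod
    def initialize(y):
        return np.log(np.clip(np.mean(y), 1e-3, None)) * np.ones(len(y))


def _family(name):
    return _Binomial if name == "binomial" else _Poisson


# ---------------------------------------------------------------------------
# PIRLS core


def _re_indicators(det: pd.DataFrame, factors):
    """Sparse indicator matrix per random factor, plus level lists."""
    mats, levels = [], []
    n = len(det)
    for f in factors:
        codes, lev = pd.factorize(det[f], sort=True)
        Z = sp.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, len(lev))
        )
        mats.append(Z)
        levels.append(list(lev))
    return mats, levels


def _pirls(X, Zs, y, fam, sigmas, coef0=None, max_iter=200, tol=1e-8):
    """Joint penalized IRLS for (beta, u) at fixed random-effect sds.

    Returns (beta, us, eta, objective, n_iter).  ``objective`` is the
    profiled Laplace deviance at convergence.
    """
    n, p = X.shape
    act = [i for i, s in enumerate(sigmas) if s > 0]
    Zact = [Zs[i] for i in act]
    qs = [Z.shape[1] for Z in Zact]
    q = int(np.sum(qs)) if qs else 0
    Zt = sp.hstack(Zact).tocsr() if q else None
    scale = np.concatenate([np.full(m, sigmas[act[j]]) for j, m in enumerate(qs)]) if q else np.empty(0)

    coef = np.zeros(p + q)
    if coef0 is not None and len(coef0) == p + q:
        coef = coef0.copy()
        eta = X @ coef[:p] + (Zt @ (scale * coef[p:]) if q else 0.0)
    else:
        eta = fam.initialize(y)

    n_iter = 0
    pendev_prev, plateau = np.inf, 0
    for n_iter in range(1, max_iter + 1):
        mu = fam.linkinv(eta)
        me = np.clip(fam.mu_eta(eta), 1e-10, None)
        w = me**2 / fam.variance(mu)
        z = eta + (y - mu) / me

        Xw = X * w[:, None]
        M = np.empty((p + q, p + q))
        M[:p, :p] = X.T @ Xw
        rhs = np.empty(p + q)
        rhs[:p] = Xw.T @ z
        if q:
            ZtW = Zt.multiply(w[:, None]).tocsr()
            XtWZ = (ZtW.T @ X).T * scale[None, :]
            ZtWZ = (ZtW.T @ Zt).toarray() * np.outer(scale, scale)
            M[:p, p:] = XtWZ
            M[p:, :p] = XtWZ.T
            M[p:, p:] = ZtWZ + np.eye(q)
            rhs[p:] = (ZtW.T @ z) * scale
        try:
            c, low = cho_factor(M, lower=True)
            new = cho_solve((c, low), rhs)
        except np.linalg.LinAlgError as e:  # pragma: no cover - degenerate design
            raise ConvergenceError(f"singular PIRLS system: {e}")

        def _pen_dev(cf):
            e = X @ cf[:p] + (Zt @ (scale * cf[p:]) if q else 0.0)
            return fam.deviance(y, fam.linkinv(e)) + float(cf[p:] @ cf[p:])

        # step-halving: never accept a step that increases the penalized deviance
        if n_iter > 1:
            old_obj = _pen_dev(coef)
            for _ in range(15):
                if _pen_dev(new) <= old_obj + 1e-10:
                    break
                new = 0.5 * (new + coef)
        delta = np.max(np.abs(new - coef)) if n_iter > 1 else np.inf
        coef = new
        eta = X @ coef[:p] + (Zt @ (scale * coef[p:]) if q else 0.0)
        if delta < tol:
            break
        # quasi-separated cells drift forever at a flat penalized deviance;
        # a sustained plateau counts as convergence
        pendev = _pen_dev(coef) if n_iter > 1 else np.inf
        if np.isfinite(pendev) and abs(pendev_prev - pendev) < 1e-10 * (1.0 + abs(pendev)):
            plateau += 1
            if plateau >= 4:
                break
        else:
            plateau = 0
        pendev_prev = pendev
    else:
        raise ConvergenceError(
            f"PIRLS did not converge in {max_iter} iterations (last change {delta:.3g})",
            trace={"delta": delta},
        )

    mu = fam.linkinv(eta)
    u = coef[p:]
    obj = fam.deviance(y, mu) + float(u @ u)
    if q:
        me = np.clip(fam.mu_eta(eta), 1e-10, None)
        w = me**2 / fam.variance(mu)
        ZtW = Zt.multiply(w[:, None]).tocsr()
        A = (ZtW.T @ Zt).toarray() * np.outer(scale, scale) + np.eye(q)
        sign, logdet = np.linalg.slogdet(A)
        obj += logdet

    # split u back into per-factor blocks over *all* factors (zeros where sd=0)
    us_full = []
    pos = 0
    for i, Z in enumerate(Zs):
        m = Z.shape[1]
        if i in act:
            us_full.append(u[pos:pos + m])
            pos += m
        else:
            us_full.append(np.zeros(m))
    return coef[:p], us_full, eta, obj, n_iter, M, (p, q, act, scale)


def fit_glmm(det: pd.DataFrame, spec: GlmmSpec, max_outer: int = 200) -> GlmmFit:
    """Fit the mixed model on a standardized detection table.

    The outer loop minimizes the profiled Laplace deviance over the log
    random-effect sds (Nelder-Mead); fitted sds below 1e-4 collapse to
    exactly zero and the model is re-profiled without that factor, so
    zero-variance data reproduce the plain GLM solution to machine
    precision.
    """
    fam = _family(spec.family)
    y = det[spec.response].to_numpy(dtype=float)
    if spec.family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial family requires a 0/1 response")
    dmat = dmatrix(spec.formula(), det, return_type="dataframe")
    X = np.ascontiguousarray(dmat.to_numpy(dtype=float))
    names = list(dmat.columns)
    Zs, levels = _re_indicators(det, spec.re_factors)
    k = len(Zs)

    def objective(logsd):
        sig = np.exp(np.clip(logsd, -12.0, 3.0))
        try:
            out = _pirls(X, Zs, y, fam, sig, coef0=None)
        except ConvergenceError:
            return 1e12
        return out[3]

    if k:
        res = minimize(
            objective,
            x0=np.full(k, np.log(0.5)),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": max_outer * k,
                     "maxfev": max_outer * k},
        )
        sig = np.exp(np.clip(res.x, -12.0, 3.0))
        sig[sig < _SIGMA_FLOOR] = 0.0
        outer_ok = bool(res.success) or res.fun < 1e11
    else:
        sig = np.empty(0)
        outer_ok = True

    try:
        beta, us, eta, obj, n_iter, M, (p, q, act, scale) = _pirls(X, Zs, y, fam, sig)
    except ConvergenceError as e:
        big = [nm for nm, b in zip(names, getattr(e, "beta", []) or []) if abs(b) > 25]
        raise ConvergenceError(
            "final PIRLS failed" + (f" (possible separation in {big})" if big else ""),
            trace=getattr(e, "trace", None),
        )
    mu = fam.linkinv(eta)
    if (
        spec.family == "binomial"
        and np.max(np.abs(beta)) > 25
        and fam.deviance(y, mu) < 0.05 * len(y)
    ):
        # boundary coefficients plus a near-perfect fit: the design separates
        j = int(np.argmax(np.abs(beta)))
        raise ConvergenceError(
            f"complete separation suspected: coefficient {names[j]!r} = {beta[j]:.1f}"
        )

    if spec.family == "quasipoisson":
        pearson = float(np.sum((y - mu) ** 2 / fam.variance(mu)))
        phi = pearson / max(len(y) - X.shape[1], 1)
    else:
        phi = 1.0

    Minv = np.linalg.inv(M)
    vcov = phi * Minv[: X.shape[1], : X.shape[1]]

    sigma = {f: float(s) for f, s in zip(spec.re_factors, sig)}
    u = {
        f: pd.Series(us[i], index=levels[i])
        for i, f in enumerate(spec.re_factors)
    }
    return GlmmFit(
        spec=spec,
        design_info=dmat.design_info,
        beta=pd.Series(beta, index=names),
        vcov_beta=vcov,
        sigma=sigma,
        u=u,
        phi=phi,
        centering={
            "doy_mean": det.attrs.get("doy_mean", 0.0),
            "start_mean": det.attrs.get("start_mean", 0.0),
        },
        deviance=obj,
        loglik=-0.5 * obj,
        converged=outer_ok,
        n_iter=n_iter,
        message="",
    )


def select_effort_form(det: pd.DataFrame, family: str = "binomial"):
    """Choose between list length and log list length on a per-species basis.

    Both candidate models are fitted; the form with the better (maximum)
    approximate log-likelihood wins, ties going to untransformed list length.
    If one candidate fails to converge the survivor is used with a warning.
    """
    fits = {}
    for form in ("L", "logL"):
        try:
            fits[form] = fit_glmm(det, GlmmSpec(family=family, effort=form))
        except (ConvergenceError, ValueError) as e:
            warnings.warn(f"effort form {form} failed: {e}")
    if not fits:
        raise ConvergenceError("both effort-form candidates failed")
    if len(fits) == 1:
        form = next(iter(fits))
        return form, fits[form]
    if fits["logL"].loglik > fits["L"].loglik:
        return "logL", fits["logL"]
    return "L", fits["L"]  # ties break toward untransformed list length


# ---------------------------------------------------------------------------
# standardized prediction


def make_prediction_grid(det: pd.DataFrame, towns=None, years=None) -> pd.DataFrame:
    """Standardized (town, year) grid for a species' detection table.

    Covariates describe one idealized survey: the day of year and start time
    with the highest detection frequency for the species, the species' mean
    list length, and the traveling protocol.  Covariates are identical
    across towns; centering uses the table's stored means.
    """
    towns = sorted(det["town"].unique()) if towns is None else list(towns)
    years = sorted(det["year"].unique()) if years is None else list(years)
    hits = det[det["response"] > 0]
    if len(hits):
        doy_mode = float(hits["doy"].round().mode().iloc[0])
        start_mode = float((hits["start_time"] * 24).round().mode().iloc[0]) / 24.0
    else:
        doy_mode, start_mode = float(det["doy"].mean()), float(det["start_time"].mean())
    grid = pd.DataFrame(
        [(g, yr) for g in towns for yr in years], columns=["town", "year"]
    )
    grid["doy"] = doy_mode
    grid["doy_c"] = doy_mode - det.attrs.get("doy_mean", 0.0)
    grid["start_time"] = start_mode
    grid["start_c"] = start_mode - det.attrs.get("start_mean", 0.0)
    grid["list_length"] = float(det["list_length"].mean()) if det["list_length"].any() else 1.0
    grid["protocol"] = "traveling" if (det["protocol"] == "traveling").any() else det["protocol"].iloc[0]
    return grid


def predict_standardized(fit: GlmmFit, grid: pd.DataFrame) -> pd.DataFrame:
    """Town x year estimates on the response scale, observer effect zeroed.

    estimate = linkinv(x'beta + sigma_town * u_town); raises if the grid
    names a town absent from the training data.
    """
    fam = _family(fit.spec.family)
    (Xg,) = build_design_matrices([fit.design_info], grid)
    eta = np.asarray(Xg) @ fit.beta.to_numpy()
    if "town" in fit.u:
        u_town = fit.u["town"]
        missing = set(grid["town"]) - set(u_town.index)
        if missing:
            raise KeyError(f"grid towns absent from training data: {sorted(missing)}")
        eta = eta + fit.sigma["town"] * u_town.reindex(grid["town"]).to_numpy()
    out = grid[["town", "year"]].copy()
    out["estimate"] = fam.linkinv(eta)
    return out


# ---------------------------------------------------------------------------
# parametric bootstrap


def _simulate_response(fit: GlmmFit, det: pd.DataFrame, rng) -> np.ndarray:
    fam = _family(fit.spec.family)
    (Xd,) = build_design_matrices([fit.design_info], det)
    eta = np.asarray(Xd) @ fit.beta.to_numpy()
    for f in fit.spec.re_factors:
        s = fit.sigma[f]
        if s > 0:
            lev = fit.u[f].index
            draw = pd.Series(rng.normal(0.0, 1.0, size=len(lev)), index=lev)
            eta = eta + s * draw.reindex(det[f]).to_numpy()
    mu = fam.linkinv(eta)
    if fit.spec.family == "binomial":
        return (rng.random(len(mu)) < mu).astype(float)
    # quasi-Poisson has no generative model; simulate Poisson at mu-hat
    return rng.poisson(mu).astype(float)


def bootstrap_se(
    fit: GlmmFit,
    det: pd.DataFrame,
    grid: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
    refit_theta: bool = True,
) -> pd.DataFrame:
    """Parametric-bootstrap SE for each grid cell.

    Simulates B response vectors from the fitted model (redrawing the random
    intercepts), refits, and re-predicts on the grid; the SE is the sample
    sd of the B predictions per cell.  ``refit_theta=False`` holds the
    variance parameters at their fitted values during refits (PIRLS only),
    which is much faster for batch runs.  Replicates whose refit fails are
    dropped; at least 0.8*B successes are required.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    fam = _family(fit.spec.family)
    (Xd,) = build_design_matrices([fit.design_info], det)
    X = np.asarray(Xd)
    Zs, levels = _re_indicators(det, fit.spec.re_factors)
    sig_hat = np.array([fit.sigma[f] for f in fit.spec.re_factors])

    preds, failures = [], 0
    for b in range(B):
        yb = _simulate_response(fit, det, rng)
        db = det.copy()
        db[fit.spec.response] = yb
        try:
            if refit_theta and len(sig_hat):
                def obj(logsd, yb=yb):
                    s = np.exp(np.clip(logsd, -12.0, 3.0))
                    try:
                        return _pirls(X, Zs, yb, fam, s)[3]
                    except ConvergenceError:
                        return 1e12
                x0 = np.log(np.clip(sig_hat, 1e-3, None))
                res = minimize(obj, x0=x0, method="Nelder-Mead",
                               options={"xatol": 1e-3, "fatol": 1e-5})
                sig_b = np.exp(np.clip(res.x, -12.0, 3.0))
                sig_b[sig_b < _SIGMA_FLOOR] = 0.0
            else:
                sig_b = sig_hat
            beta_b, us_b, *_ = _pirls(X, Zs, yb, fam, sig_b)
        except ConvergenceError:
            failures += 1
            continue
        fit_b = GlmmFit(
            spec=fit.spec, design_info=fit.design_info,
            beta=pd.Series(beta_b, index=fit.beta.index),
            vcov_beta=fit.vcov_beta, phi=fit.phi,
            sigma={f: float(s) for f, s in zip(fit.spec.re_factors, sig_b)},
            u={f: pd.Series(us_b[i], index=levels[i]) for i, f in enumerate(fit.spec.re_factors)},
            centering=fit.centering, deviance=np.nan, loglik=np.nan,
            converged=True, n_iter=0,
        )
        preds.append(predict_standardized(fit_b, grid)["estimate"].to_numpy())
    if len(preds) < 0.8 * B:
        raise ConvergenceError(
            f"only {len(preds)}/{B} bootstrap refits succeeded (need >= {0.8 * B:.0f})"
        )
    P = np.vstack(preds)
    out = grid[["town", "year"]].copy()
    out["se"] = P.std(axis=0, ddof=1)
    out.attrs["n_success"] = len(preds)
    out.attrs["n_failures"] = failures
    return out
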