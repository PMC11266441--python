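"""Single-environment trial models.

Each trial is analysed with the linear mixed model

    y = mu + Hybrid (fixed) + Replicate (fixed)
        + block-within-replicate + row + column (random) + residual,

variance components estimated by average-information REML (EM warm start),
with effect estimates solved from Henderson's mixed-model equations.
The per-hybrid fixed-effect estimates (BLUEs, on the Mg/ha data scale, averaged
over replicate effects) form the phenotypic table consumed by all downstream
prediction models.  A companion refit with the hybrid term random yields the
genetic variance and the mean pairwise prediction error variance used by the
generalized (Cullis) heritability

    H^2 = 1 - Vbar(Delta) / (2 * sigma^2_g),

and the trial coefficient of variation is CV% = 100 * sqrt(sigma^2_e) / mean
of the model's fitted values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import EstimabilityError, UndefinedMetricError

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-10
RANDOM_TERMS = ("block", "row", "col")


@dataclass
class SingleTrialFit:
    env: str
    blues: pd.Series  # hybrid -> BLUE (Mg/ha)
    mu: float
    var_block: float
    var_row: float
    var_col: float
    var_resid: float
    var_genetic: float  # sigma^2_g from the random-hybrid refit
    pev: float  # mean pairwise prediction error variance Vbar(Delta)
    converged: bool
    n_iter: int
    mean_fitted: float
    degenerate: bool = False
    dropped_hybrids: list = field(default_factory=list)

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "block": self.var_block,
            "row": self.var_row,
            "col": self.var_col,
            "resid": self.var_resid,
        }


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels))
    idx = pd.Categorical(labels, categories=levels).codes
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), idx] = 1.0
    return Z, levels


def _random_design(plots: pd.DataFrame, terms) -> dict[str, np.ndarray]:
    keys = {
        "block": plots["Replicate"].astype(str) + ":" + plots["Block"].astype(str),
        "row": plots["Row"].astype(str),
        "col": plots["Col"].astype(str),
    }
    Zs = {}
    for t in terms:
        Z, levels = _dummies(keys[t])
        if len(levels) > 1:  # a single level is confounded with the intercept
            Zs[t] = Z
    return Zs


def _fixed_design(plots: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str], list]:
    hybrids = sorted(pd.unique(plots["Hybrid"]))
    reps = sorted(pd.unique(plots["Replicate"]))
    n = len(plots)
    cols = ["(Intercept)"]
    X = [np.ones(n)]
    h_codes = pd.Categorical(plots["Hybrid"], categories=hybrids).codes
    for j, h in enumerate(hybrids[1:], start=1):
        X.append((h_codes == j).astype(float))
        cols.append(f"Hybrid[{h}]")
    r_codes = pd.Categorical(plots["Replicate"], categories=reps).codes
    for j, r in enumerate(reps[1:], start=1):
        X.append((r_codes == j).astype(float))
        cols.append(f"Replicate[{r}]")
    return np.column_stack(X), cols, hybrids, reps


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 1.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        raise EstimabilityError([names[j] for j in piv[rank:]])


def _mme_solve(y, X, Zs, sigma):
    """Solve Henderson's mixed-model equations at the given variances.

    Returns (beta, u dict, Cinv, slices, W) where Cinv is the inverse of the
    lambda-scaled coefficient matrix (so sigma_e * Cinv is the sampling
    covariance of the estimated effects).
    """
    n, p = X.shape
    terms = list(Zs)
    W = np.hstack([X] + [Zs[t] for t in terms]) if terms else X
    C = W.T @ W
    rhs = W.T @ y
    slices, start = {}, p
    for t in terms:
        q = Zs[t].shape[1]
        slices[t] = slice(start, start + q)
        start += q
        lam = sigma["resid"] / max(sigma[t], VARIANCE_FLOOR)
        sl = slices[t]
        C[sl, sl] += np.eye(q) * lam
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    beta = sol[:p]
    u = {t: sol[slices[t]] for t in terms}
    return beta, u, Cinv, slices, W


def _reml(y, X, Zs, fixed=None, tol=1e-6, max_iter=200, n_em_warmup=3):
    """REML via average-information updates with an EM warm start.

    Works on the observation-level covariance V = sigma_e I + sum_i sigma_i
    Z_i Z_i'.  The first ``n_em_warmup`` iterations take EM steps (slow but
    monotone), after which Newton-like AI steps drive the fit to the 1e-6
    relative-change criterion, typically in well under 20 iterations.
    Variances proposed below the floor are truncated there (boundary
    handling); components listed in ``fixed`` are held constant.

    Returns (sigma dict incl. "resid", beta, u, Cinv, slices, W, converged,
    n_iter) with the mixed-model-equation solve done once at convergence.
    """
    fixed = dict(fixed or {})
    n, p = X.shape
    terms = list(Zs)
    Gs = {t: Zs[t] @ Zs[t].T for t in terms}
    qs = {t: Zs[t].shape[1] for t in terms}
    eye = np.eye(n)

    var_y = float(np.var(y)) or 1.0
    init = var_y / (len(terms) + 1)
    sigma = {t: float(fixed.get(t, init)) for t in terms}
    sigma["resid"] = float(fixed.get("resid", init))
    free = [t for t in terms if t not in fixed]
    if "resid" not in fixed:
        free = free + ["resid"]

    def pieces(sig):
        V = sig["resid"] * eye
        for t in terms:
            V += sig[t] * Gs[t]
        if not np.all(np.isfinite(V)):
            return None, None, None, None, -np.inf
        try:
            Vinv = np.linalg.inv(V)
            _, logdet_v = np.linalg.slogdet(V)
            VinvX = Vinv @ X
            XtViX_inv = np.linalg.inv(X.T @ VinvX)
            _, logdet_x = np.linalg.slogdet(X.T @ VinvX)
        except np.linalg.LinAlgError:
            return None, None, None, None, -np.inf
        Viy = Vinv @ y
        Py = Viy - VinvX @ (XtViX_inv @ (X.T @ Viy))
        ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
        if not np.isfinite(ll):
            ll = -np.inf
        return Vinv, VinvX, XtViX_inv, Py, ll

    def term_score(t, pieces_now):
        Vinv, VinvX, XtViX_inv, Py, _ = pieces_now
        if t == "resid":
            Gv = Py
            trPG = float(np.trace(Vinv)) - float(
                np.trace(XtViX_inv @ (VinvX.T @ VinvX))
            )
        else:
            G = Gs[t]
            Gv = G @ Py
            trPG = float(np.trace(Vinv @ G)) - float(
                np.trace(XtViX_inv @ (VinvX.T @ (G @ VinvX)))
            )
        return -0.5 * (trPG - float(Py @ Gv)), Gv

    converged = False
    n_iter = 0
    pinned: list[str] = []
    released: set[str] = set()
    cur = pieces(sigma) if free else None
    for n_iter in range(1, max_iter + 1):
        if not free:
            converged = True
            break
        Vinv, VinvX, XtViX_inv, Py, ll = cur

        def P(v):
            w = Vinv @ v
            return w - VinvX @ (XtViX_inv @ (X.T @ w))

        score, Gy = [], []
        for t in free:
            s, Gv = term_score(t, cur)
            Gy.append(Gv)
            score.append(s)
        score = np.asarray(score)

        old = np.array([sigma[t] for t in free])
        # EM direction: sigma_i^2 * (y'P G_i P y - tr(P G_i)) / q_i
        qvec = np.array([qs.get(t, n - p) for t in free], dtype=float)
        em_delta = (old**2) * (2.0 * score) / qvec
        if n_iter <= n_em_warmup:
            delta = em_delta
        else:
            PGy = [P(g) for g in Gy]
            AI = 0.5 * np.array([[float(Gy[i] @ PGy[j]) for j in range(len(free))]
                                 for i in range(len(free))])
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                delta = em_delta
        # step-halve against the REML log-likelihood (monotone iterations)
        step, accepted = 1.0, None
        for _ in range(8):
            new = np.maximum(old + step * delta, VARIANCE_FLOOR)
            trial = dict(sigma)
            trial.update({t: float(v) for t, v in zip(free, new)})
            cand = pieces(trial)
            if cand[-1] >= ll - 1e-10:
                accepted = (trial, cand)
                break
            step *= 0.5
        if accepted is None and delta is not em_delta:
            # AI direction failed: retry along the (ascent) EM direction
            for _ in range(8):
                new = np.maximum(old + step * em_delta, VARIANCE_FLOOR)
                trial = dict(sigma)
                trial.update({t: float(v) for t, v in zip(free, new)})
                cand = pieces(trial)
                if cand[-1] >= ll - 1e-10:
                    accepted = (trial, cand)
                    break
                step *= 0.5
        if accepted is None:  # no ascent in either direction: local optimum
            converged = True
            break
        sigma, cur = accepted
        new = np.array([sigma[t] for t in free])

        # active set: a component collapsing toward zero is pinned at the
        # boundary, otherwise AI/EM steps shrink it geometrically forever
        pin = [t for t, v in zip(free, new) if v < 1e-8 * var_y]
        if pin:
            for t in pin:
                sigma[t] = VARIANCE_FLOOR
            pinned.extend(pin)
            free = [t for t in free if t not in pin]
            cur = pieces(sigma)
            if free:
                continue
        rel = (
            np.max(np.abs(new - old) / (np.abs(old) + 1e-12)) if free else 0.0
        )
        if rel < tol or not free:
            # release pinned components whose likelihood gradient is positive
            # (a joint clipped step can pin a component prematurely)
            back = [
                t
                for t in pinned
                if t not in released and term_score(t, cur)[0] > 0
            ]
            if back:
                released.update(back)
                for t in back:
                    sigma[t] = 1e-4 * var_y
                pinned = [t for t in pinned if t not in back]
                free = free + back
                cur = pieces(sigma)
                continue
            converged = True
            break

    beta, u, Cinv, slices, W = _mme_solve(y, X, Zs, sigma)
    return sigma, beta, u, Cinv, slices, W, converged, n_iter


def fit_single_trial(
    plots: pd.DataFrame,
    env: str | None = None,
    random_terms=RANDOM_TERMS,
    fixed_variances: dict | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    refit_random_hybrid: bool = True,
) -> SingleTrialFit:
    """Fit the single-trial mixed model for one environment's plots.

    ``fixed_variances`` pins chosen variance components; a component fixed at
    exactly 0 removes its random term from the model (the zero-variance limit
    then reproduces ordinary least squares).  Hybrids with no non-missing plot
    are dropped with a warning.  Non-convergence is flagged on the result, not
    raised.
    """
    if env is None:
        env = str(plots["Env"].iloc[0]) if "Env" in plots else "?"
    fixed_variances = dict(fixed_variances or {})

    # canonical plot order makes the fit exactly invariant to input order
    data = (
        plots.dropna(subset=["Yield_Mg_ha"])
        .sort_values(["Replicate", "Row", "Col", "Hybrid"], kind="stable")
        .reset_index(drop=True)
    )
    all_hybrids = sorted(pd.unique(plots["Hybrid"]))
    kept_hybrids = sorted(pd.unique(data["Hybrid"]))
    dropped = sorted(set(all_hybrids) - set(kept_hybrids))
    if dropped:
        logger.warning("%s: dropping hybrids with no observed plots: %s", env, dropped)
    if len(kept_hybrids) < 2:
        raise ValueError(f"{env}: need >= 2 hybrids with data")

    y = data["Yield_Mg_ha"].to_numpy(dtype=float)
    X, xnames, hybrids, reps = _fixed_design(data)
    _check_rank(X, xnames)

    terms = [
        t
        for t in random_terms
        if fixed_variances.get(t, None) != 0
    ]
    Zs = _random_design(data, terms)
    fixed = {t: v for t, v in fixed_variances.items() if v != 0 and (t in Zs or t == "resid")}

    n, p = X.shape
    if n == p:  # saturated: every plot its own fixed cell, no residual df
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        blues = _blues_from_beta(beta, xnames, hybrids, reps)
        return SingleTrialFit(
            env=env,
            blues=blues,
            mu=float(beta[0]),
            var_block=0.0,
            var_row=0.0,
            var_col=0.0,
            var_resid=0.0,
            var_genetic=float("nan"),
            pev=float("nan"),
            converged=True,
            n_iter=0,
            mean_fitted=float(np.mean(X @ beta)),
            degenerate=True,
            dropped_hybrids=dropped,
        )

    sigma, beta, u, Cinv, slices, W, converged, n_iter = _reml(
        y, X, Zs, fixed=fixed, tol=tol, max_iter=max_iter
    )
    if not converged:
        logger.warning("%s: REML did not converge in %d iterations", env, max_iter)

    blues = _blues_from_beta(beta, xnames, hybrids, reps)
    fitted = W @ np.concatenate([beta] + [u[t] for t in u])

    var_g, pev = float("nan"), float("nan")
    if refit_random_hybrid:
        var_g, pev, refit_conv = _random_hybrid_refit(
            data, terms, fixed, tol, max_iter
        )
        converged = converged and refit_conv

    return SingleTrialFit(
        env=env,
        blues=blues,
        mu=float(beta[0]),
        var_block=float(sigma.get("block", 0.0)),
        var_row=float(sigma.get("row", 0.0)),
        var_col=float(sigma.get("col", 0.0)),
        var_resid=float(sigma["resid"]),
        var_genetic=var_g,
        pev=pev,
        converged=converged,
        n_iter=n_iter,
        mean_fitted=float(np.mean(fitted)),
        dropped_hybrids=dropped,
    )


def _blues_from_beta(beta, xnames, hybrids, reps) -> pd.Series:
    coef = dict(zip(xnames, beta))
    rep_effects = [0.0] + [coef[f"Replicate[{r}]"] for r in reps[1:]]
    rep_mean = float(np.mean(rep_effects))
    vals = {}
    for h in hybrids:
        vals[h] = coef["(Intercept)"] + coef.get(f"Hybrid[{h}]", 0.0) + rep_mean
    return pd.Series(vals, name="BLUE").sort_index()


def _random_hybrid_refit(data, terms, fixed, tol, max_iter):
    """Hybrid treated random: returns (sigma_g, Vbar(Delta), converged)."""
    n = len(data)
    reps = sorted(pd.unique(data["Replicate"]))
    cols = [np.ones(n)]
    r_codes = pd.Categorical(data["Replicate"], categories=reps).codes
    for j in range(1, len(reps)):
        cols.append((r_codes == j).astype(float))
    X = np.column_stack(cols)
    Zh, hyb_levels = _dummies(data["Hybrid"])
    if Zh.shape[1] >= n:  # one plot per hybrid: sigma_g and sigma_e confounded
        return float("nan"), float("nan"), True
    Zs = {"hybrid": Zh}
    Zs.update(_random_design(data, terms))
    y = data["Yield_Mg_ha"].to_numpy(dtype=float)
    sigma, beta, u, Cinv, slices, W, converged, _ = _reml(
        y, X, Zs, fixed=fixed, tol=tol, max_iter=max_iter
    )
    sl = slices["hybrid"]
    pev_mat = sigma["resid"] * Cinv[sl, sl]
    q = sl.stop - sl.start
    if q < 2:
        return float(sigma["hybrid"]), float("nan"), converged
    tr = float(np.trace(pev_mat))
    total = float(pev_mat.sum())
    vbar = 2.0 * (q * tr - total) / (q * (q - 1))
    return float(sigma["hybrid"]), float(vbar), converged


def coefficient_of_variation(fit: SingleTrialFit) -> float:
    """Trial CV% = 100 * sqrt(residual variance) / mean fitted value."""
    if not fit.converged:
        raise UndefinedMetricError(f"{fit.env}: fit did not converge")
    if abs(fit.mean_fitted) < 1e-12:
        raise UndefinedMetricError(f"{fit.env}: mean predicted value is zero")
    return 100.0 * float(np.sqrt(fit.var_resid)) / fit.mean_fitted


def cullis_heritability(fit: SingleTrialFit) -> float:
    """Generalized heritability 1 - Vbar(Delta) / (2 sigma^2_g), clamped to [0, 1].

    Returns 0 (degenerate) when the genetic variance is zero.
    """
    if not np.isfinite(fit.var_genetic) or fit.var_genetic <= VARIANCE_FLOOR:
        logger.warning("%s: zero genetic variance, H2 degenerate at 0", fit.env)
        return 0.0
    h2 = 1.0 - fit.pev / (2.0 * fit.var_genetic)
    if h2 < 0 or h2 > 1:
        warnings.warn(f"{fit.env}: H2_Cullis={h2:.3f} outside [0,1], clamped")
    return float(np.clip(h2, 0.0, 1.0))


def fit_all_trials(
    plot_table: pd.DataFrame, **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame, list[SingleTrialFit]]:
    """Fit every environment; return (BLUE table, diagnostics table, fits).

    The BLUE table has columns Env, Hybrid, y — the phenotypic matrix used as
    the response by all prediction models.
    """
    blues_rows, diag_rows, fits = [], [], []
    for env, plots in plot_table.groupby("Env", sort=True):
        fit = fit_single_trial(plots, env=env, **kwargs)
        fits.append(fit)
        blues_rows.append(
            pd.DataFrame(
                {"Env": env, "Hybrid": fit.blues.index, "y": fit.blues.to_numpy()}
            )
        )
        try:
            cv = coefficient_of_variation(fit)
        except UndefinedMetricError:
            cv = float("nan")
        diag_rows.append(
            {
                "Env": env,
                "n_hybrids": len(fit.blues),
                "CV_pct": cv,
                "H2_cullis": cullis_heritability(fit),
                "var_block": fit.var_block,
                "var_row": fit.var_row,
                "var_col": fit.var_col,
                "var_resid": fit.var_resid,
                "var_genetic": fit.var_genetic,
                "pev": fit.pev,
                "converged": fit.converged,
                "n_iter": fit.n_iter,
            }
        )
    blues = pd.concat(blues_rows, ignore_index=True)
    return blues, pd.DataFrame(diag_rows), fits


def plot_mean_blues(plot_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(Env, Hybrid) plot means as a cheap stand-in BLUE table.

    Useful when only the record keys matter (e.g. building cross-validation
    plans) or as a starting point; for balanced designs the plot mean is close
    to the mixed-model BLUE.
    """
    out = (
        plot_table.dropna(subset=["Yield_Mg_ha"])
        .groupby(["Env", "Hybrid"], as_index=False)["Yield_Mg_ha"]
        .mean()
        .rename(columns={"Yield_Mg_ha": "y"})
    )
    return out
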