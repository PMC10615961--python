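"""Performance and learning-rate models.

Two model families:

* **GLMM-LASSO** — a Gaussian linear mixed model with a per-participant
  random intercept and an L1 penalty on the fixed slopes, estimated by
  maximizing the penalized marginal log-likelihood.  Fixed effects are
  updated by coordinate-wise soft-thresholding on the GLS-whitened design,
  variance components by EM, iterated to convergence.  The penalty is
  chosen on a grid by minimum BIC with ``df = |support| + 2`` (intercept
  and random-intercept variance).  Selected supports are re-fit
  unpenalized with ``statsmodels`` MixedLM for Wald standard errors and
  p-values (naive post-selection inference, no selective correction).

* **Forward selection + LOOCV** — for learning-rate models: starting from
  the empty model, greedily add the candidate that most reduces
  leave-one-out RMSE, stop when no candidate improves it; final OLS fit
  reports estimates, 95% CIs, p-values and LOOCV MAE/RMSE.

Plus the learning-rate slope (OLS of score on attempt index), column
standardization, Local Outlier Factor exclusion (10 neighbors), and
R2/MAE/RMSE metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.neighbors import LocalOutlierFactor

from .names import ALL_FEATURES


# ---------------------------------------------------------------------------
# elementary pieces


def learning_rate(scores: np.ndarray, attempts: np.ndarray | None = None) -> float:
    """OLS slope of performance score on 1-based attempt index."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("learning rate needs at least 2 attempts")
    x = np.arange(1, scores.size + 1, dtype=float) if attempts is None else np.asarray(attempts, float)
    if x.size != scores.size:
        raise ValueError("attempts and scores differ in length")
    return float(np.polyfit(x, scores, 1)[0])


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score feature columns (ddof=1); drop zero-variance columns.

    Returns the standardized table and a ``{column: (mean, sd)}`` record
    for back-transformation.
    """
    if columns is None:
        columns = [c for c in ALL_FEATURES if c in table.columns]
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = {}
    dropped = []
    for c in columns:
        col = out[c].to_numpy(dtype=float)
        mu, sd = float(col.mean()), float(col.std(ddof=1)) if col.size > 1 else 0.0
        if not np.isfinite(sd) or sd <= 0:
            dropped.append(c)
            out = out.drop(columns=[c])
            continue
        out[c] = (col - mu) / sd
        scaling[c] = (mu, sd)
    if dropped:
        warnings.warn(f"dropped zero-variance columns: {dropped}", stacklevel=2)
    return out, scaling


def model_metrics(y: np.ndarray, y_hat: np.ndarray) -> dict[str, float]:
    """R2, MAE and RMSE of predictions against observations."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.size != y_hat.size:
        raise ValueError("y and y_hat must be non-empty and equal length")
    resid = y - y_hat
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    if sst == 0:
        warnings.warn("zero-variance response: R^2 undefined", stacklevel=2)
    return {
        "r_squared": r2,
        "mae": float(np.mean(np.abs(resid))),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }


def lof_outliers(
    X: np.ndarray, k: int = 10, threshold: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Local Outlier Factor scores and the exclusion mask.

    Standard LOF with ``k`` neighbors (k-distance reachability); rows whose
    score exceeds ``threshold`` are flagged for exclusion.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] <= k:
        raise ValueError(f"LOF with k={k} needs more than {k} rows, got {X.shape[0]}")
    lof = LocalOutlierFactor(n_neighbors=k)
    lof.fit(X)
    scores = -lof.negative_outlier_factor_
    return scores, scores > threshold


# ---------------------------------------------------------------------------
# GLMM-LASSO


@dataclass
class GlmmLassoFit:
    """A penalized mixed-model fit at one penalty value."""

    lam: float
    intercept: float
    fixed_coefficients: dict[str, float]
    random_intercept_sd: float
    residual_sd: float
    loglik: float
    bic: float
    converged: bool
    n_iter: int
    n_obs: int
    features: list[str]
    post_refit: pd.DataFrame | None = None
    path: list[tuple[float, float, int]] | None = None  # (lambda, bic, |support|)

    @property
    def selected_support(self) -> list[str]:
        return [f for f, b in self.fixed_coefficients.items() if b != 0.0]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Population-level prediction (random intercepts set to zero)."""
        yhat = np.full(len(table), self.intercept)
        for f, b in self.fixed_coefficients.items():
            if b != 0.0:
                yhat += b * table[f].to_numpy(dtype=float)
        return yhat


def _marginal_loglik(
    resid_by_group: list[np.ndarray], sigma2: float, tau2: float
) -> float:
    """Marginal Gaussian log-likelihood of a random-intercept model."""
    ll = 0.0
    for r in resid_by_group:
        n = r.size
        s = r.sum()
        denom = sigma2 + n * tau2
        quad = (r @ r - (tau2 / denom) * s * s) / sigma2
        logdet = n * np.log(sigma2) + np.log(denom / sigma2)
        ll += -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return float(ll)


def _profile_variance_ml(
    resid: np.ndarray, group_rows: list[np.ndarray], n_g: np.ndarray
) -> tuple[float, float]:
    """ML variance components of a random-intercept model, given residuals.

    Profiles the residual variance out in closed form and maximizes the
    marginal likelihood over the ratio rho = tau^2/sigma^2 in 1-D, which
    handles the rho -> 0 boundary exactly (unlike EM, which stalls there).
    """
    from scipy.optimize import minimize_scalar

    N = resid.size
    ss_g = np.array([float(resid[rows] @ resid[rows]) for rows in group_rows])
    s_g = np.array([float(resid[rows].sum()) for rows in group_rows])

    def neg_ll(log_rho: float) -> float:
        rho = np.exp(log_rho)
        quad = ss_g - (rho / (1.0 + n_g * rho)) * s_g**2
        sig2 = max(quad.sum() / N, 1e-300)
        return 0.5 * (N * np.log(sig2) + np.log1p(n_g * rho).sum())

    nll0 = 0.5 * N * np.log(max(ss_g.sum() / N, 1e-300))  # rho = 0
    res = minimize_scalar(neg_ll, bounds=(-30.0, 8.0), method="bounded",
                          options={"xatol": 1e-10})
    if res.fun < nll0 - 1e-12:
        rho = float(np.exp(res.x))
    else:
        rho = 0.0
    quad = ss_g - (rho / (1.0 + n_g * rho)) * s_g**2
    sigma2 = max(float(quad.sum() / N), 1e-12)
    return sigma2, max(rho * sigma2, 1e-12)


def glmm_lasso_fit(
    table: pd.DataFrame,
    response: str = "score",
    groups: str = "participant_id",
    lam: float = 1.0,
    features: list[str] | None = None,
    *,
    fit_random_intercept: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
    warm_start: np.ndarray | None = None,
) -> GlmmLassoFit:
    """Fit the L1-penalized Gaussian mixed model at one penalty value.

    Minimizes ``-loglik_marginal + lam * sum_j |beta_j|`` over fixed slopes
    (intercept unpenalized) and the two variance components, alternating
    coordinate-descent soft-thresholding on the whitened design with EM
    variance updates until the relative change of the penalized objective
    falls below ``tol``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if features is None:
        features = [c for c in ALL_FEATURES if c in table.columns]
    y = table[response].to_numpy(dtype=float)
    X = table[features].to_numpy(dtype=float)
    g_labels, g_idx = np.unique(table[groups].to_numpy(), return_inverse=True)
    n_groups = g_labels.size
    if n_groups < 2 and fit_random_intercept:
        raise ValueError("need at least 2 groups for a random intercept")
    N, p = X.shape
    group_rows = [np.flatnonzero(g_idx == g) for g in range(n_groups)]
    n_g = np.array([r.size for r in group_rows])

    beta = np.zeros(p) if warm_start is None else warm_start.copy()
    beta0 = float(y.mean())
    var_y = float(y.var()) or 1.0
    sigma2 = 0.5 * var_y
    tau2 = 0.25 * var_y if fit_random_intercept else 0.0

    def objective(b0: float, b: np.ndarray, s2: float, t2: float) -> float:
        r = y - b0 - X @ b
        ll = _marginal_loglik([r[rows] for rows in group_rows], s2, t2)
        return -ll + lam * np.abs(b).sum()

    obj = objective(beta0, beta, sigma2, tau2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # --- whiten: V^{-1/2} = (1/sigma)(I - a_g J_g) per group
        rho = tau2 / sigma2
        a_g = (1.0 - 1.0 / np.sqrt(1.0 + n_g * rho)) / n_g
        Xw = np.empty_like(X)
        yw = np.empty_like(y)
        ones_w = np.empty_like(y)
        for g, rows in enumerate(group_rows):
            a = a_g[g]
            Xg = X[rows]
            Xw[rows] = Xg - a * Xg.sum(axis=0, keepdims=True)
            yw[rows] = y[rows] - a * y[rows].sum()
            ones_w[rows] = 1.0 - a * n_g[g]
        Xw /= np.sqrt(sigma2)
        yw /= np.sqrt(sigma2)
        ones_w /= np.sqrt(sigma2)

        # --- coordinate descent on 0.5||yw - b0*1w - Xw b||^2 + lam |b|
        col_ss = (Xw**2).sum(axis=0)
        ones_ss = float(ones_w @ ones_w)
        r = yw - beta0 * ones_w - Xw @ beta
        for _ in range(100):
            max_delta = 0.0
            b0_new = beta0 + (ones_w @ r) / ones_ss
            r -= (b0_new - beta0) * ones_w
            max_delta = max(max_delta, abs(b0_new - beta0))
            beta0 = b0_new
            for j in range(p):
                if col_ss[j] <= 0:
                    continue
                rho_j = Xw[:, j] @ r + col_ss[j] * beta[j]
                bj = np.sign(rho_j) * max(abs(rho_j) - lam, 0.0) / col_ss[j]
                if bj != beta[j]:
                    r += Xw[:, j] * (beta[j] - bj)
                    max_delta = max(max_delta, abs(bj - beta[j]))
                    beta[j] = bj
            if max_delta < 1e-10:
                break

        # --- exact ML update of variance components given beta
        resid = y - beta0 - X @ beta
        if fit_random_intercept:
            sigma2, tau2 = _profile_variance_ml(resid, group_rows, n_g)
        else:
            sigma2 = max(float((resid**2).mean()), 1e-12)

        new_obj = objective(beta0, beta, sigma2, tau2)
        if abs(new_obj - obj) <= tol * max(1.0, abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj

    resid = y - beta0 - X @ beta
    ll = _marginal_loglik([resid[rows] for rows in group_rows], sigma2, tau2)
    support = int(np.count_nonzero(beta))
    bic = -2.0 * ll + (support + 2) * np.log(N)
    if not converged:
        warnings.warn(
            f"GLMM-LASSO did not converge in {max_iter} iterations (lambda={lam:g})",
            stacklevel=2,
        )
    return GlmmLassoFit(
        lam=float(lam),
        intercept=float(beta0),
        fixed_coefficients={f: float(b) for f, b in zip(features, beta)},
        random_intercept_sd=float(np.sqrt(tau2)),
        residual_sd=float(np.sqrt(sigma2)),
        loglik=ll,
        bic=float(bic),
        converged=converged,
        n_iter=it,
        n_obs=N,
        features=list(features),
    )


def default_lambda_grid(
    table: pd.DataFrame,
    response: str = "score",
    features: list[str] | None = None,
    n_lambdas: int = 20,
    ratio: float = 1e-3,
) -> np.ndarray:
    """Geometric penalty grid from the full-shrinkage point downward."""
    if features is None:
        features = [c for c in ALL_FEATURES if c in table.columns]
    y = table[response].to_numpy(dtype=float)
    X = table[features].to_numpy(dtype=float)
    lam_max = float(np.abs(X.T @ (y - y.mean())).max())
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def lambda_grid_search(
    table: pd.DataFrame,
    response: str = "score",
    groups: str = "participant_id",
    grid: np.ndarray | None = None,
    features: list[str] | None = None,
    *,
    refit: bool = True,
    **fit_kwargs,
) -> GlmmLassoFit:
    """Fit every penalty on the grid and return the minimum-BIC fit.

    Ties break toward the larger (sparser) penalty.  The grid is traversed
    from largest to smallest lambda with warm starts.  With ``refit`` the
    winning support is re-estimated unpenalized for SEs and p-values.
    """
    if grid is None:
        grid = default_lambda_grid(table, response, features)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    best: GlmmLassoFit | None = None
    path: list[tuple[float, float, int]] = []
    warm = None
    failures = []
    for lam in grid:
        try:
            fit = glmm_lasso_fit(
                table, response, groups, lam, features, warm_start=warm, **fit_kwargs
            )
        except Exception as exc:  # keep scanning; report if all fail
            failures.append((lam, exc))
            continue
        warm = np.array([fit.fixed_coefficients[f] for f in fit.features])
        path.append((float(lam), fit.bic, len(fit.selected_support)))
        if best is None or fit.bic < best.bic:  # strict: ties keep larger lambda
            best = fit
    if best is None:
        raise RuntimeError(f"all {len(failures)} penalized fits failed; first: {failures[0][1]}")
    best.path = path
    if refit and best.selected_support:
        # the L1 fit tolerates exactly collinear predictors (e.g. a rate
        # and its complement); the unpenalized refit cannot, so keep a
        # maximal linearly independent subset for inference
        keep: list[str] = []
        ones = np.ones((len(table), 1))
        for f in best.selected_support:
            M = np.column_stack([ones] + [table[c].to_numpy(dtype=float) for c in keep + [f]])
            if np.linalg.matrix_rank(M) == M.shape[1]:
                keep.append(f)
        if len(keep) < len(best.selected_support):
            dropped = sorted(set(best.selected_support) - set(keep))
            warnings.warn(f"refit drops collinear predictors: {dropped}", stacklevel=2)
        try:
            best.post_refit = post_selection_refit(table, keep, groups, response)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"post-selection refit failed ({exc}); penalized estimates "
                "are reported without SEs",
                stacklevel=2,
            )
            best.post_refit = None
    return best


def post_selection_refit(
    table: pd.DataFrame,
    support: list[str],
    groups: str = "participant_id",
    response: str = "score",
) -> pd.DataFrame:
    """Unpenalized random-intercept refit of a selected support.

    Returns one row per predictor (plus intercept) with Wald estimate,
    standard error and p-value.  No selective-inference correction is
    applied; see the methods note for this limitation.
    """
    if not support:
        raise ValueError("empty support: nothing to refit")
    X = sm.add_constant(table[list(support)].to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"singular refit design; collinear features among {support}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            table[response].to_numpy(dtype=float),
            X,
            groups=table[groups].to_numpy(),
        )
        res = model.fit(reml=True)
    names = ["intercept", *support]
    k = len(names)
    return pd.DataFrame(
        {
            "predictor": names,
            "estimate": np.asarray(res.params)[:k],
            "std_error": np.asarray(res.bse)[:k],
            "p_value": np.asarray(res.pvalues)[:k],
        }
    )


# ---------------------------------------------------------------------------
# forward selection with LOOCV


@dataclass
class ForwardSelectionFit:
    """A forward-selected linear model with leave-one-out metrics."""

    selected_features: list[str]
    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    loocv_mae: float
    loocv_rmse: float
    r_squared: float
    n_observations: int
    history: list[tuple[str, float]] = field(default_factory=list)  # (feature, loocv_rmse)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        yhat = np.full(len(table), self.coefficients["intercept"])
        for f in self.selected_features:
            yhat += self.coefficients[f] * table[f].to_numpy(dtype=float)
        return yhat


def _loocv_residuals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out residuals of OLS via the hat-matrix identity."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    H = np.einsum("ij,jk,ik->i", X, np.linalg.inv(XtX), X)
    return resid / np.clip(1.0 - H, 1e-12, None)


def forward_select_loocv(
    table: pd.DataFrame,
    response: str,
    candidates: list[str],
    *,
    min_improvement: float = 1e-6,
    min_obs: int = 5,
    max_features: int | None = None,
    enter_alpha: float | None = 0.01,
) -> ForwardSelectionFit:
    """Greedy forward selection minimizing leave-one-out RMSE.

    Starts from the intercept-only model; at each step the candidate with
    the lowest LOOCV RMSE among those that (a) improve the current LOOCV
    RMSE by more than ``min_improvement`` and (b) pass a partial F-test at
    ``enter_alpha`` is added; selection stops when no candidate qualifies
    or when ``n - 2`` features are in.  The F-to-enter gate exists because
    the minimum LOOCV error over many candidates keeps "improving" by
    chance on pure noise; without it the selected set grows without bound
    at small n (``enter_alpha=None`` disables the gate).  The final model
    is refit by OLS for estimates, 95% CIs and p-values.
    """
    from scipy import stats as _stats

    y = table[response].to_numpy(dtype=float)
    n = y.size
    if n < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {n}")
    cap = n - 2 if max_features is None else min(max_features, n - 2)

    cols = {c: table[c].to_numpy(dtype=float) for c in candidates}
    selected: list[str] = []
    history: list[tuple[str, float]] = []

    def design(feats: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [cols[f] for f in feats])

    def evaluate(feats: list[str]) -> tuple[float, float]:
        """(LOOCV RMSE, in-sample RSS) of the model on ``feats``."""
        X = design(feats)
        try:
            e = _loocv_residuals(X, y)
            raw = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        except np.linalg.LinAlgError:
            return np.inf, np.inf
        return float(np.sqrt(np.mean(e**2))), float(raw @ raw)

    current, current_rss = evaluate([])
    while len(selected) < cap:
        df2 = n - (len(selected) + 2)
        best: tuple[float, str, float] | None = None
        for f in candidates:
            if f in selected:
                continue
            rmse, rss = evaluate(selected + [f])
            if rmse >= current - min_improvement:
                continue
            if enter_alpha is not None and df2 > 0:
                f_stat = (current_rss - rss) / (rss / df2) if rss > 0 else np.inf
                if _stats.f.sf(f_stat, 1, df2) > enter_alpha:
                    continue
            if best is None or rmse < best[0]:
                best = (rmse, f, rss)
        if best is None:
            break
        selected.append(best[1])
        history.append((best[1], best[0]))
        current, current_rss = best[0], best[2]

    X = design(selected)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y, X).fit()
    names = ["intercept", *selected]
    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    e_loo = _loocv_residuals(X, y)
    return ForwardSelectionFit(
        selected_features=selected,
        coefficients=dict(zip(names, np.asarray(res.params))),
        conf_int={nm: (float(ci[i, 0]), float(ci[i, 1])) for i, nm in enumerate(names)},
        p_values=dict(zip(names, np.asarray(res.pvalues))),
        loocv_mae=float(np.mean(np.abs(e_loo))),
        loocv_rmse=float(np.sqrt(np.mean(e_loo**2))),
        r_squared=float(res.rsquared) if len(selected) else 0.0,
        n_observations=n,
        history=history,
    )


# ---------------------------------------------------------------------------
# learning-rate dataset assembly


def build_learning_rate_dataset(
    table: pd.DataFrame,
    *,
    response_name: str = "learning_rate",
) -> pd.DataFrame:
    """Per-participant learning-rate rows from an attempt-wise table.

    The response is the OLS slope of score on attempt; predictors are the
    first-attempt feature values plus the baseline (first-attempt) score.
    Participants with fewer than two attempts are dropped with a warning.
    """
    rows = []
    feature_cols = [c for c in ALL_FEATURES if c in table.columns]
    for (pid, task), grp in table.groupby(["participant_id", "task"], sort=True):
        grp = grp.sort_values("attempt")
        if len(grp) < 2:
            warnings.warn(f"participant {pid} has <2 attempts; skipped", stacklevel=2)
            continue
        slope = learning_rate(grp["score"].to_numpy(), grp["attempt"].to_numpy(dtype=float))
        first = grp.iloc[0]
        rows.append(
            {
                "participant_id": pid,
                "task": task,
                response_name: slope,
                "baseline_score": float(first["score"]),
                **{c: float(first[c]) for c in feature_cols},
            }
        )
    return pd.DataFrame(rows)
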