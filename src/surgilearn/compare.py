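"""Performance comparison across skill levels.

Fits a Gaussian linear mixed model of performance score on skill level
(four-level fixed factor) with a per-participant random intercept (REML),
then reports the omnibus ANOVA F-test for the level factor, least-squares
means (model-based marginal means) with standard errors per level, and all
pairwise level contrasts.  Pairwise p-values use the Tukey HSD adjustment
by default (the studentized-range distribution); unadjusted Wald p-values
are available via ``adjust="none"``.

The skill-level factor varies between participants, so the denominator
degrees of freedom of the F-test use the containment value
``n_participants - n_levels``, which coincides with the Satterthwaite
approximation in the balanced random-intercept design.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .names import LEVELS


@dataclass
class LevelModel:
    """A fitted mixed model of score on skill level."""

    levels: list[str]
    beta: np.ndarray          # [intercept, level_2, ..., level_k] effects
    cov: np.ndarray           # covariance of the fixed effects
    ddf: float                # denominator degrees of freedom
    n_obs: int
    n_participants: int
    residual_sd: float
    random_intercept_sd: float
    degenerate: bool = False


@dataclass
class LevelComparisonResult:
    """LSMs, omnibus ANOVA and pairwise contrasts across skill levels."""

    lsm: pd.DataFrame         # level, lsm, se
    anova_f: float
    anova_p: float
    df_num: int
    df_den: float
    contrasts: pd.DataFrame   # level_a, level_b, estimate, se, p_value


def fit_level_model(
    table: pd.DataFrame,
    response: str = "score",
    level_col: str = "level",
    groups: str = "participant_id",
) -> LevelModel:
    """REML mixed model: score ~ level with a participant random intercept."""
    present = [lv for lv in LEVELS if lv in set(table[level_col])]
    extra = sorted(set(table[level_col]) - set(LEVELS))
    if extra:
        raise ValueError(f"unknown skill levels: {extra}")
    if len(present) < 2:
        raise ValueError("need at least 2 skill levels to compare")
    counts = table.groupby(level_col)[response].count()
    if (counts < 2).any():
        warnings.warn(
            f"levels with a single observation: {list(counts[counts < 2].index)}",
            stacklevel=2,
        )
    y = table[response].to_numpy(dtype=float)
    k = len(present)
    X = np.column_stack(
        [np.ones(len(table))]
        + [(table[level_col] == lv).to_numpy(dtype=float) for lv in present[1:]]
    )
    n_participants = table[groups].nunique()
    ddf = float(n_participants - k)

    if np.var(y) < 1e-12:
        warnings.warn("degenerate model: zero response variance", stacklevel=2)
        return LevelModel(
            levels=present,
            beta=np.concatenate(([y[0] if y.size else 0.0], np.zeros(k - 1))),
            cov=np.zeros((k, k)),
            ddf=ddf,
            n_obs=len(table),
            n_participants=n_participants,
            residual_sd=0.0,
            random_intercept_sd=0.0,
            degenerate=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=table[groups].to_numpy())
        res = model.fit(reml=True)
    cov_re = np.asarray(res.cov_re)
    tau2 = float(cov_re[0, 0]) if cov_re.size else 0.0
    if tau2 <= 1e-10:
        warnings.warn("random-intercept variance estimated at zero (singular fit)", stacklevel=2)
    return LevelModel(
        levels=present,
        beta=np.asarray(res.params)[:k],
        cov=np.asarray(res.cov_params())[:k, :k],
        ddf=ddf,
        n_obs=len(table),
        n_participants=n_participants,
        residual_sd=float(np.sqrt(res.scale)),
        random_intercept_sd=float(np.sqrt(max(tau2, 0.0))),
    )


def anova_levels(model: LevelModel) -> tuple[float, float]:
    """Omnibus F-test of the skill-level factor.

    Wald F on the level effects with containment denominator df;
    returns ``(F, p)``.
    """
    k = len(model.levels)
    if k < 2:
        raise ValueError("omnibus test needs at least 2 levels")
    if model.degenerate:
        raise ValueError("degenerate model: omnibus test undefined")
    c = np.zeros((k - 1, k))
    c[:, 1:] = np.eye(k - 1)
    est = c @ model.beta
    V = c @ model.cov @ c.T
    F = float(est @ np.linalg.solve(V, est)) / (k - 1)
    p = float(stats.f.sf(F, k - 1, model.ddf))
    return F, p


def least_squares_means(model: LevelModel) -> pd.DataFrame:
    """Model-based marginal mean and SE per skill level."""
    k = len(model.levels)
    rows = []
    for i, lv in enumerate(model.levels):
        c = np.zeros(k)
        c[0] = 1.0
        if i > 0:
            c[i] = 1.0
        est = float(c @ model.beta)
        se = float(np.sqrt(c @ model.cov @ c))
        rows.append({"level": lv, "lsm": est, "se": se})
    return pd.DataFrame(rows)


def pairwise_contrasts(model: LevelModel, adjust: str = "tukey") -> pd.DataFrame:
    """All pairwise LSM differences with (Tukey-adjusted) p-values.

    ``estimate`` is LSM(a) - LSM(b) for each ordered pair a < b in the
    canonical level ordering; antisymmetric by construction.
    """
    if adjust not in ("tukey", "none"):
        raise ValueError("adjust must be 'tukey' or 'none'")
    k = len(model.levels)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        c = np.zeros(k)
        if i > 0:
            c[i] = 1.0
        if j > 0:
            c[j] -= 1.0
        est = float(c @ model.beta)
        se = float(np.sqrt(c @ model.cov @ c))
        if se > 0:
            t = est / se
            if adjust == "tukey":
                p = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k, model.ddf))
            else:
                p = float(2.0 * stats.t.sf(abs(t), model.ddf))
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "level_a": model.levels[i],
                "level_b": model.levels[j],
                "estimate": est,
                "se": se,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def compare_levels(
    table: pd.DataFrame,
    response: str = "score",
    level_col: str = "level",
    groups: str = "participant_id",
    adjust: str = "tukey",
) -> LevelComparisonResult:
    """Fit the level model and assemble LSMs, ANOVA and contrasts."""
    model = fit_level_model(table, response, level_col, groups)
    if model.degenerate:
        f_stat, p = np.nan, np.nan
    else:
        f_stat, p = anova_levels(model)
    return LevelComparisonResult(
        lsm=least_squares_means(model),
        anova_f=f_stat,
        anova_p=p,
        df_num=len(model.levels) - 1,
        df_den=model.ddf,
        contrasts=pairwise_contrasts(model, adjust),
    )
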