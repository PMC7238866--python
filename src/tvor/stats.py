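"""Inferential layer: repeated-measures ANOVA and the stride-frequency fit.

The experimental designs here are fully within-subjects (every subject
sees every combination of frequency, cycle, half-trial and foot position),
so the engine implements a general k-factor within-subjects ANOVA on a
complete balanced table:

* sums of squares by the classical marginal-means decomposition of the
  (subject x cells) data array, with each effect tested against its own
  effect-by-subject interaction;
* Greenhouse-Geisser epsilon per effect from the covariance of the
  subject-level orthonormal contrast scores, applied to the F degrees of
  freedom;
* generalized eta-squared with all subject-related sums of squares in the
  denominator (the observed-effect convention), which makes the effect
  size comparable across within- and between-subject designs.

Ordinary least squares with adjusted R^2 (used for the stride-frequency
regression plane on head-neck segment length and mass) goes through
statsmodels.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "rm_anova",
    "gg_epsilon",
    "ols_adjusted_r2",
    "relabel_direction",
]


def _effect_ss(arr: np.ndarray, subset: tuple[int, ...]) -> float:
    """Sum of squares of one term of the marginal-means decomposition.

    ``subset`` indexes dimensions of ``arr`` (0 = subject); the effect
    array is the inclusion-exclusion combination of marginal means over
    all sub-subsets, summed over the full grid.
    """
    ndim = arr.ndim
    eff = np.zeros_like(arr)
    for r in range(len(subset) + 1):
        for sub in combinations(subset, r):
            keep = set(sub)
            axes = tuple(d for d in range(ndim) if d not in keep)
            m = arr.mean(axis=axes, keepdims=True) if axes else arr
            eff = eff + (-1.0) ** (len(subset) - r) * m
    return float(np.sum(np.broadcast_to(eff, arr.shape) ** 2))


def _contrast_scores(arr: np.ndarray, subset: tuple[int, ...]) -> np.ndarray:
    """Subject-level orthonormal contrast scores spanning an effect space."""
    ndim = arr.ndim
    drop = tuple(d for d in range(1, ndim) if d not in subset)
    y = arr.mean(axis=drop) if drop else arr        # (subjects, l_i ...)
    y = y.reshape(y.shape[0], -1)
    mats = [helmert(arr.shape[d], full=False) for d in subset]
    contrast = mats[0]
    for m in mats[1:]:
        contrast = np.kron(contrast, m)
    return y @ contrast.T                            # (subjects, df_effect)


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str = "subject") -> pd.DataFrame:
    """Fully within-subjects ANOVA on a complete balanced long table.

    Parameters
    ----------
    data
        Long-format table with one observation per subject x cell.
    dv
        Column holding the dependent variable.
    within
        Ordered list of within-subject factor columns.
    subject
        Column identifying subjects (>= 3 required).

    Returns
    -------
    pandas.DataFrame
        One row per effect (main effects and all interactions) with
        columns effect, df_num, df_den, F, p_uncorrected, epsilon_gg,
        p_gg, eta_g_squared.
    """
    within = list(within)
    subjects = data[subject].unique()
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    counts = data.groupby([subject] + within, sort=False).size()
    if (counts != 1).any():
        raise ValueError("design must be complete and balanced with exactly "
                         "one observation per subject x cell")
    levels = [np.sort(data[f].unique()) for f in within]
    expected = len(subjects) * int(np.prod([len(lv) for lv in levels]))
    if len(data) != expected:
        raise ValueError("missing cells in the design")

    wide = data.set_index([subject] + within)[dv].sort_index()
    arr = wide.to_numpy(dtype=float).reshape(
        [len(subjects)] + [len(lv) for lv in levels])

    factor_dims = tuple(range(1, len(within) + 1))
    # subject-related SS: subject main effect and every interaction with it
    ss_subject_terms = _effect_ss(arr, (0,))
    error_ss: dict[tuple[int, ...], float] = {}
    for r in range(1, len(factor_dims) + 1):
        for sub in combinations(factor_dims, r):
            error_ss[sub] = _effect_ss(arr, (0,) + sub)
    ss_all_error = ss_subject_terms + sum(error_ss.values())

    n_subj = arr.shape[0]
    rows = []
    for r in range(1, len(factor_dims) + 1):
        for sub in combinations(factor_dims, r):
            ss_eff = _effect_ss(arr, sub)
            df_num = int(np.prod([arr.shape[d] - 1 for d in sub]))
            df_den = (n_subj - 1) * df_num
            ss_err = error_ss[sub]
            ms_eff = ss_eff / df_num
            ms_err = ss_err / df_den
            F = ms_eff / ms_err if ms_err > 0 else float("nan")
            p = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else float("nan")
            if df_num > 1:
                scores = _contrast_scores(arr, sub)
                eps = gg_epsilon(np.cov(scores, rowvar=False), contrasts_applied=True)
            else:
                eps = 1.0
            p_gg = (float(sps.f.sf(F, eps * df_num, eps * df_den))
                    if np.isfinite(F) else float("nan"))
            denom = ss_eff + ss_all_error
            eta_g = ss_eff / denom if denom > 0 else 0.0
            rows.append({
                "effect": " x ".join(within[d - 1] for d in sub),
                "df_num": df_num, "df_den": df_den, "F": F,
                "p_uncorrected": p, "epsilon_gg": eps, "p_gg": p_gg,
                "eta_g_squared": eta_g,
            })
    return pd.DataFrame(rows)


def gg_epsilon(cov: np.ndarray, contrasts_applied: bool = False) -> float:
    """Greenhouse-Geisser sphericity correction factor.

    ``cov`` is either the covariance matrix of the repeated measures
    (``contrasts_applied=False``; an orthonormal contrast basis is applied
    internally) or already the covariance of orthonormal contrast scores.
    Bounded in [1/d, 1] where d is the contrast dimension; equals 1 under
    compound symmetry, and exactly 1 for two levels.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance matrix must be symmetric")
    if not contrasts_applied:
        if cov.shape[0] < 2:
            raise ValueError("need at least 2 repeated measures")
        C = helmert(cov.shape[0], full=False)
        cov = C @ cov @ C.T
    d = cov.shape[0]
    tr = np.trace(cov)
    denom = d * np.sum(cov * cov)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr ** 2 / denom, 1.0 / d, 1.0))


def ols_adjusted_r2(y, X, names=None):
    """Least-squares plane fit with adjusted R^2.

    Parameters
    ----------
    y, X
        Response vector and (n x p) predictor matrix (no constant column;
        one is added).
    names
        Optional predictor names.

    Returns
    -------
    dict
        ``coefficients`` (incl. intercept), ``r2``, ``adj_r2`` and a
        per-coefficient table with F (= t^2) and p values.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValueError("collinear predictors")
    names = list(names) if names is not None else [f"x{i+1}" for i in range(p)]
    exog = sm.add_constant(pd.DataFrame(X, columns=names))
    fit = sm.OLS(np.asarray(y, dtype=float), exog).fit()
    table = pd.DataFrame({
        "coef": fit.params,
        "F": fit.tvalues ** 2,
        "p": fit.pvalues,
    })
    return {
        "coefficients": fit.params.to_dict(),
        "r2": float(fit.rsquared),
        "adj_r2": float(fit.rsquared_adj),
        "table": table,
    }


def relabel_direction(estimates: pd.DataFrame) -> pd.DataFrame:
    """Relabel Experiment B half-cycles by initial platform motion class.

    Alternating half-cycles reverse the platform direction, so a
    (frequency, start condition) cell can be reassigned to an up/down
    *direction* factor: odd half-cycles of a dorsiflexion start pair with
    even half-cycles of a plantarflexion start and vice versa.  The
    returned copy carries a ``direction`` column feeding :func:`rm_anova`.
    """
    df = estimates.copy()
    odd = df["cycle_index"] % 2 == 1
    dorsi = df["start_condition"] == "dorsiflexion"
    df["direction"] = np.where(odd == dorsi, "up", "down")
    return df
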