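"""Paired comparisons and mixed repeated-measures ANOVA with sphericity
handling.

The mixed design has one within-subject factor (e.g. task, effort level or
TDC segment as the repeated measures) and one between-subject factor (the
feature set used by the classifier). Sphericity of the within-subject
covariance is tested with Mauchly's W; when rejected at alpha = 0.05 the
within-effect degrees of freedom are deflated by the Greenhouse-Geisser
epsilon (the conservative correction; Huynh-Feldt is deliberately not
offered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import BalanceError, DegenerateTestError, ParameterError

ALPHA = 0.05


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Classical paired Student t on the differences; two-sided p.

    Returns (t, df, p). Raises DegenerateTestError when the differences have
    zero variance (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ParameterError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sst.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass(frozen=True)
class RmAnovaResult:
    effect: str                  # 'within' | 'between' | 'interaction'
    F: float
    df: tuple[float, float]      # possibly epsilon-adjusted
    p: float
    epsilon_gg: float | None = None
    mauchly_W: float | None = None
    mauchly_p: float | None = None
    df_unadjusted: tuple[float, float] | None = None
    p_unadjusted: float | None = None
    sphericity_assumed: bool | None = None


def _pivot(table: pd.DataFrame, dv: str, within: str, between: str, subject: str):
    wide = table.pivot_table(index=[subject, between], columns=within, values=dv)
    if wide.isna().any().any():
        raise BalanceError("missing cells: design must be complete and balanced")
    groups = wide.index.get_level_values(between)
    counts = pd.Series(groups).value_counts()
    if counts.min() < 2:
        raise BalanceError("need at least 2 subjects per group")
    return wide, groups


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """GG epsilon from the double-centred within-subject covariance.

    epsilon = tr(S~)^2 / ((k-1) * sum(S~^2)), bounded to [1/(k-1), 1].
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    if k < 2:
        raise ParameterError("need at least 2 repeated measures")
    if k == 2:
        return 1.0
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    Sc = S - row - col + S.mean()
    eps = np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc**2))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(cov: np.ndarray, n_error_df: int) -> tuple[float, float]:
    """Mauchly's sphericity test on an orthonormal-contrast-transformed
    covariance; chi-square approximation to the null distribution.

    ``n_error_df`` is the degrees of freedom of the covariance estimate
    (subjects minus groups in the mixed design). With k = 2 measures the
    test is vacuous: W = 1, p = 1.
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    if k == 2:
        return 1.0, 1.0
    # orthonormal contrasts: complete the constant vector to an orthonormal basis
    basis, _ = np.linalg.qr(
        np.column_stack([np.ones(k) / np.sqrt(k), np.eye(k)[:, : k - 1]])
    )
    C = basis[:, 1:].T  # (k-1) x k
    T = C @ S @ C.T
    eig = np.linalg.eigvalsh(T)
    eig = np.clip(eig, np.finfo(float).tiny, None)
    q = k - 1
    W = float(np.prod(eig) / (eig.mean() ** q))
    d = n_error_df
    logW = np.log(max(W, np.finfo(float).tiny))
    # Box's chi-square approximation with the second-order correction term
    f_corr = 1.0 - (2 * q**2 + q + 2) / (6.0 * q * d)
    chi2 = -f_corr * d * logW
    df = q * (q + 1) // 2 - 1
    w2 = (
        (q + 2) * (q - 1) * (q - 2) * (2 * q**3 + 6 * q**2 + 3 * q + 2)
        / (288.0 * (d * q * f_corr) ** 2)
    )
    p1 = sst.chi2.sf(chi2, df)
    p2 = sst.chi2.sf(chi2, df + 4)
    p = float(np.clip(p1 + w2 * (p2 - p1), 0.0, 1.0))
    return W, p


def rm_anova_mixed(
    table: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str,
    alpha: float = ALPHA,
) -> dict[str, RmAnovaResult]:
    """Mixed-design ANOVA: one within factor, one between factor.

    ``table`` is long-format with one row per (subject, within-level)
    observation. Returns results keyed 'between', 'within', 'interaction'.
    The within and interaction effects carry Mauchly's test and are
    GG-adjusted when sphericity is rejected at ``alpha``.
    """
    wide, groups = _pivot(table, dv, within, between, subject)
    Y = wide.to_numpy(dtype=float)
    n_tot, k = Y.shape
    glabels = np.unique(groups)
    g = glabels.size
    if g < 2:
        raise BalanceError("mixed design needs at least 2 between-factor groups")

    gm = Y.mean()
    subj_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    group_masks = [np.asarray(groups) == lbl for lbl in glabels]
    group_means = np.array([subj_means[m].mean() for m in group_masks])
    cell_means = np.vstack([Y[m].mean(axis=0) for m in group_masks])

    ss_between_subj = k * np.sum((subj_means - gm) ** 2)
    ss_groups = k * sum(m.sum() * (gmean - gm) ** 2
                        for m, gmean in zip(group_masks, group_means))
    ss_subj_within_groups = ss_between_subj - ss_groups

    ss_within_total = np.sum((Y - subj_means[:, None]) ** 2)
    ss_time = n_tot * np.sum((col_means - gm) ** 2)
    ss_inter = sum(
        m.sum() * np.sum((cell_means[i] - group_means[i] - col_means + gm) ** 2)
        for i, m in enumerate(group_masks)
    )
    ss_err_within = ss_within_total - ss_time - ss_inter

    df_groups, df_err_b = g - 1, n_tot - g
    df_time, df_inter = k - 1, (g - 1) * (k - 1)
    df_err_w = (n_tot - g) * (k - 1)

    def f_p(ss_eff, df_eff, ss_err, df_err):
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        if ms_err <= 0:
            raise DegenerateTestError("zero error variance")
        F = ms_eff / ms_err
        return F, float(sst.f.sf(F, df_eff, df_err))

    F_b, p_b = f_p(ss_groups, df_groups, ss_subj_within_groups, df_err_b)
    results = {
        "between": RmAnovaResult("between", float(F_b), (df_groups, df_err_b), p_b)
    }

    # pooled within-group covariance of the repeated measures
    pooled = np.zeros((k, k))
    for m in group_masks:
        d = Y[m] - Y[m].mean(axis=0)
        pooled += d.T @ d
    pooled /= n_tot - g
    eps = greenhouse_geisser_epsilon(pooled)
    W, p_sph = mauchly_test(pooled, n_tot - g)
    spherical = p_sph >= alpha

    for name, ss_eff, df_eff in (
        ("within", ss_time, df_time),
        ("interaction", ss_inter, df_inter),
    ):
        F, p_un = f_p(ss_eff, df_eff, ss_err_within, df_err_w)
        if spherical:
            df_adj, p_adj = (float(df_eff), float(df_err_w)), p_un
        else:
            df_adj = (eps * df_eff, eps * df_err_w)
            p_adj = float(sst.f.sf(F, *df_adj))
        results[name] = RmAnovaResult(
            name, float(F), df_adj, p_adj,
            epsilon_gg=eps, mauchly_W=W, mauchly_p=p_sph,
            df_unadjusted=(float(df_eff), float(df_err_w)), p_unadjusted=p_un,
            sphericity_assumed=spherical,
        )
    return results
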