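"""Rubin's-rules combination of statistics across imputations.

Given m per-imputation estimates Q_j with variances U_j, the pooled
point estimate is Q̄ = mean(Q_j), the within-imputation variance is
W = mean(U_j), the between-imputation variance is B = var(Q_j), and the
total variance is T = W + (1 + 1/m)·B.  Degrees of freedom use the
small-sample (Barnard–Rubin) adjustment, which yields the fractional
dfs typical of multiply-imputed analyses; with a single imputation the
procedures reduce exactly to their complete-data counterparts (Welch t,
Pearson r, one-way ANOVA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import ImputationSet
from .tabular_io import BehavioralTable, PROFILES


class PoolingError(ValueError):
    pass


@dataclass
class PooledEstimate:
    point: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    m: int


def rubin_pool(estimates, variances, df_complete: float | None = None) -> PooledEstimate:
    """Combine m estimates and their variances by Rubin's rules.

    ``df_complete`` is the complete-data degrees of freedom; when given,
    the Barnard–Rubin small-sample adjustment
    ν̃ = (ν_large · ν_obs)/(ν_large + ν_obs) applies, with
    ν_large = (m−1)(1 + W/((1+1/m)B))² and
    ν_obs = ((ν_com+1)/(ν_com+3))·ν_com·(1−r), r = (1+1/m)B/T.
    With m = 1 the between-imputation variance is undefined: the estimate
    is returned with W and the complete-data df, with a warning.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape or len(q) < 1:
        raise PoolingError("estimates and variances must be equal-length 1-d arrays")
    if np.any(u < 0):
        raise PoolingError("variances must be non-negative")
    m = len(q)
    qbar = float(q.mean())
    w = float(u.mean())
    if m == 1:
        warnings.warn("m=1: between-imputation variance undefined; using W only")
        df = df_complete if df_complete is not None else np.inf
        return PooledEstimate(qbar, w, 0.0, w, float(df), 1)
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = df_complete if df_complete is not None else np.inf
        return PooledEstimate(qbar, w, 0.0, t, float(df), m)
    nu_large = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    if df_complete is None:
        df = nu_large
    else:
        r = (1.0 + 1.0 / m) * b / t
        nu_com = float(df_complete)
        nu_obs = ((nu_com + 1.0) / (nu_com + 3.0)) * nu_com * (1.0 - r)
        df = (nu_large * nu_obs) / (nu_large + nu_obs)
    return PooledEstimate(qbar, w, b, t, float(df), m)


def _group_values(table: BehavioralTable, labels, group, variable) -> np.ndarray:
    labels = np.asarray(labels)
    vals = table.df.loc[labels == group, variable].dropna().to_numpy(float)
    return vals


def pooled_t_test(
    tableset: ImputationSet, labels, group_a: str, group_b: str, variable: str
):
    """Welch-type two-group comparison pooled over imputations.

    Per imputation the mean difference and its Welch variance are
    computed; Rubin's rules combine them, t = Q̄/√T with the adjusted
    (fractional) df.  Cohen's d uses the pooled-across-groups SD,
    averaged over imputations.  Returns ``(t, df, p, d)``.
    """
    diffs, variances, dfs_w, ds = [], [], [], []
    for table in tableset.tables:
        a = _group_values(table, labels, group_a, variable)
        b = _group_values(table, labels, group_b, variable)
        if len(a) < 2 or len(b) < 2:
            raise PoolingError("both groups need >= 2 rows in every imputation")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            raise PoolingError("degenerate (zero-variance) groups")
        na, nb = len(a), len(b)
        se2 = va / na + vb / nb
        diffs.append(a.mean() - b.mean())
        variances.append(se2)
        dfs_w.append(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
        sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        ds.append((a.mean() - b.mean()) / sp if sp > 0 else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = rubin_pool(diffs, variances, df_complete=float(np.mean(dfs_w)))
    if pooled.total_var == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = pooled.point / np.sqrt(pooled.total_var)
        p = 2.0 * stats.t.sf(abs(t_stat), pooled.df)
    return float(t_stat), float(pooled.df), float(p), float(np.mean(ds))


def pooled_correlation(tableset: ImputationSet, labels, group, var_x, var_y):
    """Pearson correlation pooled on the Fisher-z scale.

    Per imputation r maps to z = atanh(r) with variance 1/(n−3);
    Rubin's rules pool z; the pooled z back-transforms to r.  With a
    single imputation this is the plain Pearson correlation with n−2 df.
    Returns ``(r, df, p)``.
    """
    zs, variances, ns = [], [], []
    for table in tableset.tables:
        x = _group_values(table, labels, group, var_x)
        y = _group_values(table, labels, group, var_y)
        if len(x) != len(y) or len(x) < 4:
            raise PoolingError("group needs >= 4 complete paired rows")
        if x.std() == 0 or y.std() == 0:
            raise PoolingError("zero variance in a correlated variable")
        r = float(np.corrcoef(x, y)[0, 1])
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        zs.append(np.arctanh(r))
        variances.append(1.0 / (len(x) - 3))
        ns.append(len(x))
    n = float(np.mean(ns))
    if len(zs) == 1:
        r = float(np.tanh(zs[0]))
        df = n - 2
        t_stat = r * np.sqrt(df / (1 - r**2)) if abs(r) < 1 else np.inf
        return r, float(df), float(2 * stats.t.sf(abs(t_stat), df))
    pooled = rubin_pool(zs, variances, df_complete=n - 3)
    r = float(np.tanh(pooled.point))
    z_stat = pooled.point / np.sqrt(pooled.total_var) if pooled.total_var > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(z_stat), pooled.df)
    return r, float(pooled.df), float(p)


def _anova_once(values: np.ndarray, groups: np.ndarray):
    levels = [g for g in PROFILES if (groups == g).any()] or list(np.unique(groups))
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise PoolingError("ANOVA needs >= 2 groups with >= 2 rows each")
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_total = float(((values - grand) ** 2).sum())
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    f, _ = stats.f_oneway(*samples)
    return float(f), float(eta2), levels


def _d1_pool(qs: list[np.ndarray], us: list[np.ndarray]):
    """Multivariate Wald combination (D1) of m vector estimates.

    Pools the (k-1)-vector of group-mean contrasts with within-covariance
    W̄ inflated by the average relative increase in variance; returns the
    D1 statistic, numerator df, and denominator df.
    """
    m = len(qs)
    k = len(qs[0])
    qbar = np.mean(qs, axis=0)
    wbar = np.mean(us, axis=0)
    if m == 1:
        d1 = float(qbar @ np.linalg.solve(wbar, qbar)) / k
        return d1, k, np.inf
    b = np.cov(np.stack(qs).T, ddof=1).reshape(k, k)
    r = (1.0 + 1.0 / m) * float(np.trace(b @ np.linalg.pinv(wbar))) / k
    wt = wbar * (1.0 + r)
    d1 = float(qbar @ np.linalg.solve(wt, qbar)) / k
    t_ = k * (m - 1)
    if t_ > 4:
        df2 = 4 + (t_ - 4) * (1 + (1 - 2 / t_) / r) ** 2
    else:
        df2 = t_ * (1 + 1 / k) * (1 + 1 / r) ** 2 / 2
    return d1, k, float(df2)


def pooled_anova(tableset: ImputationSet, labels, variable: str, method: str = "mean_f"):
    """One-way ANOVA across profiles, summarized over imputations.

    Reports the across-imputation mean F (with its SD), pooled eta² as
    the across-imputation mean, a p-value from the mean F with the
    complete-data numerator/denominator df, and the Tukey-HSD pairwise
    orderings that hold (at α = 0.05) in at least half the imputations.
    ``method="d1"`` additionally pools the group-contrast vector by the
    multivariate Wald (D1) combination rule and reports its statistic and
    p-value.  Returns a dict.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.asarray(labels)
    fs, etas, orderings = [], [], []
    contrast_qs, contrast_us = [], []
    k = n = None
    for table in tableset.tables:
        mask_obs = table.df[variable].notna().to_numpy()
        vals = table.df.loc[mask_obs, variable].to_numpy(float)
        grp = labels[mask_obs]
        f, eta2, levels = _anova_once(vals, grp)
        fs.append(f)
        etas.append(eta2)
        k, n = len(levels), len(vals)
        if method == "d1":
            means = np.array([vals[grp == g].mean() for g in levels])
            variances = np.array(
                [vals[grp == g].var(ddof=1) / (grp == g).sum() for g in levels]
            )
            contrast_qs.append(means[1:] - means[0])
            c = np.full((k - 1, k - 1), variances[0]) + np.diag(variances[1:])
            contrast_us.append(c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tk = pairwise_tukeyhsd(vals, grp, alpha=0.05)
        rel = set()
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in res.iterrows():
            if bool(row["reject"]):
                hi, lo_ = (
                    (row["group1"], row["group2"])
                    if float(row["meandiff"]) < 0
                    else (row["group2"], row["group1"])
                )
                rel.add(f"{hi}>{lo_}")
        orderings.append(rel)
    f_mean = float(np.mean(fs))
    p = float(stats.f.sf(f_mean, k - 1, n - k))
    threshold = len(orderings) / 2.0
    all_rel = set().union(*orderings)
    stable = sorted(r for r in all_rel if sum(r in o for o in orderings) >= threshold)
    out = {
        "F": f_mean,
        "F_sd": float(np.std(fs, ddof=1)) if len(fs) > 1 else 0.0,
        "eta_squared": float(np.mean(etas)),
        "p": p,
        "df": (k - 1, n - k),
        "pairwise": stable,
        "n": n,
    }
    if method == "d1":
        d1, df1, df2 = _d1_pool(contrast_qs, contrast_us)
        out["D1"] = d1
        out["D1_df"] = (df1, df2)
        out["D1_p"] = float(stats.f.sf(d1, df1, df2))
    return out


def pooled_profile_means(tableset: ImputationSet, labels) -> pd.DataFrame:
    """Per-profile, per-variable mean ± SEM pooled over imputations.

    Means are computed per imputation then averaged; the SEM is the
    square root of the Rubin total variance of the per-imputation means.
    Tidy frame with columns (profile, variable, mean, sem).
    """
    labels = np.asarray(labels)
    numeric = tableset.tables[0].numeric_vars
    rows = []
    for profile in PROFILES:
        idx = labels == profile
        if not idx.any():
            continue
        for v in numeric:
            means, sems2 = [], []
            for table in tableset.tables:
                vals = table.df.loc[idx, v].dropna().to_numpy(float)
                means.append(vals.mean())
                sems2.append(vals.var(ddof=1) / len(vals))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pooled = rubin_pool(means, sems2)
            rows.append(
                {
                    "profile": profile,
                    "variable": v,
                    "mean": pooled.point,
                    "sem": float(np.sqrt(pooled.total_var)),
                }
            )
    return pd.DataFrame(rows)
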