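"""The three competing imputation methods and the efficiency diagnostic.

* mean replacement — each missing cell set to the observed column mean
  (single imputation; known to shrink variance by the missing fraction);
* predictive mean matching (PMM) — chained equations where each missing
  cell copies the observed value of a donor row whose model-predicted
  value is nearest, with Bayesian perturbation of the regression
  coefficients so the m imputations are proper;
* missForest — iterative random-forest regression of each incomplete
  variable on all the others, sweeping until the change statistic stops
  improving; repeated m times on independent RNG streams to obtain a
  multiple-imputation set.

All imputers see only the classification-side variables plus the
always-observed covariates (sex, site): profile labels and validation
scores are structurally invisible to them.  Efficiency is the ratio of
an imputed column's variance to the original complete column's variance
(1 is ideal; below 1 means variance shrinkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .tabular_io import ELIGIBLE_MISSING_VARS, BehavioralTable

IMPUTATION_METHODS = ("mean_replacement", "pmm", "missforest")


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSet:
    """m completed tables from one method, plus diagnostics."""

    method: str
    tables: list[BehavioralTable]
    convergence: list[list[float]] = field(default_factory=list)  # missforest deltas
    notes: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.tables)

    def efficiency(self, original: BehavioralTable) -> pd.Series:
        return efficiency(self, original)


def _incomplete_vars(df: pd.DataFrame) -> list[str]:
    """Eligible variables with missing cells, ascending missingness."""
    counts = {v: int(df[v].isna().sum()) for v in ELIGIBLE_MISSING_VARS}
    vars_ = [v for v, c in counts.items() if c > 0]
    return sorted(vars_, key=lambda v: (counts[v], v))


def _check_observed(df: pd.DataFrame) -> None:
    for v in _incomplete_vars(df):
        if df[v].notna().sum() == 0:
            raise ImputationError(f"column {v!r} has no observed cells")


def _covariate_matrix(df: pd.DataFrame, site_levels) -> np.ndarray:
    """Sex indicator and one-hot site columns (always observed)."""
    sex = (df["sex"] == "F").to_numpy(float)[:, None]
    site = pd.Categorical(df["site"], categories=site_levels)
    onehot = pd.get_dummies(site, drop_first=True).to_numpy(float)
    return np.hstack([sex, onehot])


def impute_mean(table: BehavioralTable) -> ImputationSet:
    """Replace every missing cell with its column's observed mean (m = 1)."""
    _check_observed(table.df)
    out = table.copy()
    for v in _incomplete_vars(table.df):
        out.df[v] = out.df[v].fillna(float(table.df[v].mean()))
    return ImputationSet(method="mean_replacement", tables=[out])


def _pmm_one(
    df: pd.DataFrame,
    covariates: np.ndarray,
    k_donors: int,
    n_cycles: int,
    rng: np.random.Generator,
    notes: list[str],
    perturbation: str = "normal",
) -> pd.DataFrame:
    vars_ = _incomplete_vars(df)
    miss = {v: df[v].isna().to_numpy() for v in vars_}
    # numpy working matrix over the eligible variables (hot loop)
    cols = list(ELIGIBLE_MISSING_VARS)
    col_ix = {v: i for i, v in enumerate(cols)}
    mat = df[cols].to_numpy(float).copy()
    for v in vars_:  # initialize with random observed draws
        obs_vals = df.loc[~miss[v], v].to_numpy()
        mat[miss[v], col_ix[v]] = rng.choice(obs_vals, size=int(miss[v].sum()), replace=True)
    ones = np.ones((len(mat), 1))
    for _ in range(n_cycles):
        for v in vars_:
            other_ix = [col_ix[u] for u in cols if u != v]
            X = np.hstack([ones, mat[:, other_ix], covariates])
            obs = ~miss[v]
            y = mat[obs, col_ix[v]]
            Xo, Xm = X[obs], X[miss[v]]
            XtX = Xo.T @ Xo
            p = X.shape[1]
            ridge = 0.0
            if np.linalg.cond(XtX) > 1e10:
                ridge = 1e-6 * np.trace(XtX) / p
                notes.append(f"ridge-stabilized fit for {v}")
            XtX_inv = np.linalg.pinv(XtX + ridge * np.eye(p))
            beta_hat = XtX_inv @ Xo.T @ y
            if perturbation == "bootstrap":
                idx = rng.integers(len(y), size=len(y))
                Xb, yb = Xo[idx], y[idx]
                XtXb = Xb.T @ Xb
                beta_star = np.linalg.pinv(XtXb + ridge * np.eye(p)) @ Xb.T @ yb
            else:  # posterior-style normal draw
                resid = y - Xo @ beta_hat
                dof = max(len(y) - p, 1)
                sigma2_star = resid @ resid / rng.chisquare(dof)
                cov = sigma2_star * XtX_inv
                cov = 0.5 * (cov + cov.T)
                beta_star = rng.multivariate_normal(
                    beta_hat, cov, check_valid="ignore", method="svd"
                )
            pred_obs = Xo @ beta_hat
            pred_mis = Xm @ beta_star
            k = min(k_donors, len(y))
            filled = np.empty(len(pred_mis))
            for j, t in enumerate(pred_mis):  # k nearest donors, uniform draw
                idx = np.argpartition(np.abs(pred_obs - t), k - 1)[:k]
                filled[j] = y[idx[rng.integers(k)]]
            mat[miss[v], col_ix[v]] = filled
    work = df.copy()
    for v in vars_:
        work[v] = mat[:, col_ix[v]]
    return work


def impute_pmm(
    table: BehavioralTable,
    m: int = 10,
    k_donors: int = 5,
    n_cycles: int = 5,
    seed: int = 0,
    perturbation: str = "normal",
) -> ImputationSet:
    """Multiple imputation by chained equations with predictive mean matching.

    ``perturbation`` selects how the regression coefficients are made
    proper: ``"normal"`` draws from their estimated sampling distribution,
    ``"bootstrap"`` refits on a bootstrap resample of the observed rows.
    """
    _check_observed(table.df)
    if perturbation not in ("normal", "bootstrap"):
        raise ImputationError(f"unknown perturbation {perturbation!r}")
    for v in _incomplete_vars(table.df):
        if table.df[v].notna().sum() < k_donors:
            raise ImputationError(f"fewer than {k_donors} observed donors for {v!r}")
    covariates = _covariate_matrix(table.df, table.site_levels)
    notes: list[str] = []
    tables = []
    for j in range(m):
        rng = child_rng(seed, "pmm", j)
        filled = _pmm_one(table.df, covariates, k_donors, n_cycles, rng, notes, perturbation)
        tables.append(BehavioralTable(filled, table.sex_levels, table.site_levels))
    return ImputationSet(method="pmm", tables=tables, notes=notes)


def _missforest_one(
    df: pd.DataFrame,
    covariates: np.ndarray,
    max_iter: int,
    ntree: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[float]]:
    from sklearn.ensemble import RandomForestRegressor

    vars_ = _incomplete_vars(df)
    miss = {v: df[v].isna().to_numpy() for v in vars_}
    work = df.copy()
    for v in vars_:  # mean initialization
        work.loc[miss[v], v] = float(df[v].mean())
    prev = work.copy()
    deltas: list[float] = []
    for _ in range(max_iter):
        old_imputed = {v: work.loc[miss[v], v].to_numpy() for v in vars_}
        for v in vars_:
            others = [u for u in ELIGIBLE_MISSING_VARS if u != v]
            X = np.hstack([work[others].to_numpy(float), covariates])
            obs = ~miss[v]
            forest = RandomForestRegressor(
                n_estimators=ntree,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(X[obs], work.loc[obs, v].to_numpy(float))
            work.loc[miss[v], v] = forest.predict(X[miss[v]])
        num = sum(
            float(((work.loc[miss[v], v].to_numpy() - old_imputed[v]) ** 2).sum())
            for v in vars_
        )
        den = sum(float((work.loc[miss[v], v].to_numpy() ** 2).sum()) for v in vars_)
        delta = num / den if den > 0 else 0.0
        deltas.append(delta)
        if len(deltas) > 1 and delta > deltas[-2]:
            return prev, deltas  # change statistic worsened: keep previous sweep
        prev = work.copy()
    return prev, deltas


def impute_missforest(
    table: BehavioralTable,
    m: int = 10,
    max_iter: int = 10,
    ntree: int = 100,
    seed: int = 0,
) -> ImputationSet:
    """Iterative random-forest imputation, run m times on separate RNG streams."""
    _check_observed(table.df)
    if not _incomplete_vars(table.df):  # nothing to do: 0 iterations
        return ImputationSet(
            method="missforest",
            tables=[table.copy() for _ in range(m)],
            convergence=[[] for _ in range(m)],
        )
    covariates = _covariate_matrix(table.df, table.site_levels)
    tables, traces = [], []
    for j in range(m):
        rng = child_rng(seed, "missforest", j)
        filled, deltas = _missforest_one(table.df, covariates, max_iter, ntree, rng)
        tables.append(BehavioralTable(filled, table.sex_levels, table.site_levels))
        traces.append(deltas)
    return ImputationSet(method="missforest", tables=tables, convergence=traces)


def impute(table: BehavioralTable, method: str, m: int = 10, seed: int = 0, **kw) -> ImputationSet:
    """Dispatch by method name."""
    if method == "mean_replacement":
        return impute_mean(table)
    if method == "pmm":
        return impute_pmm(table, m=m, seed=seed, **kw)
    if method == "missforest":
        return impute_missforest(table, m=m, seed=seed, **kw)
    raise ImputationError(f"unknown method {method!r}; choose from {IMPUTATION_METHODS}")


def efficiency(imputed, original: BehavioralTable) -> pd.Series:
    """Variance ratio Var(imputed v) / Var(original v), full columns.

    ``imputed`` may be a single table or an :class:`ImputationSet`, in
    which case the ratio is averaged over its m tables.  Variables whose
    original variance is zero report NaN.
    """
    if isinstance(imputed, ImputationSet):
        ratios = [efficiency(t, original) for t in imputed.tables]
        return pd.concat(ratios, axis=1).mean(axis=1)
    if not original.is_complete():
        raise ImputationError("original table must be complete")
    out = {}
    for v in ELIGIBLE_MISSING_VARS:
        denom = float(original.df[v].var(ddof=1))
        out[v] = float(imputed.df[v].var(ddof=1)) / denom if denom > 0 else np.nan
    return pd.Series(out)
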