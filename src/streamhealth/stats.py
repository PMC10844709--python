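"""Comparison statistics: collinearity screening, Spearman index–environment
matrices, random-forest variable importance and Kruskal–Wallis tests.

The screening step removes environmental variables that are rank-correlated
at |r| ≥ 0.75 with another variable, either via an explicit override list or
a mean-|r| heuristic. Index–environment association is summarised two ways:
a Spearman correlation matrix (with hierarchical-clustering display orders)
and a random-forest regression per index reporting %IncMSE permutation
importance on out-of-bag samples with response-permutation p-values.
Original-vs-modified index distributions are compared with the two-group
Kruskal–Wallis test (tie-corrected, chi-squared approximation with 1 df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# collinearity screening

@dataclass
class ScreenReport:
    """Outcome of the |r| < threshold collinearity screen."""

    threshold: float
    dropped: list[str]
    flagged_pairs: pd.DataFrame  # columns var_a, var_b, spearman_r, reason


def collinearity_screen(env: pd.DataFrame, threshold: float = 0.75,
                        drop_overrides: list[str] | None = None
                        ) -> tuple[pd.DataFrame, ScreenReport]:
    """Flag variable pairs with Spearman |r| ≥ threshold and drop one member.

    With ``drop_overrides`` the caller decides which variables leave (the
    study's choice was ecological: NO3–N derives from TN; Forest is the more
    variable member of the land-use trio). Otherwise variables are removed
    greedily, highest mean |r| against the remaining variables first, until
    no flagged pair remains. Constant variables have undefined correlations
    and are dropped up front.
    """
    df = env.copy()
    records = []
    dropped: list[str] = []

    constant = [c for c in df.columns if df[c].nunique() <= 1]
    for c in constant:
        records.append({"var_a": c, "var_b": "", "spearman_r": np.nan,
                        "reason": "constant variable, correlation undefined"})
        dropped.append(c)
    df = df.drop(columns=constant)

    corr = df.corr(method="spearman")
    pairs = [(a, b, corr.loc[a, b])
             for i, a in enumerate(corr.columns)
             for b in corr.columns[i + 1:]
             if abs(corr.loc[a, b]) >= threshold]
    for a, b, r in pairs:
        records.append({"var_a": a, "var_b": b, "spearman_r": r,
                        "reason": f"|r| >= {threshold}"})

    if drop_overrides is not None:
        missing = set(drop_overrides) - set(env.columns)
        if missing:
            raise ValueError(f"drop_overrides not in table: {sorted(missing)}")
        for v in drop_overrides:
            if v in df.columns:
                dropped.append(v)
                records.append({"var_a": v, "var_b": "", "spearman_r": np.nan,
                                "reason": "drop_overrides"})
        df = df.drop(columns=[v for v in drop_overrides if v in df.columns])
    else:
        remaining = list(df.columns)
        while True:
            sub = corr.loc[remaining, remaining].abs()
            flagged = [(a, b) for i, a in enumerate(remaining)
                       for b in remaining[i + 1:] if sub.loc[a, b] >= threshold]
            if not flagged:
                break
            involved = sorted({v for p in flagged for v in p})
            mean_r = {v: sub.loc[v, [c for c in remaining if c != v]].mean()
                      for v in involved}
            victim = max(mean_r, key=mean_r.get)
            dropped.append(victim)
            records.append({"var_a": victim, "var_b": "", "spearman_r": np.nan,
                            "reason": "highest mean |r| among flagged"})
            remaining.remove(victim)
        df = df[remaining]

    report = ScreenReport(threshold=threshold, dropped=dropped,
                          flagged_pairs=pd.DataFrame(
                              records, columns=["var_a", "var_b",
                                                "spearman_r", "reason"]))
    return df, report


# ---------------------------------------------------------------------------
# Spearman index–environment matrix

@dataclass
class CorrelationReport:
    """Spearman r and two-sided p per (index, variable) pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    row_order: list[str]  # indices, hierarchical-clustering leaf order
    col_order: list[str]  # variables, likewise

    def stars(self) -> pd.DataFrame:
        """Significance marks: '**' p<.01, '*' p<.05, '' otherwise."""
        return self.p.map(lambda p: "**" if p < 0.01 else
                          ("*" if p < 0.05 else ""))


def _cluster_order(mat: pd.DataFrame) -> list[str]:
    """Complete-linkage Euclidean leaf order of the matrix rows."""
    if mat.shape[0] < 3:
        return list(mat.index)
    z = linkage(mat.fillna(0.0).to_numpy(), method="complete",
                metric="euclidean")
    return [mat.index[i] for i in leaves_list(z)]


def spearman_matrix(index_table: pd.DataFrame, env: pd.DataFrame,
                    cluster: bool = True) -> CorrelationReport:
    """Spearman r/p for every index column against every env variable.

    Sites are matched on the shared index; each pair uses its complete
    cases, and pairs with fewer than 3 observations stay undefined.
    """
    shared = index_table.index.intersection(env.index)
    idx = index_table.loc[shared]
    ev = env.loc[shared]
    r = pd.DataFrame(index=idx.columns, columns=ev.columns, dtype=float)
    p = pd.DataFrame(index=idx.columns, columns=ev.columns, dtype=float)
    for icol in idx.columns:
        x = idx[icol]
        for ecol in ev.columns:
            y = ev[ecol]
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                continue
            res = sps.spearmanr(x[ok], y[ok])
            r.loc[icol, ecol] = res.statistic
            p.loc[icol, ecol] = res.pvalue
    row_order = _cluster_order(r) if cluster else list(r.index)
    col_order = _cluster_order(r.T) if cluster else list(r.columns)
    return CorrelationReport(r=r, p=p, row_order=row_order, col_order=col_order)


# ---------------------------------------------------------------------------
# random-forest regression importance

@dataclass
class RFConfig:
    """Random-forest regression settings (cited implementation's defaults).

    ``n_trees`` 500 and ``mtry`` ⌊p/3⌋ (≥1) with terminal nodes of ≥5
    samples mirror the reference regression defaults. ``n_permutations``
    response permutations feed the importance p-values; each null forest
    uses ``null_trees`` trees to keep the null affordable.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 5
    n_permutations: int = 500
    null_trees: int = 100
    seed: int = 0


@dataclass
class ImportanceReport:
    """%IncMSE per predictor, permutation p-values and OOB R² (percent)."""

    importance: pd.DataFrame  # columns pct_inc_mse, p_value
    r2_percent: float
    oob_mse: float
    n_sites: int
    config: RFConfig = field(repr=False, default_factory=RFConfig)


def _fit_oob_forest(X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
                    min_node: int, rng: np.random.Generator,
                    want_importance: bool) -> tuple[float, float, np.ndarray]:
    """Bagged regression trees with out-of-bag bookkeeping.

    Returns (oob_mse, r2_percent, per-predictor mean increase in OOB MSE).
    Importance permutes one predictor at a time within each tree's OOB set;
    the permuted design matrices for all predictors are stacked so each tree
    is queried once.
    """
    n, p = X.shape
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=int)
    inc = np.zeros(p)
    inc_trees = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=mtry, min_samples_leaf=min_node,
            random_state=int(rng.integers(2 ** 31)))
        tree.fit(X[boot], y[boot])
        if len(oob) == 0:
            continue
        pred = tree.predict(X[oob])
        oob_sum[oob] += pred
        oob_cnt[oob] += 1
        if want_importance:
            base_mse = float(np.mean((y[oob] - pred) ** 2))
            m = len(oob)
            stacked = np.tile(X[oob], (p, 1))
            for j in range(p):
                stacked[j * m:(j + 1) * m, j] = rng.permutation(X[oob, j])
            perm_pred = tree.predict(stacked).reshape(p, m)
            perm_mse = np.mean((y[oob][None, :] - perm_pred) ** 2, axis=1)
            inc += perm_mse - base_mse
            inc_trees += 1
    seen = oob_cnt > 0
    oob_pred = oob_sum[seen] / oob_cnt[seen]
    oob_mse = float(np.mean((y[seen] - oob_pred) ** 2))
    r2 = 100.0 * (1.0 - oob_mse / np.var(y, ddof=1))
    mean_inc = inc / max(inc_trees, 1)
    return oob_mse, r2, mean_inc


def rf_importance(index_values: pd.Series, env: pd.DataFrame,
                  config: RFConfig | None = None) -> ImportanceReport:
    """Random-forest regression of one index on the environment table.

    %IncMSE for predictor j is 100 × mean over trees of (OOB MSE with j
    permuted − OOB MSE) / forest OOB MSE, i.e. a literal percent increase in
    out-of-bag error. Its p-value is the upper tail of the same statistic
    recomputed under ``n_permutations`` permutations of the response. R² is
    the out-of-bag percent variance explained (can be negative). Complete
    cases only.
    """
    config = config or RFConfig()
    shared = index_values.index.intersection(env.index)
    y_s = index_values.loc[shared]
    X_df = env.loc[shared]
    ok = y_s.notna() & X_df.notna().all(axis=1)
    y = y_s[ok].to_numpy(dtype=float)
    X = X_df[ok].to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 * p:
        logger.warning("rf_importance: only %d sites for %d predictors", n, p)
    mtry = config.mtry if config.mtry is not None else max(1, p // 3)
    rng = np.random.default_rng(config.seed)

    oob_mse, r2, mean_inc = _fit_oob_forest(
        X, y, config.n_trees, mtry, config.min_node_size, rng,
        want_importance=True)
    pct_inc = 100.0 * mean_inc / oob_mse

    exceed = np.zeros(p)
    for _ in range(config.n_permutations):
        y_perm = rng.permutation(y)
        null_mse, _, null_inc = _fit_oob_forest(
            X, y_perm, config.null_trees, mtry, config.min_node_size, rng,
            want_importance=True)
        null_pct = 100.0 * null_inc / null_mse
        exceed += null_pct >= pct_inc
    p_values = (1.0 + exceed) / (1.0 + config.n_permutations)

    imp = pd.DataFrame({"pct_inc_mse": pct_inc, "p_value": p_values},
                       index=X_df.columns)
    imp.index.name = "variable"
    return ImportanceReport(importance=imp, r2_percent=float(r2),
                            oob_mse=oob_mse, n_sites=n, config=config)


# ---------------------------------------------------------------------------
# Kruskal–Wallis

@dataclass
class GroupTestResult:
    """Two-group Kruskal–Wallis: tie-corrected H, df, chi-squared p."""

    chi_squared: float
    df: int
    p_value: float


def kruskal_wallis(values_a, values_b) -> GroupTestResult:
    """Kruskal–Wallis test between two columns of index values.

    Undefined values are dropped per group; each group needs ≥2 defined
    values. When every pooled value ties, H = 0 and p = 1 by convention.
    """
    a = pd.Series(values_a).dropna().to_numpy(dtype=float)
    b = pd.Series(values_b).dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 defined values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return GroupTestResult(chi_squared=0.0, df=1, p_value=1.0)
    h, p = sps.kruskal(a, b)
    return GroupTestResult(chi_squared=float(h), df=1, p_value=float(p))


def holm_adjust(p_values: pd.Series) -> pd.Series:
    """Holm step-down adjustment (optional; raw p is the default report)."""
    p = p_values.dropna()
    order = np.argsort(p.to_numpy())
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p.iloc[i])
        adj[i] = min(1.0, running)
    out = pd.Series(np.nan, index=p_values.index)
    out.loc[p.index] = adj
    return out
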