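"""Statistics battery against literal-formula oracles and an external
reference random-forest implementation."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from streamhealth.stats import (RFConfig, collinearity_screen, holm_adjust,
                                kruskal_wallis, rf_importance, spearman_matrix)


# ---------------------------------------------------------------------------
# oracles: hand-rolled midranks, Pearson, rank-sum H

def midranks(x):
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson(u, v):
    u = u - u.mean()
    v = v - v.mean()
    return float((u * v).sum() / np.sqrt((u * u).sum() * (v * v).sum()))


def kw_literal(a, b):
    """Tie-corrected two-group Kruskal–Wallis H from the rank-sum formula."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    r = midranks(pooled)
    ra, rb = r[:len(a)], r[len(a):]
    h = (12.0 / (n * (n + 1))
         * (ra.sum() ** 2 / len(a) + rb.sum() ** 2 / len(b))
         - 3.0 * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / correction


# ---------------------------------------------------------------------------
# collinearity screening

def test_screen_drops_one_of_two_identical_columns():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    env = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
    reduced, report = collinearity_screen(env)
    assert set(reduced.columns) == {"a", "c"} or set(reduced.columns) == {"b", "c"}
    assert len(report.dropped) == 1
    assert (report.flagged_pairs["spearman_r"].abs() >= 0.75).any()


def test_screen_passes_everything_below_threshold():
    rng = np.random.default_rng(1)
    env = pd.DataFrame(rng.normal(size=(100, 5)),
                       columns=list("abcde"))
    reduced, report = collinearity_screen(env)
    assert list(reduced.columns) == list("abcde")
    assert report.dropped == []


def test_screen_drops_constant_variables_and_honours_overrides():
    rng = np.random.default_rng(2)
    x = rng.normal(size=60)
    env = pd.DataFrame({"tn": x, "no3": 0.95 * x + 0.05 * rng.normal(size=60),
                        "flat": np.ones(60), "ph": rng.normal(size=60)})
    reduced, report = collinearity_screen(env, drop_overrides=["no3"])
    assert list(reduced.columns) == ["tn", "ph"]
    assert "flat" in report.dropped and "no3" in report.dropped
    with pytest.raises(ValueError):
        collinearity_screen(env, drop_overrides=["nope"])


# ---------------------------------------------------------------------------
# Spearman matrix

def test_spearman_trivial_alignments():
    idx = pd.DataFrame({"i": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
    env = pd.DataFrame({"same": [1.0, 2.0, 3.0, 4.0],
                        "rev": [4.0, 3.0, 2.0, 1.0]}, index=list("abcd"))
    rep = spearman_matrix(idx, env, cluster=False)
    assert rep.r.loc["i", "same"] == pytest.approx(1.0)
    assert rep.r.loc["i", "rev"] == pytest.approx(-1.0)


def test_spearman_equals_pearson_on_midranks_with_ties():
    rng = np.random.default_rng(3)
    x = pd.Series(rng.integers(0, 5, 40).astype(float))  # heavy ties
    y = pd.Series(rng.integers(0, 5, 40).astype(float))
    rep = spearman_matrix(x.to_frame("x"), y.to_frame("y"), cluster=False)
    oracle = pearson(midranks(x), midranks(y))
    assert rep.r.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)


def test_spearman_undefined_below_three_pairs():
    idx = pd.DataFrame({"i": [1.0, 2.0, np.nan, np.nan]}, index=list("abcd"))
    env = pd.DataFrame({"e": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
    rep = spearman_matrix(idx, env, cluster=False)
    assert np.isnan(rep.r.loc["i", "e"])


def test_cluster_orders_are_permutations(sim_tables):
    _, orig, _ = sim_tables
    env = pd.DataFrame(
        np.random.default_rng(0).normal(size=(len(orig), 4)),
        index=orig.index, columns=["a", "b", "c", "d"])
    rep = spearman_matrix(orig[["h_prime", "bmwp", "aspt", "bi", "ept"]], env)
    assert sorted(rep.row_order) == sorted(rep.r.index)
    assert sorted(rep.col_order) == sorted(rep.r.columns)


# ---------------------------------------------------------------------------
# Kruskal–Wallis

def test_kw_identical_groups_and_all_ties():
    same = [1.0, 2.0, 3.0]
    res = kruskal_wallis(same, same)
    assert res.chi_squared == pytest.approx(0.0, abs=1e-12)
    tied = kruskal_wallis([2.0, 2.0], [2.0, 2.0])
    assert (tied.chi_squared, tied.p_value) == (0.0, 1.0)


@pytest.mark.parametrize("a, b", [
    ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
    ([1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 3.0]),
    ([0.0, 0.0, 1.0], [1.0, 1.0, 2.0, 9.0]),
])
def test_kw_matches_literal_rank_sum_formula(a, b):
    res = kruskal_wallis(a, b)
    assert res.df == 1
    assert res.chi_squared == pytest.approx(
        kw_literal(np.array(a), np.array(b)), abs=1e-12)


def test_kw_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=30), rng.normal(1.0, 1.0, size=25)
    h1 = kruskal_wallis(a, b).chi_squared
    h2 = kruskal_wallis(np.exp(a), np.exp(b)).chi_squared
    assert h1 == pytest.approx(h2, abs=1e-12)


def test_kw_equals_squared_rank_sum_z_on_tie_free_data():
    rng = np.random.default_rng(5)
    a, b = rng.normal(size=20), rng.normal(0.8, 1.0, size=24)
    na, nb = len(a), len(b)
    n = na + nb
    ra = midranks(np.concatenate([a, b]))[:na].sum()
    z = (ra - na * (n + 1) / 2.0) / np.sqrt(na * nb * (n + 1) / 12.0)
    assert kruskal_wallis(a, b).chi_squared == pytest.approx(z ** 2, abs=1e-9)


def test_kw_requires_two_values_per_group():
    with pytest.raises(ValueError):
        kruskal_wallis([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# random-forest importance

def test_rf_reproducible_bit_for_bit_under_fixed_seed():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
    y = pd.Series(X["a"] + 0.5 * rng.normal(size=60))
    cfg = RFConfig(n_trees=100, n_permutations=10, null_trees=30, seed=9)
    r1 = rf_importance(y, X, cfg)
    r2 = rf_importance(y, X, cfg)
    pd.testing.assert_frame_equal(r1.importance, r2.importance)
    assert r1.r2_percent == r2.r2_percent


def test_rf_duplicated_predictor_shares_importance():
    """With every feature considered at each split (so duplication cannot
    change the draw probability), a duplicated predictor splits its
    importance between the copies while out-of-bag R² stays put."""
    rng = np.random.default_rng(7)
    cols = [f"n{j}" for j in range(11)] + ["a"]
    X = pd.DataFrame(rng.normal(size=(120, 12)), columns=cols)
    y = pd.Series(2.0 * X["a"] + 0.3 * rng.normal(size=120))
    base = rf_importance(y, X, RFConfig(n_trees=300, n_permutations=0,
                                        seed=1, mtry=12))
    dup = rf_importance(y, X.assign(a2=X["a"]),
                        RFConfig(n_trees=300, n_permutations=0, seed=1,
                                 mtry=13))
    assert abs(base.r2_percent - dup.r2_percent) <= 5.0  # R² ~unchanged
    imp = dup.importance["pct_inc_mse"]
    noise_max = imp.drop(["a", "a2"]).max()
    assert imp["a"] > noise_max and imp["a2"] > noise_max  # both copies used
    assert imp["a"] < base.importance["pct_inc_mse"]["a"]  # importance shared


def test_rf_warns_when_sites_scarce(caplog):
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(10, 6)))
    y = pd.Series(rng.normal(size=10))
    with caplog.at_level("WARNING"):
        rf_importance(y, X, RFConfig(n_trees=20, n_permutations=0, seed=0))
    assert any("predictors" in r.message for r in caplog.records)


def test_rf_agrees_with_reference_implementation_on_planted_signal(tmp_path):
    """Both this forest and R's randomForest must rank the planted
    predictor first in %IncMSE on the same data."""
    rng = np.random.default_rng(12)
    X = pd.DataFrame(rng.normal(size=(90, 5)), columns=list("abcde"))
    y = pd.Series(np.tanh(X["c"]) + 0.25 * rng.normal(size=90), name="y")
    rep = rf_importance(y, X, RFConfig(n_trees=300, n_permutations=0, seed=3))
    assert rep.importance["pct_inc_mse"].idxmax() == "c"

    df = X.assign(y=y)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = (
        f"d <- read.csv('{csv}'); library(randomForest); set.seed(1); "
        "f <- randomForest(y ~ ., data=d, ntree=300, importance=TRUE); "
        "imp <- importance(f, scale=FALSE)[, '%IncMSE']; "
        "cat(names(which.max(imp)))")
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    assert out.stdout.strip() == "c"


def test_holm_adjustment_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    p = pd.Series([0.001, 0.02, 0.04, 0.2, 0.9])
    mine = holm_adjust(p)
    _, ref, _, _ = multipletests(p, method="holm")
    assert np.allclose(mine, ref)
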