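"""Associate indices with environmental variables.

Screens the 21 environment variables at Spearman |r| ≥ 0.75 (dropping NO3-N
in favour of TN and Cropland/Impervious in favour of Forest, mirroring how a
practitioner resolves those pairs ecologically), computes the Spearman
index–environment matrix with clustered display orders, and runs a
random-forest regression per index reporting %IncMSE and permutation
p-values. Writes CSVs under results/assoc/.
"""

from pathlib import Path

import pandas as pd

from streamhealth import collinearity_screen, read_env, rf_importance, \
    spearman_matrix
from streamhealth.indices import INDEX_COLUMNS
from streamhealth.stats import RFConfig

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 42
# problem sizes for the permutation null: 200 response permutations over
# 100-tree null forests keep the driver desk-scale at 147 sites
RF = dict(n_trees=500, n_permutations=200, null_trees=100)
DROP_OVERRIDES = ["NO3N", "Cropland", "Impervious"]


def main() -> None:
    out = ROOT / "assoc"
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(ROOT / "indices.csv", index_col=0)
    env = read_env(ROOT / "sim" / "env.csv").table

    screened, report = collinearity_screen(env, 0.75, DROP_OVERRIDES)
    report.flagged_pairs.to_csv(out / "screening_report.csv", index=False)
    screened.to_csv(out / "env_screened.csv")
    print(f"screen dropped {report.dropped} -> {screened.shape[1]} variables")

    cols = [c for c in table.columns if c.removesuffix("_mod") in INDEX_COLUMNS]
    corr = spearman_matrix(table[cols], screened)
    corr.r.to_csv(out / "correlation_r.csv")
    corr.p.to_csv(out / "correlation_p.csv")
    n_sig = int((corr.p < 0.05).sum().sum())
    print(f"Spearman matrix: {n_sig} of {corr.p.size} pairs significant "
          f"at p<.05")

    rf_rows, rf_sum = [], []
    for i, col in enumerate(cols):
        rep = rf_importance(table[col], env, RFConfig(seed=SEED + i, **RF))
        top = rep.importance["pct_inc_mse"].nlargest(3)
        print(f"  RF {col:12s} OOB R2 {rep.r2_percent:6.2f}%  top: "
              + ", ".join(f"{v} ({top[v]:.1f}%)" for v in top.index))
        for var, row in rep.importance.iterrows():
            rf_rows.append({"index": col, "variable": var, **row.to_dict()})
        rf_sum.append({"index": col, "r2_percent": rep.r2_percent,
                       "n_sites": rep.n_sites})
    pd.DataFrame(rf_rows).to_csv(out / "rf_importance.csv", index=False)
    pd.DataFrame(rf_sum).to_csv(out / "rf_summary.csv", index=False)
    print(f"association reports written to {out}")


if __name__ == "__main__":
    main()
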