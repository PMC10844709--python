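"""Grade river health per site on the five-class criteria.

Summarises, for every index column of results/indices.csv, how many sites
fall in each class (Excellent … Very poor) over the sites where the index is
defined; writes results/grade_summary.csv.
"""

from pathlib import Path

import pandas as pd

from streamhealth import load_schemes, summarize_grades

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(ROOT / "indices.csv", index_col=0)
    schemes = load_schemes()
    rows = []
    for col in table.columns:
        base = col.removesuffix("_mod")
        if base not in schemes:
            continue
        s = summarize_grades(table[col], schemes[base])
        for label, cnt in s.counts.items():
            rows.append({"index": col, "class": label, "count": int(cnt),
                         "percent": round(float(s.percentages[label]), 2),
                         "denominator": s.denominator})
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "grade_summary.csv", index=False)

    wide = out.pivot(index="index", columns="class", values="percent")
    eg = wide["Excellent"] + wide["Good"]
    print("share of sites graded Excellent+Good (percent of defined sites):")
    for idx, v in eg.items():
        print(f"  {idx:12s} {v:6.2f}")
    print(f"grade summary written to {ROOT / 'grade_summary.csv'}")


if __name__ == "__main__":
    main()
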