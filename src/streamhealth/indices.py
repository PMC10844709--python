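"""Per-site bioassessment indices.

Five classic macroinvertebrate indices are computed from a site's specimen
counts and the taxon traits:

* **H′** — Shannon–Wiener diversity, −Σ pᵢ ln pᵢ (natural log by default);
* **BMWP** — sum of pollution-sensitivity scores over the distinct scoring
  families present (presence-based, each family counted once);
* **ASPT** — BMWP divided by the number of scoring families present;
* **BI** — Hilsenhoff's biotic index, the abundance-weighted mean tolerance
  Σ nᵢaᵢ / N over taxa with a known tolerance value;
* **EPT** — number of distinct families of Ephemeroptera, Plecoptera and
  Trichoptera present.

Undefined values (e.g. ASPT at a site with no scoring family, BI at a site
with no tolerance-bearing taxon, H′ at an empty site) are reported as NaN
and propagate to downstream grading, which excludes them from denominators;
they are never silently zero-filled.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .io import EPT_ORDERS, AlignedBundle, ScoreTable, TraitTable

INDEX_COLUMNS = ("h_prime", "bmwp", "aspt", "bi", "ept")


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity of a vector of non-negative counts.

    Natural log by default; ``base`` switches the unit. All-zero input is
    undefined and returns NaN.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    total = a.sum()
    if total == 0:
        return math.nan
    h = float(entropy(a[a > 0]))
    if base is not None:
        h /= math.log(base)
    return h


def ept_richness(site_counts: pd.Series, traits: TraitTable) -> int:
    """Number of distinct E/P/T families with non-zero abundance.

    Family-level deduplication: several genera of one mayfly family count
    once. Taxa without a family record cannot contribute.
    """
    present = site_counts[site_counts > 0].index
    t = traits.table.loc[present]
    is_ept = t["order"].isin(EPT_ORDERS) & t["family"].notna()
    return int(t.loc[is_ept, "family"].nunique())


def bmwp(site_counts: pd.Series, traits: TraitTable,
         scores: ScoreTable) -> tuple[float, int, int]:
    """BMWP score, number of scoring families, number of excluded taxa.

    A family present through any number of taxa contributes its score once.
    Taxa whose family is absent from the score table (or unknown) are
    excluded and tallied.
    """
    present = site_counts[site_counts > 0].index
    t = traits.table.loc[present]
    fams = t["family"]
    scored = fams.isin(scores.scores.index)
    families = fams[scored].unique()
    total = float(scores.scores.loc[families].sum()) if len(families) else 0.0
    n_excluded = int((~scored).sum())
    return total, int(len(families)), n_excluded


def aspt(bmwp_value: float, n_scoring_families: int) -> float:
    """Average score per taxon: BMWP / number of scoring families."""
    if n_scoring_families <= 0:
        return math.nan
    return bmwp_value / n_scoring_families


def hilsenhoff_bi(site_counts: pd.Series, traits: TraitTable,
                  family_fallback: pd.Series | None = None) -> float:
    """Hilsenhoff biotic index Σ nᵢaᵢ / N over tolerance-bearing taxa.

    Taxa lacking a tolerance value are dropped from both numerator and
    denominator. ``family_fallback`` optionally supplies family-level
    tolerances for taxa without their own value.
    """
    present = site_counts[site_counts > 0]
    tol = traits.table.loc[present.index, "tolerance"].copy()
    if family_fallback is not None:
        fams = traits.table.loc[present.index, "family"]
        fill = fams.map(family_fallback)
        tol = tol.fillna(fill)
    known = tol.notna()
    n = present[known].to_numpy(dtype=float)
    a = tol[known].to_numpy(dtype=float)
    if n.sum() == 0:
        return math.nan
    return float((n * a).sum() / n.sum())


def compute_index_table(bundle: AlignedBundle, scores: ScoreTable | None = None,
                        family_fallback: pd.Series | None = None,
                        shannon_base: float | None = None) -> pd.DataFrame:
    """All five indices per site, plus bookkeeping counts.

    Returns a DataFrame indexed by site with columns ``h_prime, bmwp, aspt,
    bi, ept, n_scoring_families, n_excluded_taxa``. Missing values stay NaN.
    """
    if scores is None:
        from .io import read_scores
        scores = read_scores()
    rows = []
    for site_id, counts in bundle.community.counts.iterrows():
        h = shannon(counts.to_numpy(), base=shannon_base)
        b, nfam, nexcl = bmwp(counts, bundle.traits, scores)
        rows.append({
            "h_prime": h,
            "bmwp": b,
            "aspt": aspt(b, nfam),
            "bi": hilsenhoff_bi(counts, bundle.traits, family_fallback),
            "ept": ept_richness(counts, bundle.traits),
            "n_scoring_families": nfam,
            "n_excluded_taxa": nexcl,
        })
    out = pd.DataFrame(rows, index=bundle.community.counts.index)
    out.index.name = "site_id"
    return out
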