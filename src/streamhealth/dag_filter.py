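"""Removal of dispersal-dominated taxa and modified-index computation.

Metacommunity theory distinguishes community assembly by local environmental
filtering (species sorting) from assembly by regional dispersal processes —
dispersal limitation in weak dispersers and mass effects in very strong
ones. Taxa whose occurrence is dominated by dispersal carry little local
environmental signal, so the analysis recomputes every index after removing
whole dispersal ability groups (by default DAG01, weak passive dispersers
with aquatic adults, and DAG04, strong aerial dispersers with flying
adults). Which groups to remove is a configuration parameter; the variance
partitioning that motivates the default lives upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import DAG_CATEGORIES, AlignedBundle, CommunityMatrix, ScoreTable
from .indices import compute_index_table

DEFAULT_REMOVE_GROUPS = frozenset({"DAG01", "DAG04"})


@dataclass
class FilterSpec:
    """Which dispersal ability groups to drop, and what was dropped."""

    remove_groups: frozenset[str] = DEFAULT_REMOVE_GROUPS
    removed_taxa: list[str] = field(default_factory=list)
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.remove_groups = frozenset(self.remove_groups)
        bad = self.remove_groups - set(DAG_CATEGORIES)
        if bad:
            raise ValueError(f"unknown DAG groups {sorted(bad)}; "
                             f"'unknown' taxa are never removed")


def filter_by_dag(community: CommunityMatrix, traits, spec: FilterSpec) -> CommunityMatrix:
    """Drop taxon columns whose DAG is in ``spec.remove_groups``.

    Sites are always retained, even if every taxon at a site is removed
    (their modified indices become undefined downstream). Taxa with an
    unknown DAG are never removed. ``spec`` is updated in place with the
    resolved removal list.
    """
    dag = traits.table["dag"].reindex(community.taxon_ids)
    drop = dag.index[dag.isin(spec.remove_groups)]
    spec.removed_taxa = list(drop)
    spec.n_removed = len(drop)
    kept = community.counts.drop(columns=drop)
    return CommunityMatrix(kept)


def modified_index_table(bundle: AlignedBundle, spec: FilterSpec | None = None,
                         scores: ScoreTable | None = None,
                         family_fallback: pd.Series | None = None,
                         shannon_base: float | None = None) -> pd.DataFrame:
    """Indices recomputed on the DAG-filtered matrix; columns suffixed _mod."""
    if spec is None:
        spec = FilterSpec()
    filtered = filter_by_dag(bundle.community, bundle.traits, spec)
    sub = AlignedBundle(community=filtered, traits=bundle.traits,
                        env=bundle.env, unscored_taxa=bundle.unscored_taxa)
    table = compute_index_table(sub, scores=scores,
                                family_fallback=family_fallback,
                                shannon_base=shannon_base)
    return table.add_suffix("_mod")
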