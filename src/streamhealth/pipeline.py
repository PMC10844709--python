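"""End-to-end orchestration: indices → filter → grading → comparison stats.

``run_all`` reproduces the full workflow on either a simulated bundle or
user-supplied CSV tables, writing every report as CSV plus a JSON manifest
(seed, config hash, package version, bookkeeping counts) so a run is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dag_filter import DEFAULT_REMOVE_GROUPS, FilterSpec, modified_index_table
from .grading import load_schemes, summarize_grades
from .indices import INDEX_COLUMNS, compute_index_table
from .io import (AlignedBundle, align, read_community, read_env,
                 read_family_tolerances, read_scores, read_traits)
from .simulate import SimulationConfig, SyntheticBundle, simulate
from .stats import (RFConfig, collinearity_screen, kruskal_wallis,
                    rf_importance, spearman_matrix)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: either input paths or a simulation config."""

    community_path: str | None = None
    traits_path: str | None = None
    env_path: str | None = None
    scores_path: str | None = None
    scheme_path: str | None = None
    simulation: SimulationConfig | None = None
    remove_groups: frozenset[str] = DEFAULT_REMOVE_GROUPS
    family_fallback: bool = False
    screen_threshold: float = 0.75
    drop_overrides: list[str] | None = None
    rf: RFConfig = field(default_factory=RFConfig)
    seed: int = 0
    out_dir: str = "results/run"

    def digest(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=default,
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_bundle(cfg: RunConfig) -> tuple[AlignedBundle, SyntheticBundle | None]:
    if cfg.simulation is not None:
        sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        bundle = simulate(sim_cfg)
        return bundle.aligned(), bundle
    if not (cfg.community_path and cfg.traits_path):
        raise ValueError("need community and trait tables, or a simulation "
                         "config")
    community = read_community(cfg.community_path)
    traits = read_traits(cfg.traits_path)
    env = read_env(cfg.env_path) if cfg.env_path else None
    return align(community, traits, env), None


def compute_all_indices(bundle: AlignedBundle, cfg: RunConfig
                        ) -> tuple[pd.DataFrame, FilterSpec]:
    """Original and modified index tables side by side."""
    scores = read_scores(cfg.scores_path)
    fallback = read_family_tolerances() if cfg.family_fallback else None
    spec = FilterSpec(remove_groups=cfg.remove_groups)
    orig = compute_index_table(bundle, scores=scores, family_fallback=fallback)
    mod = modified_index_table(bundle, spec, scores=scores,
                               family_fallback=fallback)
    return orig.join(mod), spec


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write CSV reports under ``cfg.out_dir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, sim = _load_bundle(cfg)

    if sim is not None:
        sim.community.counts.to_csv(out / "community.csv")
        sim.traits.table.to_csv(out / "traits.csv")
        sim.env.table.to_csv(out / "env.csv")
        sim.coords.to_csv(out / "coords.csv")

    index_table, spec = compute_all_indices(bundle, cfg)
    index_table.to_csv(out / "indices.csv")

    schemes = load_schemes(cfg.scheme_path)
    grade_rows = []
    for name in INDEX_COLUMNS:
        for col in (name, f"{name}_mod"):
            summary = summarize_grades(index_table[col], schemes[name])
            for label, cnt in summary.counts.items():
                grade_rows.append({"index": col, "class": label,
                                   "count": int(cnt),
                                   "percent": summary.percentages[label],
                                   "denominator": summary.denominator})
    grades = pd.DataFrame(grade_rows)
    grades.to_csv(out / "grade_summary.csv", index=False)

    results: dict = {"indices": index_table, "grades": grades,
                     "filter_spec": spec}

    if bundle.env is not None:
        screened, screen_report = collinearity_screen(
            bundle.env.table, threshold=cfg.screen_threshold,
            drop_overrides=cfg.drop_overrides)
        screened.to_csv(out / "env_screened.csv")
        screen_report.flagged_pairs.to_csv(out / "screening_report.csv",
                                           index=False)

        index_cols = [c for c in index_table.columns
                      if c.split("_mod")[0] in INDEX_COLUMNS]
        corr = spearman_matrix(index_table[index_cols], screened)
        corr.r.to_csv(out / "correlation_r.csv")
        corr.p.to_csv(out / "correlation_p.csv")

        rf_rows, rf_summary = [], []
        for i, col in enumerate(index_cols):
            rep = rf_importance(index_table[col], bundle.env.table,
                                dataclasses.replace(cfg.rf,
                                                    seed=cfg.seed + i))
            for var, row in rep.importance.iterrows():
                rf_rows.append({"index": col, "variable": var,
                                "pct_inc_mse": row["pct_inc_mse"],
                                "p_value": row["p_value"]})
            rf_summary.append({"index": col, "r2_percent": rep.r2_percent,
                               "n_sites": rep.n_sites})
        pd.DataFrame(rf_rows).to_csv(out / "rf_importance.csv", index=False)
        pd.DataFrame(rf_summary).to_csv(out / "rf_summary.csv", index=False)

        results.update(screen_report=screen_report, correlation=corr,
                       rf_summary=pd.DataFrame(rf_summary))

    kw_rows = []
    for name in INDEX_COLUMNS:
        res = kruskal_wallis(index_table[name], index_table[f"{name}_mod"])
        kw_rows.append({"index": name, "chi_squared": res.chi_squared,
                        "df": res.df, "p_value": res.p_value})
    kw = pd.DataFrame(kw_rows)
    kw.to_csv(out / "kruskal_wallis.csv", index=False)
    results["kruskal_wallis"] = kw

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "n_sites": len(bundle.community.site_ids),
        "n_taxa": len(bundle.community.taxon_ids),
        "n_removed_taxa": spec.n_removed,
        "removed_groups": sorted(spec.remove_groups),
        "n_unscored_taxa": len(bundle.unscored_taxa),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    results["manifest"] = manifest
    return results
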