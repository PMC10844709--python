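"""Typed readers, writers and validation for the four input tables.

The analysis consumes four delimited-text tables:

* a site × taxon **community matrix** of specimen counts,
* a **trait table** mapping each taxon to family, order, dispersal ability
  group (DAG) and a pollution tolerance value,
* a **BMWP score table** mapping families to pollution-sensitivity scores,
* a site × variable **environment table**.

All tables are plain CSV/TSV with a header row; the first column holds the
row identifier. Two reference resources ship with the package: the original
UK BMWP family scores and a family-level tolerance table, both overridable
by passing an explicit path to the corresponding reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised dispersal ability groups, ordered from weak passive dispersers
#: with fully aquatic adults (DAG01) to strong aerial dispersers (DAG04).
DAG_CATEGORIES: tuple[str, ...] = ("DAG01", "DAG02", "DAG03", "DAG04")

#: Sentinel used for taxa whose dispersal group is not recognised.
DAG_UNKNOWN = "unknown"

#: Orders contributing to the EPT index.
EPT_ORDERS = frozenset({"Ephemeroptera", "Plecoptera", "Trichoptera"})

#: Environment-table columns expressed as percentages.
PERCENT_COLUMNS = ("QHEI", "Forest", "Cropland", "Shrubs", "Grassland",
                   "Water", "Impervious")

#: Canonical 21 environment variable codes.
ENV_COLUMNS = ("Width", "Depth", "Velocity", "pH", "WT", "Cond", "CODMn",
               "NH3N", "NO3N", "TN", "TP", "QHEI", "Elevation", "Slope",
               "Aspect", "Forest", "Cropland", "Shrubs", "Grassland",
               "Water", "Impervious")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(values, what: str) -> None:
    dupes = pd.Index(values)[pd.Index(values).duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate {what}: {list(dupes)[:5]}")


@dataclass
class CommunityMatrix:
    """Site × taxon specimen counts (non-negative integers)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        # ≥1 taxon is enforced at read time; DAG filtering may empty a matrix
        if df.shape[0] < 1:
            raise ValidationError("community matrix needs ≥1 site")
        _check_unique(df.index, "site ids")
        _check_unique(df.columns, "taxon ids")
        if df.isna().any().any():
            raise ValidationError("community matrix has missing cells; counts "
                                  "must be explicit (0 is allowed)")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("community matrix has non-numeric cells")
        if (arr < 0).any():
            raise ValidationError("negative counts in community matrix")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("non-integer counts in community matrix")
        self.counts = df.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.index.name = "site_id"
        self.counts.columns = self.counts.columns.astype(str)
        self.counts.columns.name = "taxon_id"

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class TraitTable:
    """Per-taxon family, order, dispersal group and tolerance value."""

    table: pd.DataFrame  # index taxon_id; columns family, order, dag, tolerance

    def __post_init__(self) -> None:
        df = self.table
        required = {"family", "order", "dag", "tolerance"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"trait table missing columns {sorted(missing)}")
        _check_unique(df.index, "taxon ids in trait table")
        bad_dag = ~df["dag"].isin(DAG_CATEGORIES + (DAG_UNKNOWN,))
        if bad_dag.any():
            unknown = sorted(df.loc[bad_dag, "dag"].unique())
            logger.warning("unrecognised DAG categories %s mapped to %r",
                           unknown, DAG_UNKNOWN)
            df = df.copy()
            df.loc[bad_dag, "dag"] = DAG_UNKNOWN
        tol = pd.to_numeric(df["tolerance"], errors="coerce")
        stated = df["tolerance"].notna()
        if (tol[stated].isna()).any():
            raise ValidationError("non-numeric tolerance values")
        out_of_range = stated & ((tol < 0) | (tol > 10))
        if out_of_range.any():
            raise ValidationError(
                f"tolerance outside [0, 10] for {list(df.index[out_of_range])[:5]}")
        df = df.copy()
        df["tolerance"] = tol
        df.index = df.index.astype(str)
        df.index.name = "taxon_id"
        self.table = df


@dataclass
class ScoreTable:
    """BMWP pollution-sensitivity score per family, integers in [1, 10]."""

    scores: pd.Series  # index family -> int score

    def __post_init__(self) -> None:
        s = self.scores
        _check_unique(s.index, "families in score table")
        if s.isna().any():
            raise ValidationError("missing BMWP scores")
        vals = pd.to_numeric(s, errors="coerce")
        if vals.isna().any() or not np.allclose(vals, np.round(vals)):
            raise ValidationError("BMWP scores must be integers")
        if ((vals < 1) | (vals > 10)).any():
            raise ValidationError("BMWP scores must lie in [1, 10]")
        s = vals.astype(int)
        s.index = s.index.astype(str)
        s.index.name = "family"
        s.name = "bmwp_score"
        self.scores = s


@dataclass
class EnvironmentTable:
    """Per-site environmental variables; no missing values allowed."""

    table: pd.DataFrame  # index site_id

    def __post_init__(self) -> None:
        df = self.table
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("environment table is empty")
        _check_unique(df.index, "site ids in environment table")
        _check_unique(df.columns, "environment variables")
        if df.isna().any().any():
            raise ValidationError("missing environment values are not allowed")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("environment table has non-numeric cells")
        for col in PERCENT_COLUMNS:
            if col in df.columns:
                v = df[col]
                if ((v < 0) | (v > 100)).any():
                    raise ValidationError(f"{col} outside [0, 100]")
        df = df.copy()
        df.index = df.index.astype(str)
        df.index.name = "site_id"
        self.table = df


@dataclass
class AlignedBundle:
    """Community, trait and environment tables restricted to common sites.

    Taxa present in the community but absent from the trait table are kept
    and flagged ``unscored`` (family/order missing, dag ``unknown``).
    """

    community: CommunityMatrix
    traits: TraitTable
    env: EnvironmentTable | None = None
    unscored_taxa: list[str] = field(default_factory=list)
    n_sites_dropped: int = 0


# ---------------------------------------------------------------------------
# readers / writers

def _read_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    sep = {None: None, "csv": ",", "tsv": "\t"}.get(dialect, dialect)
    return pd.read_csv(path, sep=sep, engine="python", index_col=0,
                       comment="#", skipinitialspace=True)


def _check_header_unique(path: str | Path, dialect: str | None,
                         what: str) -> None:
    # pandas silently renames duplicated header columns, so inspect them raw
    header = pd.read_csv(path, sep={None: None, "csv": ",",
                                    "tsv": "\t"}.get(dialect, dialect),
                         engine="python", comment="#", header=None, nrows=1,
                         skipinitialspace=True).iloc[0, 1:]
    _check_unique(header, what)


def read_community(path: str | Path, dialect: str | None = None) -> CommunityMatrix:
    """Read a site × taxon count table (first column = site id)."""
    _check_header_unique(path, dialect, "taxon columns")
    df = _read_table(path, dialect)
    if df.shape[1] < 1:
        raise ValidationError("community matrix needs ≥1 taxon column")
    return CommunityMatrix(df)


def read_traits(path: str | Path, dialect: str | None = None) -> TraitTable:
    """Read a taxon trait table (columns family, order, dag, tolerance)."""
    df = _read_table(path, dialect)
    if "tolerance" not in df.columns:
        df["tolerance"] = np.nan
    return TraitTable(df)


def read_scores(path: str | Path | None = None,
                dialect: str | None = None) -> ScoreTable:
    """Read a BMWP family score table; defaults to the packaged UK scores."""
    if path is None:
        path = resources.files(__package__) / "data" / "bmwp_scores.tsv"
    df = _read_table(path, dialect)
    return ScoreTable(df["bmwp_score"])


def read_family_tolerances(path: str | Path | None = None,
                           dialect: str | None = None) -> pd.Series:
    """Family-level tolerance fallback table (packaged by default)."""
    if path is None:
        path = resources.files(__package__) / "data" / "family_tolerances.tsv"
    df = _read_table(path, dialect)
    s = pd.to_numeric(df["tolerance"])
    if ((s < 0) | (s > 10)).any():
        raise ValidationError("family tolerance outside [0, 10]")
    s.index = s.index.astype(str)
    return s


def read_env(path: str | Path, dialect: str | None = None) -> EnvironmentTable:
    """Read a site × variable environment table."""
    _check_header_unique(path, dialect, "environment variable columns")
    return EnvironmentTable(_read_table(path, dialect))


def write_community(cm: CommunityMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path)


def write_traits(tt: TraitTable, path: str | Path) -> None:
    tt.table.to_csv(path)


def write_scores(st: ScoreTable, path: str | Path) -> None:
    st.scores.to_frame().to_csv(path)


def write_env(et: EnvironmentTable, path: str | Path) -> None:
    et.table.to_csv(path)


# ---------------------------------------------------------------------------
# alignment

def align(community: CommunityMatrix, traits: TraitTable,
          env: EnvironmentTable | None = None) -> AlignedBundle:
    """Align the three tables on shared sites and the community's taxa.

    Counts are never altered: sites present in only one table are dropped
    (logged), and taxa missing from the trait table are retained but flagged
    unscored so downstream indices can exclude them explicitly.
    """
    sites = pd.Index(community.site_ids)
    if env is not None:
        shared = sites.intersection(env.table.index)
        if len(shared) == 0:
            raise ValidationError("no sites shared between community and "
                                  "environment tables")
        n_dropped = (len(sites) - len(shared)) + (len(env.table) - len(shared))
        if n_dropped:
            logger.info("align: dropped %d unmatched site rows", n_dropped)
        community = CommunityMatrix(community.counts.loc[shared])
        env = EnvironmentTable(env.table.loc[shared])
    else:
        n_dropped = 0

    taxa = pd.Index(community.taxon_ids)
    missing = taxa.difference(traits.table.index)
    aligned = traits.table.reindex(taxa)
    aligned["dag"] = aligned["dag"].fillna(DAG_UNKNOWN)
    if len(missing):
        logger.info("align: %d taxa lack trait records and are flagged "
                    "unscored", len(missing))
    tt = TraitTable(aligned)
    return AlignedBundle(community=community, traits=tt, env=env,
                         unscored_taxa=sorted(missing),
                         n_sites_dropped=n_dropped)
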