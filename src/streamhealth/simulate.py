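"""Seeded synthetic metacommunity generator.

The generator emulates the data structure the analysis assumes: ~147 stream
sites on a plane, ~147 taxa in four dispersal ability groups, and two latent
environmental axes — an "elevation-like" axis that follows the spatial
layout and an independent "pollution-like" water-quality axis. Expected
abundances follow Gaussian niche responses on both axes (species sorting).
Two groups are then corrupted by dispersal processes:

* **DAG01** (weak passive dispersers, aquatic adults) suffer dispersal
  limitation: expected abundance is multiplied by a distance-decay kernel
  ``exp(−d/λ)`` from a per-taxon source locus, so occupancy is spatially
  structured beyond the environment.
* **DAG04** (strong aerial dispersers) experience mass effects: expected
  abundance is a mixture ``(1−w)·niche + w·field`` where the field is a
  spatially smooth surface independent of the environment, so occurrence is
  partially decoupled from local conditions.

Pollution optima are skewed toward clean conditions (most macroinvertebrate
taxa are pollution sensitive), so richness, diversity and the tolerance
composition all degrade along the pollution axis, which is what the biotic
indices are designed to detect. Taxon tolerance values are an affine map of
the pollution optimum into [0, 10] plus noise. Observed counts are Poisson
(optionally negative-binomial) draws around expected abundance.

The latent axes are embedded into named environment variables with realistic
loadings (water-quality chemistry on the pollution axis, terrain and land
use on the elevation axis, NO3–N derived from TN and Cropland/Impervious
from Forest so the collinearity screen has work to do), and the remaining
variables are pure-noise decoys scaled to field-plausible ranges. Ground
truth (axes, niche parameters, loadings) travels with the bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grading import load_schemes
from .io import (AlignedBundle, CommunityMatrix, EnvironmentTable, TraitTable,
                 align)

# family pools per dispersal ability group: (family, order)
_DAG_FAMILY_POOLS: dict[str, tuple[tuple[str, str], ...]] = {
    # weak passive dispersers with aquatic adults: molluscs, worms, crustaceans
    "DAG01": (("Gammaridae", "Amphipoda"), ("Asellidae", "Isopoda"),
              ("Lymnaeidae", "Gastropoda"), ("Physidae", "Gastropoda"),
              ("Planorbidae", "Gastropoda"), ("Hydrobiidae", "Gastropoda"),
              ("Viviparidae", "Gastropoda"), ("Ancylidae", "Gastropoda"),
              ("Sphaeriidae", "Bivalvia"), ("Unionidae", "Bivalvia"),
              ("Glossiphoniidae", "Rhynchobdellida"),
              ("Erpobdellidae", "Arhynchobdellida"),
              ("Oligochaeta", "Haplotaxida"), ("Planariidae", "Tricladida")),
    # weak aerial dispersers with flying adults: mayflies, stoneflies, caddis
    "DAG02": (("Baetidae", "Ephemeroptera"), ("Heptageniidae", "Ephemeroptera"),
              ("Leptophlebiidae", "Ephemeroptera"),
              ("Ephemerellidae", "Ephemeroptera"),
              ("Ephemeridae", "Ephemeroptera"), ("Caenidae", "Ephemeroptera"),
              ("Potamanthidae", "Ephemeroptera"),
              ("Siphlonuridae", "Ephemeroptera"),
              ("Perlidae", "Plecoptera"), ("Perlodidae", "Plecoptera"),
              ("Nemouridae", "Plecoptera"), ("Leuctridae", "Plecoptera"),
              ("Capniidae", "Plecoptera"), ("Chloroperlidae", "Plecoptera"),
              ("Hydropsychidae", "Trichoptera"),
              ("Rhyacophilidae", "Trichoptera"),
              ("Leptoceridae", "Trichoptera"),
              ("Philopotamidae", "Trichoptera"),
              ("Polycentropodidae", "Trichoptera"),
              ("Lepidostomatidae", "Trichoptera"),
              ("Brachycentridae", "Trichoptera")),
    # intermediate aerial dispersers: true flies, riffle beetles
    "DAG03": (("Chironomidae", "Diptera"), ("Simuliidae", "Diptera"),
              ("Tipulidae", "Diptera"), ("Ceratopogonidae", "Diptera"),
              ("Elmidae", "Coleoptera"), ("Hydrophilidae", "Coleoptera")),
    # strong aerial dispersers: dragonflies, bugs, swimming beetles
    "DAG04": (("Gomphidae", "Odonata"), ("Libellulidae", "Odonata"),
              ("Coenagrionidae", "Odonata"), ("Aeshnidae", "Odonata"),
              ("Calopterygidae", "Odonata"), ("Dytiscidae", "Coleoptera"),
              ("Gyrinidae", "Coleoptera"), ("Haliplidae", "Coleoptera"),
              ("Corixidae", "Hemiptera"), ("Gerridae", "Hemiptera"),
              ("Nepidae", "Hemiptera")),
}

# field-plausible (mean, sd, min, max) per environment variable, used to put
# simulated z-scores on the scale of real monitoring data
_ENV_SCALE = {
    "Width": (13.2, 15.0, 1.2, 105.0), "Depth": (24.9, 11.9, 9.0, 80.0),
    "Velocity": (0.41, 0.20, 0.01, 1.07), "pH": (7.65, 0.8, 5.5, 9.5),
    "WT": (17.2, 2.0, 7.9, 23.3), "Cond": (167.0, 84.8, 14.0, 363.0),
    "CODMn": (1.12, 0.36, 0.48, 2.64), "NH3N": (0.11, 0.04, 0.03, 0.40),
    "NO3N": (1.02, 0.55, 0.21, 3.40), "TN": (1.80, 0.60, 0.81, 4.20),
    "TP": (0.05, 0.05, 0.01, 0.51), "QHEI": (65.7, 9.2, 31.9, 80.8),
    "Elevation": (270.9, 131.5, 102.0, 648.0), "Slope": (11.0, 8.4, 0.2, 33.2),
    "Aspect": (200.4, 106.6, 3.7, 358.7), "Forest": (96.1, 6.6, 59.8, 100.0),
    "Cropland": (3.5, 6.1, 0.0, 38.4), "Shrubs": (0.01, 0.03, 0.0, 0.25),
    "Grassland": (0.02, 0.05, 0.0, 0.26), "Water": (0.06, 0.24, 0.0, 2.12),
    "Impervious": (0.35, 0.66, 0.0, 4.49),
}

# loadings of named variables on the latent axes (q = pollution, e = elevation)
_POLLUTION_LOADINGS = {"Cond": 0.80, "CODMn": 0.80, "NH3N": 0.70,
                       "TN": 0.85, "TP": 0.70}
_ELEVATION_LOADINGS = {"Elevation": 0.90, "Slope": 0.60, "WT": -0.50}
_DECOYS = ("Width", "Depth", "Velocity", "pH", "QHEI", "Aspect", "Shrubs",
           "Grassland", "Water")


@dataclass
class SimulationConfig:
    """Study-scale defaults: 147 sites, 49/70/11/17 taxa per DAG group.

    ``mass_effect_weight`` (w) is the DAG04 mixing weight between the niche
    response and an environment-independent smooth field; ``dispersal_lambda``
    (λ) is the DAG01 distance-decay scale on the unit-square site layout
    (np.inf disables dispersal limitation). Pollution optima are drawn
    uniformly on ``pollution_opt_range``, skewed low because most taxa are
    pollution sensitive; tolerance is the affine image of the optimum in
    [0, 10] plus Gaussian noise.
    """

    n_sites: int = 147
    n_taxa_per_dag: tuple[int, int, int, int] = (49, 70, 11, 17)
    niche_breadth: float = 0.75
    pollution_opt_range: tuple[float, float] = (-3.0, 1.5)
    elevation_opt_range: tuple[float, float] = (-2.5, 2.5)
    base_abundance_log_mean: float = math.log(2.0)
    base_abundance_log_sd: float = 1.0
    dispersal_lambda: float = 0.2
    mass_effect_weight: float = 0.9
    mass_effect_range: float = 0.3
    mass_effect_bumps: int = 5
    tolerance_noise_sd: float = 1.2
    tolerance_missing_frac: float = 0.10
    effort: float = 1.0
    overdispersion: float | None = None  # NB size; None -> Poisson counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2 or any(k < 0 for k in self.n_taxa_per_dag):
            raise ValueError("need ≥2 sites and non-negative taxon counts")
        for name in ("niche_breadth", "dispersal_lambda", "mass_effect_range",
                     "effort"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.mass_effect_weight <= 1.0:
            raise ValueError("mass_effect_weight must lie in [0, 1]")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion (NB size) must be > 0")


@dataclass
class SyntheticBundle:
    """Simulated tables plus the generating ground truth."""

    community: CommunityMatrix
    traits: TraitTable
    env: EnvironmentTable
    coords: pd.DataFrame          # site x, y on the unit square
    truth: dict = field(repr=False, default_factory=dict)

    def aligned(self) -> AlignedBundle:
        return align(self.community, self.traits, self.env)


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def _scale_env(name: str, z: np.ndarray) -> np.ndarray:
    mean, sd, lo, hi = _ENV_SCALE[name]
    return np.clip(mean + sd * z, lo, hi)


def simulate(config: SimulationConfig | None = None) -> SyntheticBundle:
    """Draw one synthetic bundle; identical seeds give identical bundles."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites

    coords = rng.uniform(0.0, 1.0, size=(n, 2))
    elev = _standardize(coords.sum(axis=1) + 0.4 * rng.normal(size=n))
    poll = _standardize(rng.normal(size=n))

    # taxon roster
    records = []
    for dag, n_taxa in zip(("DAG01", "DAG02", "DAG03", "DAG04"),
                           cfg.n_taxa_per_dag):
        pool = _DAG_FAMILY_POOLS[dag]
        picks = rng.integers(0, len(pool), n_taxa)
        per_family_counter: dict[str, int] = {}
        for k in picks:
            fam, order = pool[k]
            per_family_counter[fam] = per_family_counter.get(fam, 0) + 1
            records.append({"taxon_id": f"{fam}_sp{per_family_counter[fam]:02d}",
                            "family": fam, "order": order, "dag": dag})
    taxa = pd.DataFrame(records).set_index("taxon_id")
    n_taxa = len(taxa)

    qlo, qhi = cfg.pollution_opt_range
    elo, ehi = cfg.elevation_opt_range
    mu_q = rng.uniform(qlo, qhi, n_taxa)
    mu_e = rng.uniform(elo, ehi, n_taxa)
    a0 = rng.lognormal(cfg.base_abundance_log_mean,
                       cfg.base_abundance_log_sd, n_taxa)

    sig2 = 2.0 * cfg.niche_breadth ** 2
    niche = (a0[None, :]
             * np.exp(-(poll[:, None] - mu_q[None, :]) ** 2 / sig2)
             * np.exp(-(elev[:, None] - mu_e[None, :]) ** 2 / sig2))

    lam = niche.copy()
    dag_arr = taxa["dag"].to_numpy()

    # DAG01: dispersal limitation, distance decay from a random source locus
    idx01 = np.flatnonzero(dag_arr == "DAG01")
    loci = rng.uniform(0.0, 1.0, size=(len(idx01), 2))
    if len(idx01):
        d = np.linalg.norm(coords[:, None, :] - loci[None, :, :], axis=2)
        lam[:, idx01] *= np.exp(-d / cfg.dispersal_lambda)

    # DAG04: mass effect, mix with an environment-independent smooth field
    idx04 = np.flatnonzero(dag_arr == "DAG04")
    w = cfg.mass_effect_weight
    for j in idx04:
        centers = rng.uniform(0.0, 1.0, size=(cfg.mass_effect_bumps, 2))
        gains = rng.exponential(1.0, cfg.mass_effect_bumps)
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        fld = (gains[None, :]
               * np.exp(-d2 / (2.0 * cfg.mass_effect_range ** 2))).sum(axis=1)
        fld = fld / fld.mean() * niche[:, j].mean() if fld.mean() > 0 else fld
        lam[:, j] = (1.0 - w) * niche[:, j] + w * fld

    mean_counts = cfg.effort * lam
    if cfg.overdispersion is None:
        counts = rng.poisson(mean_counts)
    else:
        k = cfg.overdispersion
        p = k / (k + np.maximum(mean_counts, 1e-12))
        counts = rng.negative_binomial(k, p)

    site_ids = [f"site{i + 1:03d}" for i in range(n)]
    community = CommunityMatrix(pd.DataFrame(counts, index=site_ids,
                                             columns=taxa.index))

    # tolerance: affine image of the pollution optimum in [0, 10] + noise
    tol_true = 10.0 * (mu_q - qlo) / (qhi - qlo)
    tol = np.clip(tol_true + rng.normal(0.0, cfg.tolerance_noise_sd, n_taxa),
                  0.0, 10.0)
    missing = rng.uniform(size=n_taxa) < cfg.tolerance_missing_frac
    tol_obs = tol.copy()
    tol_obs[missing] = np.nan
    traits = TraitTable(taxa.assign(tolerance=tol_obs))

    # environment table: loaded proxies + collinear derivatives + decoys
    env_cols: dict[str, np.ndarray] = {}
    for name, load in _POLLUTION_LOADINGS.items():
        z = load * poll + math.sqrt(1 - load ** 2) * rng.normal(size=n)
        env_cols[name] = _scale_env(name, z)
    for name, load in _ELEVATION_LOADINGS.items():
        z = load * elev + math.sqrt(1 - abs(load) ** 2) * rng.normal(size=n)
        env_cols[name] = _scale_env(name, z)
    # NO3-N derives from TN (r ≈ .9), as in real nitrogen chemistry
    tn_z = _standardize(env_cols["TN"])
    env_cols["NO3N"] = _scale_env("NO3N", 0.95 * tn_z
                                  + 0.31 * rng.normal(size=n))
    # land use: Forest responds to both axes; Cropland/Impervious mirror it
    forest_z = _standardize(0.6 * elev - 0.45 * poll + 0.4 * rng.normal(size=n))
    env_cols["Forest"] = _scale_env("Forest", forest_z)
    env_cols["Cropland"] = _scale_env("Cropland",
                                      -0.85 * forest_z
                                      + 0.53 * rng.normal(size=n))
    env_cols["Impervious"] = _scale_env("Impervious",
                                        -0.80 * forest_z
                                        + 0.60 * rng.normal(size=n))
    for name in _DECOYS:
        env_cols[name] = _scale_env(name, rng.normal(size=n))

    from .io import ENV_COLUMNS
    env = EnvironmentTable(pd.DataFrame({c: env_cols[c] for c in ENV_COLUMNS},
                                        index=site_ids))

    coords_df = pd.DataFrame(coords, index=site_ids, columns=["x", "y"])
    coords_df.index.name = "site_id"
    truth = {
        "pollution_axis": pd.Series(poll, index=site_ids, name="pollution"),
        "elevation_axis": pd.Series(elev, index=site_ids, name="elevation"),
        "taxon_params": pd.DataFrame({"mu_pollution": mu_q,
                                      "mu_elevation": mu_e,
                                      "base_abundance": a0,
                                      "tolerance_true": tol,
                                      "dag": dag_arr}, index=taxa.index),
        "pollution_loadings": dict(_POLLUTION_LOADINGS),
        "elevation_loadings": dict(_ELEVATION_LOADINGS),
        "config": cfg,
    }
    return SyntheticBundle(community=community, traits=traits, env=env,
                           coords=coords_df, truth=truth)


# ---------------------------------------------------------------------------
# hand-checkable fixtures

def _toy_bundle(taxa_rows: list[dict], counts: list[int]) -> AlignedBundle:
    taxa = pd.DataFrame(taxa_rows).set_index("taxon_id")
    community = CommunityMatrix(pd.DataFrame([counts], index=["S1"],
                                             columns=taxa.index))
    return align(community, TraitTable(taxa))


def make_fixture(kind: str):
    """Tiny worked datasets with pre-computed expected values.

    ``bi_toy``/``ept_toy``/``bmwp_toy`` return ``(AlignedBundle, expected)``
    where ``expected`` maps index names to the hand-computed values;
    ``grading_edges`` returns a DataFrame of boundary values with their
    expected classes under the packaged scheme.
    """
    if kind == "bi_toy":
        bundle = _toy_bundle(
            [{"taxon_id": "Baetis_sp", "family": "Baetidae",
              "order": "Ephemeroptera", "dag": "DAG02", "tolerance": 2.0},
             {"taxon_id": "Hydropsyche_sp", "family": "Hydropsychidae",
              "order": "Trichoptera", "dag": "DAG02", "tolerance": 6.0}],
            [10, 30])
        return bundle, {"bi": 5.0}
    if kind == "ept_toy":
        bundle = _toy_bundle(
            [{"taxon_id": "Baetis_sp", "family": "Baetidae",
              "order": "Ephemeroptera", "dag": "DAG02", "tolerance": 4.0},
             {"taxon_id": "Perla_sp", "family": "Perlidae",
              "order": "Plecoptera", "dag": "DAG02", "tolerance": 1.0},
             {"taxon_id": "Hydropsyche_sp", "family": "Hydropsychidae",
              "order": "Trichoptera", "dag": "DAG02", "tolerance": 4.0},
             {"taxon_id": "Chironomus_sp", "family": "Chironomidae",
              "order": "Diptera", "dag": "DAG03", "tolerance": 7.0}],
            [5, 2, 3, 40])
        return bundle, {"ept": 3}
    if kind == "bmwp_toy":
        # packaged scores: Heptageniidae 10, Gammaridae 6, Baetidae 4
        bundle = _toy_bundle(
            [{"taxon_id": "Epeorus_sp", "family": "Heptageniidae",
              "order": "Ephemeroptera", "dag": "DAG02", "tolerance": 4.0},
             {"taxon_id": "Gammarus_sp", "family": "Gammaridae",
              "order": "Amphipoda", "dag": "DAG01", "tolerance": 6.0},
             {"taxon_id": "Baetis_sp", "family": "Baetidae",
              "order": "Ephemeroptera", "dag": "DAG02", "tolerance": 4.0}],
            [4, 7, 9])
        return bundle, {"bmwp": 20.0, "aspt": 20.0 / 3.0,
                        "n_scoring_families": 3}
    if kind == "grading_edges":
        rows = [
            ("h_prime", 3.5, "Excellent"), ("h_prime", 3.0, "Good"),
            ("h_prime", 2.5, "Good"), ("h_prime", 2.0, "Fair"),
            ("h_prime", 1.0, "Poor"), ("h_prime", 0.5, "Very poor"),
            ("h_prime", 0.0, "Very poor"),
            ("bmwp", 81.0, "Excellent"), ("bmwp", 80.0, "Good"),
            ("bmwp", 50.0, "Fair"), ("bmwp", 25.0, "Poor"),
            ("bmwp", 10.0, "Very poor"), ("bmwp", 0.0, "Very poor"),
            ("aspt", 4.01, "Excellent"), ("aspt", 4.0, "Good"),
            ("aspt", 3.5, "Fair"), ("aspt", 3.05, "Fair"),
            ("aspt", 3.0, "Poor"), ("aspt", 2.0, "Very poor"),
            ("bi", 0.0, "Excellent"), ("bi", 3.5, "Excellent"),
            ("bi", 5.5, "Good"), ("bi", 6.5, "Fair"), ("bi", 8.5, "Poor"),
            ("bi", 8.6, "Very poor"),
            ("ept", 29.0, "Excellent"), ("ept", 28.0, "Good"),
            ("ept", 27.0, "Good"), ("ept", 20.0, "Fair"),
            ("ept", 14.0, "Poor"), ("ept", 6.0, "Very poor"),
            ("ept", 0.0, "Very poor"),
        ]
        # sanity: every listed index exists in the packaged scheme
        schemes = load_schemes()
        assert {r[0] for r in rows} <= set(schemes)
        return pd.DataFrame(rows, columns=["index_name", "value",
                                           "expected_class"])
    raise ValueError(f"unknown fixture kind {kind!r}")
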