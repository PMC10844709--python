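# streamhealth

Bioassessment of running waters from benthic macroinvertebrate samples,
with explicit handling of dispersal processes.

Classic biomonitoring assumes *species sorting*: the taxa found at a site
reflect local environmental conditions, so community-derived indices can
grade river health. Metacommunity ecology says that is only part of the
story — **dispersal limitation** keeps weak dispersers out of suitable
sites, and **mass effects** let strong dispersers persist in unsuitable
ones, both of which decouple occurrence from local conditions and blur the
index–environment relationship. This package computes the five standard
macroinvertebrate indices, recomputes them after removing the dispersal
ability groups (DAGs) dominated by those processes, grades river health on
five-class criteria, and quantifies whether the "modified" indices track
the environment better.

## Indices

For a site with counts $n_i$ over taxa ($N = \sum_i n_i$):

- **Shannon–Wiener diversity** $H' = -\sum_i p_i \ln p_i$, $p_i = n_i/N$;
- **BMWP** $= \sum_{f \in F} s_f$, the sum of pollution-sensitivity scores
  $s_f \in [1,10]$ over the distinct scoring families $F$ present
  (presence-based; packaged scores are the original UK table, overridable);
- **ASPT** $= \mathrm{BMWP} / |F|$, the average score per scoring family;
- **Hilsenhoff biotic index** $\mathrm{BI} = \sum_i n_i a_i / N$ with taxon
  tolerance values $a_i \in [0,10]$ (higher = more pollution tolerant, so a
  *high* BI means a degraded site);
- **EPT** $= S_E + S_P + S_T$, the number of distinct Ephemeroptera,
  Plecoptera and Trichoptera families present.

Modified variants (`*_mod`) are the same quantities computed after removing
all taxa of the configured dispersal groups — by default DAG01 (weak passive
dispersers with aquatic adults, prone to dispersal limitation) and DAG04
(strong aerial dispersers, prone to mass effects). Undefined values (e.g.
ASPT with no scoring family) stay missing and are excluded from grading
denominators.

Comparison statistics mirror biomonitoring practice: a Spearman |r| ≥ 0.75
collinearity screen over the environment table, Spearman index–environment
correlation matrices with clustered display orders, random-forest regression
per index (%IncMSE out-of-bag permutation importance, permutation p-values,
OOB R²), and Kruskal–Wallis tests of each original index against its
modified counterpart.

Because field data of this kind are rarely public, the package ships a
seeded synthetic metacommunity generator (`streamhealth.simulate`) that
reproduces the assumed structure — niche-driven DAG02/03 taxa, distance-decay
occupancy for DAG01, environment-decoupled smooth abundance fields for DAG04,
and 21 named environment variables with two embedded latent axes — so every
stage, including the headline claim, is testable end to end.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_compute_indices.py
```

prints

```
simulated 147 sites x 147 taxa (seed 42)
median site richness 19 taxa, median total count 37 specimens
...
removed 66 dispersal-dominated taxa (['DAG01', 'DAG04'])
  h_prime  median   2.704 -> modified   2.325  (defined at 147/147 sites)
  bmwp     median 109.000 -> modified  79.000  (defined at 147/147 sites)
  aspt     median   6.938 -> modified   7.769  (defined at 147/147 sites)
  bi       median   6.376 -> modified   6.527  (defined at 147/147 sites)
  ept      median   8.000 -> modified   8.000  (defined at 147/147 sites)
```

66 of the 147 simulated taxa belong to DAG01/DAG04 and are removed for the
modified indices. Median H′ drops from 2.70 ("Good") to 2.33 because the
removed taxa contributed diversity that carried no environmental signal;
ASPT rises because the weak passive dispersers are mostly low-scoring
families. `analysis/03_grade_health.py` then tabulates five-class health
grades per index, `analysis/04_environment_associations.py` runs the
screen/correlation/random-forest battery, and
`analysis/05_dispersal_effect.py` performs the headline comparison: averaged
over 20 simulation seeds, |Spearman r| between H′/BI and the true pollution
axis rises when the dispersal-dominated taxa are removed, and shows no such
gain when the simulation is re-run with dispersal processes switched off.

The same workflow is available as a CLI (`streamhealth simulate|indices|
grade|compare|run-all`) for user-supplied CSV tables.

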