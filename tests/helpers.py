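"""Small constructors shared across test modules."""

import numpy as np
import pandas as pd

import streamhealth as sh


def make_community(counts, sites=None, taxa=None):
    counts = np.asarray(counts)
    sites = sites or [f"S{i+1}" for i in range(counts.shape[0])]
    taxa = taxa or [f"T{j+1}" for j in range(counts.shape[1])]
    return sh.CommunityMatrix(pd.DataFrame(counts, index=sites, columns=taxa))


def make_traits(rows):
    """rows: list of (taxon_id, family, order, dag, tolerance)."""
    df = pd.DataFrame(rows, columns=["taxon_id", "family", "order", "dag",
                                     "tolerance"]).set_index("taxon_id")
    return sh.TraitTable(df)


def random_bundle(rng, n_sites=6, n_taxa=12):
    """Random small aligned bundle with real family/order labels."""
    fams = [("Baetidae", "Ephemeroptera"), ("Heptageniidae", "Ephemeroptera"),
            ("Perlidae", "Plecoptera"), ("Hydropsychidae", "Trichoptera"),
            ("Leptoceridae", "Trichoptera"), ("Chironomidae", "Diptera"),
            ("Gammaridae", "Amphipoda"), ("Lymnaeidae", "Gastropoda"),
            ("Unknownidae", "Mysteria")]
    rows = []
    for i in range(n_taxa):
        fam, order = fams[rng.integers(0, len(fams))]
        dag = ("DAG01", "DAG02", "DAG03", "DAG04")[rng.integers(0, 4)]
        tol = float(rng.uniform(0, 10)) if rng.uniform() > 0.2 else np.nan
        rows.append((f"tax{i}", fam, order, dag, tol))
    counts = rng.poisson(2.0, size=(n_sites, n_taxa))
    cm = make_community(counts, taxa=[r[0] for r in rows])
    return sh.align(cm, make_traits(rows))
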