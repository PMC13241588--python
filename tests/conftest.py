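import numpy as np
import pandas as pd
import pytest

from rivergsi.genotypes import MISSING, GenotypeMatrix
from rivergsi.riverscape import (
    SimulationConfig,
    _codes_to_alleles,
    _hwe_genotypes,
    generate_allele_frequencies,
    generate_covariates,
    generate_network,
    simulate_baseline,
)


def make_matrix(rows, locus_names, role="baseline"):
    """Build a GenotypeMatrix from explicit allele tuples.

    ``rows``: list of (individual_id, collection_id, [(a1, a2), ...]).
    Use (None, None) for a missing call.
    """
    meta = pd.DataFrame({
        "individual_id": [r[0] for r in rows],
        "collection_id": [r[1] for r in rows],
        "role": role,
        "section": "",
        "year": pd.array([pd.NA] * len(rows), dtype="Int64"),
    })
    alleles = np.empty((len(rows), len(locus_names), 2), dtype=object)
    for i, r in enumerate(rows):
        for l, (a, b) in enumerate(r[2]):
            alleles[i, l, 0] = MISSING if a is None else str(a)
            alleles[i, l, 1] = MISSING if b is None else str(b)
    return GenotypeMatrix(meta, alleles, list(locus_names))


def codes_matrix(codes, ids=None, collection="c1", role="baseline",
                 section="A", year=2020):
    """GenotypeMatrix from an (n, L) dosage array (alleles '1'/'2')."""
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    ids = ids or [f"i{k}" for k in range(n)]
    meta = pd.DataFrame({
        "individual_id": ids,
        "collection_id": collection if role == "baseline" else "",
        "role": role,
        "section": section if role == "mixture" else "",
        "year": pd.array([year if role == "mixture" else pd.NA] * n, dtype="Int64"),
    })
    miss = codes < 0
    return GenotypeMatrix(meta, _codes_to_alleles(np.clip(codes, 0, 2), miss),
                          [f"L{l + 1:03d}" for l in range(L)])


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=11, n_populations=8, n_loci=80, n_sections=4,
                            n_split_populations=0, n_small_collections=0,
                            sib_family_rate=0.0, missing_rate=0.0,
                            mixture_size_per_year=120, n_years=2)


@pytest.fixture(scope="session")
def small_network(small_cfg):
    return generate_network(small_cfg)


@pytest.fixture(scope="session")
def small_covariates(small_cfg, small_network):
    return generate_covariates(small_network, small_cfg)


@pytest.fixture(scope="session")
def theta04_baseline():
    """Well-differentiated 8-unit baseline at theta = 0.04, 266 loci,
    ~35 individuals per unit (shared across assignment tests)."""
    from rivergsi import baseline as bl

    cfg = SimulationConfig(seed=3, n_populations=8, n_loci=266,
                           n_per_collection=(35, 36), n_split_populations=0,
                           n_small_collections=0, sib_family_rate=0.0,
                           missing_rate=0.0)
    freqs = generate_allele_frequencies(cfg)
    G, _ = simulate_baseline(freqs, cfg)
    return cfg, freqs, G, bl.build_units(G)
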