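import numpy as np
import pandas as pd
import pytest

from polyqst.data_io import GenotypeTable
from polyqst.synthetic import make_grid_sites, simulate_genotypes, simulate_phenotypes


def build_genotypes(rows, repeat_lengths):
    """rows: list of (individual, population, {locus: iterable of alleles})."""
    loci = list(repeat_lengths)
    data = pd.DataFrame(
        {
            "individual_id": [r[0] for r in rows],
            "population_id": [r[1] for r in rows],
            **{
                locus: [
                    None if r[2].get(locus) is None else tuple(sorted(set(r[2][locus])))
                    for r in rows
                ]
                for locus in loci
            },
        }
    )
    table = GenotypeTable(data, dict(repeat_lengths))
    table.validate()
    return table


@pytest.fixture
def toy_genotypes():
    """Two populations, two loci, fully specified by hand."""
    return build_genotypes(
        [
            ("a1", "P1", {"L1": (100, 102), "L2": (200,)}),
            ("a2", "P1", {"L1": (100,), "L2": (200, 204)}),
            ("a3", "P1", {"L1": (102, 104), "L2": (204,)}),
            ("b1", "P2", {"L1": (104,), "L2": (200,)}),
            ("b2", "P2", {"L1": (104, 106), "L2": (208,)}),
            ("b3", "P2", {"L1": (106,), "L2": (200, 208)}),
        ],
        {"L1": 2, "L2": 4},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Session-wide synthetic dataset on the 11-site grid (ALP2 dropped)."""
    sites = make_grid_sites(drop="ALP2")
    pop_ids = list(sites.data["population_id"])
    g, truth_g = simulate_genotypes(
        n_pop=len(pop_ids), n_ind=8, fst_target=0.08, seed=421, pop_ids=pop_ids
    )
    spec = {f"t{k}": (0.1, 0.3, 0.6) for k in range(1, 4)}
    traits, truth_t = simulate_phenotypes(g, spec, sigma_gxe2=0.05, seed=422)
    return {
        "genotypes": g,
        "traits": traits,
        "sites": sites,
        "truth_g": truth_g,
        "truth_t": truth_t,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)
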