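import numpy as np
import pandas as pd
import pytest

import liabel as lb


@pytest.fixture(scope="session")
def small_population():
    """600-animal population with genotypes, shared across tests."""
    cfg = lb.SimConfig(
        n_founders=200, n_generations=3, n_snps=150, seed=7,
        h2_liability=0.35, prevalence=0.10, n_cgs=5,
    )
    return lb.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_qc_phenotypes(small_population):
    phen, _ = lb.filter_cgs(small_population.phenotypes)
    phen, _ = lb.check_connectedness(phen, small_population.pedigree)
    return phen


def toy_pedigree(rows):
    """Helper: pedigree frame from (animal, sire, dam[, generation]) rows."""
    cols = ["animal", "sire", "dam", "generation"][: len(rows[0])]
    return pd.DataFrame(rows, columns=cols)
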