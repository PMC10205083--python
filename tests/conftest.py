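import numpy as np
import pandas as pd
import pytest

from fluxscale.species_scaling import CountMatrix

SPECIES_MASS = {"mouse": 30.0, "rat": 300.0, "monkey": 8000.0,
                "human": 70000.0, "cattle": 900000.0}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts():
    """Tiny 2-species count matrix: 4 genes, 2 replicates per species."""
    counts = pd.DataFrame(
        {"mouse_1": [10, 40, 5, 100], "mouse_2": [12, 38, 6, 90],
         "rat_1": [4, 41, 20, 95], "rat_2": [5, 39, 22, 105]},
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"))
    return CountMatrix(
        counts=counts,
        species_of_sample={"mouse_1": "mouse", "mouse_2": "mouse",
                           "rat_1": "rat", "rat_2": "rat"},
        body_mass_of_species={"mouse": 30.0, "rat": 300.0},
    )


@pytest.fixture
def five_species_matrix(rng):
    """Random 50-gene matrix over five species, 2 replicates each."""
    samples = [f"{sp}_{r}" for sp in SPECIES_MASS for r in (1, 2)]
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(50, len(samples))),
        index=pd.Index([f"G{i}" for i in range(50)], name="gene_id"),
        columns=samples)
    return CountMatrix(
        counts=counts,
        species_of_sample={s: s.rsplit("_", 1)[0] for s in samples},
        body_mass_of_species=dict(SPECIES_MASS),
    )
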