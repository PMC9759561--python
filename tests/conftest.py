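import numpy as np
import pandas as pd
import pytest

import nregulon as nr
from nregulon.containers import ProteinMatrix

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def design():
    return nr.make_design()


@pytest.fixture(scope="session")
def small_proteome():
    return nr.generate_proteome(60, ppp_fraction=0.5, mean_length=120, seed=42)


@pytest.fixture(scope="session")
def cascade_tables():
    """The shipped 12-gene filter-cascade fixture (peptides + design)."""
    from nregulon import io

    pep = io.read_peptides(f"{DATA_DIR}/filter_cascade_peptides.tsv")
    des = io.read_design(f"{DATA_DIR}/filter_cascade_design.tsv")
    return pep, des


def toy_matrix(values: dict, samples) -> ProteinMatrix:
    """Build a ProteinMatrix from {gene: [log2 values]} (NaN for missing)."""
    log2 = pd.DataFrame.from_dict(values, orient="index", columns=list(samples)).astype(
        float
    )
    return ProteinMatrix(log2)


@pytest.fixture(scope="session")
def noiseless_run():
    """Zero-noise, no-missing experiment: planted effects exactly recoverable."""
    proteome = nr.generate_proteome(40, ppp_fraction=0.5, mean_length=100, seed=2)
    design = nr.make_design()
    truth = nr.make_truth(proteome, n_targets=5, rna_down_fraction=0.0, n_top=0, seed=3)
    peptides = nr.generate_nascent_experiment(
        design, truth, noise_sd=0.0, missing_rate=0.0, seed=4,
        unique_fraction=1.0, contaminant_fraction=0.0,
    )
    return proteome, design, truth, peptides
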