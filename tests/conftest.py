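import io

import numpy as np
import pandas as pd
import pytest

from coralstress.design import generate_design
from coralstress.matrix import AbundanceMatrix
from coralstress.qc import ProteinGroupTable, read_protein_groups
from coralstress.simulate import SimulationParams, simulate_proteome


@pytest.fixture(scope="session")
def design3():
    """Full factorial: 3 species x 2 treatments x 3 timepoints x 3 tanks."""
    return generate_design(3, 3, ("TP0", "TP1", "TP2"), 1, bailout_species=None)


@pytest.fixture(scope="session")
def design_bailout():
    return generate_design(3, 3, ("TP0", "TP1", "TP2"), 1, bailout_species="C")


def table_from_frame(frame: pd.DataFrame, design=None) -> ProteinGroupTable:
    """Round-trip a generated protein-group frame through the TSV parser."""
    buf = io.StringIO(frame.to_csv(sep="\t", index=False))
    return read_protein_groups(buf, design=design)


@pytest.fixture()
def log2_matrix():
    """Small complete log2-state matrix with named samples."""
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.normal(20, 1, size=(12, 6)),
        index=[f"f{i}" for i in range(12)],
        columns=[f"s{i}" for i in range(6)],
    )
    return AbundanceMatrix(data, state="log2")


@pytest.fixture(scope="session")
def small_proteome(design3):
    params = SimulationParams(n_proteins=50, missing_rate=0.0, seed=5)
    frame, truth = simulate_proteome(design3, params)
    return frame, truth
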