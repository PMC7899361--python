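import numpy as np
import pandas as pd
import pytest

from dcmnet.panel_io import CohortDesign, ConcentrationTable, PairedDataset
from dcmnet.synthetic import SyntheticSpec, generate_cohort

SMALL_PANEL = {"glycerophospholipid": 8, "acylcarnitine": 6, "amino acid": 4}


def make_paired(plasma: np.ndarray, jf: np.ndarray, ids=None) -> PairedDataset:
    """Wrap two complete numeric matrices as a PairedDataset."""
    ids = ids or [f"M{k}" for k in range(plasma.shape[1])]
    return PairedDataset(
        stratum="test",
        plasma=pd.DataFrame(plasma, columns=ids,
                            index=[f"P{k}" for k in range(plasma.shape[0])]),
        jf=pd.DataFrame(jf, columns=ids,
                        index=[f"J{k}" for k in range(jf.shape[0])]),
        plasma_subjects=[f"S{k}" for k in range(plasma.shape[0])],
        jf_subjects=[f"S{k}" for k in range(jf.shape[0])],
    )


def null_paired(n: int = 30, m: int = 6, seed: int = 0) -> PairedDataset:
    """Paired dataset with independent metabolites and no differential signal."""
    rng = np.random.default_rng(seed)
    return make_paired(rng.standard_normal((n, m)), rng.standard_normal((n, m)))


@pytest.fixture(scope="session")
def small_cohort():
    """A small paired cohort with planted structure, shared across tests."""
    spec = SyntheticSpec(
        n_subjects=20,
        strata=("female",),
        panel=SMALL_PANEL,
        n_differential_pairs=2,
        low_detection_metabolites=3,
        seed=42,
    )
    table, design, truth = generate_cohort(spec)
    return spec, table, design, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (186-metabolite panel, 50 subjects/stratum)."""
    spec = SyntheticSpec(seed=7)
    table, design, truth = generate_cohort(spec)
    return spec, table, design, truth
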