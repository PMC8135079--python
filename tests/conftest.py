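import numpy as np
import pandas as pd
import pytest

from plf.ingest import PeptideObservationSet, SampleDesign
from plf.reference import ProteinRecord
from plf.simulate import simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """Small paired synthetic study with 5 planted modified regions."""
    return simulate_experiment(n_proteins=30, n_modified=5, delta=0.25, seed=1)


@pytest.fixture
def toy_protein():
    return ProteinRecord(accession="P1", sequence="MKRAPRLSVKAADERK" * 5)


@pytest.fixture
def paired_design_4():
    """Four subjects, two groups, fully paired."""
    samples = {}
    subjects = {}
    for i in range(1, 5):
        for g in ("A", "B"):
            s = f"D{i}_{g}"
            samples[s] = g
            subjects[s] = f"D{i}"
    return SampleDesign(
        sample_to_group=samples, sample_to_subject=subjects, groups=("A", "B")
    )


def make_obs(rows, samples):
    """Build a PeptideObservationSet from (accession, peptide, counts) rows."""
    table = pd.DataFrame(
        [(a, p, *c) for a, p, c in rows],
        columns=["accession", "peptide", *samples],
    )
    return PeptideObservationSet(table=table, samples=list(samples))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
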