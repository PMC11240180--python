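import numpy as np
import pytest

from evimol.mol_io import LabeledDataset, LabeledMolecule


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_predictions():
    """1,000 random (probability, label) pairs for metric oracle checks."""
    g = np.random.default_rng(777)
    probs = g.random(1000)
    labels = g.integers(0, 2, 1000)
    return probs, labels


@pytest.fixture(scope="session")
def tiny_dataset():
    """A hand-written two-class set of simple molecules."""
    mols = [
        LabeledMolecule("CCN", 0, "m0"),
        LabeledMolecule("CCCN", 0, "m1"),
        LabeledMolecule("CNC", 0, "m2"),
        LabeledMolecule("NCCO", 0, "m3"),
        LabeledMolecule("CCF", 1, "m4"),
        LabeledMolecule("CCCF", 1, "m5"),
        LabeledMolecule("FCCO", 1, "m6"),
        LabeledMolecule("CC(F)C", 1, "m7"),
    ]
    return LabeledDataset(mols, name="tiny")


@pytest.fixture(scope="session")
def small_synthetic():
    """A small four-category synthetic split, shared across tests."""
    from evimol.synthetic import SyntheticSpec, build_synthetic_splits

    spec = SyntheticSpec(
        n_train={"Nmol": 60, "Fmol": 60, "N_Fmol": 60},
        n_test={"Nmol": 25, "Fmol": 25, "N_Fmol": 25, "NULLmol": 25},
        seed=11,
    )
    return build_synthetic_splits(spec)
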