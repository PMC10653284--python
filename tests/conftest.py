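import warnings

import numpy as np
import pytest

from polyscreen import (
    ModelConfig,
    classify_monomer,
    generate_fixture_dataset,
    train_cv,
)


@pytest.fixture(scope="session")
def monomers():
    return {
        "adipic": classify_monomer("OC(=O)CCCCC(=O)O"),
        "eg": classify_monomer("OCCO"),
        "bdo": classify_monomer("OCCCCO"),
        "hda": classify_monomer("NCCCCCCN"),
        "ahx": classify_monomer("NCCCCCC(=O)O"),
        "terephthalic": classify_monomer("OC(=O)c1ccc(C(=O)O)cc1"),
        "propanediol_12": classify_monomer("CC(O)CO"),
        "dmc": classify_monomer("COC(=O)OC"),
        "hdi": classify_monomer("O=C=NCCCCCCN=C=O"),
        "propylene": classify_monomer("C=CC"),
    }


@pytest.fixture(scope="session")
def fixture_records():
    """A small labeled fixture corpus (80 polymers, DP 6)."""
    return generate_fixture_dataset(n_polymers=80, seed=11, dp=6, noise_sd=10.0)


@pytest.fixture(scope="session")
def tiny_ensemble(fixture_records):
    """A quickly trained 10-fold ensemble on the small fixture corpus."""
    config = ModelConfig(
        atom_feature_len=16,
        bond_feature_len=16,
        n_message_layers=2,
        batch_size=32,
        learning_rate=3e-3,
        decay_rate=0.99,
        epochs=60,
        dp_train=6,
        rng_seed=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_cv(fixture_records, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
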