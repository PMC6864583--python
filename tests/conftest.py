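import numpy as np
import pandas as pd
import pytest

from mtqsar import parse_smiles
from mtqsar.boxjenkins import DataRecord, ExperimentalCondition, label_activity


@pytest.fixture(scope="session")
def benzene():
    return parse_smiles("c1ccccc1", id="benzene")


@pytest.fixture(scope="session")
def ethanol():
    return parse_smiles("CCO", id="ethanol")


def make_records(values, bt="ERK-1", me="IC50", labels=None, prefix="m"):
    """Records with given activities (nM) under one condition."""
    recs = []
    for i, act in enumerate(values):
        recs.append(
            DataRecord(
                f"{prefix}{i}",
                ExperimentalCondition(bt, me),
                act,
                label_activity(act),
            )
        )
    return recs


@pytest.fixture(scope="session")
def tiny_synthetic():
    """A small planted-rule dataset shared by integration-flavoured tests."""
    from mtqsar.synthetic_data import SyntheticSpec, generate_dataset

    return generate_dataset(SyntheticSpec(n_compounds=150, seed=42))
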