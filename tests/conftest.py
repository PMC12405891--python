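import numpy as np
import pytest

import enbayes as eb
from enbayes.io import Dataset, GenotypeMatrix, PhenotypeVector, PredictionMatrix


@pytest.fixture(scope="session")
def tiny_ds():
    """Deterministic tiny dataset (n=60, p=50, dense trait, h2=0.5)."""
    ds, trait = eb.fixture_bundle("tiny")
    return ds, trait


@pytest.fixture(scope="session")
def small_ds():
    """Deterministic small dataset (n=300, p=500, dense trait, h2=0.5)."""
    ds, trait = eb.fixture_bundle("small")
    return ds, trait


@pytest.fixture
def reduced_mcmc():
    return eb.MCMCConfig.reduced(seed=0)


def make_dataset(X, y):
    """Wrap raw arrays into a Dataset with generated IDs."""
    X = np.asarray(X, dtype=float)
    ids = np.array([f"L{i}" for i in range(X.shape[0])], dtype=object)
    markers = np.array([f"M{j}" for j in range(X.shape[1])], dtype=object)
    return Dataset(GenotypeMatrix(ids, markers, X),
                   PhenotypeVector(ids, np.asarray(y, dtype=float)))


def make_predictions(values, names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1:
        values = values.T
    names = names or [f"m{j}" for j in range(values.shape[1])]
    ids = [f"L{i}" for i in range(values.shape[0])]
    return PredictionMatrix(np.array(ids, dtype=object),
                            np.array(names, dtype=object), values)
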