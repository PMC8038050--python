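import numpy as np
import pytest

import nmtqsar as q

MICRO_IDS = ["methane", "water", "ammonia", "cyclohexane", "pyrrole",
             "n-propylamine", "chloromethanol"]


@pytest.fixture(scope="session")
def toys():
    """All fixture molecules (micro + published examples), 3D-prepared.

    Maps id -> (prepared MoleculeRecord, expected-value dict).
    """
    out = {}
    for toy in q.toy_molecules():
        rec = q.prepare_3d(toy.record, q.PrepConfig(embed_seed=7))
        assert rec.failed is None, f"{rec.id}: {rec.failed}"
        out[rec.id] = (rec, toy.expected)
    return out


@pytest.fixture(scope="session")
def micro(toys):
    return {k: toys[k] for k in MICRO_IDS}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_regression(rng, n=30, p=3, sigma=0.3):
    """A small well-conditioned regression instance."""
    X = rng.standard_normal((n, p))
    beta = rng.uniform(-2, 2, size=p)
    y = 1.0 + X @ beta + rng.normal(0, sigma, size=n)
    return X, y, beta
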