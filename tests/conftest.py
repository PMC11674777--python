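import numpy as np
import pytest

from cuckoofuse import ClassScheme, PredictionSet


def scheme_of(K: int) -> ClassScheme:
    return ClassScheme(tuple(f"c{k}" for k in range(K)))


def make_ps(probs, model_id="m", truth=None, scheme=None, ids=None):
    """Build a PredictionSet from a raw row list/array."""
    probs = np.asarray(probs, dtype=np.float64)
    if scheme is None:
        scheme = scheme_of(probs.shape[1])
    if ids is None:
        ids = [f"r{i}" for i in range(probs.shape[0])]
    return PredictionSet(model_id, ids, probs, scheme, truth)


def random_ps(rng, n, K, model_id="m", with_truth=True, scheme=None):
    """Random valid prediction set: Dirichlet rows, uniform truth."""
    probs = rng.dirichlet(np.ones(K), size=n)
    truth = rng.integers(0, K, size=n) if with_truth else None
    return make_ps(probs, model_id=model_id, truth=truth, scheme=scheme)


@pytest.fixture
def dementia_scheme():
    from cuckoofuse import DEMENTIA_SCHEME
    return DEMENTIA_SCHEME
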