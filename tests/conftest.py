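import numpy as np
import pytest

from prism import (
    KmerProfile,
    ProbabilityModel,
    count_kmers,
    tensor_representation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_profile():
    """k=2 profile with a clear rank ordering: AA > AC = AG (tie)."""
    return KmerProfile(k=2, counts={"AA": 4, "AC": 2, "AG": 2}, total=8)


@pytest.fixture
def uniform_model_4096():
    """Uniform probability model over all 4096 DNA 6-mers."""
    bases = "ACGT"
    bins = [
        a + b + c + d + e + f
        for a in bases for b in bases for c in bases
        for d in bases for e in bases for f in bases
    ]
    return ProbabilityModel("uniform6", bins, np.full(4096, 1 / 4096), 4096)


@pytest.fixture
def random_info_tensor(rng):
    """Random N x M x 1 information tensor over categorical payloads."""
    n, m = 23, 7
    payloads = [f"tok{rng.integers(0, 10)}" for _ in range(n)]
    models = []
    for j in range(m):
        toks = [f"tok{t}" for t in range(10)]
        w = rng.dirichlet(np.ones(10))
        models.append(ProbabilityModel(f"m{j}", toks, w, total_count=100))
    return tensor_representation(payloads, models, ["info"])
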