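import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cleavspec.nomenclature import ALPHABET
from cleavspec.simulate import TRUTH_MODEL_NAMES, make_truth_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210528)


@pytest.fixture
def random_nonamer(rng):
    def _make(n=1):
        seqs = [
            "".join(rng.choice(list(ALPHABET), 9)) for _ in range(n)
        ]
        return seqs if n > 1 else seqs[0]

    return _make


@pytest.fixture(scope="session", params=TRUTH_MODEL_NAMES)
def truth_model(request):
    return make_truth_model(request.param, 0.9)
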