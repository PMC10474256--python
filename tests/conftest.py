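import numpy as np
import pytest

import nntrace


@pytest.fixture(scope="session")
def traced():
    """Cache of traced + post-processed fixture histories (read-only use)."""
    cache = {}

    def get(name: str, seed: int = 1):
        key = (name, seed)
        if key not in cache:
            model, x, spec = nntrace.make_fixture(name, seed=seed)
            history = nntrace.log_forward_pass(model, x, seed=seed)
            cache[key] = (history, spec)
        return cache[key]

    return get


@pytest.fixture()
def fresh_history():
    """A freshly traced history (safe to mutate, e.g. for fault injection)."""

    def make(name: str, seed: int = 1):
        model, x, spec = nntrace.make_fixture(name, seed=seed)
        return nntrace.log_forward_pass(model, x, seed=seed), spec

    return make


SMALL_FIXTURES = [n for n in nntrace.list_fixtures() if n != "alexnet"]


def model_output_array(model, x, seed):
    """Untraced reference forward pass under the same seed."""
    np.random.seed(seed)
    out = model(x)
    return np.asarray(out)
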