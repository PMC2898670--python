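import numpy as np
import pytest

from oscirc.models import Design, ModelParams, make_model

# the comparative reference condition used throughout the figures
REF = dict(alpha=50.0, delta_ratio=10.0, sigma=1.0)


@pytest.fixture(scope="session")
def design_grid():
    """One model per family at benign parameters, for property sweeps."""
    out = []
    for d in Design:
        kw = dict(alpha=50, beta=0.3, gamma=0.05, sigma=1, delta_ratio=10)
        if d is Design.DESIGN_II:
            kw["sigma_prime"] = 1.0
        if d is Design.GENERALIZED_III:
            kw.update(n=3, m=2)
        if d is Design.SMOLEN:
            kw.update(n=2, m=1)
        out.append(make_model(d, **kw))
    return out


@pytest.fixture(scope="session")
def fig6_models():
    """The printed time-series comparison point: alpha=50, Delta=11,
    beta=1.58, gamma=0.079."""
    kw = dict(alpha=50, beta=1.58, gamma=0.079, delta_ratio=11, sigma=1)
    return {d: make_model(d, **kw) for d in ("DESIGN_I", "DESIGN_III")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100517)


def random_states(rng, n, lo=1e-3, hi=30.0):
    """Log-uniform admissible (x, y) states."""
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, 2)))
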