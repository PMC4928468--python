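import numpy as np
import pytest

from ipscfit.configdsl import load_builtin_config
from ipscfit.models import ClampContext, GephyrinParams
from ipscfit.synthetic import DatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def ctx() -> ClampContext:
    return ClampContext(v=-70.0, erev=-16.0)


@pytest.fixture(scope="session")
def clean_dataset():
    """Small noiseless dataset without overlaps (exact recovery territory)."""
    spec = DatasetSpec(n_traces=6, sigma=0.0, p_overlap=0.0)
    return generate_dataset(spec, seed=1)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default study conditions: 2 pA noise, 10% overlap chance."""
    spec = DatasetSpec(n_traces=30, sigma=2.0, p_overlap=0.1)
    return generate_dataset(spec, seed=7)


@pytest.fixture(scope="session")
def reduced_config():
    return load_builtin_config("gephyrin_reduced")


@pytest.fixture(scope="session")
def full_config():
    return load_builtin_config("gephyrin")


def random_valid_params(rng: np.random.Generator,
                        margin: float = 0.05) -> GephyrinParams:
    """A parameter vector inside the model domain, away from singularities."""
    while True:
        p = GephyrinParams(
            w=rng.uniform(0.1, 5.0),
            tau_r=rng.uniform(0.05, 0.5),
            tau_d=rng.uniform(3.0, 20.0),
            beta=rng.uniform(0.2, 3.0),
            alpha_f=rng.uniform(0.2, 3.0),
            alpha_b=rng.uniform(0.35, 2.0),
            geph=rng.uniform(0.2, 3.0),
            phi=rng.uniform(0.2, 1.8),
            h=rng.uniform(0.2, 3.0),
            h1=rng.uniform(0.2, 3.0),
            c1=rng.uniform(0.01, 10.0),
            t0=rng.uniform(0.0, 5.0),
        )
        if (abs(1.0 - p.alpha_b * p.tau_d) > margin
                and abs(1.0 - p.alpha_b * p.tau_r) > margin):
            return p
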