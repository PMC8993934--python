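import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def forcing_2yr():
    from hybridevap import generate_forcing

    return generate_forcing(seed=42, n_days=730)


@pytest.fixture(scope="session")
def tall_params():
    from hybridevap import SoilParams

    return SoilParams.tall()


@pytest.fixture(scope="session")
def small_training_table():
    """A small noisy training world shared by the model unit tests."""
    from hybridevap import make_training_world

    return make_training_world(n_rows=6000, n_sites=3, noise_sd_mm=0.05, seed=17)
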