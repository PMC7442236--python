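import numpy as np
import pytest

import stagegrow as sg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured three-stream dataset."""
    cfg = sg.SimulationConfig(
        n_larvae=25, n_metamorphs=30, n_adults=20, recapture_prob=0.5, seed=99
    )
    ds, truth = sg.simulate_dataset(cfg)
    return ds, truth


@pytest.fixture()
def true_state(small_dataset):
    """ModelState at the generating truth of ``small_dataset``."""
    ds, truth = small_dataset
    lat = truth["latents"]
    return sg.ModelState(
        params=sg.PopulationParameters(**truth["params"]),
        latents=sg.LatentState(
            tm_metamorph=lat["tm_metamorph"],
            tm_adult=lat["tm_adult"],
            age_first_capture=lat["age_first_capture"],
            Linf_individual=lat["Linf_individual"],
        ),
    )
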