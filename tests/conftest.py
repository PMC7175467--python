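import dataclasses

import pytest

from phenogwas import simulate as sim


@pytest.fixture
def config():
    return sim.SimConfig(seed=1)


@pytest.fixture
def quiet_plate_config():
    """Plate generator with no noise, no QC failures and flat strain effects."""
    cfg = sim.SimConfig(seed=1)
    cfg.plate = dataclasses.replace(
        cfg.plate,
        noise_sd=0.0,
        qc_fail_fraction=0.0,
        strain_effect_sd=0.0,
        bias_smooth_sd=0.0,
    )
    return cfg


def population_config(seed, **overrides):
    cfg = sim.SimConfig(seed=seed)
    cfg.population = dataclasses.replace(cfg.population, **overrides)
    return cfg
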