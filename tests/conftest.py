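import numpy as np
import pytest

from ricegi import GeneratorConfig, HydrolysisCurve, hydrolysis_model

DESIGN_T = np.array([0.0, 20.0, 60.0, 120.0, 180.0, 240.0])


@pytest.fixture
def design_t():
    return DESIGN_T.copy()


@pytest.fixture
def default_cfg():
    return GeneratorConfig(seed=11)


def make_curve(cinf, k, t=DESIGN_T, name="sample", noise_sd=0.0, rng=None):
    c = np.asarray(hydrolysis_model(t, cinf, k), dtype=float)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        noise = rng.normal(0.0, noise_sd, t.size)
        noise[t == 0] = 0.0
        c = np.clip(c + noise, 0.0, None)
    return HydrolysisCurve(variety=name, t=np.asarray(t, float), C=c)
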