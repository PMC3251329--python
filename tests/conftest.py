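import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fdopaquant as fq

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def full_scheme() -> fq.FramingScheme:
    """The 41-frame, 90-min dynamic framing used throughout."""
    return fq.build_framing(fq.DEFAULT_FRAMING)


@pytest.fixture(scope="session")
def plasma(full_scheme) -> fq.PlasmaCurve:
    return fq.simulate_input_function(fq.BolusShape(), full_scheme.mid_times_min)


@pytest.fixture(scope="session")
def reference_tac(plasma, full_scheme) -> fq.TimeActivityCurve:
    """Cerebellar (non-trapping) TAC from the compartmental forward model."""
    from fdopaquant.synthetic import REFERENCE_KINETICS

    return fq.simulate_tissue_tac(plasma, REFERENCE_KINETICS, full_scheme, "cerebellum")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
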