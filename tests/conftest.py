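import numpy as np
import pytest

from ca1pyr.model import (
    SimulationConfig,
    StimulusProtocol,
    simulate,
    variant_parameters,
)

ALL_VARIANTS = ("Pyr_Strong", "Pyr_Weak1", "Pyr_Weak2")


@pytest.fixture(params=ALL_VARIANTS)
def variant_params(request):
    return variant_parameters(request.param)


@pytest.fixture(scope="session")
def run_sim():
    """Session-cached simulation runner keyed by the full protocol, so
    tests sharing a protocol do not re-integrate."""
    cache = {}

    def _run(variant, amplitude, t_start=0.0, t_stop=1000.0, t_total=1000.0,
             dt=0.02, v_init=-65.0, u_init=0.0):
        key = (variant, amplitude, t_start, t_stop, t_total, dt, v_init, u_init)
        if key not in cache:
            cache[key] = simulate(
                variant_parameters(variant),
                StimulusProtocol(amplitude=amplitude, t_start=t_start,
                                 t_stop=t_stop, t_total=t_total),
                SimulationConfig(dt=dt, v_init=v_init, u_init=u_init),
            )
        return cache[key]

    return _run


@pytest.fixture(scope="session")
def default_fi_curves(run_sim):
    """The three default f-I curves (computed once per session)."""
    from ca1pyr.characterize import fi_curve

    return {v: fi_curve(variant_parameters(v)) for v in ALL_VARIANTS}
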