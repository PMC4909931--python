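import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from spinex import (  # noqa: E402
    ExchangeParams,
    FieldContext,
    SpinExchangeModel,
    SpinLockCondition,
)

TP5ABC_DELAYS = tuple(np.linspace(0.0, 0.060, 6))


@pytest.fixture
def fieldctx() -> FieldContext:
    return FieldContext()


@pytest.fixture
def exchange() -> ExchangeParams:
    # the headline globally fitted exchange parameters (no Mg2+)
    return ExchangeParams(p_minor=0.029, k_ex=423.0)


@pytest.fixture
def g174(exchange) -> SpinExchangeModel:
    return SpinExchangeModel(
        residue_label="G174",
        r1=2.0,
        r2=16.0,
        ground_state_shift_ppm=143.2,
        delta_omega_ppm=4.3,
        exchange=exchange,
    )


def make_condition(power_hz=150.0, offset_hz=0.0, delays=TP5ABC_DELAYS) -> SpinLockCondition:
    return SpinLockCondition(
        spinlock_power_hz=power_hz, carrier_offset_hz=offset_hz, duration_grid_s=tuple(delays)
    )


@pytest.fixture
def onres_150hz() -> SpinLockCondition:
    return make_condition(150.0, 0.0)
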