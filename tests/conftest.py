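import dataclasses

import numpy as np
import pytest

from popnoise import simulate
from popnoise.recording import BLANK, Protocol, Recording, UnitRecord


@pytest.fixture
def tiny_protocol():
    return Protocol(directions=(0,), has_blank=True, stimulus_duration_s=1.0, n_sweeps=2)


@pytest.fixture
def tiny_recording(tiny_protocol):
    """1 unit, 2 conditions (0 deg, BLANK), 2 sweeps, counts 0:(3,5) BLANK:(1,0)."""
    unit = UnitRecord(
        unit_id="u0", channel_index=0, depth_um=0.0,
        waveform=np.array([0.0, -1.0, 0.5, 0.2]),
    )
    counts = np.array([[[3], [5]], [[1], [0]]])
    return Recording(protocol=tiny_protocol, units=[unit], counts=counts)


@pytest.fixture(scope="session")
def young_recording():
    """One simulated young-preset animal with the canonical protocol."""
    return simulate.simulate_recording(
        simulate.PRESETS["young"], simulate.default_protocol(), group_label="young"
    )


@pytest.fixture(scope="session")
def independent_recording():
    """No shared gain: counts are independent Poisson across units."""
    params = dataclasses.replace(
        simulate.PRESETS["young"],
        gain_sd_evoked=0.0,
        gain_sd_spont=0.0,
        n_units=12,
        seed=7,
    )
    return simulate.simulate_recording(params, simulate.default_protocol(n_sweeps=50))
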