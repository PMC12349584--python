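import numpy as np
import pytest

from fibermat import PressureRecording, SensorGridSpec
from fibermat import synthetic as syn
from fibermat.core import LIMBS, Limb


@pytest.fixture
def grid():
    return SensorGridSpec()


@pytest.fixture
def grid_damaged():
    """Clinical grid with the damaged (8,5) sensor excluded."""
    return SensorGridSpec(excluded=frozenset({(8, 5)}))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(values, rate=50.0, grid=None, uniform=True):
    values = np.asarray(values, dtype=float)
    grid = grid or SensorGridSpec(sample_rate=rate)
    t = np.arange(values.shape[0]) / rate
    return PressureRecording(grid=grid, timestamps=t, values=values, uniform=uniform)


@pytest.fixture
def constant_recording(grid):
    """10 s of every sensor at a constant 7.5 units."""
    return make_recording(np.full((500, 8, 5), 7.5))


def single_limb_scenario(seed, duration_s=600.0, amplitude=12.0, noise_sd=0.6):
    """One limb active in 3 separated epochs; ground truth returned alongside.

    Legs are also exercised in the lateral posture (arms bear no load there),
    arms only in supine.
    """
    rng = np.random.default_rng(seed)
    limb = LIMBS[seed % 4]
    position = "supine"
    if limb in (Limb.LL, Limb.RL) and seed % 8 >= 4:
        position = "lateral"
    epoch_ids = rng.choice(np.arange(2, int(duration_s // 10) - 2), size=3,
                           replace=False)
    events = tuple(
        syn.MovementEvent(
            limb=limb,
            start_s=float(e * 10 + 1),
            duration_s=8.0,
            amplitude=amplitude,
            freq_hz=float(rng.uniform(0.05, 0.3)),
        )
        for e in epoch_ids
    )
    sc = syn.InfantScenario(
        position=position,
        duration_s=duration_s,
        noise_sd=noise_sd,
        movement_events=events,
        seed=seed,
    )
    return sc, limb, {int(e) for e in epoch_ids}
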