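import numpy as np
import pandas as pd
import pytest

from ctloop.spike_data import Recording, SpikeTrain, UnitMeta


def make_trials(rows):
    """Trial table from compact dicts, filling defaults."""
    defaults = {
        "led_intensity": 0.0, "led_profile": "none", "led_onset": np.nan,
        "stim_times": [], "whisker_moving": False,
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(defaults, trial_id=f"t{i:03d}")
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


@pytest.fixture
def tiny_recording():
    """One S1 unit with 3 spikes and one no-LED trial."""
    dur = 10.0
    units = {"u0": UnitMeta(unit_id="u0", region="S1", tpt_ms=0.6, layer="6")}
    spikes = {"u0": SpikeTrain(np.array([1.0, 2.5, 7.25]), dur)}
    trials = make_trials([{"stim_times": [5.0]}])
    return Recording(units=units, spikes=spikes, trials=trials, duration=dur)


@pytest.fixture
def mixed_recording():
    """Three units across regions, LED and no-LED trials, optional tpt."""
    dur = 30.0
    units = {
        "a": UnitMeta(unit_id="a", region="S1", tpt_ms=0.62, layer="5"),
        "b": UnitMeta(unit_id="b", region="VPm", tpt_ms=None),
        "c": UnitMeta(unit_id="c", region="TRN", tpt_ms=0.25),
    }
    rng = np.random.default_rng(7)
    spikes = {
        u: SpikeTrain(np.sort(rng.uniform(0, dur, size=40 + 5 * i)), dur)
        for i, u in enumerate(units)
    }
    trials = make_trials([
        {"led_intensity": 8.0, "led_profile": "ramp_hold", "led_onset": 2.0,
         "stim_times": [2.750], "whisker_moving": False},
        {"led_intensity": 0.0, "led_profile": "none",
         "stim_times": [12.0], "whisker_moving": True},
        {"led_intensity": 30.0, "led_profile": "ramp_hold", "led_onset": 20.0,
         "stim_times": [20.750], "whisker_moving": False},
    ])
    return Recording(units=units, spikes=spikes, trials=trials, duration=dur)
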