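import numpy as np
import pytest

from cfpwv.signals import Beat, SiteRecording, Waveform
from cfpwv.synthgen import SubjectSpec, generate_record
from cfpwv.tubeload import TubeLoadParams

FS = 1000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


def make_pure_delay_spec(
    ac_td: float = 0.02,
    af_td: float = 0.10,
    duration: float = 15.0,
) -> SubjectSpec:
    """Matched-load, jitter-free subject: distal waves are pure delays."""
    return SubjectSpec(
        ac_td=ac_td,
        af_td=af_td,
        carotid_params=TubeLoadParams(ac_td, 0.0, 0.02),
        femoral_params=TubeLoadParams(af_td, 0.0, 0.02),
        alpha=0.0,
        hr_jitter_sd=0.0,
        hr_offset_sd=0.0,
        duration=duration,
    )


@pytest.fixture(scope="session")
def pure_delay_records():
    """Simultaneous matched-load records with true cfPTT = 80 ms."""
    spec = make_pure_delay_spec()
    return generate_record(spec, seed=1, mode="simultaneous")


@pytest.fixture(scope="session")
def default_records():
    """Default (reflective, attenuated, jittered) sequential records."""
    spec = SubjectSpec(duration=15.0)
    return generate_record(spec, seed=7, mode="sequential")


def synthetic_beat(fs: float = FS, period: float = 0.9, delay: float = 0.0) -> Beat:
    """One physiologically shaped beat, optionally circularly delayed."""
    from cfpwv.synthgen import _template_period

    samples = _template_period(period, fs, 120.0, 75.0)
    if delay:
        samples = np.roll(samples, int(round(delay * fs)))
    return Beat(samples, fs=fs, onset_time=0.0)
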