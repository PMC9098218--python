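import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    from volmmn.montage import make_montage

    return make_montage()


@pytest.fixture(scope="session")
def short_params():
    """Small paradigm for fast continuous-recording tests."""
    from volmmn.paradigm import ScheduleParams

    return ScheduleParams(
        n_trials=300,
        n_neutral_phases=2,
        neutral_phase_len=25,
        stable_min_len=60,
        volatile_seg_min=15,
        volatile_seg_max=30,
    )


@pytest.fixture(scope="session")
def default_sequence():
    from volmmn import paradigm

    sched = paradigm.build_schedule(seed=1)
    return paradigm.generate_sequence(sched, seed=1)


@pytest.fixture(scope="session")
def short_recording(short_params):
    """One placebo subject's continuous recording on the small paradigm."""
    from volmmn import paradigm, simulate

    sched = paradigm.build_schedule(short_params, seed=3)
    seq = paradigm.generate_sequence(sched, seed=3)
    subj = simulate.SubjectRecord(id="s1", study=1, group="PLA")
    raw = simulate.simulate_recording(seq, subj, seed=5)
    return seq, raw
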