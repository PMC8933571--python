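import numpy as np
import pytest

from alarmsieve.data_io import ROLES, WaveformRecord
from alarmsieve.synthetic_data import SyntheticSpec, generate_record


@pytest.fixture(scope="session")
def quick_spec():
    """Short, clean, all-channel records for fast unit tests."""
    return SyntheticSpec(
        record_seconds=60, fs=250, noise_sd=0.0, true_fraction=0.5,
        all_channels=True, rng_seed=0,
    )


@pytest.fixture(scope="session")
def clean_true_asy(quick_spec):
    return generate_record("ASY", "true_alarm", quick_spec, rng_seed=1)


@pytest.fixture(scope="session")
def clean_false_vta(quick_spec):
    return generate_record("VTA", "false_alarm", quick_spec, rng_seed=2)


def make_record(
    n=15000, fs=250.0, onset=None, alarm_type="VTA", label="false_alarm",
    seed=0, available=None,
):
    """Hand-built record with pseudo-random content on available channels."""
    rng = np.random.default_rng(seed)
    onset = n if onset is None else onset
    available = available or {r: r != "RESP" for r in ROLES}
    channels = {
        r: rng.normal(size=n) if available.get(r, False) else np.zeros(n)
        for r in ROLES
    }
    return WaveformRecord(
        record_id=f"test{seed}",
        channels=channels,
        available={r: bool(available.get(r, False)) for r in ROLES},
        fs=fs,
        alarm_type=alarm_type,
        onset=onset,
        label=label,
    )
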