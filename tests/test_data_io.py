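import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alarmsieve.data_io import (
    ALARM_TYPES,
    ROLES,
    alarm_segment,
    extract_pair,
    load_record_npz,
    make_folds,
    preprocess,
    read_record,
    save_record_npz,
    write_record_wfdb,
)
from alarmsieve.errors import ValidationError
from alarmsieve.synthetic_data import SyntheticSpec, generate_record

from conftest import make_record


# ---------------------------------------------------------------------------
# read_record / WFDB round trip
# ---------------------------------------------------------------------------

class TestReadRecord:
    def _write_fixture(self, tmp_path, available=None, n=75_000, fs=250.0):
        spec = SyntheticSpec(record_seconds=n / fs, fs=fs, noise_sd=0.0,
                             all_channels=True)
        rec, _ = generate_record("VTA", "true_alarm", spec, rng_seed=0,
                                 record_id="fix01")
        if available is not None:
            for role in ROLES:
                rec.available[role] = available.get(role, False)
                if not rec.available[role]:
                    rec.channels[role] = np.zeros(rec.n_samples)
        return rec, write_record_wfdb(rec, str(tmp_path))

    def test_round_trip_channels_and_metadata(self, tmp_path):
        # ECG II + PLETH only: ECG2/ABP/RESP must come back zero-filled
        rec, hea = self._write_fixture(
            tmp_path, available={"ECG1": True, "PPG": True}
        )
        loaded = read_record(hea, {"record_id": "fix01",
                                   "alarm_type": "Ventricular_Tachycardia"})
        assert loaded.fs == 250.0
        assert loaded.onset == 75_000
        assert loaded.alarm_type == "VTA"
        assert loaded.available["ECG1"] and loaded.available["PPG"]
        for role in ("ECG2", "ABP", "RESP"):
            assert not loaded.available[role]
            assert np.all(loaded.channels[role] == 0.0)
        # quantization error bounded by half an ADC step
        assert np.abs(loaded.channels["ECG1"] - rec.channels["ECG1"]).max() < 1e-4

    def test_missing_pulsatile_channels_zero_filled(self, tmp_path):
        _, hea = self._write_fixture(
            tmp_path, available={"ECG1": True, "ECG2": True}
        )
        loaded = read_record(hea, {"alarm_type": "Asystole"})
        assert not loaded.available["PPG"] and not loaded.available["ABP"]
        assert np.all(loaded.channels["PPG"] == 0.0)
        assert np.all(loaded.channels["ABP"] == 0.0)

    def test_unknown_alarm_type_rejected(self, tmp_path):
        _, hea = self._write_fixture(tmp_path)
        with pytest.raises(ValidationError):
            read_record(hea, {"alarm_type": "Flutter"})

    def test_record_shorter_than_onset_rejected(self, tmp_path):
        _, hea = self._write_fixture(tmp_path, n=70_000)
        with pytest.raises(ValidationError):
            read_record(hea, {"alarm_type": "Asystole"})

    def test_unreadable_file_raises_io(self, tmp_path):
        with pytest.raises(IOError):
            read_record(str(tmp_path / "nothere"), {"alarm_type": "Asystole"})


def test_npz_fixture_round_trip_bit_exact(tmp_path, clean_true_asy):
    rec, _ = clean_true_asy
    prefix = str(tmp_path / rec.record_id)
    save_record_npz(rec, prefix)
    loaded = load_record_npz(prefix)
    assert np.array_equal(loaded.matrix, rec.matrix)
    assert loaded.onset == rec.onset and loaded.alarm_type == rec.alarm_type
    assert loaded.available == rec.available


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_affine_map(self):
        rec = make_record(n=6000, seed=1)
        rec.channels["ECG1"] = np.linspace(-2.0, 6.0, 6000)
        out = preprocess(rec)
        expected = (rec.channels["ECG1"] + 2.0) / 8.0
        np.testing.assert_allclose(out.channels["ECG1"], expected, atol=1e-12)
        assert out.channels["ECG1"].min() == 0.0
        assert out.channels["ECG1"].max() == 1.0

    def test_constant_channel_maps_to_zero(self):
        rec = make_record(n=6000, seed=2)
        rec.channels["PPG"] = np.full(6000, 5.0)
        out = preprocess(rec)
        assert np.all(out.channels["PPG"] == 0.0)

    def test_truncates_to_onset(self):
        rec = make_record(n=75_500, onset=75_000, seed=3)
        out = preprocess(rec)
        assert out.n_samples == 75_000

    def test_statistics_from_pre_onset_window_only(self):
        rec = make_record(n=8000, onset=5000, seed=4)
        rec.channels["ECG1"][5000:] = 1e6   # post-onset garbage
        out = preprocess(rec)
        assert out.channels["ECG1"].max() == 1.0

    def test_idempotent(self):
        rec = make_record(n=6000, seed=5)
        once = preprocess(rec)
        twice = preprocess(once)
        for role in ROLES:
            np.testing.assert_array_equal(once.channels[role], twice.channels[role])

    def test_outputs_in_unit_interval_and_attained(self):
        rec = make_record(n=6000, seed=6)
        out = preprocess(rec)
        for role in ROLES:
            x = out.channels[role]
            assert x.min() >= 0.0 and x.max() <= 1.0
            if out.available[role] and np.ptp(rec.channels[role][:6000]) > 0:
                assert x.min() == 0.0 and x.max() == 1.0

    def test_unavailable_channels_untouched(self):
        rec = make_record(n=6000, seed=7)
        out = preprocess(rec)
        assert np.all(out.channels["RESP"] == 0.0)


# ---------------------------------------------------------------------------
# extract_pair
# ---------------------------------------------------------------------------

class TestExtractPair:
    def test_window_arithmetic(self):
        # 10 s x 250 Hz = 2500 samples
        rec = preprocess(make_record(n=75_000, seed=8))
        pair = extract_pair(rec, rng_seed=0)
        assert pair.alarm_segment.shape == (5, 2500)
        np.testing.assert_array_equal(
            pair.alarm_segment, rec.matrix[:, 72_500:75_000]
        )
        assert 0 <= pair.baseline_start <= 70_000
        np.testing.assert_array_equal(
            pair.baseline_segment,
            rec.matrix[:, pair.baseline_start : pair.baseline_start + 2500],
        )

    def test_boundary_onset_allows_single_start(self):
        rec = preprocess(make_record(n=5000, seed=9))
        pair = extract_pair(rec, rng_seed=3)
        assert pair.baseline_start == 0

    def test_too_short_rejected(self):
        rec = preprocess(make_record(n=4999, seed=10))
        with pytest.raises(ValidationError):
            extract_pair(rec, rng_seed=0)

    def test_deterministic_for_fixed_seed(self):
        rec = preprocess(make_record(n=75_000, seed=11))
        a = extract_pair(rec, rng_seed=7)
        b = extract_pair(rec, rng_seed=7)
        assert a.baseline_start == b.baseline_start
        np.testing.assert_array_equal(a.baseline_segment, b.baseline_segment)

    def test_baseline_strictly_before_alarm_window(self):
        rec = preprocess(make_record(n=75_000, seed=12))
        for seed in range(20):
            pair = extract_pair(rec, rng_seed=seed)
            last = pair.baseline_start + 2500 - 1
            assert last < rec.onset - 2500

    def test_onehot_matches_type(self):
        rec = preprocess(make_record(n=75_000, alarm_type="EBR", seed=13))
        pair = extract_pair(rec, rng_seed=0)
        assert pair.alarm_onehot.tolist() == [0.0, 1.0, 0.0, 0.0, 0.0]

    def test_alarm_segment_helper_matches(self):
        rec = preprocess(make_record(n=75_000, seed=14))
        np.testing.assert_array_equal(
            alarm_segment(rec), extract_pair(rec, 0).alarm_segment
        )


# ---------------------------------------------------------------------------
# make_folds
# ---------------------------------------------------------------------------

def _fake_population(n, rng):
    ids = [f"r{i:04d}" for i in range(n)]
    types = [ALARM_TYPES[rng.integers(5)] for _ in range(n)]
    labels = [("true_alarm", "false_alarm")[rng.integers(2)] for _ in range(n)]
    return ids, labels, types


class TestMakeFolds:
    def test_750_records_five_equal_folds(self):
        rng = np.random.default_rng(0)
        ids, labels, types = _fake_population(750, rng)
        folds = make_folds(ids, labels, types, k=5, rng_seed=0)
        assert [len(f) for f in folds] == [150] * 5

    def test_exact_stratification_single_stratum(self):
        ids = [f"x{i}" for i in range(10)]
        folds = make_folds(ids, ["true_alarm"] * 10, ["ASY"] * 10, 5, rng_seed=1)
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_k1_rejected(self):
        with pytest.raises(ValidationError):
            make_folds(["a", "b"], ["true_alarm"] * 2, ["ASY"] * 2, 1, 0)

    @settings(max_examples=25, deadline=None)
    @given(n=st.integers(10, 200), k=st.integers(2, 7), seed=st.integers(0, 99))
    def test_partition_and_balance_properties(self, n, k, seed):
        rng = np.random.default_rng(seed)
        ids, labels, types = _fake_population(n, rng)
        folds = make_folds(ids, labels, types, k, rng_seed=seed)
        flat = [i for f in folds for i in f]
        assert sorted(flat) == sorted(ids)                     # partition
        assert len(set(flat)) == n                             # disjoint
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1                    # balanced
        # per-(type, label) balance
        strata = {}
        for rid, lab, typ in zip(ids, labels, types):
            strata[rid] = (typ, lab)
        for key in set(strata.values()):
            counts = [sum(1 for rid in f if strata[rid] == key) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_seeded_reproducible(self):
        rng = np.random.default_rng(5)
        ids, labels, types = _fake_population(60, rng)
        a = make_folds(ids, labels, types, 5, rng_seed=42)
        b = make_folds(ids, labels, types, 5, rng_seed=42)
        assert a == b
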