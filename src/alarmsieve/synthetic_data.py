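"""Synthetic multi-channel alarm records with known ground truth.

The generator emits 5-role monitor records that follow the corpus regime:
250 Hz sampling, alarm onset at the end of the record, and the triggering
event confined to the final 10 s. True alarms carry the per-type rhythm
signature (beat-count / heart-rate definitions); false alarms keep a normal
rhythm and are corrupted by one waveform artifact instead.

Morphology is deliberately schematic — QRS complexes are narrow Gaussian
bumps, pulsatile channels are lagged smooth pulses — chosen so that the
beat-timing statistics behind each alarm definition are exactly realizable
and recoverable by a peak detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ALARM_TYPES, ROLES, WaveformRecord, write_manifest
from .errors import ValidationError
from .seeding import substream

__all__ = [
    "ARTIFACT_KINDS",
    "SyntheticSpec",
    "GroundTruth",
    "generate_record",
    "generate_dataset",
    "largest_remainder_counts",
]

ARTIFACT_KINDS = ("noise_burst", "lead_flat", "baseline_wander", "spike_train")

#: Default alarm-type mix, mirroring the corpus proportions.
DEFAULT_TYPE_MIX = {"ASY": 0.17, "EBR": 0.11, "ETC": 0.17, "VTA": 0.47, "VFB": 0.07}

# Rendering constants (seconds / relative amplitudes). The 200 ms pulse lag
# stands in for pulse-transit delay; the value is arbitrary but fixed.
_QRS_SIGMA = 0.017
_VT_SIGMA = 0.034          # doubled-width ventricular complexes
_PULSE_LAG = 0.2
_PULSE_SIGMA = 0.075


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset."""

    n_records: int = 100
    type_mix: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    true_fraction: float = 0.5
    record_seconds: float = 300.0
    fs: float = 250.0
    noise_sd: float = 0.02
    artifact_menu: tuple = ARTIFACT_KINDS
    rng_seed: int = 0
    all_channels: bool = False   # force every role available (no missing data)

    def validate(self) -> None:
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")
        if set(self.type_mix) - set(ALARM_TYPES):
            raise ValidationError(f"unknown alarm types in mix: {self.type_mix}")
        total = sum(self.type_mix.values())
        if not np.isclose(total, 1.0, atol=0.02):
            raise ValidationError(f"type_mix must sum to 1, got {total}")
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValidationError("true_fraction must lie in [0, 1]")
        if self.record_seconds < 20:
            raise ValidationError(
                "record_seconds must be >= 20 (baseline window required)"
            )
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not set(self.artifact_menu) <= set(ARTIFACT_KINDS):
            raise ValidationError(f"unknown artifacts: {self.artifact_menu}")


@dataclass
class GroundTruth:
    """Generator-side truth for one record."""

    beat_times: dict[str, np.ndarray]   # role -> strictly increasing sample indices
    event_window: tuple[int, int] | None
    label: str
    alarm_type: str
    artifact: str | None = None
    base_hr: float = 0.0

    def to_json(self) -> dict:
        return {
            "beat_times": {r: [int(i) for i in v] for r, v in self.beat_times.items()},
            "event_window": list(self.event_window) if self.event_window else None,
            "label": self.label,
            "alarm_type": self.alarm_type,
            "artifact": self.artifact,
            "base_hr": self.base_hr,
        }


def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer counts summing to ``n`` by largest-remainder apportionment.

    Ties are broken by larger quota, then by canonical type order, so the
    result is deterministic.
    """
    keys = [k for k in ALARM_TYPES if k in proportions] or sorted(proportions)
    total = sum(proportions[k] for k in keys)
    quotas = {k: n * proportions[k] / total for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    leftover = n - sum(counts.values())
    order = sorted(
        keys,
        key=lambda k: (-(quotas[k] - counts[k]), -quotas[k], keys.index(k)),
    )
    for k in order[:leftover]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# Beat-train construction
# ---------------------------------------------------------------------------

def _normal_train(t_start, t_end, hr, rng, jitter=0.02):
    """Quasi-periodic beat times (seconds) on [t_start, t_end)."""
    times = []
    t = t_start + rng.uniform(0, 60.0 / hr)
    while t < t_end:
        times.append(t)
        t += (60.0 / hr) * (1.0 + rng.uniform(-jitter, jitter))
    return times


def _event_plan(alarm_type, label, duration, hr, rng):
    """Return (beat list in seconds, per-beat kind list, event window in s, vfb window).

    Beat kinds: ``n`` normal, ``v`` ventricular (wide, inverted). For false
    alarms the rhythm is normal throughout and the event window is reserved
    for the artifact.
    """
    final = duration - 10.0
    if label == "false_alarm":
        beats = _normal_train(0.0, duration, hr, rng)
        return beats, ["n"] * len(beats), None, None

    if alarm_type == "ASY":
        # >= 4 s beat-free gap wholly inside the final 10 s
        gap_start, gap_end = duration - 9.3, duration - 4.3
        beats = _normal_train(0.0, gap_start, hr, rng)
        beats += _normal_train(gap_end, duration, hr, rng)
        return beats, ["n"] * len(beats), (gap_start, gap_end), None

    if alarm_type == "EBR":
        # run of 6 beats at HR ~ 35 bpm (< 40) inside the final 10 s
        slow_hr = rng.uniform(33.0, 37.0)
        start = duration - 9.6
        run = [start + i * 60.0 / slow_hr for i in range(6)]
        beats = _normal_train(0.0, start - 60.0 / hr, hr, rng) + run
        return beats, ["n"] * len(beats), (run[0], run[-1]), None

    if alarm_type == "ETC":
        # run of 22 beats at HR ~ 170 bpm (> 140)
        fast_hr = rng.uniform(160.0, 185.0)
        start = duration - 9.0
        run = [start + i * 60.0 / fast_hr for i in range(22)]
        beats = _normal_train(0.0, start - 60.0 / hr, hr, rng) + run
        kinds = ["n"] * len(beats)
        return beats, kinds, (run[0], run[-1]), None

    if alarm_type == "VTA":
        # run of 8 wide ventricular beats at HR ~ 150 bpm (> 100)
        vt_hr = rng.uniform(130.0, 170.0)
        start = duration - 7.0
        run = [start + i * 60.0 / vt_hr for i in range(8)]
        beats = _normal_train(0.0, start - 60.0 / hr, hr, rng)
        kinds = ["n"] * len(beats) + ["v"] * len(run)
        return beats + run, kinds, (run[0], run[-1]), None

    if alarm_type == "VFB":
        # beats cease; 4–6 Hz fibrillatory oscillation for >= 4 s
        osc_start, osc_end = duration - 6.8, duration - 1.3
        beats = _normal_train(0.0, osc_start - 1.0, hr, rng)
        return beats, ["n"] * len(beats), (osc_start, osc_end), (osc_start, osc_end)

    raise ValidationError(f"unknown alarm type: {alarm_type!r}")


def _bump(signal, fs, center_s, sigma_s, amplitude):
    """Add a Gaussian bump in place (vectorized over a +-4 sigma support)."""
    n = len(signal)
    half = int(4 * sigma_s * fs) + 1
    c = center_s * fs
    lo = max(int(c) - half, 0)
    hi = min(int(c) + half + 1, n)
    if lo >= hi:
        return
    t = np.arange(lo, hi)
    signal[lo:hi] += amplitude * np.exp(-0.5 * ((t - c) / (sigma_s * fs)) ** 2)


def _render_ecg(n, fs, beats_s, kinds, lead_gain):
    sig = np.zeros(n)
    for t_b, kind in zip(beats_s, kinds):
        if kind == "v":
            _bump(sig, fs, t_b, _VT_SIGMA, -1.2 * lead_gain)
        else:
            _bump(sig, fs, t_b - 0.20, 0.030, 0.15 * lead_gain)  # P
            _bump(sig, fs, t_b, _QRS_SIGMA, 1.0 * lead_gain)     # QRS
            _bump(sig, fs, t_b + 0.30, 0.060, 0.30 * lead_gain)  # T
    return sig


def _render_pulse(n, fs, beats_s, kinds, gain, offset):
    sig = np.full(n, offset)
    for t_b, kind in zip(beats_s, kinds):
        amp = 0.4 * gain if kind == "v" else gain   # weakened pulse during VT
        _bump(sig, fs, t_b + _PULSE_LAG, _PULSE_SIGMA, amp)
    return sig


def _vfb_wave(n, fs, window_s, rng):
    """Irregular 4–6 Hz oscillation confined to ``window_s``."""
    sig = np.zeros(n)
    lo, hi = int(window_s[0] * fs), int(window_s[1] * fs)
    t = np.arange(hi - lo) / fs
    freq = 5.0 + 0.6 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * t + rng.uniform(0, 6.28))
    phase = 2 * np.pi * np.cumsum(freq) / fs
    amp = 0.8 * (1.0 + 0.25 * np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 6.28)))
    wave = amp * np.sin(phase)
    ramp = np.minimum(1.0, np.minimum(t, t[::-1]) / 0.3)   # soft edges
    sig[lo:hi] = wave * ramp
    return sig


def _apply_artifact(channels, available, fs, n, kind, rng):
    """Corrupt one available channel inside the final 10 s; returns window."""
    candidates = [r for r in ("ECG1", "ECG2", "PPG", "ABP") if available[r]]
    role = candidates[int(rng.integers(len(candidates)))]
    sig = channels[role]
    if kind == "noise_burst":
        start = n - int(rng.uniform(6.0, 9.0) * fs)
        width = int(rng.uniform(2.5, 3.5) * fs)
        sig[start : start + width] += rng.normal(0.0, 1.0, width)
        window = (start, start + width)
    elif kind == "lead_flat":
        start = n - int(10 * fs)
        sig[start:] = sig[start]
        window = (start, n)
    elif kind == "baseline_wander":
        start = n - int(10 * fs)
        t = np.arange(n - start) / fs
        sig[start:] += 1.5 * np.sin(2 * np.pi * 0.45 * t + rng.uniform(0, 6.28))
        window = (start, n)
    elif kind == "spike_train":
        start = n - int(rng.uniform(5.0, 7.0) * fs)
        period = int(fs / rng.uniform(1.6, 2.0))
        for c in range(start, n - 4, period):
            sig[c : c + 3] += 1.5
        window = (start, n)
    else:
        raise ValidationError(f"unknown artifact kind: {kind!r}")
    return role, window


def generate_record(
    alarm_type: str,
    label: str,
    spec: SyntheticSpec,
    rng_seed: int,
    record_id: str | None = None,
) -> tuple[WaveformRecord, GroundTruth]:
    """Generate one labeled record plus its ground truth.

    Same arguments and seed produce bit-identical channel matrices.
    """
    spec.validate()
    if alarm_type not in ALARM_TYPES:
        raise ValidationError(f"unknown alarm type: {alarm_type!r}")
    if label not in ("true_alarm", "false_alarm"):
        raise ValidationError(f"label must be true_alarm/false_alarm, got {label!r}")

    fs = spec.fs
    n = int(round(spec.record_seconds * fs))
    rng = substream(spec.rng_seed, "record", rng_seed, alarm_type, label)

    hr = rng.uniform(63.0, 97.0)   # jitter keeps instantaneous HR inside [60, 100]
    beats_s, kinds, event_s, vfb_s = _event_plan(
        alarm_type, label, spec.record_seconds, hr, rng
    )
    order = np.argsort(beats_s)
    beats_s = [beats_s[i] for i in order]
    kinds = [kinds[i] for i in order]

    if spec.all_channels:
        available = {r: True for r in ROLES}
    else:
        available = {
            "ECG1": True,
            "ECG2": True,
            "PPG": rng.random() < 0.75,
            "ABP": rng.random() < 0.5,
            "RESP": rng.random() < 0.3,
        }
        if not (available["PPG"] or available["ABP"]):
            available["ABP" if rng.random() < 0.5 else "PPG"] = True

    channels = {
        "ECG1": _render_ecg(n, fs, beats_s, kinds, 1.0),
        "ECG2": _render_ecg(n, fs, beats_s, kinds, 0.7),
        "PPG": _render_pulse(n, fs, beats_s, kinds, 1.0, 0.1),
        "ABP": _render_pulse(n, fs, beats_s, kinds, 0.8, 0.5),
        "RESP": 0.5 * np.sin(2 * np.pi * rng.uniform(0.2, 0.3) * np.arange(n) / fs),
    }
    if vfb_s is not None:
        for role, gain in (("ECG1", 1.0), ("ECG2", 0.7)):
            channels[role] += gain * _vfb_wave(n, fs, vfb_s, rng)

    artifact = None
    event_window = (
        (int(event_s[0] * fs), min(int(event_s[1] * fs) + 1, n)) if event_s else None
    )
    if label == "false_alarm":
        if not spec.artifact_menu:
            raise ValidationError("artifact_menu is empty")
        artifact = spec.artifact_menu[int(rng.integers(len(spec.artifact_menu)))]
        _, event_window = _apply_artifact(channels, available, fs, n, artifact, rng)

    if spec.noise_sd > 0:
        for role in ROLES:
            if available[role]:
                channels[role] += rng.normal(0.0, spec.noise_sd, n)
    for role in ROLES:
        if not available[role]:
            channels[role] = np.zeros(n)

    beat_idx = np.array([int(round(b * fs)) for b in beats_s if 0 <= b * fs < n])
    pulse_idx = beat_idx + int(round(_PULSE_LAG * fs))
    pulse_idx = pulse_idx[pulse_idx < n]
    beat_times = {}
    for role in ROLES:
        if not available[role] or role == "RESP":
            beat_times[role] = np.array([], dtype=int)
        elif role in ("ECG1", "ECG2"):
            beat_times[role] = beat_idx
        else:
            beat_times[role] = pulse_idx

    record = WaveformRecord(
        record_id=record_id or f"syn{rng_seed:05d}",
        channels=channels,
        available=available,
        fs=fs,
        alarm_type=alarm_type,
        onset=n,
        label=label,
    )
    truth = GroundTruth(
        beat_times=beat_times,
        event_window=event_window,
        label=label,
        alarm_type=alarm_type,
        artifact=artifact,
        base_hr=hr,
    )
    return record, truth


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[tuple[WaveformRecord, GroundTruth]], list[dict]]:
    """Generate ``spec.n_records`` records; returns (records+truths, manifest rows).

    Per-type counts follow largest-remainder apportionment of ``type_mix``;
    within each type the number of true alarms is ``round(count *
    true_fraction)``, assigned in a seeded shuffled order.
    """
    spec.validate()
    counts = largest_remainder_counts(spec.n_records, spec.type_mix)
    if spec.n_records < len([k for k, v in spec.type_mix.items() if v > 0]):
        raise ValidationError(
            "n_records smaller than the number of requested strata"
        )

    plan: list[tuple[str, str]] = []
    for typ in ALARM_TYPES:
        c = counts.get(typ, 0)
        n_true = int(round(c * spec.true_fraction))
        plan.extend((typ, "true_alarm") for _ in range(n_true))
        plan.extend((typ, "false_alarm") for _ in range(c - n_true))

    rng = substream(spec.rng_seed, "dataset")
    rng.shuffle(plan)

    out, manifest = [], []
    for i, (typ, label) in enumerate(plan):
        rid = f"s{i:05d}"
        rec, truth = generate_record(typ, label, spec, rng_seed=i, record_id=rid)
        out.append((rec, truth))
        manifest.append({"record_id": rid, "alarm_type": typ, "label": label})
    return out, manifest


def write_dataset(spec: SyntheticSpec, directory: str, wfdb: bool = False) -> list[dict]:
    """Materialize a dataset on disk (fixture containers, truth JSON, manifest).

    With ``wfdb=True`` records are additionally written as WFDB pairs.
    """
    import json
    import os

    from .data_io import save_record_npz, write_record_wfdb

    os.makedirs(directory, exist_ok=True)
    records, manifest = generate_dataset(spec)
    for rec, truth in records:
        prefix = os.path.join(directory, rec.record_id)
        save_record_npz(rec, prefix)
        with open(prefix + ".truth.json", "w") as fh:
            json.dump(truth.to_json(), fh)
        if wfdb:
            write_record_wfdb(rec, directory)
    write_manifest(manifest, os.path.join(directory, "manifest.csv"))
    return manifest
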