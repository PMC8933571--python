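"""Rule-based alarm verification producing the scalar score R.

The reference implementation detects beats per channel (band-pass, squaring,
moving-window integration, adaptive-threshold peak picking with a 250 ms
refractory period) and tests the final 10 s of each usable channel against
the record's own alarm-type definition:

* ASY — some 4 s window contains no beats
* EBR — a run of >= 5 beats whose instantaneous HR stays below 40 bpm
* ETC — a run of > 17 beats whose instantaneous HR stays above 140 bpm
* VTA — a run of > 5 widened beats at HR above 100 bpm (width proxy:
  per-beat half-width above 1.5x the record's median beat width)
* VFB — a >= 4 s beat-free stretch whose spectrum is dominated by 4-6 Hz

The score is discrete: 0.9 if any usable channel satisfies the definition,
0.1 if none does, and 0.5 (abstention) if every channel is flat or noisy.
Any callable mapping a record to [0, 1] can be plugged in instead.
"""

from __future__ import annotations

import importlib.util
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data_io import ROLES, SEGMENT_SECONDS, WaveformRecord
from .errors import ValidationError

__all__ = [
    "RuleResult",
    "detect_beats",
    "evaluate_rules",
    "reference_rule_scorer",
    "constant_rule_scorer",
    "resolve_rule_scorer",
]

#: Discrete score levels (hit / miss / abstain); configurable module-wide.
SCORE_HIT = 0.9
SCORE_MISS = 0.1
SCORE_ABSTAIN = 0.5

EPS_FLAT = 0.01            # amplitude range below which a channel is flat
NOISE_CROSSINGS_PER_S = 5.0   # > 300 bpm-equivalent threshold crossings
REFRACTORY_S = 0.25

_ECG_BAND = (5.0, 25.0)
_PULSE_BAND = (0.5, 8.0)
#: Channels the beat rules look at; RESP carries no beat information.
_RULE_ROLES = ("ECG1", "ECG2", "PPG", "ABP")


@dataclass
class RuleResult:
    score: float
    beats: dict[str, np.ndarray]
    hr_series: dict[str, np.ndarray]
    quality: dict[str, str]
    decision_trace: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score outside [0,1]: {self.score}")


def _integrate(signal: np.ndarray, fs: float, band) -> np.ndarray:
    nyq = fs / 2.0
    lo = min(band[0] / nyq, 0.95)
    hi = min(band[1] / nyq, 0.98)
    b, a = sps.butter(2, [lo, hi], btype="band")
    filtered = sps.filtfilt(b, a, signal)
    squared = filtered ** 2
    win = max(int(0.15 * fs), 1)
    return np.convolve(squared, np.ones(win) / win, mode="same")


def detect_beats(
    signal: np.ndarray,
    fs: float,
    band: tuple[float, float] = _ECG_BAND,
) -> tuple[np.ndarray, str]:
    """Detect beat sample indices in a single-channel series.

    Returns ``(beats, quality)`` with quality one of ``usable``, ``flat``
    (amplitude range below ``EPS_FLAT``) or ``noisy`` (threshold crossings
    beyond a physiologic ceiling).
    """
    if fs <= 0:
        raise ValidationError(f"fs must be positive, got {fs}")
    signal = np.asarray(signal, dtype=np.float64)
    if len(signal) < 4 * fs:
        raise ValidationError("signal shorter than 4 s")

    if np.ptp(signal) < EPS_FLAT:
        return np.array([], dtype=int), "flat"

    integrated = _integrate(signal, fs, band)
    threshold = 0.25 * np.percentile(integrated, 99.5)
    if threshold <= 0:
        return np.array([], dtype=int), "flat"

    # above-threshold excursion rate without the refractory period: clean
    # rhythms stay below a 300 bpm-equivalent ceiling, broadband noise does not
    raw_peaks, _ = sps.find_peaks(
        integrated, height=threshold, distance=max(int(0.08 * fs), 1)
    )
    duration = len(signal) / fs
    if len(raw_peaks) / duration > NOISE_CROSSINGS_PER_S:
        return np.array([], dtype=int), "noisy"

    peaks, _ = sps.find_peaks(
        integrated, height=threshold, distance=max(int(REFRACTORY_S * fs), 1)
    )
    return peaks.astype(int), "usable"


def _instant_hr(beats: np.ndarray, fs: float) -> np.ndarray:
    """Per-interval instantaneous heart rate in bpm (length ``len(beats)-1``)."""
    if len(beats) < 2:
        return np.array([])
    return 60.0 * fs / np.diff(beats)


def _max_gap(beats: np.ndarray, lo: int, hi: int) -> int:
    """Longest beat-free stretch (in samples) inside window [lo, hi)."""
    inside = beats[(beats >= lo) & (beats < hi)]
    edges = np.concatenate(([lo], inside, [hi]))
    return int(np.max(np.diff(edges)))


def _run_satisfies(hr: np.ndarray, min_beats: int, cmp) -> bool:
    """True if some run of ``min_beats`` consecutive beats has every
    instantaneous HR satisfying ``cmp`` (needs ``min_beats - 1`` intervals)."""
    need = min_beats - 1
    if len(hr) < need:
        return False
    good = cmp(hr)
    run = 0
    for g in good:
        run = run + 1 if g else 0
        if run >= need:
            return True
    return False


def _beat_widths(signal: np.ndarray, fs: float, beats: np.ndarray, band) -> np.ndarray:
    """Half-height width (samples) of the squared band-passed signal at beats."""
    nyq = fs / 2.0
    b, a = sps.butter(2, [min(band[0] / nyq, 0.95), min(band[1] / nyq, 0.98)], "band")
    squared = sps.filtfilt(b, a, signal) ** 2
    widths = np.zeros(len(beats))
    half = int(0.12 * fs)
    with warnings.catch_warnings():
        # beats riding on a flat stretch yield zero-prominence peaks; a zero
        # width simply never counts as "wide"
        warnings.simplefilter("ignore")
        for i, beat in enumerate(beats):
            lo, hi = max(beat - half, 0), min(beat + half, len(squared))
            local = lo + int(np.argmax(squared[lo:hi]))
            widths[i] = sps.peak_widths(squared, [local], rel_height=0.5)[0][0]
    return widths


def _vfb_window_test(window: np.ndarray, fs: float, beats: np.ndarray) -> bool:
    """Fibrillatory-wave test: some 4 s stretch of the window is spectrally
    dominated by the 4-6 Hz band.

    Dominance (>= 60 % of the power above 0.5 Hz, spectral peak inside the
    band) doubles as the absent-discrete-beats check: trains of narrow QRS
    complexes spread their power across a much wider band.
    """
    n4 = int(4 * fs)
    if len(window) < n4:
        return False
    step = max(int(0.5 * fs), 1)
    for start in range(0, len(window) - n4 + 1, step):
        seg = window[start : start + n4]
        seg = seg - np.mean(seg)
        freqs, psd = sps.welch(seg, fs=fs, nperseg=n4)
        total = np.trapezoid(psd[freqs >= 0.5], freqs[freqs >= 0.5])
        if total <= 0:
            continue
        band_mask = (freqs >= 3.5) & (freqs <= 6.5)
        frac = np.trapezoid(psd[band_mask], freqs[band_mask]) / total
        peak = freqs[np.argmax(psd * (freqs >= 1.0))]
        if frac >= 0.6 and 3.5 <= peak <= 6.5:
            return True
    return False


def _channel_satisfies(
    record: WaveformRecord, role: str, beats_full: np.ndarray, band
) -> tuple[bool, str]:
    """Test one channel's final 10 s against the record's alarm definition."""
    fs = record.fs
    w_lo = record.onset - int(SEGMENT_SECONDS * fs)
    w_hi = record.onset
    beats_win = beats_full[(beats_full >= w_lo) & (beats_full < w_hi)]
    hr = _instant_hr(beats_win, fs)
    typ = record.alarm_type

    if typ == "ASY":
        if _max_gap(beats_full, w_lo, w_hi) >= int(4 * fs):
            return True, "asystole: 4 s beat-free window"
    elif typ == "EBR":
        if _run_satisfies(hr, 5, lambda h: h < 40.0):
            return True, "bradycardia: >=5-beat run under 40 bpm"
    elif typ == "ETC":
        if _run_satisfies(hr, 18, lambda h: h > 140.0):
            return True, "tachycardia: >17-beat run over 140 bpm"
    elif typ == "VTA":
        if len(beats_full) >= 4 and len(beats_win) >= 6:
            widths = _beat_widths(record.channels[role], fs, beats_full, band)
            median_w = float(np.median(widths))
            wide = widths[(beats_full >= w_lo) & (beats_full < w_hi)] > 1.5 * median_w
            ok = np.zeros(max(len(hr), 0), dtype=bool)
            for i in range(len(hr)):
                ok[i] = hr[i] > 100.0 and wide[i] and wide[i + 1]
            if _run_satisfies(np.where(ok, 150.0, 0.0), 6, lambda h: h > 100.0):
                return True, "ventricular tachycardia: >5 wide-beat run over 100 bpm"
    elif typ == "VFB":
        window = record.channels[role][w_lo:w_hi]
        if _vfb_window_test(window, fs, beats_win - w_lo):
            return True, "fibrillation: 4-6 Hz waves over >=4 s"
    return False, ""


def evaluate_rules(record: WaveformRecord) -> RuleResult:
    """Score a preprocessed record against its alarm-type definition."""
    if not any(record.available.values()):
        raise ValidationError("record has no available channels")
    fs = record.fs
    w_lo = record.onset - int(SEGMENT_SECONDS * fs)
    if w_lo < 0:
        raise ValidationError("record shorter than the 10 s analysis window")

    beats: dict[str, np.ndarray] = {}
    hr_series: dict[str, np.ndarray] = {}
    quality: dict[str, str] = {}
    hit, trace = False, ""
    any_usable = False

    for role in ROLES:
        if role not in _RULE_ROLES or not record.available[role]:
            beats[role] = np.array([], dtype=int)
            hr_series[role] = np.array([])
            quality[role] = "flat" if not record.available[role] else "usable"
            continue
        band = _ECG_BAND if role.startswith("ECG") else _PULSE_BAND
        sig = record.channels[role][: record.onset]
        b, q = detect_beats(sig, fs, band=band)
        # quality is judged on the analysis window: a lead that went flat in
        # the final 10 s must not masquerade as asystole
        if q == "usable" and np.ptp(sig[w_lo:]) < EPS_FLAT:
            q = "flat"
        beats[role] = b
        hr_series[role] = _instant_hr(b, fs)
        quality[role] = q
        if q != "usable":
            continue
        any_usable = True
        if not hit:
            ok, why = _channel_satisfies(record, role, b, band)
            if ok:
                hit, trace = True, f"{role}: {why}"

    if not any_usable:
        score, trace = SCORE_ABSTAIN, "all channels flat or noisy"
    elif hit:
        score = SCORE_HIT
    else:
        score, trace = SCORE_MISS, "no usable channel met the definition"
    return RuleResult(score, beats, hr_series, quality, trace)


def reference_rule_scorer(record: WaveformRecord) -> float:
    return evaluate_rules(record).score


def constant_rule_scorer(value: float):
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"constant rule score outside [0,1]: {value}")

    def scorer(record: WaveformRecord) -> float:
        return value

    return scorer


def resolve_rule_scorer(spec: str):
    """Resolve a ``--rule-scorer`` string to a callable.

    Accepted forms: ``reference``, ``constant:<v>``, ``plugin:<path>`` where
    the plugin module must expose ``rule_score(record) -> float``.
    """
    if spec == "reference":
        return reference_rule_scorer
    if spec.startswith("constant:"):
        return constant_rule_scorer(float(spec.split(":", 1)[1]))
    if spec.startswith("plugin:"):
        path = spec.split(":", 1)[1]
        module_spec = importlib.util.spec_from_file_location("alarmsieve_plugin", path)
        if module_spec is None or module_spec.loader is None:
            raise ValidationError(f"cannot load rule plugin: {path}")
        module = importlib.util.module_from_spec(module_spec)
        module_spec.loader.exec_module(module)
        if not hasattr(module, "rule_score"):
            raise ValidationError(f"plugin {path} lacks a rule_score callable")
        return module.rule_score
    raise ValidationError(f"unknown rule scorer spec: {spec!r}")
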