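"""Record I/O, pre-processing and Siamese segment-pair extraction.

Records are multi-channel bedside-monitor waveforms sampled at 250 Hz with an
alarm raised 5 minutes in. Channels are mapped onto a fixed canonical role
tuple ``(ECG1, ECG2, PPG, ABP, RESP)``; roles absent from a file are kept,
flagged unavailable and zero-filled, so every downstream consumer sees a
constant-shape channel matrix.

A minimal WFDB reader/writer (header + 16-bit signal file, optional byte
offset) is included because the full ``wfdb`` package is not a dependency.
"""

from __future__ import annotations

import csv
import json
import os
import re
from dataclasses import dataclass, replace

import numpy as np

from .errors import DataIOError, ValidationError
from .seeding import substream

__all__ = [
    "ROLES",
    "ALARM_TYPES",
    "ALARM_TYPE_NAMES",
    "SEGMENT_SECONDS",
    "WaveformRecord",
    "SegmentPair",
    "read_record",
    "write_record_wfdb",
    "save_record_npz",
    "load_record_npz",
    "read_manifest",
    "write_manifest",
    "load_dataset",
    "preprocess",
    "alarm_segment",
    "extract_pair",
    "make_folds",
]

#: Canonical channel roles, in encoder input order.
ROLES = ("ECG1", "ECG2", "PPG", "ABP", "RESP")

#: The five alarm types, in one-hot order.
ALARM_TYPES = ("ASY", "EBR", "ETC", "VTA", "VFB")

#: Manifest spelling of each alarm type (Challenge convention).
ALARM_TYPE_NAMES = {
    "ASY": "Asystole",
    "EBR": "Bradycardia",
    "ETC": "Tachycardia",
    "VTA": "Ventricular_Tachycardia",
    "VFB": "Ventricular_Flutter_Fib",
}
_NAME_TO_TYPE = {v: k for k, v in ALARM_TYPE_NAMES.items()}
_NAME_TO_TYPE.update({k: k for k in ALARM_TYPES})

LABELS = ("true_alarm", "false_alarm", "unknown")
_LABEL_ALIASES = {
    "true": "true_alarm",
    "false": "false_alarm",
    "true_alarm": "true_alarm",
    "false_alarm": "false_alarm",
    "unknown": "unknown",
    "": "unknown",
}

#: Length of the alarm / baseline analysis windows in seconds.
SEGMENT_SECONDS = 10

# Signal-name patterns used to assign a file's channels to canonical roles.
_ECG_NAMES = {
    "I", "II", "III", "V", "AVR", "AVL", "AVF", "MCL",
    "V1", "V2", "V3", "V4", "V5", "V6", "ECG", "EKG",
}
_PPG_NAMES = {"PLETH", "PPG"}
_ABP_NAMES = {"ABP", "ART", "AO", "BP"}
_RESP_NAMES = {"RESP", "RESPIRATION", "IMP"}


def canonical_alarm_type(value: str) -> str:
    """Map a manifest alarm-type string (code or full name) to its code."""
    try:
        return _NAME_TO_TYPE[str(value)]
    except KeyError:
        raise ValidationError(f"unknown alarm type: {value!r}") from None


def canonical_label(value: str) -> str:
    try:
        return _LABEL_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValidationError(f"unknown alarm label: {value!r}") from None


@dataclass
class WaveformRecord:
    """One monitor record with a fixed 5-role channel map.

    ``channels`` maps every canonical role to a 1-D float array; all five
    arrays share one length. ``onset`` is the 0-based sample index at which
    the alarm was raised; only samples before it may influence a real-time
    decision.
    """

    record_id: str
    channels: dict[str, np.ndarray]
    available: dict[str, bool]
    fs: float
    alarm_type: str
    onset: int
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def matrix(self) -> np.ndarray:
        """Channel matrix of shape ``(len(ROLES), n_samples)`` in role order."""
        return np.stack([self.channels[r] for r in ROLES])

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.alarm_type not in ALARM_TYPES:
            raise ValidationError(f"unknown alarm type: {self.alarm_type!r}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label: {self.label!r}")
        if set(self.channels) != set(ROLES):
            raise ValidationError(
                f"channels must cover roles {ROLES}, got {tuple(self.channels)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError(f"channel lengths differ: {sorted(lengths)}")
        n = lengths.pop()
        if not 0 < self.onset <= n:
            raise ValidationError(
                f"onset {self.onset} outside record of {n} samples"
            )
        for role in ROLES:
            if not self.available.get(role, False):
                if np.any(self.channels[role] != 0.0):
                    raise ValidationError(
                        f"unavailable channel {role} must be zero-filled"
                    )


@dataclass
class SegmentPair:
    """Siamese input: the 10 s alarm window plus a same-length baseline window
    sampled from strictly earlier signal of the same record."""

    alarm_segment: np.ndarray      # (M, T)
    baseline_segment: np.ndarray   # (M, T)
    baseline_start: int
    label: str
    alarm_onehot: np.ndarray       # (5,)
    rule_score: float = 0.5

    def __post_init__(self) -> None:
        if self.alarm_segment.shape != self.baseline_segment.shape:
            raise ValidationError("alarm and baseline segments differ in shape")
        if self.label not in ("true_alarm", "false_alarm"):
            raise ValidationError(f"pair label must be known, got {self.label!r}")
        onehot = np.asarray(self.alarm_onehot, dtype=float)
        if onehot.shape != (len(ALARM_TYPES),) or not (
            np.isclose(onehot.sum(), 1.0) and set(np.unique(onehot)) <= {0.0, 1.0}
        ):
            raise ValidationError("alarm_onehot must be a length-5 one-hot vector")
        if not 0.0 <= self.rule_score <= 1.0:
            raise ValidationError(f"rule_score outside [0,1]: {self.rule_score}")


def alarm_onehot(alarm_type: str) -> np.ndarray:
    vec = np.zeros(len(ALARM_TYPES))
    vec[ALARM_TYPES.index(canonical_alarm_type(alarm_type))] = 1.0
    return vec


# ---------------------------------------------------------------------------
# WFDB-style header/signal I/O (format 16, little-endian, frame-interleaved)
# ---------------------------------------------------------------------------

_GAIN_RE = re.compile(r"^(?P<gain>-?[\d.]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?$")


def _parse_header(hea_path: str):
    try:
        with open(hea_path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    except OSError as exc:
        raise DataIOError(f"cannot read header {hea_path}: {exc}") from exc
    if not lines:
        raise DataIOError(f"empty header: {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise DataIOError(f"malformed record line in {hea_path}: {lines[0]!r}")
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0])
    nsamp = int(head[3])
    signals = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        if len(parts) < 2:
            raise DataIOError(f"malformed signal line in {hea_path}: {ln!r}")
        fname, fmt = parts[0], parts[1]
        offset = 0
        if "+" in fmt:
            fmt, off = fmt.split("+", 1)
            offset = int(off)
        gain, baseline = 200.0, 0
        if len(parts) >= 3:
            m = _GAIN_RE.match(parts[2])
            if m:
                gain = float(m.group("gain")) or 200.0
                if m.group("baseline") is not None:
                    baseline = int(m.group("baseline"))
        if len(parts) >= 5 and m and m.group("baseline") is None:
            # adc zero column doubles as baseline when none was given inline
            try:
                baseline = int(parts[4])
            except ValueError:
                pass
        desc = parts[8] if len(parts) >= 9 else (parts[-1] if len(parts) > 3 else "")
        signals.append(
            {"file": fname, "fmt": fmt, "offset": offset, "gain": gain,
             "baseline": baseline, "desc": desc}
        )
    return name, fs, nsamp, signals


def _read_dat(path: str, nsig: int, nsamp: int, fmt: str, offset: int) -> np.ndarray:
    if fmt != "16":
        raise DataIOError(f"unsupported WFDB signal format {fmt!r} in {path}")
    try:
        raw = np.fromfile(path, dtype="<i2", offset=offset)
    except OSError as exc:
        raise DataIOError(f"cannot read signal file {path}: {exc}") from exc
    need = nsig * nsamp
    if raw.size < need:
        raise DataIOError(
            f"{path}: expected {need} samples, found {raw.size}"
        )
    return raw[:need].reshape(nsamp, nsig).T


def _assign_roles(descriptions: list[str]) -> dict[int, str]:
    """Map signal indices to canonical roles; first two ECG leads win."""
    assignment: dict[int, str] = {}
    taken: set[str] = set()
    ecg_slots = ["ECG1", "ECG2"]
    for i, desc in enumerate(descriptions):
        token = desc.upper().strip()
        if token in _ECG_NAMES:
            if ecg_slots:
                assignment[i] = ecg_slots.pop(0)
        elif token in _PPG_NAMES and "PPG" not in taken:
            assignment[i] = "PPG"
        elif token in _ABP_NAMES and "ABP" not in taken:
            assignment[i] = "ABP"
        elif token in _RESP_NAMES and "RESP" not in taken:
            assignment[i] = "RESP"
        taken.update(assignment.values())
    return assignment


def read_record(path: str, manifest_row: dict) -> WaveformRecord:
    """Read a WFDB header/signal pair into a :class:`WaveformRecord`.

    ``path`` may point at the ``.hea`` file or at the record prefix.
    ``manifest_row`` must provide ``alarm_type`` (code or Challenge spelling)
    and may provide ``label``. Channel roles are assigned by matching signal
    descriptions; missing roles are zero-filled and flagged unavailable. The
    alarm onset is fixed at ``fs * 300`` (the real-time event convention).
    """
    prefix = path[:-4] if path.endswith(".hea") else path
    name, fs, nsamp, signals = _parse_header(prefix + ".hea")
    alarm_type = canonical_alarm_type(manifest_row["alarm_type"])
    label = canonical_label(manifest_row.get("label", "unknown"))

    onset = int(round(fs * 300))
    if nsamp < onset:
        raise ValidationError(
            f"record {name}: {nsamp} samples, shorter than onset {onset}"
        )

    # all signals of a record live in one file for format-16 Challenge data
    dat_path = os.path.join(os.path.dirname(prefix) or ".", signals[0]["file"])
    adc = _read_dat(dat_path, len(signals), nsamp, signals[0]["fmt"],
                    signals[0]["offset"])

    roles = _assign_roles([s["desc"] for s in signals])
    channels = {r: np.zeros(nsamp) for r in ROLES}
    available = {r: False for r in ROLES}
    for idx, role in roles.items():
        sig = signals[idx]
        physical = (adc[idx].astype(np.float64) - sig["baseline"]) / sig["gain"]
        # NaN-coded gaps count as missing data and are imputed with zero
        physical[~np.isfinite(physical)] = 0.0
        channels[role] = physical
        available[role] = True

    return WaveformRecord(
        record_id=manifest_row.get("record_id", name),
        channels=channels,
        available=available,
        fs=fs,
        alarm_type=alarm_type,
        onset=onset,
        label=label,
    )


_WRITE_GAIN = 8000.0


def write_record_wfdb(record: WaveformRecord, directory: str) -> str:
    """Write ``record`` as a format-16 WFDB header/signal pair.

    Only available channels are written. Returns the header path.
    """
    os.makedirs(directory, exist_ok=True)
    roles = [r for r in ROLES if record.available[r]]
    if not roles:
        raise ValidationError("cannot write a record with no available channels")
    n = record.n_samples
    dat_name = f"{record.record_id}.dat"
    sig = np.stack([record.channels[r] for r in roles], axis=1)
    adc = np.clip(np.round(sig * _WRITE_GAIN), -32768, 32767).astype("<i2")
    adc.tofile(os.path.join(directory, dat_name))

    desc = {"ECG1": "II", "ECG2": "V", "PPG": "PLETH", "ABP": "ABP", "RESP": "RESP"}
    lines = [f"{record.record_id} {len(roles)} {record.fs:g} {n}"]
    for r in roles:
        lines.append(
            f"{dat_name} 16 {_WRITE_GAIN:g}(0)/mV 16 0 0 0 0 {desc[r]}"
        )
    hea_path = os.path.join(directory, f"{record.record_id}.hea")
    with open(hea_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return hea_path


# ---------------------------------------------------------------------------
# Internal fixture container: .npz channel matrix + JSON sidecar, bit-exact
# ---------------------------------------------------------------------------

def save_record_npz(record: WaveformRecord, prefix: str) -> None:
    np.savez_compressed(prefix + ".npz", matrix=record.matrix)
    meta = {
        "record_id": record.record_id,
        "available": {r: bool(record.available[r]) for r in ROLES},
        "fs": record.fs,
        "alarm_type": record.alarm_type,
        "onset": record.onset,
        "label": record.label,
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_record_npz(prefix: str) -> WaveformRecord:
    try:
        matrix = np.load(prefix + ".npz")["matrix"]
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
    except OSError as exc:
        raise DataIOError(f"cannot load fixture {prefix}: {exc}") from exc
    channels = {r: matrix[i] for i, r in enumerate(ROLES)}
    return WaveformRecord(
        record_id=meta["record_id"],
        channels=channels,
        available=dict(meta["available"]),
        fs=meta["fs"],
        alarm_type=meta["alarm_type"],
        onset=meta["onset"],
        label=meta["label"],
    )


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("record_id", "alarm_type", "label")


def read_manifest(path: str) -> list[dict]:
    """Read an alarm manifest CSV; validates alarm types and labels."""
    try:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    except OSError as exc:
        raise DataIOError(f"cannot read manifest {path}: {exc}") from exc
    out = []
    for row in rows:
        out.append(
            {
                "record_id": row["record_id"],
                "alarm_type": canonical_alarm_type(row["alarm_type"]),
                "label": canonical_label(row.get("label", "unknown")),
            }
        )
    return out


def write_manifest(rows: list[dict], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for row in rows:
            label = {"true_alarm": "true", "false_alarm": "false"}.get(
                row["label"], "unknown"
            )
            writer.writerow(
                [row["record_id"], ALARM_TYPE_NAMES[row["alarm_type"]], label]
            )


def read_challenge_manifest(data_dir: str) -> list[dict]:
    """Parse a PhysioNet Challenge 2015 style record list.

    Prefers ``manifest.csv``; otherwise reads an ``ALARMS`` file whose rows
    are ``record,alarm_type,label`` with the label given as 1/0 (true/false
    alarm). Falls back to a ``RECORDS`` list with unknown labels, inferring
    the alarm type from the record-name prefix (a=ASY, b=EBR, t=ETC, v=VTA,
    f=VFB).
    """
    csv_path = os.path.join(data_dir, "manifest.csv")
    if os.path.exists(csv_path):
        return read_manifest(csv_path)
    prefix_map = {"a": "ASY", "b": "EBR", "t": "ETC", "v": "VTA", "f": "VFB"}
    alarms_path = os.path.join(data_dir, "ALARMS")
    if os.path.exists(alarms_path):
        rows = []
        with open(alarms_path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.replace("\t", ",").split(",")]
                if len(parts) < 2 or not parts[0]:
                    continue
                label = "unknown"
                if len(parts) >= 3:
                    label = {"1": "true_alarm", "0": "false_alarm"}.get(
                        parts[2], canonical_label(parts[2])
                    )
                rows.append(
                    {
                        "record_id": parts[0],
                        "alarm_type": canonical_alarm_type(parts[1]),
                        "label": label,
                    }
                )
        return rows
    records_path = os.path.join(data_dir, "RECORDS")
    if not os.path.exists(records_path):
        raise DataIOError(f"no manifest.csv, ALARMS or RECORDS in {data_dir}")
    rows = []
    with open(records_path) as fh:
        for line in fh:
            name = line.strip()
            if not name:
                continue
            typ = prefix_map.get(name[0].lower())
            if typ is None:
                raise ValidationError(f"cannot infer alarm type of {name!r}")
            rows.append({"record_id": name, "alarm_type": typ, "label": "unknown"})
    return rows


def load_dataset(data_dir: str, manifest: str = "manifest.csv") -> list[WaveformRecord]:
    """Load every record named by ``data_dir/manifest``.

    Records stored as fixtures (``.npz`` + ``.json``) are preferred when both
    representations exist; otherwise the WFDB pair is read.
    """
    rows = read_manifest(os.path.join(data_dir, manifest))
    records = []
    for row in rows:
        prefix = os.path.join(data_dir, row["record_id"])
        if os.path.exists(prefix + ".npz"):
            rec = load_record_npz(prefix)
            rec.alarm_type = row["alarm_type"]
            rec.label = row["label"]
        else:
            rec = read_record(prefix, row)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Pre-processing and segment extraction
# ---------------------------------------------------------------------------

def preprocess(record: WaveformRecord) -> WaveformRecord:
    """Truncate to the pre-onset window and min–max scale each channel to [0, 1].

    Scaling statistics are computed on ``[0, onset)`` only. Channels whose
    pre-onset range is (numerically) zero map to all-zeros, the same value
    used to impute missing channels; unavailable channels are left untouched.
    The operation is idempotent.
    """
    if record.onset <= 0:
        raise ValidationError("onset must be positive")
    channels = {}
    for role in ROLES:
        x = record.channels[role][: record.onset].astype(np.float64)
        if record.available[role]:
            lo, hi = x.min(), x.max()
            if hi - lo > 0:
                x = (x - lo) / (hi - lo)
            else:
                x = np.zeros_like(x)
        channels[role] = x
    return replace(record, channels=channels, onset=record.onset)


def alarm_segment(record: WaveformRecord) -> np.ndarray:
    """The ``(M, fs*10)`` window immediately preceding the alarm onset."""
    t_seg = int(round(record.fs * SEGMENT_SECONDS))
    if record.onset < t_seg:
        raise ValidationError("record too short for an alarm segment")
    return record.matrix[:, record.onset - t_seg : record.onset]


def extract_pair(
    record: WaveformRecord,
    rng_seed: int,
    rule_score: float = 0.5,
) -> SegmentPair:
    """Extract the Siamese (alarm, baseline) segment pair.

    The alarm segment covers ``[onset - fs*10, onset)``. The baseline start is
    drawn uniformly from ``{0, ..., onset - 2*fs*10}`` with ``rng_seed``, so
    the baseline window ends at or before ``onset - fs*10``.
    """
    t_seg = int(round(record.fs * SEGMENT_SECONDS))
    if record.onset < 2 * t_seg:
        raise ValidationError(
            f"onset {record.onset} leaves no legal baseline window "
            f"(need >= {2 * t_seg} samples)"
        )
    matrix = record.matrix
    alarm = matrix[:, record.onset - t_seg : record.onset]
    rng = substream(rng_seed, "baseline", record.record_id)
    start = int(rng.integers(0, record.onset - 2 * t_seg + 1))
    baseline = matrix[:, start : start + t_seg]
    return SegmentPair(
        alarm_segment=alarm,
        baseline_segment=baseline,
        baseline_start=start,
        label=record.label,
        alarm_onehot=alarm_onehot(record.alarm_type),
        rule_score=rule_score,
    )


def make_folds(
    record_ids: list[str],
    labels: list[str],
    types: list[str],
    k: int,
    rng_seed: int,
) -> list[list[str]]:
    """Split ids into ``k`` folds, stratified jointly on (alarm type, label).

    Members of each stratum are shuffled with a seeded stream and dealt
    cyclically across folds through a shared pointer, so fold sizes differ by
    at most one overall and within every stratum.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if len(record_ids) < k:
        raise ValidationError(f"need at least {k} records for {k} folds")
    if not (len(record_ids) == len(labels) == len(types)):
        raise ValidationError("record_ids, labels and types must align")

    strata: dict[tuple[str, str], list[str]] = {}
    for rid, lab, typ in zip(record_ids, labels, types):
        strata.setdefault((canonical_alarm_type(typ), canonical_label(lab)), []).append(rid)

    rng = substream(rng_seed, "folds")
    folds: list[list[str]] = [[] for _ in range(k)]
    pointer = int(rng.integers(0, k))
    for key in sorted(strata):
        members = sorted(strata[key])
        rng.shuffle(members)
        for rid in members:
            folds[pointer % k].append(rid)
            pointer += 1
    return folds
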