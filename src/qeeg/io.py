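"""Core data types and on-disk formats.

An :class:`EEGRecording` is a channels x samples matrix of voltages in
microvolts plus a sampling rate and 10-20 electrode labels.  Two disk
formats are supported: 16-bit EDF (the EEG interchange standard; written by
this module, read back through :mod:`mne`) and a dependency-light raw-array
format (``.dat`` float64 + ``.json`` sidecar header) used mainly in tests.

Cohort metadata (group, infarct side, NIHSS at the two timepoints) travels
as a CSV with header ``subject_id,group,infarct_side,age,sex,nihss_t0,
nihss_t1``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MissingChannelError, ValidationError

#: Electrodes the analysis pipeline requires (10-20 system; odd index = left
#: hemisphere, even = right).
REQUIRED_CHANNELS = ("C3", "C4", "P3", "P4", "O1", "O2")

SESSIONS = ("T0", "T1")
GROUPS = ("experimental", "control")
SIDES = ("left", "right")
SEXES = ("F", "M")

COHORT_COLUMNS = (
    "subject_id",
    "group",
    "infarct_side",
    "age",
    "sex",
    "nihss_t0",
    "nihss_t1",
)

#: Left-hemisphere members of the required montage, keyed by region.
LEFT_CHANNELS = ("C3", "P3", "O1")
RIGHT_CHANNELS = ("C4", "P4", "O2")


def normalize_label(label: str) -> str:
    """Canonical form of an electrode label: stripped, upper-case."""
    return label.strip().upper()


@dataclass
class EEGRecording:
    """A multi-channel EEG recording in physical units (microvolts).

    Parameters
    ----------
    subject_id : str
    session : str
        One of ``"T0"`` (baseline) or ``"T1"`` (after treatment).
    fs : float
        Sampling frequency in Hz.
    channels : sequence of str
        Ordered electrode labels, one per data row.
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    """

    subject_id: str
    session: str
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self):
        if self.session not in SESSIONS:
            raise ValidationError(
                f"session must be one of {SESSIONS}, got {self.session!r}"
            )
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        self.channels = tuple(str(c) for c in self.channels)
        if len(self.channels) == 0:
            raise ValidationError("channel list is empty")
        norm = [normalize_label(c) for c in self.channels]
        if len(set(norm)) != len(norm):
            raise ValidationError(f"duplicate channel labels in {self.channels}")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"{len(self.channels)} channel labels but "
                f"{self.data.shape[0]} data rows"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        norm = [normalize_label(c) for c in self.channels]
        key = normalize_label(label)
        try:
            return norm.index(key)
        except ValueError:
            raise MissingChannelError([label], self.subject_id) from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def require_channels(self, labels: Sequence[str] = REQUIRED_CHANNELS) -> None:
        """Raise :class:`MissingChannelError` naming any absent labels."""
        have = {normalize_label(c) for c in self.channels}
        missing = [l for l in labels if normalize_label(l) not in have]
        if missing:
            raise MissingChannelError(missing, self.subject_id)

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(self.subject_id, self.session, self.fs,
                            self.channels, data)


@dataclass
class SubjectRecord:
    """Clinical metadata for one enrolled subject.

    ``delta_nihss`` (NIHSS_T0 - NIHSS_T1; positive = improvement) is exposed
    as a property rather than a stored field so it can never disagree with
    the two scores.
    """

    subject_id: str
    group: str
    infarct_side: str
    age: int
    sex: str
    nihss_t0: int
    nihss_t1: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; allowed: {GROUPS}"
            )
        if self.infarct_side not in SIDES:
            raise ValidationError(
                f"unknown infarct_side {self.infarct_side!r}; allowed: {SIDES}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}; allowed: {SEXES}")
        self.age = int(self.age)
        self.nihss_t0 = int(self.nihss_t0)
        self.nihss_t1 = int(self.nihss_t1)
        if self.nihss_t1 < 0:
            raise ValidationError(
                f"{self.subject_id}: nihss_t1 must be >= 0, got {self.nihss_t1}"
            )

    def validate_inclusion(self, strict: bool = False) -> None:
        """Check the 5-20 baseline-NIHSS inclusion window.

        Outside the window: warn by default, raise when ``strict``.
        """
        if not 5 <= self.nihss_t0 <= 20:
            msg = (f"{self.subject_id}: nihss_t0={self.nihss_t0} outside the "
                   f"inclusion range [5, 20]")
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)

    @property
    def delta_nihss(self) -> int:
        return self.nihss_t0 - self.nihss_t1

    def affected_channels(self) -> tuple[str, ...]:
        """Electrodes over the infarcted hemisphere (odd labels = left)."""
        return LEFT_CHANNELS if self.infarct_side == "left" else RIGHT_CHANNELS


@dataclass
class EpochSet:
    """The artifact-free segments selected from one recording.

    When selection succeeds there are exactly ``n_epochs`` (default 5)
    epochs of ``epoch_length_s`` (default 4 s) each, i.e. 20 s of signal.
    """

    subject_id: str
    session: str
    fs: float
    channels: tuple[str, ...]
    epochs: list[np.ndarray]
    epoch_length_s: float

    def __post_init__(self):
        self.channels = tuple(self.channels)
        want = int(round(self.epoch_length_s * self.fs))
        for i, ep in enumerate(self.epochs):
            ep = np.asarray(ep, dtype=float)
            if ep.shape != (len(self.channels), want):
                raise ValidationError(
                    f"epoch {i} has shape {ep.shape}, expected "
                    f"({len(self.channels)}, {want})"
                )
            self.epochs[i] = ep

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def channel_index(self, label: str) -> int:
        norm = [normalize_label(c) for c in self.channels]
        key = normalize_label(label)
        try:
            return norm.index(key)
        except ValueError:
            raise MissingChannelError([label], self.subject_id) from None

    def channel_epochs(self, label: str) -> np.ndarray:
        """All epochs for one channel, shape (n_epochs, n_samples)."""
        i = self.channel_index(label)
        return np.stack([ep[i] for ep in self.epochs])


# ---------------------------------------------------------------------------
# EDF writing (16-bit EDF, one-second data records)
# ---------------------------------------------------------------------------

_EDF_DIGITAL_MAX = 32767
_EDF_DIGITAL_MIN = -32768


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int) -> str:
    """Shortest decimal representation of ``x`` fitting an EDF field."""
    for nd in range(6, -1, -1):
        s = f"{x:.{nd}f}".rstrip("0").rstrip(".")
        if len(s) <= width:
            return s
    raise ValidationError(f"cannot format {x} in {width} chars")


def write_edf(recording: EEGRecording, path) -> Path:
    """Write a recording as 16-bit EDF with one-second data records.

    The physical range is set per channel to (just above) the signal's
    absolute maximum, so the round-trip error is bounded by one quantization
    step of that range.  Requires an integer sampling rate and a whole number
    of seconds of data.  The start date/time is fixed (01.01.2000) so that
    repeated writes are byte-identical.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError(f"EDF writer requires integer fs, got {fs}")
    spr = int(round(fs))  # samples per 1-s record
    n_samples = recording.n_samples
    if n_samples % spr != 0:
        raise ValidationError(
            f"EDF writer requires a whole number of seconds: {n_samples} "
            f"samples at fs={spr}"
        )
    n_records = n_samples // spr
    ns = len(recording.channels)

    # Per-channel symmetric physical range covering the data.
    phys_max = []
    for row in recording.data:
        m = float(np.max(np.abs(row))) if row.size else 0.0
        m = max(m * 1.000001, 1e-3)  # avoid zero range; tiny headroom
        phys_max.append(m)

    header = bytearray()
    header += _edf_field("0", 8)  # version
    header += _edf_field(f"{recording.subject_id} {recording.session}", 80)
    header += _edf_field("qeeg recording", 80)
    header += _edf_field("01.01.00", 8)  # fixed start date -> deterministic
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + ns), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)  # record duration, seconds
    header += _edf_field(ns, 4)

    def signal_fields(fmt, width):
        out = bytearray()
        for ch in range(ns):
            out += _edf_field(fmt(ch), width)
        return out

    header += signal_fields(lambda c: recording.channels[c], 16)
    header += signal_fields(lambda c: "", 80)  # transducer
    header += signal_fields(lambda c: "uV", 8)
    header += signal_fields(lambda c: "-" + _fmt_float(phys_max[c], 7), 8)
    header += signal_fields(lambda c: _fmt_float(phys_max[c], 8), 8)
    header += signal_fields(lambda c: _EDF_DIGITAL_MIN, 8)
    header += signal_fields(lambda c: _EDF_DIGITAL_MAX, 8)
    header += signal_fields(lambda c: "", 80)  # prefiltering
    header += signal_fields(lambda c: spr, 8)
    header += signal_fields(lambda c: "", 32)  # reserved

    # Digitize: physical range [-pm, pm] -> digital [-32768, 32767].
    digital = np.empty((ns, n_samples), dtype="<i2")
    for c in range(ns):
        pm = phys_max[c]
        scale = (_EDF_DIGITAL_MAX - _EDF_DIGITAL_MIN) / (2 * pm)
        d = np.rint((recording.data[c] + pm) * scale) + _EDF_DIGITAL_MIN
        digital[c] = np.clip(d, _EDF_DIGITAL_MIN, _EDF_DIGITAL_MAX)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # EDF interleaves: for each record, each channel's block of samples.
        blocks = digital.reshape(ns, n_records, spr)
        for r in range(n_records):
            fh.write(blocks[:, r, :].tobytes())
    return path


_STEM_RE = re.compile(r"^(?P<sid>.+)_(?P<sess>T[01])$")


def _infer_identity(path: Path, subject_id, session):
    """Subject/session from explicit args or a ``<sid>_<T0|T1>`` filename."""
    if subject_id is None or session is None:
        m = _STEM_RE.match(path.stem)
        if m:
            subject_id = subject_id or m.group("sid")
            session = session or m.group("sess")
    return subject_id or path.stem, session or "T0"


def read_edf(path, subject_id: str | None = None, session: str | None = None,
             require: Sequence[str] | None = REQUIRED_CHANNELS) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts).

    Header sampling rate and labels are taken as-is; values are converted
    to physical units.  ``require`` lists channels that must be present
    (pass ``None`` to accept any montage).  Subject and session default to
    a ``<subject>_<T0|T1>`` filename convention.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise FormatError(f"{path} is not a readable EDF file: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    subject_id, session = _infer_identity(path, subject_id, session)
    rec = EEGRecording(
        subject_id=subject_id,
        session=session,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        data=data_uv,
    )
    if require is not None:
        rec.require_channels(require)
    return rec


# ---------------------------------------------------------------------------
# Raw-array sidecar format
# ---------------------------------------------------------------------------

def write_array(recording: EEGRecording, basepath) -> Path:
    """Write ``<basepath>.dat`` (float64 LE, channel-major) + ``.json`` header."""
    basepath = Path(basepath)
    dat = basepath.with_suffix(".dat")
    recording.data.astype("<f8").tofile(dat)
    header = {
        "subject_id": recording.subject_id,
        "session": recording.session,
        "fs": recording.fs,
        "channels": list(recording.channels),
        "shape": list(recording.data.shape),
        "dtype": "<f8",
        "unit": "uV",
    }
    basepath.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return dat


def read_array(basepath, require: Sequence[str] | None = None) -> EEGRecording:
    basepath = Path(basepath)
    try:
        header = json.loads(basepath.with_suffix(".json").read_text())
        shape = tuple(header["shape"])
        data = np.fromfile(basepath.with_suffix(".dat"),
                           dtype=header.get("dtype", "<f8")).reshape(shape)
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"bad array header for {basepath}: {exc}") from exc
    rec = EEGRecording(header["subject_id"], header["session"],
                       float(header["fs"]), tuple(header["channels"]), data)
    if require is not None:
        rec.require_channels(require)
    return rec


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

def read_cohort_csv(path, strict: bool = False) -> list[SubjectRecord]:
    """Read cohort metadata; one :class:`SubjectRecord` per row.

    Enum fields are validated; a baseline NIHSS outside the 5-20 inclusion
    window warns (or raises when ``strict``).
    """
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing columns {sorted(missing)}; expected header "
            f"{','.join(COHORT_COLUMNS)}"
        )
    records = []
    for _, row in df.iterrows():
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            infarct_side=str(row["infarct_side"]),
            age=int(row["age"]),
            sex=str(row["sex"]),
            nihss_t0=int(row["nihss_t0"]),
            nihss_t1=int(row["nihss_t1"]),
        )
        rec.validate_inclusion(strict=strict)
        records.append(rec)
    return records


def write_cohort_csv(records: Sequence[SubjectRecord], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "infarct_side": r.infarct_side,
                "age": r.age,
                "sex": r.sex,
                "nihss_t0": r.nihss_t0,
                "nihss_t1": r.nihss_t1,
            }
            for r in records
        ],
        columns=list(COHORT_COLUMNS),
    )
    df.to_csv(path, index=False)
    return path


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame with a ``delta_nihss`` column appended."""
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "infarct_side": r.infarct_side,
                "age": r.age,
                "sex": r.sex,
                "nihss_t0": r.nihss_t0,
                "nihss_t1": r.nihss_t1,
                "delta_nihss": r.delta_nihss,
            }
            for r in records
        ]
    )
    return df
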