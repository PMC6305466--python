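"""Reading and writing of EEG recordings and annotation tracks.

Recordings are held in :class:`RawRecording`: a channels x samples matrix in
microvolts with 10-20-system channel labels, a sampling rate and a list of
annotations. Two on-disk formats are supported:

* EDF/EDF+ — read through :mod:`mne`; written by a minimal 16-bit EDF writer
  (one data record per second).
* wide CSV — header row of channel labels, one row per sample, values in
  microvolts, with a JSON sidecar (``<file>.meta.json``) carrying the
  sampling rate, subject id and unit.

Annotations live in a separate TSV (columns ``onset_s``, ``duration_s``,
``label``) regardless of the recording format, so EDF and CSV inputs behave
identically downstream.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

#: The 12-channel montage used throughout: forehead blink reference, five
#: frontal and six parietal sites of the 10-20 system.
MONTAGE: tuple[str, ...] = (
    "FPz", "AF3", "AF4", "F3", "Fz", "F4",
    "P3", "P7", "Pz", "P4", "P8", "POz",
)

#: Channel dominated by eye-blink potentials; used for blink detection and
#: regression, excluded from spectral features.
BLINK_REFERENCE = "FPz"

FRONTAL_CHANNELS: tuple[str, ...] = ("AF3", "AF4", "F3", "Fz", "F4")
PARIETAL_CHANNELS: tuple[str, ...] = ("P3", "P7", "Pz", "P4", "P8", "POz")

HOURS = ("Normal", "Rush")
ROADS = ("Easy", "Hard")
LAPS = (1, 2, 3)
EVENT_TYPES = ("Pedestrian", "Car")
BASELINE_LABEL = "eyes_closed"


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Annotation:
    """A labeled time interval: baseline, condition segment, or event.

    Labels follow a small grammar:

    * ``eyes_closed`` — resting baseline used for alpha-peak estimation;
    * ``hour=<Normal|Rush>;road=<Easy|Hard>;lap=<1|2|3>`` — a condition
      segment (key order free);
    * ``event=<Pedestrian|Car>[;key=value...]`` — an acted event; extra keys
      (e.g. a position id) are kept in :attr:`attrs`.
    """

    onset: float
    duration: float
    label: str
    attrs: dict = field(default_factory=dict, compare=False)

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def kind(self) -> str:
        if self.label == BASELINE_LABEL:
            return "baseline"
        return "event" if "event" in self.attrs else "condition"

    @property
    def hour(self) -> str | None:
        return self.attrs.get("hour")

    @property
    def road(self) -> str | None:
        return self.attrs.get("road")

    @property
    def lap(self) -> int | None:
        lap = self.attrs.get("lap")
        return None if lap is None else int(lap)

    @property
    def event_type(self) -> str | None:
        return self.attrs.get("event")

    def contains(self, t: float) -> bool:
        return self.onset <= t < self.end


def parse_label(label: str) -> dict:
    """Parse an annotation label into its attribute dict, validating it
    against the label grammar. Raises :class:`InputError` on violation."""
    label = label.strip()
    if label == BASELINE_LABEL:
        return {}
    attrs: dict = {}
    for part in label.split(";"):
        if "=" not in part:
            raise InputError(
                f"annotation label {label!r}: segment {part!r} is not key=value"
            )
        key, _, value = part.partition("=")
        key, value = key.strip(), value.strip()
        if key in attrs:
            raise InputError(f"annotation label {label!r}: duplicate key {key!r}")
        attrs[key] = value
    if "event" in attrs:
        if attrs["event"] not in EVENT_TYPES:
            raise InputError(
                f"unknown event type {attrs['event']!r}; expected one of {EVENT_TYPES}"
            )
        return attrs
    # condition segment: hour, road, lap all required
    missing = {"hour", "road", "lap"} - attrs.keys()
    if missing:
        raise InputError(
            f"condition label {label!r} lacks required keys: {sorted(missing)}"
        )
    if attrs["hour"] not in HOURS:
        raise InputError(f"hour must be one of {HOURS}, got {attrs['hour']!r}")
    if attrs["road"] not in ROADS:
        raise InputError(f"road must be one of {ROADS}, got {attrs['road']!r}")
    try:
        lap = int(attrs["lap"])
    except ValueError:
        lap = -1
    if lap not in LAPS:
        raise InputError(f"lap must be one of {LAPS}, got {attrs['lap']!r}")
    attrs["lap"] = lap
    return attrs


def make_annotation(onset: float, duration: float, label: str) -> Annotation:
    if duration < 0 or onset < 0:
        raise InputError(
            f"annotation {label!r}: onset and duration must be nonnegative "
            f"(got onset={onset}, duration={duration})"
        )
    return Annotation(onset, duration, label, parse_label(label))


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read a TSV annotation track (header ``onset_s  duration_s  label``),
    validate every label against the grammar and return the annotations
    sorted by onset."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    out: list[Annotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["onset_s", "duration_s", "label"]:
            raise InputError(
                f"{path}: expected header 'onset_s\\tduration_s\\tlabel', got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                onset, duration = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-numeric onset/duration") from exc
            try:
                out.append(make_annotation(onset, duration, parts[2]))
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    out.sort(key=lambda a: a.onset)
    return out


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("onset_s\tduration_s\tlabel\n")
        for ann in sorted(annotations, key=lambda a: a.onset):
            fh.write(f"{ann.onset:.6g}\t{ann.duration:.6g}\t{ann.label}\n")


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """A labeled multichannel EEG time series in microvolts."""

    data: np.ndarray                     # (n_channels, n_samples), uV
    channel_labels: list[str]
    sampling_rate: float                 # Hz
    annotations: list[Annotation] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = list(self.channel_labels)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 2:
            raise InputError("data must be a channels x samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise InputError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InputError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        for ann in self.annotations:
            if ann.end > self.duration + 1e-9:
                raise InputError(
                    f"annotation {ann.label!r} ([{ann.onset}, {ann.end}] s) "
                    f"extends beyond the {self.duration:.3f}-s recording"
                )

    # -- convenience --------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InputError(
                f"channel {label!r} not present (have {self.channel_labels})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        return RawRecording(
            data=data,
            channel_labels=list(self.channel_labels),
            sampling_rate=self.sampling_rate,
            annotations=list(self.annotations),
            subject_id=self.subject_id,
        )

    def require_channels(self, labels: Sequence[str]) -> None:
        missing = [lb for lb in labels if lb not in self.channel_labels]
        if missing:
            raise InputError(f"required channels absent: {missing}")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_recording(rec: RawRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as wide CSV (+ JSON sidecar) or EDF."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        pd.DataFrame(rec.data.T, columns=rec.channel_labels).to_csv(path, index=False)
        meta = {
            "sampling_rate_hz": rec.sampling_rate,
            "subject_id": rec.subject_id,
            "unit": "uV",
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise InputError(f"unknown recording format {fmt!r} (expected 'edf' or 'csv')")


def read_recording(
    path: str | Path,
    format: str | None = None,
    require_channels: Sequence[str] | None = None,
) -> RawRecording:
    """Read an EDF or wide-CSV recording, converting to microvolts.

    ``require_channels`` lets callers fail fast, with an error naming the
    absent labels, when the downstream configuration needs specific sites.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"recording not found: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        rec = _read_csv(path)
    elif fmt == "edf":
        rec = _read_edf(path)
    else:
        raise InputError(f"unknown recording format {fmt!r} (expected 'edf' or 'csv')")
    if require_channels is not None:
        rec.require_channels(require_channels)
    return rec


def _read_csv(path: Path) -> RawRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise InputError(f"CSV recording {path} lacks sidecar metadata {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    try:
        fs = float(meta["sampling_rate_hz"])
    except KeyError as exc:
        raise InputError(f"{sidecar}: missing key 'sampling_rate_hz'") from exc
    frame = pd.read_csv(path)
    if frame.isna().any().any():
        raise InputError(f"{path}: missing values (inconsistent channel lengths?)")
    data = frame.to_numpy(dtype=float).T
    unit = str(meta.get("unit", "uV"))
    scale = {"uv": 1.0, "mv": 1e3, "v": 1e6}.get(unit.lower().replace("µ", "u"))
    if scale is None:
        raise InputError(f"{sidecar}: unknown unit {unit!r}")
    return RawRecording(
        data=data * scale,
        channel_labels=list(frame.columns),
        sampling_rate=fs,
        subject_id=str(meta.get("subject_id", "")),
    )


def _read_edf(path: Path) -> RawRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # mne normalizes physical dimensions to SI volts for EEG channels, so a
    # channel declared in mV is already rescaled; one factor takes us to uV.
    data = raw.get_data() * 1e6
    subject = ""
    info_sub = raw.info.get("subject_info") or {}
    subject = info_sub.get("his_id") or info_sub.get("last_name") or ""
    labels = [ch[4:] if ch.startswith("EEG ") else ch for ch in raw.ch_names]
    return RawRecording(
        data=data,
        channel_labels=labels,
        sampling_rate=float(raw.info["sfreq"]),
        subject_id=subject,
    )


# ---------------------------------------------------------------------------
# minimal EDF writer
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    out = value[:width].ljust(width)
    return out.encode("ascii")


def _edf_num(v: float, width: int = 8) -> str:
    # shortest representation that fits the fixed-width header field
    for prec in range(6, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= width:
            return s
    return f"{v:.0e}"[:width]


def _write_edf(rec: RawRecording, path: Path) -> None:
    """Write a 16-bit EDF file with one data record per second.

    The recording length must be a whole number of seconds and the sampling
    rate an integer, so that samples fill whole records without padding.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise InputError(f"EDF export needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise InputError(
            "EDF export needs a whole number of seconds "
            f"({rec.n_samples} samples at {fs} Hz)"
        )
    n_records = rec.n_samples // fs
    nch = rec.n_channels

    phys_min, phys_max = [], []
    digital = np.empty((nch, rec.n_samples), dtype="<i2")
    for c in range(nch):
        x = rec.data[c]
        lim = float(np.max(np.abs(x))) if x.size else 1.0
        lim = max(lim, 1e-6)
        # digitize against the header-rounded limits so read-back is exact
        pmax = float(_edf_num(lim * 1.001))
        pmin = -pmax
        phys_min.append(pmin)
        phys_max.append(pmax)
        scaled = (x - pmin) / (pmax - pmin) * 65535.0 - 32768.0
        digital[c] = np.clip(np.round(scaled), -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(rec.subject_id or "X", 80))
        fh.write(_edf_field("Startdate 01-JAN-2000", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(256 * (nch + 1)), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field("1", 8))
        fh.write(_edf_field(str(nch), 4))
        for label in rec.channel_labels:
            fh.write(_edf_field(label, 16))
        for _ in range(nch):
            fh.write(_edf_field("", 80))          # transducer
        for _ in range(nch):
            fh.write(_edf_field("uV", 8))
        for v in phys_min:
            fh.write(_edf_field(_edf_num(v), 8))
        for v in phys_max:
            fh.write(_edf_field(_edf_num(v), 8))
        for _ in range(nch):
            fh.write(_edf_field("-32768", 8))
        for _ in range(nch):
            fh.write(_edf_field("32767", 8))
        for _ in range(nch):
            fh.write(_edf_field("", 80))          # prefiltering
        for _ in range(nch):
            fh.write(_edf_field(str(fs), 8))
        for _ in range(nch):
            fh.write(_edf_field("", 32))
        for r in range(n_records):
            sl = slice(r * fs, (r + 1) * fs)
            for c in range(nch):
                fh.write(struct.pack(f"<{fs}h", *digital[c, sl]))
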