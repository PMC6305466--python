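"""Signal conditioning: band-pass filtering, blink removal, sliding-window
epoching and artifact rejection.

The processing chain mirrors standard practice for workload neurometrics:

1. zero-phase fourth-order Butterworth band-pass (1–30 Hz by default);
2. blink correction driven by the forehead channel (FPz): blinks are
   detected on a low-passed copy of FPz and, inside each detected interval,
   the FPz-correlated component is regressed out of every other channel —
   outside blink intervals the data are untouched, so no epochs are lost;
3. segmentation into 2-s epochs slid by 0.125 s;
4. per-epoch artifact flagging on every analysis channel by three criteria:
   amplitude beyond ±100 μV, least-squares trend slope beyond 10 μV/s, and
   sample-to-sample step beyond 25 μV. Any channel failing any criterion
   flags the whole epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .exceptions import ConfigError, InputError
from .io import BLINK_REFERENCE, RawRecording


@dataclass
class PreprocessConfig:
    """Filtering, epoching and artifact-rejection parameters.

    Defaults are the standard settings for this neurometric: 1–30 Hz
    fourth-order Butterworth, 2-s epochs shifted by 0.125 s, and rejection
    thresholds of 100 μV (amplitude), 10 μV/s (trend slope) and 25 μV
    (sample-to-sample step).
    """

    highpass_cutoff_hz: float = 1.0
    lowpass_cutoff_hz: float = 30.0
    filter_order: int = 4
    epoch_length_s: float = 2.0
    epoch_shift_s: float = 0.125
    amplitude_threshold_uv: float = 100.0
    trend_slope_threshold_uv_s: float = 10.0
    step_threshold_uv: float = 25.0

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.highpass_cutoff_hz < self.lowpass_cutoff_hz:
            raise ConfigError(
                f"need 0 < highpass ({self.highpass_cutoff_hz}) "
                f"< lowpass ({self.lowpass_cutoff_hz})"
            )
        if self.lowpass_cutoff_hz >= sampling_rate / 2:
            raise ConfigError(
                f"lowpass cutoff {self.lowpass_cutoff_hz} Hz >= Nyquist "
                f"({sampling_rate / 2} Hz)"
            )
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if not 0 < self.epoch_shift_s <= self.epoch_length_s:
            raise ConfigError("need 0 < epoch_shift_s <= epoch_length_s")
        for name in ("epoch_length_s", "epoch_shift_s"):
            samples = getattr(self, name) * sampling_rate
            if abs(samples - round(samples)) > 1e-6:
                raise ConfigError(
                    f"{name}={getattr(self, name)} s is not a multiple of the "
                    f"sample period at {sampling_rate} Hz"
                )
        for name in (
            "amplitude_threshold_uv",
            "trend_slope_threshold_uv_s",
            "step_threshold_uv",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")


@dataclass
class EpochSet:
    """Sliding-window epochs with per-epoch artifact flags.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch); it may be
    a strided view into the continuous recording, so it should be treated as
    read-only. ``artifact_flags[i]`` is the set of reason codes
    (``amplitude``, ``trend``, ``step``) for epoch ``i``; an epoch is
    retained iff its flag set is empty.
    """

    epochs: np.ndarray
    start_times: np.ndarray
    epoch_length_s: float
    sampling_rate: float
    channel_labels: list[str]
    artifact_flags: list[set] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.artifact_flags:
            self.artifact_flags = [set() for _ in range(self.n_epochs)]
        if len(self.artifact_flags) != self.n_epochs:
            raise InputError("artifact_flags length != number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def retained_mask(self) -> np.ndarray:
        return np.array([not f for f in self.artifact_flags], dtype=bool)

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())


def design_filters(cfg: PreprocessConfig, sampling_rate: float) -> np.ndarray:
    """Second-order sections of the cascaded high-pass + low-pass design."""
    cfg.validate(sampling_rate)
    sos_hp = signal.butter(
        cfg.filter_order, cfg.highpass_cutoff_hz, "highpass", fs=sampling_rate,
        output="sos",
    )
    sos_lp = signal.butter(
        cfg.filter_order, cfg.lowpass_cutoff_hz, "lowpass", fs=sampling_rate,
        output="sos",
    )
    return np.vstack([sos_hp, sos_lp])


def bandpass_filter(rec: RawRecording, cfg: PreprocessConfig) -> RawRecording:
    """Zero-phase band-pass: forward–backward application of a fourth-order
    Butterworth high-pass and low-pass cascade."""
    sos = design_filters(cfg, rec.sampling_rate)
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=1))


# ---------------------------------------------------------------------------
# blink removal
# ---------------------------------------------------------------------------

def detect_blinks(
    reference: np.ndarray,
    sampling_rate: float,
    amplitude_threshold_uv: float = 50.0,
    derivative_threshold_uv_s: float = 1000.0,
    envelope_cutoff_hz: float = 8.0,
    pad_s: float = 0.15,
    merge_gap_s: float = 0.1,
) -> list[tuple[int, int]]:
    """Detect blink intervals on the forehead channel.

    The channel is low-passed to an envelope; samples where the envelope
    exceeds the amplitude criterion or its slope exceeds the derivative
    criterion are marked, padded by ``pad_s`` on each side, and merged into
    intervals (sample index pairs, end exclusive).
    """
    sos = signal.butter(4, envelope_cutoff_hz, "lowpass", fs=sampling_rate,
                        output="sos")
    env = signal.sosfiltfilt(sos, reference)
    slope = np.gradient(env) * sampling_rate
    mark = (np.abs(env) > amplitude_threshold_uv) | (
        np.abs(slope) > derivative_threshold_uv_s
    )
    if not mark.any():
        return []
    pad = int(round(pad_s * sampling_rate))
    gap = int(round(merge_gap_s * sampling_rate))
    idx = np.flatnonzero(mark)
    intervals: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap:
            intervals.append((start, prev + 1))
            start = i
        prev = i
    intervals.append((start, prev + 1))
    n = reference.size
    padded = [(max(0, a - pad), min(n, b + pad)) for a, b in intervals]
    merged = [padded[0]]
    for a, b in padded[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(b, merged[-1][1]))
        else:
            merged.append((a, b))
    return merged


def remove_blinks(
    rec: RawRecording,
    reference_label: str = BLINK_REFERENCE,
    **detect_kwargs,
) -> tuple[RawRecording, list[tuple[float, float]]]:
    """Regress the blink-reference component out of every other channel
    inside detected blink intervals.

    Outside detected intervals the signal is returned unchanged, so no data
    are lost. Returns the corrected recording and the blink intervals in
    seconds (onset, end).
    """
    ref_idx = rec.channel_index(reference_label)
    ref = rec.data[ref_idx]
    fs = rec.sampling_rate
    intervals = detect_blinks(ref, fs, **detect_kwargs)
    if not intervals:
        return rec.copy_with(rec.data.copy()), []
    out = rec.data.copy()
    for a, b in intervals:
        seg_ref = ref[a:b]
        denom = float(seg_ref @ seg_ref)
        if denom <= 0:
            continue
        for c in range(rec.n_channels):
            if c == ref_idx:
                continue
            beta = float(out[c, a:b] @ seg_ref) / denom
            out[c, a:b] = out[c, a:b] - beta * seg_ref
    return rec.copy_with(out), [(a / fs, b / fs) for a, b in intervals]


# ---------------------------------------------------------------------------
# epoching and artifact rejection
# ---------------------------------------------------------------------------

def segment_epochs(rec: RawRecording, cfg: PreprocessConfig) -> EpochSet:
    """Cut the recording into sliding epochs (2 s shifted by 0.125 s by
    default). Epoch ``k`` starts at ``k * shift``; epochs are emitted while
    they fit entirely inside the recording."""
    cfg.validate(rec.sampling_rate)
    fs = rec.sampling_rate
    win = int(round(cfg.epoch_length_s * fs))
    shift = int(round(cfg.epoch_shift_s * fs))
    if rec.n_samples < win:
        raise InputError(
            f"recording of {rec.duration:.3f} s is shorter than one "
            f"{cfg.epoch_length_s}-s epoch"
        )
    view = np.lib.stride_tricks.sliding_window_view(rec.data, win, axis=1)
    view = view[:, ::shift, :]                   # (ch, n_epochs, win), no copy
    epochs = view.transpose(1, 0, 2)
    n_epochs = epochs.shape[0]
    starts = np.arange(n_epochs) * cfg.epoch_shift_s
    return EpochSet(
        epochs=epochs,
        start_times=starts,
        epoch_length_s=cfg.epoch_length_s,
        sampling_rate=fs,
        channel_labels=list(rec.channel_labels),
    )


def reject_artifacts(
    ep: EpochSet,
    cfg: PreprocessConfig,
    exclude_channels: Sequence[str] = (BLINK_REFERENCE,),
) -> EpochSet:
    """Flag epochs violating the amplitude, trend or step criterion on any
    analysis channel. Flags accumulate with any pre-existing ones; the
    operation is idempotent."""
    cfg.validate(ep.sampling_rate)
    ch_idx = [
        i for i, lb in enumerate(ep.channel_labels) if lb not in exclude_channels
    ]
    n = ep.epochs.shape[2]
    t = np.arange(n) / ep.sampling_rate
    tc = t - t.mean()
    tc_norm = float(tc @ tc)
    flags = [set(f) for f in ep.artifact_flags]
    for c in ch_idx:
        x = np.asarray(ep.epochs[:, c, :])       # (n_epochs, n)
        amp = np.max(np.abs(x), axis=1) > cfg.amplitude_threshold_uv
        slope = np.abs(x @ tc) / tc_norm > cfg.trend_slope_threshold_uv_s
        step = np.max(np.abs(np.diff(x, axis=1)), axis=1) > cfg.step_threshold_uv
        for i in np.flatnonzero(amp):
            flags[i].add("amplitude")
        for i in np.flatnonzero(slope):
            flags[i].add("trend")
        for i in np.flatnonzero(step):
            flags[i].add("step")
    return replace(ep, artifact_flags=flags)
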