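"""Synthetic multichannel EEG with the statistical structure the workload
neurometric assumes, plus full ground truth.

A simulated session is the sum of

* a 1/f (pink) background per channel, scaled so that clean-signal peaks
  stay well below the 100 μV rejection threshold;
* a shared narrowband alpha source at the subject's alpha-peak frequency,
  projected onto the parietal channels (amplified during the eyes-closed
  baseline, where real alpha is strongest);
* a shared theta-band source projected onto the frontal channels;
* eye-blink transients, strongest on the forehead channel and decaying
  towards parietal sites;
* sporadic high-amplitude artifact bursts on random channels.

Workload structure is injected by multiplying the source amplitudes inside
the annotated condition segments: driving a hard road raises frontal theta
and suppresses parietal alpha, rush-hour traffic amplifies both effects,
and acted events add a transient extra theta gain. Amplitude gains act
squared on band power.

The driving protocol mirrors a three-lap circuit with an easy and a hard
segment per lap, repeated in a normal-hour and a rush-hour run, with a
pedestrian and a car event acted in each lap-3 segment, preceded by a
one-minute eyes-closed baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .exceptions import InputError
from .io import (
    Annotation,
    BLINK_REFERENCE,
    FRONTAL_CHANNELS,
    HOURS,
    MONTAGE,
    PARIETAL_CHANNELS,
    make_annotation,
)
from .spectral import FeatureVectorSeries

#: Default blink propagation: forehead-dominant, decaying towards the back.
DEFAULT_BLINK_PROPAGATION: Mapping[str, float] = {
    "FPz": 1.0, "AF3": 0.5, "AF4": 0.5, "F3": 0.3, "Fz": 0.3, "F4": 0.3,
    "P3": 0.1, "P7": 0.1, "Pz": 0.1, "P4": 0.1, "P8": 0.1, "POz": 0.1,
}


@dataclass
class SimulationSpec:
    """Everything that defines one simulated subject session."""

    iaf_hz: float = 10.0
    sampling_rate: float = 256.0
    montage: tuple[str, ...] = MONTAGE
    # sources
    background_scale_uv: float = 10.0        # RMS of the pink background
    background_exponent: float = 1.0         # PSD ~ 1/f^exponent
    alpha_amplitude_uv: float = 6.0          # RMS on each parietal channel
    theta_amplitude_uv: float = 4.0          # RMS on each frontal channel
    eyes_closed_alpha_gain: float = 2.0
    # condition effects (amplitude gains; power scales with the square)
    hard_theta_gain: float = 1.5
    hard_alpha_gain: float = 0.7
    rush_effect_gain: float = 1.2
    event_theta_gain: float = 1.3
    # blinks
    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 200.0
    blink_duration_s: float = 0.35
    blink_propagation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLINK_PROPAGATION)
    )
    # sporadic artifacts
    artifact_rate_per_min: float = 1.0
    artifact_amplitude_uv: float = 300.0
    artifact_duration_s: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "hard_theta_gain", "hard_alpha_gain", "rush_effect_gain",
            "event_theta_gain", "eyes_closed_alpha_gain",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        for name in ("blink_rate_per_min", "artifact_rate_per_min"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.iaf_hz - 6.0 <= 0:
            raise InputError("iaf_hz must exceed 6 Hz so the theta band is positive")

    # amplitude gains for a condition cell -------------------------------
    def theta_gain(self, hour: str, road: str) -> float:
        g = self.hard_theta_gain if road == "Hard" else 1.0
        return g * (self.rush_effect_gain if hour == "Rush" else 1.0)

    def alpha_gain(self, hour: str, road: str) -> float:
        g = self.hard_alpha_gain if road == "Hard" else 1.0
        return g / (self.rush_effect_gain if hour == "Rush" else 1.0)


@dataclass
class GroundTruth:
    """What the generator actually injected, for oracle checks."""

    iaf_hz: float
    annotations: list[Annotation]
    blink_intervals: list[tuple[float, float]]           # s
    artifact_intervals: list[tuple[float, float]]        # s
    band_power_gains: dict                               # (hour, road) -> dict

    def artifact_epoch_indices(
        self,
        epoch_length_s: float,
        epoch_shift_s: float,
        n_epochs: int,
        min_overlap_s: float = 0.05,
    ) -> np.ndarray:
        """Indices of epochs overlapping any injected artifact burst by at
        least ``min_overlap_s`` (filtering smears burst edges, so a few
        boundary samples do not make an epoch detectably artifactual)."""
        hit = np.zeros(n_epochs, dtype=bool)
        starts = np.arange(n_epochs) * epoch_shift_s
        ends = starts + epoch_length_s
        for a, b in self.artifact_intervals:
            hit |= (np.minimum(ends, b) - np.maximum(starts, a)) >= min_overlap_s
        return np.flatnonzero(hit)


def default_protocol(
    segment_duration_s: float = 120.0,
    baseline_duration_s: float = 60.0,
    hours: Sequence[str] = HOURS,
    n_laps: int = 3,
    event_lap: int = 3,
) -> list[Annotation]:
    """The circuit protocol: eyes-closed baseline, then for each hour run
    three laps of an Easy and a Hard segment, with a pedestrian and a car
    event acted inside each lap-3 segment."""
    anns: list[Annotation] = [
        make_annotation(0.0, baseline_duration_s, "eyes_closed")
    ]
    t = baseline_duration_s
    for hour in hours:
        for lap in range(1, n_laps + 1):
            for road in ("Easy", "Hard"):
                anns.append(
                    make_annotation(
                        t, segment_duration_s, f"hour={hour};road={road};lap={lap}"
                    )
                )
                if lap == event_lap:
                    # pedestrian early in the segment, car later; events are
                    # clamped inside the segment and skipped if they cannot
                    # fit without overlapping
                    seg_end = t + segment_duration_s
                    ped_on = min(t + 0.25 * segment_duration_s, seg_end - 10.0)
                    if ped_on >= t:
                        anns.append(make_annotation(ped_on, 10.0, "event=Pedestrian"))
                    car_on = min(t + 0.60 * segment_duration_s, seg_end - 20.0)
                    if car_on >= ped_on + 10.0:
                        anns.append(make_annotation(car_on, 20.0, "event=Car"))
                t += segment_duration_s
    return anns


def _validate_protocol(annotations: Sequence[Annotation]) -> float:
    """Condition/baseline intervals must tile the session without gaps or
    overlaps; returns total duration."""
    spans = sorted(
        [(a.onset, a.end) for a in annotations if a.kind != "event"],
        key=lambda x: x[0],
    )
    if not spans:
        raise InputError("protocol contains no baseline or condition segments")
    t = spans[0][0]
    if abs(t) > 1e-9:
        raise InputError("protocol must start at t = 0")
    for lo, hi in spans:
        if lo > t + 1e-6:
            raise InputError(f"protocol gap between {t} s and {lo} s")
        if lo < t - 1e-6:
            raise InputError(f"protocol segments overlap at {lo} s")
        t = hi
    return t


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS noise with PSD proportional to 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-RMS band-limited noise (4th-order Butterworth band-pass)."""
    sos = signal.butter(4, [lo, hi], "bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _blink_waveform(fs: float, duration_s: float) -> np.ndarray:
    n = max(4, int(round(duration_s * fs)))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))  # raised cosine


def simulate_session(
    spec: SimulationSpec,
    protocol: Sequence[Annotation] | None = None,
) -> tuple["RawRecording", GroundTruth]:
    """Generate one subject session and its ground truth.

    Identical spec and protocol give bit-identical output; the global seed
    is expanded into independent substreams per component (background,
    sources, blinks, artifacts) so one component can be varied while the
    others stay fixed.
    """
    from .io import RawRecording  # local import to avoid cycle at module load

    spec.validate()
    if protocol is None:
        protocol = default_protocol()
    duration = _validate_protocol(protocol)
    fs = spec.sampling_rate
    n = int(round(duration * fs))
    n_ch = len(spec.montage)
    t_axis = np.arange(n) / fs

    ss = np.random.SeedSequence(spec.seed)
    rng_bg, rng_alpha, rng_theta, rng_blink, rng_art = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    data = np.empty((n_ch, n))
    for c in range(n_ch):
        data[c] = spec.background_scale_uv * _pink_noise(
            rng_bg, n, spec.background_exponent
        )

    # shared band-limited sources with piecewise-constant condition gains
    alpha_src = _band_noise(rng_alpha, n, fs, spec.iaf_hz - 1.0, spec.iaf_hz + 1.0)
    theta_src = _band_noise(
        rng_theta, n, fs, spec.iaf_hz - 6.0, spec.iaf_hz - 2.0
    )
    g_alpha = np.ones(n)
    g_theta = np.ones(n)
    band_power_gains: dict = {}
    for ann in protocol:
        sl = slice(int(round(ann.onset * fs)), int(round(ann.end * fs)))
        if ann.kind == "baseline":
            g_alpha[sl] = spec.eyes_closed_alpha_gain
        elif ann.kind == "condition":
            ga = spec.alpha_gain(ann.hour, ann.road)
            gt = spec.theta_gain(ann.hour, ann.road)
            g_alpha[sl] = ga
            g_theta[sl] = gt
            band_power_gains[(ann.hour, ann.road)] = {
                "theta_power_gain": gt ** 2,
                "alpha_power_gain": ga ** 2,
            }
    for ann in protocol:                     # events stack on top of segments
        if ann.kind == "event":
            sl = slice(int(round(ann.onset * fs)), int(round(ann.end * fs)))
            g_theta[sl] = g_theta[sl] * spec.event_theta_gain

    labels = list(spec.montage)
    for chan in PARIETAL_CHANNELS:
        if chan in labels:
            data[labels.index(chan)] += (
                spec.alpha_amplitude_uv * g_alpha * alpha_src
            )
    for chan in FRONTAL_CHANNELS:
        if chan in labels:
            data[labels.index(chan)] += (
                spec.theta_amplitude_uv * g_theta * theta_src
            )

    # blinks: only while the eyes are open (driving portion)
    baseline_end = max(
        (a.end for a in protocol if a.kind == "baseline"), default=0.0
    )
    blink_intervals: list[tuple[float, float]] = []
    if spec.blink_rate_per_min > 0:
        wave = _blink_waveform(fs, spec.blink_duration_s)
        n_blinks = rng_blink.poisson(
            spec.blink_rate_per_min * (duration - baseline_end) / 60.0
        )
        onsets = np.sort(
            rng_blink.uniform(baseline_end, duration - spec.blink_duration_s,
                              size=n_blinks)
        )
        kept: list[float] = []
        for on in onsets:                    # enforce a 1-s refractory gap
            if not kept or on - kept[-1] >= 1.0:
                kept.append(float(on))
        for on in kept:
            i0 = int(round(on * fs))
            amp = spec.blink_amplitude_uv * rng_blink.uniform(0.8, 1.2)
            for chan, coef in spec.blink_propagation.items():
                if chan in labels:
                    c = labels.index(chan)
                    data[c, i0:i0 + wave.size] += amp * coef * wave[: n - i0]
            blink_intervals.append((on, on + spec.blink_duration_s))

    # sporadic high-amplitude artifact bursts, each on one random analysis
    # channel (bursts on the blink reference would read as blinks instead)
    analysis_idx = [
        i for i, lb in enumerate(labels) if lb != BLINK_REFERENCE
    ] or list(range(n_ch))
    artifact_intervals: list[tuple[float, float]] = []
    if spec.artifact_rate_per_min > 0:
        n_art = rng_art.poisson(spec.artifact_rate_per_min * duration / 60.0)
        burst_n = max(4, int(round(spec.artifact_duration_s * fs)))
        for _ in range(n_art):
            on = float(rng_art.uniform(0.0, duration - spec.artifact_duration_s))
            c = analysis_idx[int(rng_art.integers(0, len(analysis_idx)))]
            i0 = int(round(on * fs))
            burst = spec.artifact_amplitude_uv * np.sign(
                rng_art.standard_normal(burst_n)
            ) * rng_art.uniform(0.8, 1.0, burst_n)
            data[c, i0:i0 + burst_n] += burst[: n - i0]
            artifact_intervals.append((on, on + spec.artifact_duration_s))
        artifact_intervals.sort()

    rec = RawRecording(
        data=data,
        channel_labels=labels,
        sampling_rate=fs,
        annotations=list(protocol),
        subject_id=f"sim-{spec.seed}",
    )
    truth = GroundTruth(
        iaf_hz=spec.iaf_hz,
        annotations=list(protocol),
        blink_intervals=blink_intervals,
        artifact_intervals=artifact_intervals,
        band_power_gains=band_power_gains,
    )
    return rec, truth


def simulate_cohort(
    n_subjects: int = 16,
    base_seed: int = 0,
    segment_duration_s: float = 120.0,
    iaf_range_hz: tuple[float, float] = (9.0, 11.5),
    **spec_overrides,
) -> list[tuple[SimulationSpec, list[Annotation]]]:
    """Specs and protocols for a cohort: per-subject seeds and alpha-peak
    frequencies drawn reproducibly from ``base_seed`` (IAF snapped to the
    0.5 Hz bin grid)."""
    rng = np.random.default_rng(base_seed)
    out = []
    for k in range(n_subjects):
        iaf = float(
            np.round(rng.uniform(*iaf_range_hz) * 2.0) / 2.0
        )
        spec = SimulationSpec(
            iaf_hz=iaf,
            seed=int(rng.integers(0, 2**31 - 1)),
            **spec_overrides,
        )
        out.append((spec, default_protocol(segment_duration_s=segment_duration_s)))
    return out


def simulate_feature_set(
    n_epochs_per_class: int,
    n_features: int,
    informative: Mapping[int, float] | None = None,
    seed: int = 0,
    epoch_shift_s: float = 0.125,
) -> FeatureVectorSeries:
    """Labeled Gaussian feature matrices for unit-testing the stepwise fit.

    ``informative`` maps feature indices to between-class mean shifts in SD
    units (class 1 shifted upward); all other features are label-independent
    standard normal noise.
    """
    informative = dict(informative or {})
    bad = [j for j in informative if not 0 <= j < n_features]
    if bad:
        raise InputError(f"informative feature ids out of range: {bad}")
    rng = np.random.default_rng(seed)
    n = 2 * n_epochs_per_class
    X = rng.standard_normal((n, n_features))
    labels = np.repeat([0, 1], n_epochs_per_class)
    for j, effect in informative.items():
        X[labels == 1, j] += effect
    ids = [(f"S{j}", float(j)) for j in range(n_features)]
    return FeatureVectorSeries(
        features=X,
        feature_ids=ids,
        start_times=np.arange(n) * epoch_shift_s,
        labels=labels,
    )
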