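"""End-to-end workflow: raw recording -> workload model / workload index.

The calibration scheme follows the circuit protocol: class 0 is the Easy
segment of lap 2 during the Normal hour, class 1 the Hard segment of lap 2
during the Rush hour (the presumed lowest- and highest-workload
conditions); testing uses lap 3 of both hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InputError
from . import preprocess as pp
from . import spectral as sp
from . import swlda
from .io import Annotation, RawRecording

#: (hour, road, lap) defining the two calibration classes.
DEFAULT_CLASS0 = ("Normal", "Easy", 2)
DEFAULT_CLASS1 = ("Rush", "Hard", 2)
TEST_LAP = 3


@dataclass
class PipelineConfig:
    """Aggregated settings for the whole chain, with the standard defaults
    baked in (2-s/0.125-s epoching, 1–30 Hz order-4 filters, 100 μV /
    10 μV/s / 25 μV rejection, 8-s smoothing window)."""

    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    stepwise: swlda.StepwiseConfig = field(default_factory=swlda.StepwiseConfig)
    iaf_search_range_hz: tuple[float, float] = (7.0, 13.0)
    feature_transform: str = "log10"
    smoothing_window_s: float = 8.0
    min_window_coverage: float = 0.25
    class0: tuple[str, str, int] = DEFAULT_CLASS0
    class1: tuple[str, str, int] = DEFAULT_CLASS1


@dataclass
class SessionSpectra:
    """Intermediate products of the preprocessing + spectral stage."""

    frame: sp.SpectralFrame
    iaf: sp.IAFEstimate
    epochs: pp.EpochSet
    blink_intervals: list[tuple[float, float]]


def _segments(
    annotations: Sequence[Annotation], hour: str, road: str, lap: int
) -> list[Annotation]:
    return [
        a for a in annotations
        if a.kind == "condition" and a.hour == hour and a.road == road
        and a.lap == lap
    ]


def process_session(
    rec: RawRecording,
    annotations: Sequence[Annotation] | None = None,
    config: PipelineConfig | None = None,
) -> SessionSpectra:
    """Filter, blink-correct, epoch, reject artifacts, compute PSD and
    estimate the individual alpha frequency from the eyes-closed baseline."""
    config = config or PipelineConfig()
    annotations = list(annotations if annotations is not None else rec.annotations)
    filtered = pp.bandpass_filter(rec, config.preprocess)
    cleaned, blink_intervals = pp.remove_blinks(filtered)
    epochs = pp.segment_epochs(cleaned, config.preprocess)
    epochs = pp.reject_artifacts(epochs, config.preprocess)
    frame = sp.compute_psd(epochs)
    baseline = [a for a in annotations if a.kind == "baseline"]
    if not baseline:
        raise InputError("no eyes_closed baseline annotation for IAF estimation")
    iaf = sp.estimate_iaf(
        frame.select_annotations(baseline),
        search_range_hz=config.iaf_search_range_hz,
    )
    return SessionSpectra(
        frame=frame, iaf=iaf, epochs=epochs, blink_intervals=blink_intervals
    )


def calibration_features(
    spectra: SessionSpectra,
    annotations: Sequence[Annotation],
    config: PipelineConfig | None = None,
) -> sp.FeatureVectorSeries:
    """ROI features of the two calibration segments, labeled 0/1."""
    config = config or PipelineConfig()
    seg0 = _segments(annotations, *config.class0)
    seg1 = _segments(annotations, *config.class1)
    missing = []
    if not seg0:
        missing.append("hour=%s;road=%s;lap=%d" % config.class0)
    if not seg1:
        missing.append("hour=%s;road=%s;lap=%d" % config.class1)
    if missing:
        raise InputError(f"calibration segments not annotated: {missing}")
    feats = sp.extract_roi_features(
        spectra.frame, spectra.iaf, transform=config.feature_transform,
        min_freq_hz=config.preprocess.highpass_cutoff_hz,
    )
    parts = []
    for label, segs in ((0, seg0), (1, seg1)):
        frame_part = np.zeros(feats.n_epochs, dtype=bool)
        for seg in segs:
            frame_part |= (feats.start_times >= seg.onset) & (
                feats.start_times + config.preprocess.epoch_length_s <= seg.end
            )
        part = feats.subset(frame_part)
        parts.append(part.with_labels(np.full(part.n_epochs, label)))
    return sp.concat_features(parts)


def train_session(
    rec: RawRecording,
    annotations: Sequence[Annotation] | None = None,
    config: PipelineConfig | None = None,
) -> tuple[swlda.WorkloadModel, SessionSpectra]:
    """Full training chain on one recording."""
    config = config or PipelineConfig()
    annotations = list(annotations if annotations is not None else rec.annotations)
    spectra = process_session(rec, annotations, config)
    feats = calibration_features(spectra, annotations, config)
    model = swlda.fit(feats, config.stepwise)
    model.training_meta.update(
        {
            "subject": rec.subject_id,
            "iaf_hz": spectra.iaf.iaf_hz,
            "class0": list(config.class0),
            "class1": list(config.class1),
        }
    )
    return model, spectra


def score_lap(
    spectra: SessionSpectra,
    model: swlda.WorkloadModel,
    annotations: Sequence[Annotation],
    hour: str,
    lap: int = TEST_LAP,
    config: PipelineConfig | None = None,
) -> tuple[swlda.WorkloadScoreSeries, np.ndarray]:
    """Workload index over one hour's test lap.

    Returns the smoothed score series (window grid anchored at the lap's
    first epoch) and, per window, the road class (0 Easy / 1 Hard) covering
    the window midpoint — NaN-labeled windows straddling segments are
    excluded by the caller via the label array (-1 there).
    """
    config = config or PipelineConfig()
    segs = [
        a for a in annotations
        if a.kind == "condition" and a.hour == hour and a.lap == lap
    ]
    if not segs:
        raise InputError(f"no lap-{lap} segments for hour={hour!r}")
    feats = sp.extract_roi_features(
        spectra.frame, spectra.iaf, transform=config.feature_transform,
        min_freq_hz=config.preprocess.highpass_cutoff_hz,
    )
    mask = np.zeros(feats.n_epochs, dtype=bool)
    for seg in segs:
        mask |= (feats.start_times >= seg.onset) & (
            feats.start_times + config.preprocess.epoch_length_s <= seg.end
        )
    part = feats.subset(mask)
    if part.n_epochs == 0:
        raise InputError(f"no retained epochs in lap-{lap} ({hour}) segments")
    series = swlda.score(model, part,
                         epoch_shift_s=config.preprocess.epoch_shift_s)
    series = swlda.workload_index(
        series, config.smoothing_window_s, config.min_window_coverage
    )
    road_class = np.full(series.wl_times.size, -1, dtype=int)
    for seg in segs:
        hit = (series.wl_times >= seg.onset) & (series.wl_times < seg.end)
        road_class[hit] = 1 if seg.road == "Hard" else 0
    return series, road_class


def evaluate_simulated_subject(
    sim_spec,
    protocol: Sequence[Annotation],
    config: PipelineConfig | None = None,
    n_shuffles: int = 0,
    shuffle_seed: int = 0,
) -> dict:
    """Run the full chain on one simulated subject and measure recovery.

    Trains on the lap-2 calibration segments, scores lap 3 of each hour,
    and returns per-hour test AUCs (with an optional shuffled-label
    baseline), the lap-3 condition-mean table and the event-window
    analysis, alongside the estimated alpha peak and the selected features.
    """
    from . import evaluation
    from .synthetic import simulate_session

    config = config or PipelineConfig()
    rec, truth = simulate_session(sim_spec, protocol)
    model, spectra = train_session(rec, rec.annotations, config)
    aucs: dict[str, float] = {}
    shuffled_means: dict[str, float] = {}
    for hour in ("Normal", "Rush"):
        series, road = score_lap(spectra, model, rec.annotations, hour,
                                 config=config)
        ok = (road >= 0) & ~np.isnan(series.wl)
        wl, lab = series.wl[ok], road[ok]
        aucs[hour] = evaluation.roc_auc(wl, lab)
        if n_shuffles:
            shuffled_means[hour] = float(
                evaluation.shuffled_baseline(wl, lab, n_shuffles,
                                             shuffle_seed).mean()
            )
    full = score_session(rec, model, rec.annotations, config, spectra=spectra)
    cond = evaluation.aggregate_conditions(full, rec.annotations, lap=TEST_LAP)
    events = evaluation.event_window_analysis(full, rec.annotations)
    return {
        "iaf_true": truth.iaf_hz,
        "iaf_est": spectra.iaf.iaf_hz,
        "n_selected": len(model.selected_features),
        "auc": aucs,
        "shuffled_mean": shuffled_means,
        "condition_means": cond,
        "event_windows": events,
    }


def score_session(
    rec: RawRecording,
    model: swlda.WorkloadModel,
    annotations: Sequence[Annotation] | None = None,
    config: PipelineConfig | None = None,
    spectra: SessionSpectra | None = None,
) -> swlda.WorkloadScoreSeries:
    """Workload index over the whole recording timeline."""
    config = config or PipelineConfig()
    annotations = list(annotations if annotations is not None else rec.annotations)
    if spectra is None:
        spectra = process_session(rec, annotations, config)
    feats = sp.extract_roi_features(
        spectra.frame, spectra.iaf, transform=config.feature_transform,
        min_freq_hz=config.preprocess.highpass_cutoff_hz,
    )
    series = swlda.score(model, feats,
                         epoch_shift_s=config.preprocess.epoch_shift_s)
    return swlda.workload_index(
        series, config.smoothing_window_s, config.min_window_coverage
    )
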