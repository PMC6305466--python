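"""Spectral analysis: per-epoch PSD, individual alpha frequency (IAF),
IAF-anchored band/ROI features and the frontal-theta / parietal-alpha ratio.

Each retained 2-s epoch yields one Hanning-windowed periodogram per channel
at 0.5 Hz resolution. Bands are anchored to the subject's alpha peak: theta
is [IAF−6, IAF−2] Hz over the frontal sites and alpha [IAF−2, IAF+2] Hz over
the parietal sites, endpoints inclusive on both sides (the IAF−2 bin belongs
to both bands). With the default 12-channel montage and 0.5 Hz bins this
gives 45 frontal-theta + 54 parietal-alpha = 99 selectable features out of a
full 11-channel × 17-bin = 187 domain (the blink-reference channel carries
no features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .exceptions import InputError, NumericalError
from .io import BLINK_REFERENCE, FRONTAL_CHANNELS, PARIETAL_CHANNELS, Annotation
from .preprocess import EpochSet

#: Frequency tolerance when matching bin centers (fraction of a bin).
_FTOL = 1e-6


@dataclass
class ROIDefinition:
    """Frontal/parietal channel sets and IAF-relative band offsets (Hz)."""

    frontal_channels: tuple[str, ...] = FRONTAL_CHANNELS
    parietal_channels: tuple[str, ...] = PARIETAL_CHANNELS
    theta_offsets: tuple[float, float] = (-6.0, -2.0)
    alpha_offsets: tuple[float, float] = (-2.0, 2.0)

    def theta_band(self, iaf_hz: float) -> tuple[float, float]:
        return (iaf_hz + self.theta_offsets[0], iaf_hz + self.theta_offsets[1])

    def alpha_band(self, iaf_hz: float) -> tuple[float, float]:
        return (iaf_hz + self.alpha_offsets[0], iaf_hz + self.alpha_offsets[1])

    def full_range(self, iaf_hz: float) -> tuple[float, float]:
        return (iaf_hz + self.theta_offsets[0], iaf_hz + self.alpha_offsets[1])


@dataclass
class SpectralFrame:
    """Per-epoch channel × frequency-bin PSD matrix (μV²/Hz), for retained
    epochs only."""

    psd: np.ndarray                      # (n_epochs, n_channels, n_bins)
    bin_frequencies: np.ndarray          # Hz
    start_times: np.ndarray              # s, one per retained epoch
    channel_labels: list[str]

    @property
    def bin_spacing_hz(self) -> float:
        return float(self.bin_frequencies[1] - self.bin_frequencies[0])

    @property
    def n_epochs(self) -> int:
        return self.psd.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InputError(f"channel {label!r} not in spectral frame") from None

    def bin_index(self, freq_hz: float) -> int:
        d = np.abs(self.bin_frequencies - freq_hz)
        i = int(np.argmin(d))
        if d[i] > self.bin_spacing_hz * 0.5 + _FTOL:
            raise InputError(f"no frequency bin at {freq_hz} Hz")
        return i

    def band_bins(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        """Indices of bins with center in [lo, hi], endpoints inclusive."""
        tol = self.bin_spacing_hz * _FTOL
        return np.flatnonzero(
            (self.bin_frequencies >= lo_hz - tol)
            & (self.bin_frequencies <= hi_hz + tol)
        )

    def select_time(self, intervals: Sequence[tuple[float, float]]) -> "SpectralFrame":
        """Restrict to epochs that lie entirely inside one of the given
        (onset, end) intervals. Epoch length is 1/bin_spacing seconds."""
        epoch_len = 1.0 / self.bin_spacing_hz
        keep = np.zeros(self.n_epochs, dtype=bool)
        for lo, hi in intervals:
            keep |= (self.start_times >= lo - _FTOL) & (
                self.start_times + epoch_len <= hi + _FTOL
            )
        return SpectralFrame(
            psd=self.psd[keep],
            bin_frequencies=self.bin_frequencies,
            start_times=self.start_times[keep],
            channel_labels=list(self.channel_labels),
        )

    def select_annotations(self, annotations: Sequence[Annotation]) -> "SpectralFrame":
        return self.select_time([(a.onset, a.end) for a in annotations])


@dataclass
class IAFEstimate:
    """Individual alpha frequency from eyes-closed parietal spectra."""

    iaf_hz: float
    search_range_hz: tuple[float, float]
    peak_power: float                    # μV²/Hz at the peak bin
    source: str = "eyes_closed"


@dataclass
class FeatureVectorSeries:
    """Epoch × feature matrix of (transformed) band-restricted PSD values.

    ``feature_ids`` are (channel label, bin frequency Hz) pairs in canonical
    channel-major, frequency-ascending order.
    """

    features: np.ndarray                 # (n_epochs, n_features)
    feature_ids: list[tuple[str, float]]
    start_times: np.ndarray
    labels: np.ndarray | None = None     # optional per-epoch class in {0, 1}
    transform: str = "log10"

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.features.shape[0]

    def with_labels(self, labels: np.ndarray) -> "FeatureVectorSeries":
        labels = np.asarray(labels)
        if labels.shape[0] != self.n_epochs:
            raise InputError("labels length != number of epochs")
        return FeatureVectorSeries(
            self.features, list(self.feature_ids), self.start_times,
            labels=labels, transform=self.transform,
        )

    def subset(self, mask: np.ndarray) -> "FeatureVectorSeries":
        return FeatureVectorSeries(
            self.features[mask], list(self.feature_ids), self.start_times[mask],
            labels=None if self.labels is None else self.labels[mask],
            transform=self.transform,
        )

    def column(self, feature_id: tuple[str, float]) -> np.ndarray:
        for j, fid in enumerate(self.feature_ids):
            if fid[0] == feature_id[0] and abs(fid[1] - feature_id[1]) < 1e-9:
                return self.features[:, j]
        raise InputError(f"feature {feature_id} not present")


def concat_features(parts: Sequence[FeatureVectorSeries]) -> FeatureVectorSeries:
    """Stack feature series (same feature ids) along the epoch axis."""
    first = parts[0]
    for p in parts[1:]:
        if p.feature_ids != first.feature_ids:
            raise InputError("cannot concatenate: feature ids differ")
    labels = None
    if all(p.labels is not None for p in parts):
        labels = np.concatenate([p.labels for p in parts])
    return FeatureVectorSeries(
        np.vstack([p.features for p in parts]),
        list(first.feature_ids),
        np.concatenate([p.start_times for p in parts]),
        labels=labels,
        transform=first.transform,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_psd(ep: EpochSet, retained_only: bool = True) -> SpectralFrame:
    """One Hanning-windowed periodogram per retained epoch per channel.

    Density scaling is normalized by the window power, so the integral of
    the PSD over frequency equals the mean square of the (windowed) signal:
    a stationary sinusoid of amplitude A integrates to ≈ A²/2.
    """
    mask = ep.retained_mask if retained_only else np.ones(ep.n_epochs, bool)
    if not mask.any():
        raise InputError("no retained epochs to compute PSD from")
    idx = np.flatnonzero(mask)
    n = ep.epochs.shape[2]
    n_ch = ep.epochs.shape[1]
    psd = None
    freqs = None
    for c in range(n_ch):                # per channel to bound memory
        f, p = signal.periodogram(
            np.asarray(ep.epochs[idx, c, :]),
            fs=ep.sampling_rate,
            window="hann",
            nfft=n,
            detrend=False,
            scaling="density",
            axis=-1,
        )
        if psd is None:
            freqs = f
            psd = np.empty((idx.size, n_ch, f.size))
        psd[:, c, :] = p
    return SpectralFrame(
        psd=psd,
        bin_frequencies=freqs,
        start_times=np.asarray(ep.start_times)[idx],
        channel_labels=list(ep.channel_labels),
    )


def estimate_iaf(
    frame: SpectralFrame,
    roi: ROIDefinition | None = None,
    search_range_hz: tuple[float, float] = (7.0, 13.0),
    fallback_hz: float = 10.0,
    source: str = "eyes_closed",
) -> IAFEstimate:
    """Alpha-peak frequency of the epoch- and parietal-averaged spectrum.

    The caller passes a frame restricted to the eyes-closed baseline. The
    IAF is the frequency of the maximum within ``search_range_hz``, accepted
    only if it is a strict local maximum in the interior of the range;
    otherwise the population-typical ``fallback_hz`` is returned with a
    warning.
    """
    roi = roi or ROIDefinition()
    if frame.n_epochs == 0:
        raise InputError("empty spectral frame: no eyes-closed epochs")
    ch = [frame.channel_index(c) for c in roi.parietal_channels]
    spectrum = frame.psd[:, ch, :].mean(axis=(0, 1))
    bins = frame.band_bins(*search_range_hz)
    if bins.size < 3:
        raise InputError(
            f"search range {search_range_hz} Hz covers fewer than 3 bins"
        )
    sub = spectrum[bins]
    k = int(np.argmax(sub))
    interior = 0 < k < sub.size - 1
    strict_peak = interior and sub[k] > sub[k - 1] and sub[k] > sub[k + 1]
    if not strict_peak:
        warnings.warn(
            "no alpha peak strictly inside the search range; "
            f"falling back to IAF = {fallback_hz} Hz",
            stacklevel=2,
        )
        return IAFEstimate(
            iaf_hz=fallback_hz,
            search_range_hz=search_range_hz,
            peak_power=float(spectrum[frame.bin_index(fallback_hz)]),
            source=source,
        )
    return IAFEstimate(
        iaf_hz=float(frame.bin_frequencies[bins[k]]),
        search_range_hz=search_range_hz,
        peak_power=float(sub[k]),
        source=source,
    )


def _transform(psd: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log10":
        return np.log10(np.maximum(psd, 1e-12))
    if transform == "linear":
        return psd
    raise InputError(f"unknown feature transform {transform!r}")


def extract_roi_features(
    frame: SpectralFrame,
    iaf: IAFEstimate | float,
    roi: ROIDefinition | None = None,
    transform: str = "log10",
    domain: str = "roi",
    min_freq_hz: float = 1.0,
    exclude_channels: Sequence[str] = (BLINK_REFERENCE,),
) -> FeatureVectorSeries:
    """Band-restricted spectral features in canonical order.

    ``domain='roi'`` (default) yields frontal-theta + parietal-alpha
    features (99 for the default montage); ``domain='full'`` yields every
    analysis channel × every bin in [IAF−6, IAF+2] (187). The PSD is log10-
    transformed by default before classification.
    """
    roi = roi or ROIDefinition()
    iaf_hz = iaf.iaf_hz if isinstance(iaf, IAFEstimate) else float(iaf)
    lo = roi.full_range(iaf_hz)[0]
    if lo < min_freq_hz - _FTOL:
        raise InputError(
            f"theta band starts at {lo} Hz, below the {min_freq_hz} Hz "
            "high-pass cutoff; bins would be truncated"
        )
    if domain == "roi":
        blocks = [
            (roi.frontal_channels, roi.theta_band(iaf_hz)),
            (roi.parietal_channels, roi.alpha_band(iaf_hz)),
        ]
    elif domain == "full":
        channels = tuple(
            c for c in frame.channel_labels if c not in exclude_channels
        )
        blocks = [(channels, roi.full_range(iaf_hz))]
    else:
        raise InputError(f"unknown feature domain {domain!r}")
    cols = []
    ids: list[tuple[str, float]] = []
    for channels, (b_lo, b_hi) in blocks:
        bins = frame.band_bins(b_lo, b_hi)
        if bins.size == 0:
            raise InputError(f"band [{b_lo}, {b_hi}] Hz contains no bins")
        for chan in channels:
            ci = frame.channel_index(chan)
            for b in bins:
                cols.append(frame.psd[:, ci, b])
                ids.append((chan, float(frame.bin_frequencies[b])))
    features = _transform(np.column_stack(cols), transform)
    return FeatureVectorSeries(
        features=features,
        feature_ids=ids,
        start_times=frame.start_times.copy(),
        transform=transform,
    )


def theta_alpha_ratio(
    frame: SpectralFrame,
    iaf: IAFEstimate | float,
    roi: ROIDefinition | None = None,
) -> np.ndarray:
    """Frontal-theta / parietal-alpha PSD ratio per epoch (linear scale).

    A classical workload indicator: mean PSD over frontal channels × theta
    bins divided by mean PSD over parietal channels × alpha bins. Epochs
    with zero denominator yield NaN with a warning.
    """
    roi = roi or ROIDefinition()
    iaf_hz = iaf.iaf_hz if isinstance(iaf, IAFEstimate) else float(iaf)
    f_ch = [frame.channel_index(c) for c in roi.frontal_channels]
    p_ch = [frame.channel_index(c) for c in roi.parietal_channels]
    t_bins = frame.band_bins(*roi.theta_band(iaf_hz))
    a_bins = frame.band_bins(*roi.alpha_band(iaf_hz))
    if t_bins.size == 0 or a_bins.size == 0:
        raise NumericalError("empty theta or alpha band for this IAF")
    num = frame.psd[:, f_ch, :][:, :, t_bins].mean(axis=(1, 2))
    den = frame.psd[:, p_ch, :][:, :, a_bins].mean(axis=(1, 2))
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} epoch(s) with zero parietal-alpha power; "
            "ratio set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero, np.nan, num / np.where(zero, 1.0, den))
    return ratio
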