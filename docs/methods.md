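# Methods

This note documents the models, algorithms and numerical choices behind
`eegworkload`, and what the synthetic-data tests do and do not demonstrate.

## The neurometric

The package computes an EEG-based mental-workload index for one subject at
a time. The processing chain is:

1. **Filtering.** Zero-phase (forward–backward) fourth-order Butterworth
   high-pass at 1 Hz and low-pass at 30 Hz. The order and cutoffs are the
   standard settings for this metric; the zero-phase application mode is
   our choice — spectral features must not be phase-shifted relative to
   the annotation timeline, and band power is unaffected by the doubled
   effective order.
2. **Blink correction.** The forehead channel (FPz) is dominated by blink
   potentials. Blinks are detected on a low-passed (8 Hz) copy of FPz by an
   amplitude criterion (default 50 μV) or a slope criterion (default
   1000 μV/s, chosen between the background envelope's extreme slopes,
   roughly 150–800 μV/s over a half-hour recording, and a blink's
   1400–1800 μV/s). Inside each detected interval, padded by 150 ms, every
   other channel is regressed on FPz and the fitted component subtracted;
   outside the intervals the data are untouched, so no epochs are lost to
   blinks. The detector/regressor is deliberately simple and pluggable;
   commercial blink removers solve the same problem with unpublished
   internals.
3. **Epoching.** 2-s windows slid by 0.125 s (the windows therefore overlap
   by 1.875 s). The shift is the authoritative parameter; one output epoch
   starts every 0.125 s while a full window fits.
4. **Artifact rejection.** Per epoch, on every channel except FPz:
   amplitude beyond ±100 μV, least-squares trend slope beyond 10 μV/s
   (ordinary least squares of the raw samples against time — the fit is
   not named in the source conventions, OLS is the default reading), or a
   sample-to-sample step beyond 25 μV. Any channel failing any criterion
   rejects the whole epoch — the conservative reading. Thresholds apply to
   the filtered, blink-corrected signal, matching the processing order.
5. **Spectra.** One Hanning-windowed periodogram per epoch per channel
   (no sub-segmentation: the window equals the epoch), density-scaled so a
   sinusoid of amplitude A integrates to A²/2. 2-s epochs give 0.5 Hz
   resolution.
6. **Individual alpha frequency (IAF).** The frequency of the maximum of
   the epoch- and parietal-averaged PSD over the eyes-closed baseline,
   searched in 7–13 Hz (a standard alpha-peak window). The maximum is
   accepted only if it is a strict local peak in the interior of the
   range; otherwise the estimate falls back to 10 Hz (the population-
   typical center) with a warning, so batch runs surface the fallback.
   The IAF is estimated once per recording session.
7. **Features.** Theta band [IAF−6, IAF−2] Hz on the five frontal channels
   (AF3, AF4, F3, Fz, F4) and alpha band [IAF−2, IAF+2] Hz on the six
   parietal channels (P3, P7, Pz, P4, P8, POz), endpoints inclusive — the
   IAF−2 bin belongs to both bands, which is the only reading consistent
   with the counts 9 + 9 bins, 45 + 54 = 99 ROI features and 17 bins ×
   11 channels = 187 for the unrestricted domain. Features are log10 of
   the PSD: band power is heavily right-skewed (approximately scaled
   chi-square per bin), and the log stabilizes the scale for the linear
   model. The transform is configurable (`linear` is available).
8. **Classifier.** Stepwise linear discriminant (SWLDA) fitted by least
   squares onto 0/1 targets — equivalent to the two-class LDA direction up
   to affine scale, and directly interpretable: scores sit near 0 for the
   easy calibration condition and near 1 for the hard one. Forward steps
   add the candidate with the smallest partial-F p-value if below
   `p_enter` (0.05); backward steps drop members whose coefficient p-value
   exceeds `p_remove` (0.10). Selection halts when no candidate enters,
   when the selected count reaches a cap (10), or when mean squared error
   on a held-out quarter of the training epochs (fixed-seed split) fails
   to improve for two consecutive steps, in which case the selection
   reverts to the best-validated step. Final weights and bias are refit on
   the full training set. Ties among equally significant candidates break
   toward the lowest index in channel-major feature order, making the
   procedure deterministic. The halting rule is this package's own
   re-specification of an automatic-stop idea whose reference
   implementation is not public; all three knobs are configurable.
9. **Workload index.** The discriminant output y(t) exists per retained
   epoch at 0.125-s spacing. WL_SCORE is its 8-s moving average evaluated
   once per window (8-s time resolution). Scores are *not* clipped to
   [0, 1]: the unit interval is a tendency of the calibration targets, not
   a constraint, and clipping would bias window averages. A window's value
   is reported only if at least 25% of its expected epochs survive
   rejection; sparser windows are missing rather than masquerading as 8-s
   averages.

Calibration uses the Easy segment of lap 2 in the Normal hour (class 0)
and the Hard segment of lap 2 in the Rush hour (class 1); testing uses
lap 3 of both hours. Both are overridable.

## Evaluation battery

* **ROC-AUC** equals P(score₁ > score₀) + ½ P(tie); the shuffled-label
  baseline permutes test labels with a seeded generator and reports the
  AUC distribution.
* **Wilcoxon signed-rank** drops zero differences (standard practice),
  uses the exact null distribution for n ≤ 25 when ranks are untied, and
  the continuity-corrected normal approximation otherwise.
* **Friedman** is the rank test with average ranks and tie correction; a
  table whose rows are all fully tied returns statistic 0, p = 1 by
  convention.
* **FDR** is Benjamini–Hochberg step-up; the family is whatever set of
  p-values is passed in one call. Note the adjustment is not idempotent —
  re-adjusting already-adjusted values inflates them again — so q-values
  must be computed once per family.
* **Condition aggregation** averages WL_SCORE per (hour, road) cell over
  lap-3 segments; event windows can be excluded.
* **Event windows** are fixed at 20 s (car) and 10 s (pedestrian) from
  event onset. The matched no-event window is placed at the same offset
  within the corresponding (hour, road) segment of the previous lap —
  "same circuit position" resolved through the annotation timeline, since
  the package has no telemetry.
* **NASA-TLX**: weights are per-factor win counts over the 15 pairwise
  comparisons (summing to 15); the score is the weight-weighted mean of
  the six 0–100 ratings. The Performance scale is used as rated; no
  reverse-coding is applied beyond the questionnaire's own anchoring.

## The synthetic generator

`synthetic.simulate_session` produces sessions with the statistical
structure the neurometric assumes, with full ground truth:

* 1/f background (exponent 1.0) at 10 μV RMS per channel — typical for
  referenced scalp EEG, and low enough that clean-signal peaks (≤ ~50 μV)
  stay clear of the 100 μV rejection threshold.
* A shared narrowband alpha source (IAF ± 1 Hz band-limited noise, not a
  sinusoid, so all ROI bins are populated as in real EEG) on the parietal
  channels at 6 μV RMS, doubled during the eyes-closed baseline; a shared
  theta-band source ([IAF−6, IAF−2]) on the frontal channels at 4 μV RMS.
* Condition effects are multiplicative on source amplitude: Hard road
  multiplies theta by 1.5 and alpha by 0.7; Rush hour multiplies the
  theta gain by 1.2 and divides the alpha gain by 1.2. Power scales with
  the square of the gain, so oracle band-power checks use squared gains.
  Events add a transient theta gain of 1.3 inside their windows.
* Blinks at 10/min (outside the eyes-closed baseline, 1-s refractory
  gap): 0.35-s raised-cosine transients of 200 μV ± 20% on FPz,
  propagating with coefficients 0.5 to the AF sites, 0.3 to F sites and
  0.1 to parietal sites.
* Artifact bursts at 1/min: 0.4-s, ±300 μV sign-flip noise on one random
  analysis channel (never FPz, where a burst would read as a blink and be
  invisible to rejection, which ignores the reference channel).
* The default protocol is a 60-s eyes-closed baseline followed by two
  hour conditions × three laps × (Easy then Hard) segments of 120 s each
  (roughly a 1-km urban segment at city speed), with a pedestrian and a
  car event inside each lap-3 segment. One global seed expands into
  per-component substreams, so tests can vary one component while holding
  the rest fixed.

**What passing synthetic tests shows — and does not.** The generator
encodes exactly the band/topography structure the metric assumes, with
stationary sources and linear blink mixing. Recovery on this data
demonstrates that the pipeline is implemented correctly (filters, bands,
selection, scoring, aggregation all recover injected ground truth), not
that real driving EEG satisfies the assumptions: real data have
non-stationary rhythms, movement and muscle artifacts with richer spectra,
imperfect blink topographies, and workload effects far smaller and less
uniform than the injected gains. Cohort-level numbers (median test AUC
≈ 0.99 on simulation) are therefore upper bounds tied to the generator's
idealizations, not forecasts for real recordings.

## Problem sizes and determinism

The cohort analyses (tests and `scripts/acceptance.py`) use 16 simulated
subjects with the default 120-s segments — per subject about 25 minutes of
12-channel EEG at 256 Hz, ~11 000 epochs — with 100 label shuffles per
test lap, and 1000 replicates for the type-I-error calibration of the
Wilcoxon and Friedman implementations. Per-subject alpha peaks are drawn
from 9–11.5 Hz snapped to the 0.5 Hz bin grid. Every random element
(generator substreams, validation split, shuffles, null simulations) is
seeded; identical inputs give identical models, traces and scores, with
candidate ties broken by canonical feature order.

## Known limitations

* Blink correction assumes linear, interval-local mixing of the FPz
  component; slow ocular drifts below the 1 Hz high-pass and saccadic
  spike potentials are out of scope.
* Re-referencing is not performed: input data are taken as referenced at
  acquisition time.
* The IAF is estimated once per session; drifting alpha peaks within a
  session are not tracked.
* The stepwise cap (10 features) and p-value thresholds trade parsimony
  against fit; on strongly structured synthetic data the cap binds, on
  noisier real data the p-value and validation rules bind first.
* The Friedman test treats the four (hour × road) cells as one factor;
  factorial decompositions beyond the two within-factor Wilcoxon tests
  are out of scope.
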