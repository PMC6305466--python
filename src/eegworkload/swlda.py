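"""Stepwise linear discriminant training and workload scoring.

The classifier is a stepwise-selected linear discriminant (SWLDA, as used
throughout the BCI literature) fitted by least squares onto 0/1 class
targets: class 0 for the easy calibration condition and 1 for the hard one.
Regression onto 0/1 targets gives the same discriminant direction as
two-class LDA up to an affine rescaling, and produces scores y(t) that sit
near 0 on easy data and near 1 on hard data.

Feature selection is forward inclusion / backward elimination on partial-F
p-values, halted automatically by whichever fires first of

* no remaining candidate with entry p-value below ``p_enter``;
* a cap on the number of selected features;
* held-out validation error failing to improve for ``patience`` steps
  (a fixed-seed split of the training epochs is reserved for validation).

After selection the final weights and bias are re-estimated by ordinary
least squares on the full training set. The per-epoch discriminant output
y(t) is then smoothed by an 8-s moving average into the workload index
WL_SCORE, reported at one value per window (8-s time resolution).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, InputError, NumericalError
from .spectral import FeatureVectorSeries


@dataclass
class StepwiseConfig:
    """Settings for stepwise selection and the automatic stop rule."""

    p_enter: float = 0.05
    p_remove: float = 0.10
    max_features: int = 10
    validation_fraction: float = 0.25
    patience: int = 2                    # non-improving steps before stopping
    min_epochs_per_class: int = 16
    seed: int = 0                        # validation-split RNG seed

    def validate(self) -> None:
        if not 0 < self.p_enter <= self.p_remove <= 1:
            raise ConfigError("need 0 < p_enter <= p_remove <= 1")
        if self.max_features < 0:
            raise ConfigError("max_features must be >= 0")
        if not 0 <= self.validation_fraction < 1:
            raise ConfigError("validation_fraction must be in [0, 1)")
        if self.min_epochs_per_class < 2:
            raise ConfigError("min_epochs_per_class must be >= 2")


@dataclass
class WorkloadModel:
    """Selected spectral features with their least-squares weights and bias."""

    selected_features: list[tuple[str, float]]
    weights: np.ndarray
    bias: float
    stepwise_trace: list[dict] = field(default_factory=list)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.selected_features):
            raise InputError("weights length != selected feature count")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "selected_features": [
                {"channel": ch, "freq_hz": fr} for ch, fr in self.selected_features
            ],
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "trace": self.stepwise_trace,
            "training_meta": self.training_meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "WorkloadModel":
        return cls(
            selected_features=[
                (f["channel"], float(f["freq_hz"])) for f in d["selected_features"]
            ],
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            stepwise_trace=list(d.get("trace", [])),
            training_meta=dict(d.get("training_meta", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "WorkloadModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class WorkloadScoreSeries:
    """Discriminant output y(t) per epoch and the smoothed workload index.

    ``wl`` is filled by :func:`workload_index`: one value per smoothing
    window, NaN where the fraction of retained epochs in the window falls
    below the minimum coverage.
    """

    y: np.ndarray
    start_times: np.ndarray
    epoch_shift_s: float
    smoothing_window_s: float = 8.0
    wl: np.ndarray | None = None
    wl_times: np.ndarray | None = None
    coverage: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.wl is None:
            raise InputError("workload index not computed yet")
        return pd.DataFrame(
            {
                "timestamp_s": self.wl_times,
                "y_mean": np.where(self.coverage > 0, self.wl_raw, np.nan),
                "wl": self.wl,
                "coverage": self.coverage,
            }
        )

    # raw window mean before coverage masking (kept for the CSV export)
    @property
    def wl_raw(self) -> np.ndarray:
        return getattr(self, "_wl_raw", self.wl)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stepwise fitting
# ---------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (coefficients, rss)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid)


def _partial_f_p(rss_small: float, rss_big: float, n: int, k_big: int) -> float:
    """p-value for adding one regressor (k_big includes the intercept)."""
    dof = n - k_big
    if dof <= 0 or rss_big <= 0:
        return 0.0 if rss_big < rss_small else 1.0
    f = (rss_small - rss_big) / (rss_big / dof)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, 1, dof))


def _coef_p_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values of the non-intercept OLS coefficients."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    coef, rss = _ols(X, y)
    dof = n - (k + 1)
    if dof <= 0:
        return np.zeros(k)
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv)[1:], 1e-300))
    t = coef[1:] / se
    return 2.0 * stats.t.sf(np.abs(t), dof)


def fit(features: FeatureVectorSeries, config: StepwiseConfig | None = None) -> WorkloadModel:
    """Train the stepwise discriminant on labeled calibration features.

    ``features.labels`` must contain both classes 0 and 1 with at least
    ``config.min_epochs_per_class`` epochs each. Identical inputs and
    configuration produce identical models (ties among equally significant
    candidates are broken by canonical feature order; the validation split
    is drawn from a fixed seed).
    """
    config = config or StepwiseConfig()
    config.validate()
    if features.labels is None:
        raise InputError("features carry no class labels")
    y_all = np.asarray(features.labels, dtype=float)
    classes = np.unique(y_all)
    if not np.array_equal(classes, [0.0, 1.0]):
        if classes.size < 2:
            raise InputError("single-class input: both classes 0 and 1 required")
        raise InputError(f"labels must be in {{0, 1}}, got {classes}")
    for cls in (0.0, 1.0):
        n_cls = int((y_all == cls).sum())
        if n_cls < config.min_epochs_per_class:
            raise InputError(
                f"class {int(cls)} has {n_cls} epochs; "
                f"need >= {config.min_epochs_per_class}"
            )
    X_all = np.asarray(features.features, dtype=float)
    n, p = X_all.shape

    # fixed-seed validation split (selection runs on the remainder)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    use_val = n_val >= 4 and (n - n_val) > 8
    if use_val:
        val_idx, sel_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, sel_idx = np.empty(0, dtype=int), perm
    Xs, ys = X_all[sel_idx], y_all[sel_idx]
    Xv, yv = X_all[val_idx], y_all[val_idx]

    selected: list[int] = []
    trace: list[dict] = []
    best_val = np.inf
    best_selected: list[int] = []
    stall = 0
    step = 0
    _, rss_cur = _ols(Xs[:, selected], ys)

    while len(selected) < min(config.max_features, p):
        step += 1
        # forward: best candidate by partial-F p-value, first index on ties
        best_j, best_p, best_rss = -1, 1.0, rss_cur
        k_big = len(selected) + 2        # intercept + current + candidate
        for j in range(p):
            if j in selected:
                continue
            _, rss_j = _ols(Xs[:, selected + [j]], ys)
            p_j = _partial_f_p(rss_cur, rss_j, len(ys), k_big)
            if p_j < best_p - 1e-15:
                best_j, best_p, best_rss = j, p_j, rss_j
        if best_j < 0 or best_p >= config.p_enter:
            break
        selected.append(best_j)
        rss_cur = best_rss
        trace.append(
            {"step": step, "action": "enter",
             "feature": list(features.feature_ids[best_j]), "p": best_p}
        )
        # backward: drop any member whose coefficient p exceeds p_remove
        changed = True
        while changed and len(selected) > 1:
            changed = False
            p_vals = _coef_p_values(Xs[:, selected], ys)
            worst = int(np.argmax(p_vals))
            if p_vals[worst] > config.p_remove and selected[worst] != best_j:
                dropped = selected.pop(worst)
                _, rss_cur = _ols(Xs[:, selected], ys)
                trace.append(
                    {"step": step, "action": "remove",
                     "feature": list(features.feature_ids[dropped]),
                     "p": float(p_vals[worst])}
                )
                changed = True
        # automatic stop on held-out validation error
        if use_val:
            coef, _ = _ols(Xs[:, selected], ys)
            pred = coef[0] + Xv[:, selected] @ coef[1:]
            val_err = float(np.mean((pred - yv) ** 2))
            if val_err < best_val - 1e-12:
                best_val = val_err
                best_selected = list(selected)
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    selected = best_selected
                    trace.append(
                        {"step": step, "action": "stop",
                         "feature": None, "p": val_err}
                    )
                    break

    # final weights: OLS refit on the full training set
    coef, _ = _ols(X_all[:, selected], y_all)
    model = WorkloadModel(
        selected_features=[features.feature_ids[j] for j in selected],
        weights=coef[1:],
        bias=float(coef[0]),
        stepwise_trace=trace,
        training_meta={
            "n_epochs": int(n),
            "n_candidates": int(p),
            "class_counts": {
                "0": int((y_all == 0).sum()), "1": int((y_all == 1).sum())
            },
            "config": asdict(config),
            "transform": features.transform,
        },
    )
    return model


def score(model: WorkloadModel, features: FeatureVectorSeries,
          epoch_shift_s: float | None = None) -> WorkloadScoreSeries:
    """Evaluate the discriminant y(t) = Σ w_i·f_i(t) + b on new features.

    Scores are not clipped to [0, 1]; they concentrate there for data
    resembling the calibration conditions but may exceed the interval.
    """
    cols = []
    for fid in model.selected_features:
        cols.append(features.column(fid))    # raises naming the missing id
    X = np.column_stack(cols) if cols else np.empty((features.n_epochs, 0))
    y = X @ model.weights + model.bias if cols else np.full(
        features.n_epochs, model.bias
    )
    if epoch_shift_s is None:
        st = np.asarray(features.start_times)
        diffs = np.diff(np.sort(st))
        epoch_shift_s = float(diffs[diffs > 1e-9].min()) if diffs.size else 0.125
    return WorkloadScoreSeries(
        y=y, start_times=np.asarray(features.start_times, dtype=float),
        epoch_shift_s=epoch_shift_s,
    )


def workload_index(
    series: WorkloadScoreSeries,
    window_s: float = 8.0,
    min_coverage: float = 0.25,
) -> WorkloadScoreSeries:
    """Smooth y(t) into the workload index WL_SCORE.

    The timeline is tiled with consecutive windows of ``window_s`` seconds
    starting at the first epoch; each window's output is the mean of y over
    the retained epochs whose start times fall inside it (a centered moving
    average evaluated once per window, i.e. 8-s time resolution). Windows
    whose epoch coverage falls below ``min_coverage`` of the expected count
    yield NaN.
    """
    if window_s < series.epoch_shift_s:
        raise ConfigError(
            f"window ({window_s} s) shorter than the epoch shift "
            f"({series.epoch_shift_s} s)"
        )
    if series.y.size == 0:
        raise NumericalError("empty score series")
    t0 = float(series.start_times.min())
    span = float(series.start_times.max()) - t0
    n_win = max(1, int(np.floor(span / window_s)) + 1)
    expected = window_s / series.epoch_shift_s
    wl = np.full(n_win, np.nan)
    raw = np.full(n_win, np.nan)
    cov = np.zeros(n_win)
    times = t0 + (np.arange(n_win) + 0.5) * window_s
    k = np.floor((series.start_times - t0) / window_s).astype(int)
    for w in range(n_win):
        mask = k == w
        n_in = int(mask.sum())
        cov[w] = n_in / expected
        if n_in:
            raw[w] = float(series.y[mask].mean())
            if cov[w] >= min_coverage:
                wl[w] = raw[w]
    out = WorkloadScoreSeries(
        y=series.y, start_times=series.start_times,
        epoch_shift_s=series.epoch_shift_s, smoothing_window_s=window_s,
        wl=wl, wl_times=times, coverage=cov,
    )
    out._wl_raw = raw
    return out
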