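"""Evaluation battery for the workload neurometric.

ROC-AUC with a shuffled-label baseline, Wilcoxon signed-rank and Friedman
tests with Benjamini–Hochberg FDR correction, condition and event-window
aggregation of the workload index, and NASA-TLX questionnaire scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .io import Annotation, HOURS, ROADS
from .swlda import WorkloadScoreSeries

#: NASA-TLX factors, in questionnaire order.
TLX_FACTORS = (
    "mental_demand", "physical_demand", "temporal_demand",
    "performance", "effort", "frustration",
)

#: Event-window lengths in seconds: from first fixation of the hazard to its
#: resolution (overtaking the car / the pedestrian clearing the road).
EVENT_WINDOW_S: Mapping[str, float] = {"Car": 20.0, "Pedestrian": 10.0}


@dataclass(frozen=True)
class EventWindowSpec:
    """Fixed analysis window per event type, with a matched no-event window
    at the same circuit position in the previous lap."""

    event_type: str
    window_s: float

    @classmethod
    def default(cls, event_type: str) -> "EventWindowSpec":
        if event_type not in EVENT_WINDOW_S:
            raise InputError(f"unknown event type {event_type!r}")
        return cls(event_type, EVENT_WINDOW_S[event_type])


# ---------------------------------------------------------------------------
# classifier metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve: P(score₁ > score₀) + ½ P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    if np.unique(labels).size < 2:
        raise InputError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, scores))


def shuffled_baseline(
    scores: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """AUC distribution under random label permutation (the 'Random'
    baseline a classifier is compared against)."""
    if n_shuffles < 1:
        raise InputError("n_shuffles must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = np.asarray(labels)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = roc_auc(scores, rng.permutation(labels))
    return out


# ---------------------------------------------------------------------------
# nonparametric tests and FDR
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    exact_cutoff: int = 25,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= ``exact_cutoff`` (ties permitting), the continuity-corrected normal
    approximation above. Returns (statistic, p).
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise InputError("all paired differences are zero")
    if d.size < 5:
        raise InputError(f"need >= 5 nonzero differences, got {d.size}")
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= exact_cutoff and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def friedman_test(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Friedman rank test on a complete subjects × conditions table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InputError("need a 2-D table with >= 2 subjects and >= 2 conditions")
    if np.isnan(arr).any():
        raise InputError("table contains missing cells")
    # fully tied rows carry no rank information: statistic 0 by convention
    if np.all(np.ptp(arr, axis=1) == 0):
        return 0.0, 1.0
    res = stats.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
    return float(res.statistic), float(res.pvalue)


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# workload aggregation
# ---------------------------------------------------------------------------

def _window_mean(series: WorkloadScoreSeries, lo: float, hi: float) -> float:
    if series.wl is None:
        raise InputError("workload index not computed (run workload_index first)")
    mask = (series.wl_times >= lo) & (series.wl_times < hi)
    vals = series.wl[mask]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else np.nan


def aggregate_conditions(
    series: WorkloadScoreSeries,
    annotations: Sequence[Annotation],
    lap: int = 3,
    exclude_event_windows: bool = False,
) -> pd.DataFrame:
    """Mean workload index per (hour, road) condition cell for one lap.

    Returns a DataFrame indexed by hour with road columns. Cells without any
    defined workload value are NaN with a warning. With
    ``exclude_event_windows`` the fixed event windows are removed before
    averaging.
    """
    if series.wl is None:
        raise InputError("workload index not computed (run workload_index first)")
    events = [a for a in annotations if a.kind == "event"]
    out = pd.DataFrame(np.nan, index=list(HOURS), columns=list(ROADS))
    for hour in HOURS:
        for road in ROADS:
            segs = [
                a for a in annotations
                if a.kind == "condition" and a.hour == hour and a.road == road
                and a.lap == lap
            ]
            vals: list[float] = []
            for seg in segs:
                mask = (series.wl_times >= seg.onset) & (series.wl_times < seg.end)
                if exclude_event_windows:
                    for ev in events:
                        L = EVENT_WINDOW_S.get(ev.event_type, ev.duration)
                        mask &= ~(
                            (series.wl_times >= ev.onset)
                            & (series.wl_times < ev.onset + L)
                        )
                v = series.wl[mask]
                vals.extend(v[~np.isnan(v)].tolist())
            if vals:
                out.loc[hour, road] = float(np.mean(vals))
            elif segs:
                warnings.warn(
                    f"no workload values in cell ({hour}, {road}), lap {lap}",
                    stacklevel=2,
                )
    return out


def event_window_analysis(
    series: WorkloadScoreSeries,
    annotations: Sequence[Annotation],
    event_lap: int = 3,
    matched_lap: int = 2,
) -> pd.DataFrame:
    """Paired event vs. matched no-event workload means.

    Each event (lap 3) defines a fixed window (20 s for Car, 10 s for
    Pedestrian) starting at its onset. The matched no-event window sits at
    the same circuit position — the same offset within the corresponding
    (hour, road) segment — of the previous lap. Returns one row per event
    with columns event_type, hour, road, event_mean, matched_mean.
    """
    events = [a for a in annotations if a.kind == "event"]
    rows = []
    for ev in events:
        spec = EventWindowSpec.default(ev.event_type)
        seg3 = _enclosing_segment(annotations, ev.onset, lap=event_lap)
        if seg3 is None:
            raise InputError(
                f"event {ev.event_type!r} at {ev.onset} s lies in no lap-"
                f"{event_lap} condition segment"
            )
        seg2 = _segment_for(annotations, seg3.hour, seg3.road, matched_lap)
        if seg2 is None:
            raise InputError(
                f"no matched lap-{matched_lap} segment ({seg3.hour}, {seg3.road}) "
                f"for event {ev.event_type!r} at {ev.onset} s"
            )
        offset = ev.onset - seg3.onset
        rows.append(
            {
                "event_type": ev.event_type,
                "hour": seg3.hour,
                "road": seg3.road,
                "window_s": spec.window_s,
                "event_mean": _window_mean(series, ev.onset, ev.onset + spec.window_s),
                "matched_mean": _window_mean(
                    series, seg2.onset + offset, seg2.onset + offset + spec.window_s
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_type", "hour", "road", "window_s", "event_mean", "matched_mean",
        ],
    )


def _enclosing_segment(
    annotations: Sequence[Annotation], t: float, lap: int
) -> Annotation | None:
    for a in annotations:
        if a.kind == "condition" and a.lap == lap and a.contains(t):
            return a
    return None


def _segment_for(
    annotations: Sequence[Annotation], hour: str, road: str, lap: int
) -> Annotation | None:
    for a in annotations:
        if (
            a.kind == "condition" and a.hour == hour and a.road == road
            and a.lap == lap
        ):
            return a
    return None


# ---------------------------------------------------------------------------
# NASA-TLX
# ---------------------------------------------------------------------------

def nasa_tlx_score(
    ratings: Mapping[str, float],
    choices: Iterable[tuple[str, str, str]],
) -> float:
    """Weighted NASA-TLX workload score in [0, 100].

    ``ratings`` maps each of the six factors to its 0–100 rating;
    ``choices`` holds the 15 pairwise comparisons as (factor_a, factor_b,
    winner) triples covering every unordered factor pair exactly once. The
    weight of a factor is the number of comparisons it won (weights sum to
    15) and the score is Σ rating·weight / 15.
    """
    missing = set(TLX_FACTORS) - set(ratings)
    if missing:
        raise InputError(f"missing ratings for factors: {sorted(missing)}")
    for f in TLX_FACTORS:
        if not 0 <= ratings[f] <= 100:
            raise InputError(f"rating for {f!r} outside [0, 100]: {ratings[f]}")
    seen: set[frozenset] = set()
    wins = {f: 0 for f in TLX_FACTORS}
    for a, b, winner in choices:
        if a not in TLX_FACTORS or b not in TLX_FACTORS:
            raise InputError(f"unknown factor in comparison ({a!r}, {b!r})")
        pair = frozenset((a, b))
        if len(pair) != 2:
            raise InputError(f"comparison pairs a factor with itself: {a!r}")
        if pair in seen:
            raise InputError(f"duplicate comparison for pair ({a!r}, {b!r})")
        if winner not in (a, b):
            raise InputError(f"winner {winner!r} not in pair ({a!r}, {b!r})")
        seen.add(pair)
        wins[winner] += 1
    if len(seen) != 15:
        raise InputError(f"expected all 15 factor pairs, got {len(seen)}")
    return float(sum(ratings[f] * wins[f] for f in TLX_FACTORS) / 15.0)
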