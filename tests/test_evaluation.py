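"""ROC-AUC, permutation baseline, nonparametric tests, FDR, aggregation,
event windows and NASA-TLX scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegworkload import evaluation as ev, io
from eegworkload.exceptions import InputError
from eegworkload.swlda import WorkloadScoreSeries


def _pair_count_auc(scores, labels):
    """Brute-force oracle: P(s1 > s0) + 0.5 P(tie) over all pairs."""
    s0 = [s for s, l in zip(scores, labels) if l == 0]
    s1 = [s for s, l in zip(scores, labels) if l == 1]
    wins = sum(1.0 if b > a else 0.5 if b == a else 0.0
               for a in s0 for b in s1)
    return wins / (len(s0) * len(s1))


class TestRocAuc:
    def test_perfect_separation(self):
        assert ev.roc_auc([0, 0.1, 0.9, 1.0], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert ev.roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_worked_example(self):
        # 4 pairs: (0.1,0.35)+, (0.1,0.8)+, (0.4,0.35)-, (0.4,0.8)+ -> 3/4
        assert ev.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(4, 60))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(-5, 5, allow_nan=False).map(lambda v: round(v, 2)),
                min_size=n, max_size=n,
            )
        )
        assert ev.roc_auc(scores, labels) == pytest.approx(
            _pair_count_auc(scores, labels)
        )

    def test_single_class_is_error(self):
        with pytest.raises(InputError):
            ev.roc_auc([0.2, 0.8], [1, 1])


class TestShuffledBaseline:
    def test_null_centered_despite_real_separation(self, rng):
        scores = np.concatenate([rng.normal(0, 0.1, 50),
                                 rng.normal(1, 0.1, 50)])
        labels = np.repeat([0, 1], 50)
        assert ev.roc_auc(scores, labels) == 1.0
        aucs = ev.shuffled_baseline(scores, labels, n_shuffles=1000, seed=9)
        assert 0.48 <= aucs.mean() <= 0.52

    def test_reproducible_with_seed(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        a = ev.shuffled_baseline(scores, labels, n_shuffles=5, seed=3)
        b = ev.shuffled_baseline(scores, labels, n_shuffles=5, seed=3)
        np.testing.assert_array_equal(a, b)


class TestWilcoxon:
    def test_exact_p_for_all_positive_differences(self):
        # oracle: exhaustive enumeration over the 2^5 sign patterns gives
        # two-sided p = 2/32
        stat, p = ev.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert p == pytest.approx(0.0625)

    def test_enumeration_oracle_small_n(self, rng):
        for _ in range(5):
            d = np.round(rng.normal(0, 2, 8), 3)
            d = d[d != 0]
            if np.unique(np.abs(d)).size < d.size or d.size < 5:
                continue
            ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
            w_obs = ranks[d > 0].sum()
            mu = d.size * (d.size + 1) / 4.0
            count = 0
            for signs in itertools.product([0, 1], repeat=d.size):
                w = ranks[np.array(signs, dtype=bool)].sum()
                if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                    count += 1
            p_oracle = count / 2 ** d.size
            _, p = ev.wilcoxon_signed_rank(d)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_antisymmetric_differences_not_significant(self):
        _, p = ev.wilcoxon_signed_rank([-2.0, -1.0, 1.0, 2.0, 3.0, -3.0])
        assert p > 0.9

    def test_all_zero_differences_error(self):
        with pytest.raises(InputError):
            ev.wilcoxon_signed_rank([0.0, 0.0, 0.0, 0.0, 0.0])

    def test_paired_form_equals_difference_form(self, rng):
        x, y = rng.normal(size=16), rng.normal(size=16)
        assert ev.wilcoxon_signed_rank(x, y) == ev.wilcoxon_signed_rank(x - y)


class TestFriedman:
    def test_identical_conditions_statistic_zero(self):
        table = np.tile([[3.0, 3.0, 3.0, 3.0]], (10, 1))
        stat, p = ev.friedman_test(table)
        assert stat == 0.0 and p == 1.0

    def test_maximal_consistency_matches_rank_formula(self):
        # every subject orders the 4 conditions identically
        n, k = 16, 4
        table = np.tile(np.arange(1.0, k + 1), (n, 1))
        stat, _ = ev.friedman_test(table)
        # direct rank formula: chi2 = 12n/(k(k+1)) * sum (Rbar - (k+1)/2)^2
        rbar = np.arange(1.0, k + 1)
        expected = 12.0 * n / (k * (k + 1)) * ((rbar - (k + 1) / 2) ** 2).sum()
        assert stat == pytest.approx(expected)
        assert expected == pytest.approx(n * (k - 1))   # maximal value

    def test_rank_formula_oracle_random_tables(self, rng):
        from scipy import stats
        for _ in range(5):
            table = rng.normal(size=(8, 3))
            stat, p = ev.friedman_test(table)
            n, k = table.shape
            ranks = np.apply_along_axis(stats.rankdata, 1, table)
            rbar = ranks.mean(axis=0)
            expected = 12.0 * n / (k * (k + 1)) * (
                (rbar - (k + 1) / 2) ** 2
            ).sum()
            assert stat == pytest.approx(expected)      # no ties here

    def test_missing_cells_error(self):
        table = np.ones((4, 3))
        table[1, 2] = np.nan
        with pytest.raises(InputError):
            ev.friedman_test(table)


class TestFdr:
    def test_three_comparison_worked_example(self):
        q = ev.fdr_correct([0.0005, 0.01, 0.64])
        np.testing.assert_allclose(q, [0.0015, 0.015, 0.64])

    def test_single_p_unchanged(self):
        assert ev.fdr_correct([0.123])[0] == pytest.approx(0.123)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_q_dominates_p_and_matches_step_up_oracle(self, ps):
        q = ev.fdr_correct(ps)
        p = np.asarray(ps)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        # direct step-up oracle
        m = p.size
        ranked = p[order] * m / np.arange(1, m + 1)
        oracle = np.minimum.accumulate(ranked[::-1])[::-1]
        np.testing.assert_allclose(q[order], np.minimum(oracle, 1.0))

    def test_constant_vectors_are_fixed_points(self):
        # step-up adjustment leaves a flat p-vector unchanged
        q = ev.fdr_correct([0.2, 0.2, 0.2, 0.2])
        np.testing.assert_allclose(q, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            ev.fdr_correct([0.1, 1.5])


def _wl_series(values, times):
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    return WorkloadScoreSeries(
        y=values, start_times=times, epoch_shift_s=1.0,
        wl=values, wl_times=times, coverage=np.ones_like(values),
    )


def _protocol_annotations(seg=64.0):
    anns = [io.make_annotation(0, 60, "eyes_closed")]
    t = 60.0
    for hour in io.HOURS:
        for lap in (1, 2, 3):
            for road in ("Easy", "Hard"):
                anns.append(io.make_annotation(
                    t, seg, f"hour={hour};road={road};lap={lap}"))
                t += seg
    return anns


class TestAggregateConditions:
    def test_constant_wl_fills_all_cells(self):
        anns = _protocol_annotations()
        times = np.arange(4.0, 830.0, 8.0)
        table = ev.aggregate_conditions(_wl_series(np.full(times.size, 0.7),
                                                   times), anns)
        assert np.allclose(table.to_numpy(), 0.7)

    def test_injected_ordering_recovered(self):
        anns = _protocol_annotations()
        times = np.arange(4.0, 830.0, 8.0)
        level = {("Normal", "Easy"): 0.1, ("Normal", "Hard"): 0.4,
                 ("Rush", "Easy"): 0.3, ("Rush", "Hard"): 0.8}
        wl = np.zeros(times.size)
        for a in anns:
            if a.kind == "condition" and a.lap == 3:
                m = (times >= a.onset) & (times < a.end)
                wl[m] = level[(a.hour, a.road)]
        table = ev.aggregate_conditions(_wl_series(wl, times), anns)
        for hour in io.HOURS:
            assert table.loc[hour, "Hard"] > table.loc[hour, "Easy"]
        for road in ("Easy", "Hard"):
            assert table.loc["Rush", road] > table.loc["Normal", road]

    def test_missing_cell_warns_others_unaffected(self):
        anns = _protocol_annotations()
        times = np.arange(4.0, 830.0, 8.0)
        wl = np.full(times.size, 0.5)
        # wipe the lap-3 Rush/Hard cell entirely
        for a in anns:
            if (a.kind == "condition" and a.lap == 3
                    and (a.hour, a.road) == ("Rush", "Hard")):
                wl[(times >= a.onset) & (times < a.end)] = np.nan
        with pytest.warns(UserWarning, match="Rush"):
            table = ev.aggregate_conditions(_wl_series(wl, times), anns)
        assert np.isnan(table.loc["Rush", "Hard"])
        assert table.loc["Normal", "Easy"] == pytest.approx(0.5)


class TestEventWindows:
    def _with_events(self):
        anns = _protocol_annotations()
        out = list(anns)
        for a in anns:
            if a.kind == "condition" and a.lap == 3:
                out.append(io.make_annotation(a.onset + 8.0, 10.0,
                                              "event=Pedestrian"))
                out.append(io.make_annotation(a.onset + 36.0, 20.0,
                                              "event=Car"))
        return sorted(out, key=lambda a: a.onset)

    def test_window_lengths_by_type(self):
        anns = self._with_events()
        times = np.arange(2.0, 830.0, 2.0)
        res = ev.event_window_analysis(_wl_series(np.zeros(times.size), times),
                                       anns)
        assert set(res.event_type) == {"Pedestrian", "Car"}
        assert (res.loc[res.event_type == "Car", "window_s"] == 20.0).all()
        assert (res.loc[res.event_type == "Pedestrian", "window_s"] == 10.0).all()
        assert len(res) == 8               # 2 events x 2 roads x 2 hours

    def test_injected_elevation_recovered(self):
        anns = self._with_events()
        times = np.arange(1.0, 830.0, 2.0)
        wl = np.full(times.size, 0.4)
        for a in anns:
            if a.kind == "event":
                L = ev.EVENT_WINDOW_S[a.event_type]
                wl[(times >= a.onset) & (times < a.onset + L)] += 0.3
        res = ev.event_window_analysis(_wl_series(wl, times), anns)
        diffs = res.event_mean - res.matched_mean
        np.testing.assert_allclose(diffs, 0.3, atol=1e-9)

    def test_no_events_empty_result(self):
        anns = _protocol_annotations()
        times = np.arange(2.0, 830.0, 8.0)
        res = ev.event_window_analysis(_wl_series(np.zeros(times.size), times),
                                       anns)
        assert len(res) == 0

    def test_unmatchable_event_is_error(self):
        anns = [io.make_annotation(0, 64, "hour=Normal;road=Easy;lap=3"),
                io.make_annotation(10, 10, "event=Pedestrian")]
        times = np.arange(0.0, 64.0, 2.0)
        with pytest.raises(InputError, match="Pedestrian"):
            ev.event_window_analysis(_wl_series(np.zeros(times.size), times),
                                     anns)


class TestNasaTlx:
    def _choices(self, wins_order):
        """All 15 pairs; the factor earlier in wins_order wins each pair."""
        rank = {f: i for i, f in enumerate(wins_order)}
        out = []
        for a, b in itertools.combinations(ev.TLX_FACTORS, 2):
            out.append((a, b, a if rank[a] < rank[b] else b))
        return out

    def test_all_ratings_100_gives_100(self):
        ratings = {f: 100.0 for f in ev.TLX_FACTORS}
        assert ev.nasa_tlx_score(ratings, self._choices(ev.TLX_FACTORS)) == 100.0

    def test_all_ratings_0_gives_0(self):
        ratings = {f: 0.0 for f in ev.TLX_FACTORS}
        assert ev.nasa_tlx_score(ratings, self._choices(ev.TLX_FACTORS)) == 0.0

    def test_weighted_sum_worked_example(self):
        # weights (5,4,3,2,1,0) x ratings (100,80,60,40,20,0) = 1100/15
        ratings = dict(zip(ev.TLX_FACTORS, [100, 80, 60, 40, 20, 0]))
        score = ev.nasa_tlx_score(ratings, self._choices(ev.TLX_FACTORS))
        assert score == pytest.approx(1100 / 15)

    def test_incomplete_pairs_rejected(self):
        ratings = {f: 50.0 for f in ev.TLX_FACTORS}
        with pytest.raises(InputError, match="15"):
            ev.nasa_tlx_score(ratings, self._choices(ev.TLX_FACTORS)[:-1])

    def test_duplicate_pair_rejected(self):
        ratings = {f: 50.0 for f in ev.TLX_FACTORS}
        choices = self._choices(ev.TLX_FACTORS)
        with pytest.raises(InputError, match="duplicate"):
            ev.nasa_tlx_score(ratings, choices[:-1] + [choices[0]])
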