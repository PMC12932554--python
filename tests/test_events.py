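"""Alignment, interval classification, burst segmentation and metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hydramea.detection import DetectionParams, PeakTrain
from hydramea.events import (
    align_and_window,
    classify_intervals,
    compute_metrics,
    metrics_from_json,
    metrics_to_json,
    raster,
)
from hydramea.exceptions import HydrameaError


def train(times, final_time, source="t", **params):
    p = DetectionParams(**params) if params else DetectionParams()
    return PeakTrain(source, np.asarray(times, dtype=float), final_time, params=p)


def brute_force_classify(durations, cp_thr, icbi_thr):
    """Independent one-line interval classifier."""
    return ["CP" if d < cp_thr else ("IcBI" if d >= icbi_thr else "ambiguous")
            for d in durations]


def brute_force_bursts(classes):
    """Burst indices as maximal runs of CP, via itertools.groupby."""
    out, b = [], -1
    for is_cp, grp in itertools.groupby(classes, key=lambda c: c == "CP"):
        n = len(list(grp))
        if is_cp:
            b += 1
            out.extend([b] * n)
        else:
            out.extend([None] * n)
    return out


class TestAlignment:
    def test_common_window_is_minimum_realigned_length(self):
        a = train([12.0, 40.0], final_time=600.0, source="a")
        b = train([30.0, 50.0], final_time=595.519, source="b")
        aligned = align_and_window([a, b])
        assert aligned.t_last == pytest.approx(565.519)
        for tr in aligned.trains:
            assert tr.peak_times[0] == 0.0
            assert np.all(tr.peak_times <= aligned.t_last + 1e-12)

    def test_single_train_already_aligned_is_identity(self):
        a = train([0.0, 5.0, 9.0], final_time=20.0)
        aligned = align_and_window([a])
        assert aligned.t_last == 20.0
        np.testing.assert_allclose(aligned.trains[0].peak_times, [0.0, 5.0, 9.0])

    def test_identical_trains_align_identically(self):
        a = train([3.0, 8.0], final_time=30.0, source="a")
        b = train([3.0, 8.0], final_time=30.0, source="b")
        aligned = align_and_window([a, b])
        np.testing.assert_allclose(aligned.trains[0].peak_times,
                                   aligned.trains[1].peak_times)

    def test_t_last_invariant_to_order(self):
        trains = [train([5.0, 9.0], 100.0, "a"), train([2.0], 60.0, "b"),
                  train([11.0, 30.0], 80.0, "c")]
        t1 = align_and_window(trains).t_last
        t2 = align_and_window(trains[::-1]).t_last
        assert t1 == t2

    def test_empty_train_excluded_with_warning(self):
        good = train([1.0, 4.0], 30.0, "good")
        empty = train([], 30.0, "empty")
        with pytest.warns(UserWarning, match="empty"):
            aligned = align_and_window([good, empty])
        assert len(aligned.trains) == 1

    def test_all_empty_is_error(self):
        with pytest.raises(HydrameaError):
            align_and_window([train([], 30.0)])

    def test_peaks_beyond_window_dropped_and_counted(self):
        a = train([0.0, 5.0], final_time=10.0, source="a")
        b = train([0.0, 4.0, 25.0], final_time=40.0, source="b")
        with pytest.warns(UserWarning, match="dropped"):
            aligned = align_and_window([a, b])
        assert aligned.t_last == 10.0
        assert aligned.dropped_peaks == [0, 1]


class TestClassification:
    def test_direct_rule_application(self):
        t = train([0.0, 1.0, 2.0, 40.0], final_time=80.0)
        table = classify_intervals(t, t_last=80.0)
        df = table.df
        np.testing.assert_allclose(df["duration_s"], [1.0, 1.0, 38.0, 40.0])
        assert list(df["class"]) == ["CP", "CP", "IcBI", "IcBI"]
        m = compute_metrics(table)
        assert m.n_burst == 1
        assert m.n_icbi == 2
        assert m.n_cp == 2

    def test_single_peak_terminal_interval(self):
        t = train([0.0], final_time=5.0)
        table = classify_intervals(t, t_last=5.0)
        m = compute_metrics(table)
        assert list(table.df["class"]) == ["CP"]
        assert m.ctime == 5.0 and m.etime == 0.0
        assert not m.hyai_defined and np.isinf(m.hyai)

    def test_unaligned_train_is_contract_violation(self):
        with pytest.raises(HydrameaError, match="not aligned"):
            classify_intervals(train([1.0, 2.0], 10.0))

    def test_ambiguous_band_warned_and_excluded(self):
        t = train([0.0, 3.0, 10.0], final_time=30.0,
                  cp_threshold=5.0, icbi_threshold=12.0)
        with pytest.warns(UserWarning, match="ambiguous"):
            table = classify_intervals(t)
        assert list(table.df["class"]) == ["CP", "ambiguous", "IcBI"]
        m = compute_metrics(table)
        assert m.ctime + m.etime < table.t_last  # ambiguous time excluded

    def test_oracle_equivalence_random_trains(self, rng):
        """Classification and burst labels match a brute-force classifier."""
        for _ in range(200):
            n = int(rng.integers(1, 30))
            times = np.sort(rng.uniform(0, 100, n))
            times[0] = 0.0
            times = np.unique(times)
            t_last = 100.0 + rng.uniform(0, 20)
            cp_thr = float(rng.uniform(0.5, 20))
            icbi_thr = cp_thr if rng.uniform() < 0.5 else cp_thr + rng.uniform(0, 5)
            t = train(times, t_last, cp_threshold=cp_thr, icbi_threshold=icbi_thr)
            table = classify_intervals(t, t_last=t_last)
            durations = np.diff(np.concatenate([times, [t_last]]))
            expected_cls = brute_force_classify(durations, cp_thr, icbi_thr)
            expected_burst = brute_force_bursts(expected_cls)
            assert list(table.df["class"]) == expected_cls
            got_burst = [None if pd.isna(x) else int(x) for x in table.df["burst_index"]]
            assert got_burst == expected_burst

    def test_idempotence(self):
        t = train([0.0, 1.0, 15.0, 16.0], final_time=40.0)
        a = classify_intervals(t).df
        b = classify_intervals(t).df
        pd.testing.assert_frame_equal(a, b)


class TestMetrics:
    def test_hyai_arithmetic(self):
        # CTime 10, ETime 40 -> HyAI 0.25
        t = train([0.0, 4.0, 10.0, 50.0], final_time=50.0,
                  cp_threshold=8.0, icbi_threshold=8.0)
        m = compute_metrics(classify_intervals(t))
        assert m.ctime == 10.0 and m.etime == 40.0
        assert m.hyai == pytest.approx(0.25)

    def test_all_icbi_gives_zero_hyai(self):
        t = train([0.0, 20.0, 45.0], final_time=80.0)
        m = compute_metrics(classify_intervals(t))
        assert m.ctime == 0.0
        assert m.hyai == 0.0 and m.hyai_defined

    def test_tiling_conservation(self):
        t = train([0.0, 0.5, 7.0, 30.0], final_time=55.5)
        m = compute_metrics(classify_intervals(t))
        assert m.ctime + m.etime == pytest.approx(55.5, rel=1e-12)

    def test_count_conventions(self):
        t = train([0.0, 1.0, 2.0, 40.0], final_time=80.0)
        m_int = compute_metrics(classify_intervals(t))
        assert list(m_int.n_cp_burst) == [2] and m_int.n_cp == 2
        t2 = train([0.0, 1.0, 2.0, 40.0], final_time=80.0, count_convention="peaks")
        m_pk = compute_metrics(classify_intervals(t2))
        assert list(m_pk.n_cp_burst) == [3] and m_pk.n_cp == 3

    def test_hyai_monotone_in_added_cp(self):
        base = train([0.0, 20.0, 25.0], final_time=60.0)
        more = train([0.0, 20.0, 25.0, 27.0], final_time=62.0)
        m0 = compute_metrics(classify_intervals(base))
        m1 = compute_metrics(classify_intervals(more))
        assert m1.etime == m0.etime  # ETime held fixed
        assert m1.hyai > m0.hyai

    def test_cv_hand_arithmetic(self):
        t = train([0.0, 2.0, 6.0, 30.0], final_time=60.0)
        m = compute_metrics(classify_intervals(t))
        np.testing.assert_allclose(m.cpi, [2.0, 4.0])
        assert m.cv["cpi"] == pytest.approx(np.sqrt(2) / 3)

    def test_json_round_trip(self):
        t = train([0.0, 1.0, 2.0, 40.0], final_time=80.0)
        m = compute_metrics(classify_intervals(t))
        back = metrics_from_json(metrics_to_json(m))
        assert back.scalars() == m.scalars()
        np.testing.assert_allclose(back.cpi, m.cpi)


class TestRaster:
    def test_structure(self):
        trains = [train([0.0, 2.0, 5.0], 10.0, "a"), train([0.0, 1.0, 9.0], 10.0, "b")]
        aligned = align_and_window(trains)
        df = raster(aligned)
        assert set(df["row"]) == {0, 1}
        assert (df.groupby("row").size() == 3).all()
        assert (df["time_s"] <= aligned.t_last).all()
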