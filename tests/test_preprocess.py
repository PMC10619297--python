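"""Cleaning-pipeline contracts: dedupe, MET/quantile filters, nightly-row
selection, sleep annotation, completeness, audit bookkeeping."""
import numpy as np
import pandas as pd
import pytest

from thermovar.errors import ConfigError, EmptySeriesError, SchemaError
from thermovar.preprocess import (
    annotate_sleep_wake,
    clean_series,
    completeness_filter,
    daily_completeness,
    index_and_dedupe,
    met_artifact_filter,
    quantile_filter,
    select_nightly_rows,
)


def _series(temps, mets=None, start="2020-01-01", freq="5min"):
    n = len(temps)
    return pd.DataFrame({
        "pid": "x",
        "timestamp": pd.date_range(start, periods=n, freq=freq),
        "temperature": np.asarray(temps, dtype=float),
        "met": np.ones(n) if mets is None else np.asarray(mets, dtype=float),
    })


class TestDedupe:
    def test_repeated_timestamp_keeps_first_and_flags(self):
        df = _series([1, 2, 3])
        dup = df.iloc[[1]].assign(temperature=99.0)
        raw = pd.concat([df, dup], ignore_index=True)
        kept, audit = index_and_dedupe(raw)
        assert len(kept) == 3
        assert kept["temperature"].tolist() == [1, 2, 3]  # first occurrence wins
        assert audit["reason"].tolist() == ["duplicate"]

    def test_sorted_unique_series_is_unchanged(self):
        df = _series([5, 6, 7])
        kept, audit = index_and_dedupe(df)
        pd.testing.assert_frame_equal(kept, df)
        assert audit.empty

    def test_shuffled_input_matches_sort_and_unique_oracle(self, rng):
        df = _series(rng.normal(size=50))
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        kept, _ = index_and_dedupe(shuffled)
        oracle = df.sort_values("timestamp").reset_index(drop=True)
        pd.testing.assert_frame_equal(kept, oracle)

    def test_empty_input_raises(self):
        with pytest.raises(EmptySeriesError):
            index_and_dedupe(_series([]))


class TestQuantileFilter:
    def test_full_band_drops_nothing(self, rng):
        df = _series(rng.normal(size=40))
        kept, audit, _ = quantile_filter(df, 0.0, 1.0)
        assert len(kept) == 40 and audit.empty

    def test_retained_count_matches_order_statistics_oracle(self, rng):
        vals = rng.permutation(np.linspace(30, 40, 100))  # 100 distinct values
        df = _series(vals)
        kept, audit, (lo, hi) = quantile_filter(df, 0.05, 0.95)
        # independent oracle: linear-interpolation quantiles on sorted values
        s = np.sort(vals)
        q = lambda f: np.interp(f * (len(s) - 1), np.arange(len(s)), s)
        expected = np.sum((vals >= q(0.05)) & (vals <= q(0.95)))
        assert len(kept) == expected
        assert lo == pytest.approx(q(0.05)) and hi == pytest.approx(q(0.95))
        assert len(kept) + len(audit) == 100

    def test_constant_series_drops_nothing_at_any_band(self):
        df = _series([36.5] * 20)
        for ql, qh in [(0.05, 0.95), (0.4, 0.6), (0.0, 1.0)]:
            kept, audit, _ = quantile_filter(df, ql, qh)
            assert len(kept) == 20 and audit.empty

    def test_inverted_band_raises(self):
        with pytest.raises(ConfigError):
            quantile_filter(_series([1, 2, 3]), 0.9, 0.1)


class TestMetFilter:
    def test_all_active_drops_nothing(self):
        kept, audit = met_artifact_filter(_series([1, 2, 3], mets=[1, 1, 1]))
        assert len(kept) == 3 and audit.empty

    def test_threshold_is_strict_below(self):
        kept, _ = met_artifact_filter(_series([1, 2], mets=[0.5, 0.49]))
        assert kept["met"].tolist() == [0.5]

    def test_generator_artifact_segments_are_fully_dropped(self, minute_participant):
        _, _, mdf, _ = minute_participant
        kept, audit = met_artifact_filter(mdf)
        assert not kept["truth_artifact"].any()
        assert len(audit) == int(mdf["truth_artifact"].sum())

    def test_missing_met_column_raises(self):
        with pytest.raises(SchemaError):
            met_artifact_filter(_series([1, 2]).drop(columns="met"))


class TestNightlySelection:
    def _rows(self, specs):
        return pd.DataFrame([
            {"pid": p, "date": pd.Timestamp(d),
             "sleep_start": pd.Timestamp(f"{d} {s}"),
             "sleep_end": pd.Timestamp(f"{d} {s}") + pd.Timedelta(minutes=dur),
             "sleep_duration": dur}
            for p, d, s, dur in specs
        ])

    def test_longest_duration_wins(self):
        rows = self._rows([("a", "2020-01-01", "23:00", 400),
                           ("a", "2020-01-01", "22:00", 480)])
        sel = select_nightly_rows(rows)
        assert len(sel) == 1 and sel["sleep_duration"].iloc[0] == 480

    def test_single_row_per_date_is_identity(self):
        rows = self._rows([("a", "2020-01-01", "23:00", 450),
                           ("a", "2020-01-02", "23:30", 430)])
        sel = select_nightly_rows(rows)
        pd.testing.assert_frame_equal(sel, rows)

    def test_ties_broken_by_earliest_start(self):
        rows = self._rows([("a", "2020-01-01", "23:30", 480),
                           ("a", "2020-01-01", "22:00", 480)])
        sel = select_nightly_rows(rows)
        assert sel["sleep_start"].iloc[0].hour == 22

    def test_randomized_fixture_matches_groupby_max_oracle(self, rng):
        specs = []
        for d in pd.date_range("2020-01-01", periods=10):
            for _ in range(int(rng.integers(1, 4))):
                specs.append(("a", d.date().isoformat(),
                              f"{int(rng.integers(20, 24)):02d}:00",
                              int(rng.integers(300, 560))))
        rows = self._rows(specs)
        sel = select_nightly_rows(rows)
        oracle = rows.groupby("date")["sleep_duration"].max()
        assert len(sel) == len(oracle)
        assert (sel.set_index("date")["sleep_duration"] == oracle).all()


class TestAnnotation:
    def _nights(self):
        return pd.DataFrame([{
            "pid": "x", "date": pd.Timestamp("2020-01-01"),
            "sleep_start": pd.Timestamp("2020-01-01 23:00"),
            "sleep_end": pd.Timestamp("2020-01-02 07:00"),
            "sleep_duration": 480.0,
        }])

    def test_halfopen_window_boundaries(self):
        df = pd.DataFrame({
            "pid": "x",
            "timestamp": [pd.Timestamp("2020-01-01 23:00"),   # == start -> sleep
                          pd.Timestamp("2020-01-02 07:00"),   # == end -> wake
                          pd.Timestamp("2020-01-02 03:00")],
            "temperature": [1.0, 2.0, 3.0], "met": [1.0, 1.0, 1.0]})
        ann = annotate_sleep_wake(df, self._nights())
        assert ann["state"].tolist() == ["sleep", "wake", "sleep"]

    def test_uncovered_date_is_unknown(self):
        df = pd.DataFrame({"pid": "x",
                           "timestamp": [pd.Timestamp("2020-03-15 12:00")],
                           "temperature": [36.0], "met": [1.0]})
        ann = annotate_sleep_wake(df, self._nights())
        assert ann["state"].tolist() == ["unknown"]

    def test_overlapping_windows_raise(self):
        from thermovar.errors import ValidationError
        nights = pd.concat([self._nights(), self._nights()], ignore_index=True)
        nights.loc[1, "sleep_start"] = pd.Timestamp("2020-01-02 05:00")
        nights.loc[1, "sleep_end"] = pd.Timestamp("2020-01-02 12:00")
        df = pd.DataFrame({"pid": "x", "timestamp": [pd.Timestamp("2020-01-01 23:30")],
                           "temperature": [36.0], "met": [1.0]})
        with pytest.raises(ValidationError):
            annotate_sleep_wake(df, nights)

    def test_synthetic_labels_agree_with_generator_truth(self, minute_participant):
        """Sleep annotation from device summaries recovers >= 99% of the
        ground-truth states (naps are summary rows the selection discards,
        so their samples are deliberately labelled wake)."""
        _, _, mdf, ndf = minute_participant
        nights = select_nightly_rows(ndf)
        ann = annotate_sleep_wake(mdf, nights)
        agree = (ann["state"] == ann["truth_state"]).mean()
        assert agree >= 0.99


class TestCompleteness:
    def test_complete_participant_retained_half_complete_dropped(self):
        full = _series(np.ones(288 * 3), freq="5min")
        half = full.iloc[::2]
        kept = completeness_filter({"full": full, "half": half}, sample_minutes=5)
        assert kept == ["full"]

    def test_planted_completeness_matches_direct_oracle(self, rng):
        frames = {}
        expected = []
        for i, frac in enumerate([0.95, 0.75, 0.69, 0.5, 1.0]):
            base = _series(np.ones(288 * 4), freq="5min")
            keep = rng.random(len(base)) < frac
            frames[f"p{i}"] = base[keep]
            comp = daily_completeness(base[keep], 5).mean()
            if comp >= 0.70:
                expected.append(f"p{i}")
        assert completeness_filter(frames, sample_minutes=5) == expected

    def test_required_months_enforced(self):
        jan = _series(np.ones(288 * 2), start="2020-01-01")
        kept = completeness_filter({"jan": jan}, 5, required_months=["2020-01", "2020-02"])
        assert kept == []
        kept = completeness_filter({"jan": jan}, 5, required_months=["2020-01"])
        assert kept == ["jan"]


class TestFullClean:
    def test_every_drop_has_exactly_one_reason_and_counts_partition(self, minute_participant):
        _, _, mdf, _ = minute_participant
        res = clean_series(mdf)
        assert len(res.clean) + len(res.audit) == len(mdf)
        assert set(res.audit["reason"]) <= {"duplicate", "met_artifact", "quantile"}

    def test_reapplication_with_stored_band_is_identity(self, minute_participant):
        _, _, mdf, _ = minute_participant
        first = clean_series(mdf)
        second = clean_series(first.clean, quantile_bounds=first.quantile_bounds)
        assert second.audit.empty
        pd.testing.assert_frame_equal(second.clean, first.clean)
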