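"""Windowing, activity matching, summaries, retention filtering, export."""

import csv

import numpy as np
import pytest

from ibiqc import (
    ActivitySeries,
    IBITrace,
    RetentionPolicy,
    SpecError,
    export_covariate_table,
    filter_windows,
    generate_activity,
    generate_clean_trace,
    match_activity,
    segment_windows,
    CleanTraceSpec,
)


def constant_trace(n, ibi=500.0, **kw):
    return IBITrace(ibi_ms=np.full(n, ibi), **kw)


class TestSegmentation:
    def test_600s_constant_trace_gives_two_windows(self):
        t = constant_trace(1200)  # 600 s at 500 ms
        wins = segment_windows(t)
        assert len(wins) == 2
        # the beat falling exactly on t=300.0 s belongs to window 1, and the
        # final beat at t=600.0 s starts the (discarded) next window
        assert [w.n_beats for w in wins] == [599, 600]

    def test_trailing_partial_window_dropped(self):
        t = constant_trace(960)  # 8 min at 500 ms
        wins = segment_windows(t)
        assert len(wins) == 1

    def test_beat_exactly_on_boundary_goes_to_next_window(self):
        # beat times 100, 200, 300, 400 s: the 300 s beat is window 1
        t = IBITrace(ibi_ms=[100000.0] * 6)
        wins = segment_windows(t, window_s=300.0)
        assert wins[0].n_beats == 2   # 100, 200
        assert wins[1].n_beats == 3   # 300, 400, 500

    def test_partition_every_beat_in_exactly_one_window(self):
        t = generate_clean_trace(CleanTraceSpec(duration_s=1500.0, seed=5))
        wins = segment_windows(t)
        total = sum(w.n_beats for w in wins)
        covered = np.sum(t.beat_time_s < len(wins) * 300.0)
        assert total == covered

    def test_nonpositive_window_rejected(self, small_trace):
        with pytest.raises(SpecError):
            segment_windows(small_trace, window_s=0)


class TestActivityMatching:
    def test_beat_matched_to_containing_second(self):
        t = IBITrace(ibi_ms=[12400.0])  # beat at 12.4 s
        a = ActivitySeries(seconds=[12], labels=["Active"])
        assert match_activity(t, a).activity[0] == "Active"

    def test_missing_second_is_unknown(self):
        t = IBITrace(ibi_ms=[12400.0])
        a = ActivitySeries(seconds=[11], labels=["Active"])
        assert match_activity(t, a).activity[0] == "Unknown"

    def test_matched_active_fraction_tracks_generator(self):
        t = generate_clean_trace(CleanTraceSpec(duration_s=20000.0, seed=6))
        a = generate_activity(t.duration_s + 1, 60.0, 0.3, seed=6)
        matched = match_activity(t, a)
        frac = float(np.mean(matched.activity == "Active"))
        assert abs(frac - 0.3) < 0.03


class TestSummaries:
    def test_flag_percentages(self):
        flat = np.zeros(1200, dtype=bool)
        flat[:30] = True  # 30 flats inside the first window
        t = IBITrace(ibi_ms=np.full(1200, 500.0), flat=flat)
        w = segment_windows(t)[0]
        assert w.n_flats == 30
        assert w.pct_flats_stairs == pytest.approx(100.0 * 30 / w.n_beats)

    def test_mean_hr(self):
        w = segment_windows(constant_trace(1200))[0]
        assert w.mean_hr_bpm == pytest.approx(120.0)

    def test_all_unknown_activity_gives_absent_pct(self):
        w = segment_windows(constant_trace(1200))[0]
        assert w.pct_active is None

    def test_counts_match_brute_force_tally(self, rng):
        n = 1200
        t = IBITrace(
            ibi_ms=np.full(n, 500.0),
            flat=rng.random(n) < 0.2, stair=rng.random(n) < 0.1,
            corrected=rng.random(n) < 0.3, out_of_bounds=rng.random(n) < 0.05,
            activity=rng.choice(["Inactive", "Active", "Unknown"], size=n),
        )
        w = segment_windows(t)[0]
        m = t.beat_time_s < 300.0
        assert w.n_flats == int(t.flat[m].sum())
        assert w.n_stairs == int(t.stair[m].sum())
        assert w.n_corrected == int(t.corrected[m].sum())
        known = m & (t.activity != "Unknown")
        expect_active = 100.0 * (t.activity[known] == "Active").sum() / known.sum()
        assert w.pct_active == pytest.approx(expect_active)


class TestRetention:
    def _window_with(self, pct_fs=0.0, pct_active=0.0, pct_art=0.0, n=600):
        from ibiqc.windows import TraceWindow

        return TraceWindow(
            window_index=0, start_s=0, end_s=300, n_beats=n,
            pct_flats_stairs=pct_fs, pct_active=pct_active, pct_artefact=pct_art,
        )

    def test_boundary_5pct_retained(self):
        ret, rej = filter_windows([self._window_with(pct_fs=5.0)])
        assert len(ret) == 1

    def test_5p1pct_rejected_with_reason(self):
        ret, rej = filter_windows([self._window_with(pct_fs=5.1)])
        assert ret == [] and rej[0][1] == "flats_stairs"

    def test_first_failed_criterion_reported(self):
        w = self._window_with(pct_fs=50.0, pct_active=50.0)
        _, rej = filter_windows([w])
        assert rej[0][1] == "flats_stairs"

    def test_matches_brute_force_filter(self, rng):
        wins = [
            self._window_with(
                pct_fs=float(rng.uniform(0, 10)), pct_active=float(rng.uniform(0, 2)),
            )
            for _ in range(200)
        ]
        policy = RetentionPolicy(max_pct_flats_stairs=5.0, max_pct_active=0.0)
        ret, _ = filter_windows(wins, policy)
        expected = [w for w in wins if w.pct_flats_stairs <= 5.0 and w.pct_active <= 0.0]
        assert ret == expected

    def test_tightening_thresholds_is_monotone(self, rng):
        wins = [self._window_with(pct_fs=float(rng.uniform(0, 10))) for _ in range(100)]
        sizes = [
            len(filter_windows(wins, RetentionPolicy(max_pct_flats_stairs=x))[0])
            for x in (10.0, 5.0, 2.0, 0.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestExport:
    def test_rows_and_roundtrip(self, tmp_path):
        t = generate_clean_trace(CleanTraceSpec(duration_s=1000.0, seed=1))
        t.individual_id, t.tag_id = "F01", "T01"
        t.covariates = {"day_of_year": 310, "time_of_day": 0.5, "mass_kg": 140.0}
        wins = segment_windows(t)
        path = tmp_path / "wins.csv"
        export_covariate_table(wins, path)
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(wins) == 3
        for row, w in zip(rows, wins):
            assert int(row["n_beats"]) == w.n_beats
            assert float(row["rmssd_ms"]) == pytest.approx(w.rmssd_ms)
            assert float(row["mean_hr_bpm"]) == pytest.approx(w.mean_hr_bpm)
            assert row["pct_active"] == ""  # no activity matched
            assert int(row["day_of_year"]) == 310
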