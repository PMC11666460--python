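"""Ensemble co-participation, lagged cross-correlations, concatenation."""

import numpy as np
import pytest

from conftest import tiny_matrix
from coreact.bursts import (
    BurstCatalog,
    detect_bursts,
    detect_bursts_with_boundaries,
    population_trace,
    zscore_cells,
    zscore_trace,
)
from coreact.coactivity import (
    concatenate_offline,
    coparticipation_fractions,
    ensemble_event_participation,
    ensemble_mean_traces,
    frame_exceedance_fractions,
    lagged_crosscorr,
    nonburst_coparticipation,
    nonburst_windows,
)
from coreact.core import EnsembleAssignment, EventMatrix
from oracles import (
    brute_coparticipation,
    brute_ensemble_event_participation,
    brute_lagged_crosscorr,
    brute_zscore_rows,
)


def as_matrix(values, rate=30.0):
    values = np.asarray(values, dtype=float)
    ts = np.arange(values.shape[1]) * (1000.0 / rate)
    return EventMatrix(values, rate, ts, np.arange(values.shape[0]))


class TestEnsembleMeanTraces:
    def test_singleton_ensemble_equals_rezscored_cell(self):
        rng = np.random.default_rng(0)
        m = tiny_matrix(rng, 3, 40)
        a = EnsembleAssignment("off", {0: "neutral", 1: "remaining",
                                       2: "remaining"})
        traces = ensemble_mean_traces(m, a, ensembles=("neutral",))
        expect = zscore_trace(zscore_cells(m.values)[0])
        np.testing.assert_allclose(traces["neutral"], expect, atol=1e-12)

    def test_empty_ensemble_omitted(self):
        m = tiny_matrix(np.random.default_rng(1), 2, 30)
        a = EnsembleAssignment("off", {0: "neutral", 1: "neutral"})
        traces = ensemble_mean_traces(m, a)
        assert set(traces) == {"neutral"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = tiny_matrix(rng, 6, 50)
        labels = ["neutral"] * 2 + ["aversive"] * 2 + ["overlap"] * 2
        a = EnsembleAssignment("off", dict(enumerate(labels)))
        traces = ensemble_mean_traces(m, a)
        z = brute_zscore_rows(m.values)
        for name, rows in (("neutral", [0, 1]), ("aversive", [2, 3]),
                           ("overlap", [4, 5])):
            mean = z[rows].mean(axis=0)
            expect = (mean - mean.mean()) / mean.std()
            np.testing.assert_allclose(traces[name], expect, atol=1e-12)


class TestEnsembleEventParticipation:
    def test_zero_trace_participates_nowhere(self):
        cat = BurstCatalog(np.zeros(30), np.array([[5, 6, 10], [20, 20, 22]]))
        out = ensemble_event_participation({"neutral": np.zeros(30)}, cat)
        assert not out["neutral"].any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        traces = {k: rng.normal(0, 1.5, 50) for k in ("a", "b", "c")}
        cat = detect_bursts(rng.normal(0, 1.5, 50), 1.0)
        got = ensemble_event_participation(traces, cat, 1.0)
        expect = brute_ensemble_event_participation(
            traces, [tuple(e) for e in cat.events], 1.0
        )
        for k in traces:
            assert np.array_equal(got[k], expect[k])

    def test_overlap_planted_in_every_burst_detected(self, small_experiment):
        exp, truth = small_experiment
        matrix = exp.sessions["offline2"].matrix
        flags = truth.bursts["offline2"]["participation"]
        windows = truth.bursts["offline2"]["windows"][flags["overlap"]]
        cat = BurstCatalog(
            population_trace(matrix),
            np.column_stack([windows[:, 0], windows[:, 0], windows[:, 1]]),
        )
        traces = ensemble_mean_traces(matrix, truth.assignment("offline2"))
        out = ensemble_event_participation(traces, cat, 2.0)
        assert out["overlap"].mean() >= 0.95


class TestCoparticipationFractions:
    def test_single_event_only_overlap(self):
        s = coparticipation_fractions({
            "overlap": np.array([True]),
            "neutral": np.array([False]),
            "aversive": np.array([False]),
        })
        assert s.independent["overlap"] == 1.0
        assert all(v == 0.0 for v in s.pairwise.values())

    def test_all_ensembles_every_event(self):
        flags = {k: np.ones(4, dtype=bool)
                 for k in ("overlap", "neutral", "aversive")}
        s = coparticipation_fractions(flags)
        assert all(v == 0.0 for v in s.independent.values())
        assert all(v == 1.0 for v in s.pairwise.values())

    def test_zero_events_empty_summary(self):
        s = coparticipation_fractions({"a": np.zeros(0, dtype=bool)})
        assert s.empty

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        flags = {k: rng.random(12) < 0.5 for k in ("x", "y", "z")}
        s = coparticipation_fractions(flags)
        ind, pair = brute_coparticipation(flags)
        assert s.independent == ind
        assert s.pairwise == pair

    def test_pair_fraction_bounded_by_members(self):
        rng = np.random.default_rng(9)
        flags = {k: rng.random(40) < 0.6 for k in ("a", "b", "c")}
        s = coparticipation_fractions(flags)
        for (a, b), v in s.pairwise.items():
            assert v <= min(s.total[a], s.total[b]) + 1e-12


class TestNonburstCoparticipation:
    def test_windows_cover_only_nonburst_frames(self):
        cat = BurstCatalog(np.zeros(100), np.array([[10, 12, 20], [50, 50, 56]]))
        wins = nonburst_windows(100, cat, window_len=6)
        mask = cat.burst_mask()
        for s, e in wins:
            assert not mask[s:e].any()
            assert e - s == 6

    def test_default_window_is_median_burst_duration(self):
        cat = BurstCatalog(np.zeros(200),
                           np.array([[10, 11, 20], [50, 50, 60], [90, 91, 100]]))
        wins = nonburst_windows(200, cat)
        assert np.all(wins[:, 1] - wins[:, 0] == 10)

    def test_subthreshold_windows_only_fill_denominator(self):
        cat = BurstCatalog(np.zeros(60), np.array([[20, 21, 25]]))
        traces = {"neutral": np.zeros(60), "aversive": np.zeros(60)}
        s = nonburst_coparticipation(traces, cat, window_len=5)
        assert s.n_events > 0
        assert all(v == 0.0 for v in s.independent.values())

    def test_framewise_variant_counts_outside_frames(self):
        cat = BurstCatalog(np.zeros(30), np.array([[10, 10, 20]]))
        trace = np.zeros(30)
        trace[5] = 3.0   # outside the burst
        trace[12] = 3.0  # inside the burst: excluded
        s = frame_exceedance_fractions({"neutral": trace}, cat, 2.0)
        assert s.n_events == 20
        assert s.independent["neutral"] == pytest.approx(1 / 20)


class TestLaggedCrosscorr:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=3600 * 2)
        out = lagged_crosscorr(a, a, frame_rate=30.0)
        assert out["mean_max_corr"] == pytest.approx(1.0)

    def test_pure_shift_recovered_within_lag_range(self):
        rng = np.random.default_rng(1)
        n = 3600 * 2
        a = rng.normal(size=n + 3)
        b = a[:-3]
        a = a[3:]
        out = lagged_crosscorr(a, b, frame_rate=30.0, max_lag_frames=5)
        assert out["mean_max_corr"] >= 0.999

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_direct_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=100)
        b = 0.5 * a + rng.normal(size=100)
        got = lagged_crosscorr(a, b, frame_rate=1.0, bin_s=25, max_lag_frames=3)
        expect = brute_lagged_crosscorr(a, b, n_bin=25, max_lag=3)
        assert got["mean_max_corr"] == pytest.approx(expect)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 240))
        ab = lagged_crosscorr(a, b, 1.0, bin_s=60, max_lag_frames=4)
        ba = lagged_crosscorr(b, a, 1.0, bin_s=60, max_lag_frames=4)
        assert ab["mean_max_corr"] == pytest.approx(ba["mean_max_corr"])

    def test_longer_lag_range_never_decreases_maxima(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(2, 500))
        vals = [
            lagged_crosscorr(a, b, 1.0, bin_s=100, max_lag_frames=L)[
                "mean_max_corr"]
            for L in (0, 2, 4, 8)
        ]
        assert vals == sorted(vals)

    def test_trailing_partial_bin_dropped(self):
        a = np.random.default_rng(7).normal(size=250)
        out = lagged_crosscorr(a, a, 1.0, bin_s=100, max_lag_frames=2)
        assert len(out["per_bin"]) == 2

    def test_zero_variance_bin_skipped(self):
        a = np.concatenate([np.ones(100), np.random.default_rng(8).normal(
            size=100)])
        out = lagged_crosscorr(a, a, 1.0, bin_s=100, max_lag_frames=2)
        assert out["skipped_bins"] == 1


class TestConcatenateOffline:
    def test_single_session_rezscored(self):
        rng = np.random.default_rng(0)
        t = rng.normal(2.0, 3.0, size=100)
        traces, bounds = concatenate_offline([{"neutral": t}])
        np.testing.assert_allclose(traces["neutral"], (t - t.mean()) / t.std())
        assert bounds.size == 0

    def test_output_length_is_sum_of_sessions(self):
        rng = np.random.default_rng(1)
        sessions = [{"neutral": rng.normal(size=50),
                     "overlap": rng.normal(size=50)} for _ in range(24)]
        traces, bounds = concatenate_offline(sessions)
        assert traces["neutral"].size == 24 * 50
        assert bounds.tolist() == [50 * k for k in range(1, 24)]

    def test_session_missing_ensemble_excluded(self):
        rng = np.random.default_rng(2)
        sessions = [
            {"neutral": rng.normal(size=30), "overlap": rng.normal(size=30)},
            {"neutral": rng.normal(size=30)},  # no overlap -> dropped
            {"neutral": rng.normal(size=30), "overlap": rng.normal(size=30)},
        ]
        traces, bounds = concatenate_offline(sessions)
        assert traces["neutral"].size == 60

    def test_no_event_crosses_a_boundary(self):
        rng = np.random.default_rng(3)
        # high-mean sessions so the concatenated z-scored trace sits above
        # threshold across a boundary unless the split is enforced
        sessions = [{"e": np.concatenate([rng.normal(size=45),
                                          rng.normal(10, 0.1, size=5)])},
                    {"e": np.concatenate([rng.normal(10, 0.1, size=5),
                                          rng.normal(size=45)])}]
        traces, bounds = concatenate_offline(sessions)
        cat = detect_bursts_with_boundaries(traces["e"], bounds, 2.0)
        assert cat.n_events >= 2
        for s, _, e in cat.events:
            assert not any(s < b < e for b in bounds)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            concatenate_offline([])
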