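"""Population burst detection, participation, shuffle null, locomotion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import tiny_matrix
from coreact.bursts import (
    BurstCatalog,
    cell_participation,
    detect_bursts,
    ensemble_participation,
    peri_burst_locomotion,
    population_trace,
    shuffle_null,
)
from coreact.core import EnsembleAssignment, EventMatrix
from oracles import (
    brute_cell_participation,
    brute_detect_bursts,
    brute_population_trace,
)


def as_matrix(values, rate=30.0):
    values = np.asarray(values, dtype=float)
    ts = np.arange(values.shape[1]) * (1000.0 / rate)
    return EventMatrix(values, rate, ts, np.arange(values.shape[0]))


class TestPopulationTrace:
    def test_constant_matrix_gives_zero_trace(self):
        trace = population_trace(as_matrix(np.ones((4, 20))))
        assert np.array_equal(trace, np.zeros(20))

    def test_hand_matrix_matches_double_zscore_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.random((3, 10))
        trace = population_trace(as_matrix(values))
        np.testing.assert_allclose(trace, brute_population_trace(values),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_standardized(self, seed):
        m = tiny_matrix(np.random.default_rng(seed), 6, 50)
        trace = population_trace(m)
        assert abs(trace.mean()) < 1e-9
        assert abs(trace.std() - 1) < 1e-9


class TestDetectBursts:
    def test_subthreshold_trace_yields_empty_catalog(self):
        trace = np.zeros(100)
        trace[50] = 1.9  # a z = 2 threshold admits nothing below it
        assert detect_bursts(trace, 2.0).n_events == 0

    def test_two_runs_give_exactly_two_events_with_bounds(self):
        trace = np.zeros(60)
        trace[10:15] = 3.0
        trace[40:42] = 2.5
        cat = detect_bursts(trace, 2.0)
        assert cat.events.tolist() == [[10, 10, 15], [40, 40, 42]]

    def test_peak_is_argmax_earliest_on_ties(self):
        trace = np.zeros(30)
        trace[5:10] = [2.5, 3.0, 2.6, 3.0, 2.5]
        cat = detect_bursts(trace, 2.0)
        assert cat.events[0].tolist() == [5, 6, 10]

    def test_planted_bursts_recovered_near_their_peaks(self, small_experiment):
        # recovery is assessed over planted bursts in which some tracked
        # ensemble participated; a burst slot that no ensemble joined adds
        # only the weak remaining-cell component and is not a population burst
        exp, truth = small_experiment
        matrix = exp.sessions["offline2"].matrix
        cat = detect_bursts(population_trace(matrix), 2.0)
        flags = truth.bursts["offline2"]["participation"]
        active = flags["overlap"] | flags["neutral"] | flags["aversive"]
        windows = truth.bursts["offline2"]["windows"][active]
        centers = windows.mean(axis=1)
        half_s_frames = int(0.5 * matrix.frame_rate)
        hits = sum(
            np.min(np.abs(cat.events[:, 1] - c)) <= half_s_frames
            for c in centers
        )
        assert hits >= 0.95 * len(centers)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        trace = rng.normal(0, 1.2, size=80)
        cat = detect_bursts(trace, 1.0)
        assert cat.events.tolist() == [
            list(t) for t in brute_detect_bursts(trace, 1.0)
        ]

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_raising_threshold_never_adds_events(self, seed):
        rng = np.random.default_rng(seed)
        trace = rng.normal(0, 1.5, size=200)
        counts = [detect_bursts(trace, z).n_events for z in (1.0, 1.5, 2.0, 2.5)]
        assert counts == sorted(counts, reverse=True)

    def test_detection_invariant_to_cell_permutation(self):
        rng = np.random.default_rng(11)
        m = tiny_matrix(rng, 6, 50)
        perm = rng.permutation(6)
        m2 = as_matrix(m.values[perm])
        a = detect_bursts(population_trace(m), 1.0).events
        b = detect_bursts(population_trace(m2), 1.0).events
        assert np.array_equal(a, b)


class TestCellParticipation:
    def test_silent_cell_participates_nowhere(self):
        values = np.zeros((2, 30))
        values[0, [5, 6, 20]] = 1.0
        m = as_matrix(values)
        cat = detect_bursts(population_trace(m), 0.5)
        part = cell_participation(m, cat)
        assert not part[1].any()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_frame_by_frame_oracle(self, seed):
        m = tiny_matrix(np.random.default_rng(seed), 5, 40)
        cat = detect_bursts(population_trace(m), 1.0)
        part = cell_participation(m, cat, 1.5)
        expect = brute_cell_participation(
            m.values, [tuple(e) for e in cat.events], 1.5
        )
        assert np.array_equal(part, expect)

    def test_frame_count_mismatch_rejected(self):
        m = tiny_matrix(np.random.default_rng(0), 4, 30)
        cat = BurstCatalog(np.zeros(40), np.zeros((0, 3)), 2.0)
        with pytest.raises(ValueError, match="frame count"):
            cell_participation(m, cat)


class TestEnsembleParticipation:
    @staticmethod
    def assignment(labels):
        return EnsembleAssignment("off", labels)

    def test_full_participation_gives_unit_fractions(self):
        part = np.ones((4, 3), dtype=bool)
        a = self.assignment({0: "neutral", 1: "neutral", 2: "aversive",
                             3: "remaining"})
        s = ensemble_participation(part, np.arange(4), a)
        assert all(v == 1.0 for v in s.ensemble_fractions.values())

    def test_zero_events_flagged_empty(self):
        part = np.zeros((2, 0), dtype=bool)
        a = self.assignment({0: "neutral", 1: "remaining"})
        s = ensemble_participation(part, np.arange(2), a)
        assert s.empty and not s.ensemble_fractions

    def test_permuting_cells_leaves_fractions_unchanged(self):
        rng = np.random.default_rng(5)
        part = rng.random((6, 10)) < 0.4
        labels = {i: l for i, l in enumerate(
            ["neutral", "neutral", "aversive", "overlap", "remaining",
             "remaining"])}
        s1 = ensemble_participation(part, np.arange(6), self.assignment(labels))
        perm = rng.permutation(6)
        s2 = ensemble_participation(
            part[perm], np.arange(6)[perm], self.assignment(labels)
        )
        assert s1.ensemble_fractions == s2.ensemble_fractions

    def test_planted_probabilities_recovered(self, small_experiment):
        """Measured ensemble fractions match the generative expectation.

        An engaged cell always fires in the burst window; with engagement
        probability p and background hit probability q inside the window the
        expected measured fraction is p + (1-p)q.
        """
        exp, truth = small_experiment
        cfg = truth.config
        matrix = exp.sessions["offline2"].matrix
        windows = truth.bursts["offline2"]["windows"]
        cat = BurstCatalog(
            population_trace(matrix),
            np.column_stack([windows[:, 0], windows[:, 0], windows[:, 1]]),
            threshold_z=2.0,
        )
        part = cell_participation(matrix, cat)
        summary = ensemble_participation(
            part, matrix.cell_ids, truth.assignment("offline2")
        )
        window = int(round(cfg.burst_duration_s * matrix.frame_rate))
        q_bg = 1 - (1 - cfg.background_rate / matrix.frame_rate) ** window
        flags = truth.bursts["offline2"]["participation"]
        n_events = len(flags["overlap"])
        for name, n_cells in (("overlap", 15), ("aversive", 20)):
            p_engage = cfg.cell_participation_prob[name]
            share = flags[name].mean()  # bursts where the ensemble engaged
            p_eff = share * (p_engage + (1 - p_engage) * q_bg) + (
                1 - share) * q_bg
            sd = np.sqrt(p_eff * (1 - p_eff) / n_cells / n_events)
            assert abs(summary.ensemble_fractions[name] - p_eff) < 4 * sd + 0.02
        p_rem = cfg.remaining_burst_prob
        p_eff = p_rem + (1 - p_rem) * q_bg
        sd = np.sqrt(p_eff * (1 - p_eff) / 45 / n_events)
        assert abs(summary.ensemble_fractions["remaining"] - p_eff) \
            < 4 * sd + 0.02


class TestShuffleNull:
    def test_fixed_seed_reproducible(self):
        m = tiny_matrix(np.random.default_rng(2), 10, 300)
        a = shuffle_null(m, n_shuffles=20, seed=5)
        b = shuffle_null(m, n_shuffles=20, seed=5)
        assert np.array_equal(a["null_counts"], b["null_counts"])
        assert a["p_value"] == b["p_value"]

    def test_independent_noise_count_within_null_range(self):
        rng = np.random.default_rng(8)
        m = tiny_matrix(rng, 30, 3000, p=0.01)
        null = shuffle_null(m, n_shuffles=100, seed=1)
        lo, hi = np.percentile(null["null_counts"], [1, 99])
        assert lo <= null["observed_count"] <= hi

    def test_planted_synchrony_is_extreme_against_null(self, small_experiment):
        """Structured sessions consolidate supra-threshold mass into few long
        events: the count falls in the extreme lower null tail and the mean
        event duration in the extreme upper tail."""
        exp, _ = small_experiment
        null = shuffle_null(exp.sessions["offline2"].matrix,
                            n_shuffles=100, seed=3)
        assert null["p_count_lower"] <= 1 / 101
        assert null["p_duration"] <= 1 / 101


class TestPeriBurstLocomotion:
    def test_no_trace_reports_not_available(self):
        cat = BurstCatalog(np.zeros(10), np.zeros((0, 3)))
        out = peri_burst_locomotion(None, None, cat, np.arange(10.0))
        assert out == {"available": False}

    def test_constant_locomotion_gives_flat_mean(self):
        n = 600
        cal_ts = np.arange(n) * (1000 / 30.0)
        loco_ts = np.arange(200) * 100.0
        cat = BurstCatalog(np.zeros(n), np.array([[300, 300, 310]]))
        out = peri_burst_locomotion(np.full(200, 3.0), loco_ts, cat, cal_ts,
                                    window_s=5.0)
        assert out["aligned"].shape[0] == 1
        np.testing.assert_allclose(out["mean"], 3.0)

    def test_edge_event_excluded_and_empty_flagged(self):
        n = 100
        cal_ts = np.arange(n) * (1000 / 30.0)
        loco_ts = np.arange(40) * 100.0
        cat = BurstCatalog(np.zeros(n), np.array([[0, 0, 5]]))
        out = peri_burst_locomotion(np.ones(40), loco_ts, cat, cal_ts, 5.0)
        assert out["empty"] and out["aligned"].shape[0] == 0

    def test_planted_dip_minimum_recovered(self, small_experiment):
        exp, truth = small_experiment
        rec = exp.sessions["offline2"]
        cat = detect_bursts(population_trace(rec.matrix), 2.0)
        out = peri_burst_locomotion(
            rec.locomotion, rec.locomotion_timestamps, cat,
            rec.matrix.timestamps, window_s=5.0,
        )
        t_min = out["offsets_s"][np.argmin(out["mean"])]
        assert abs(t_min - truth.dip["center_s"]) <= 0.25
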