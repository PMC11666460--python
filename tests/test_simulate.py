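"""Synthetic experiment generator: determinism, planted statistics."""

import dataclasses

import numpy as np
import pytest

from coreact.bursts import detect_bursts, population_trace, shuffle_null
from coreact.chemotag import rank_chemotag
from coreact.simulate import (
    SimulationConfig,
    simulate_chemotag_session,
    simulate_eeg_emg,
    simulate_experiment,
    simulate_hypnogram,
    simulate_offline_session,
)
from coreact.sleep import DELTA_BAND, THETA_BAND, band_power_per_epoch


def offline_only(**kw):
    cfg = dataclasses.replace(
        SimulationConfig.high_shock(),
        n_cells=100,
        ensemble_sizes={"neutral": 20, "aversive": 20, "overlap": 15,
                        "remaining": 45},
        n_shared_encoding=20,
        n_extra_encoding=5,
        neutral_encoding_s=30.0,
        aversive_encoding_s=30.0,
        offline_s=300.0,
        sessions=("neutral_encoding", "aversive_encoding", "offline2"),
    )
    return dataclasses.replace(cfg, **kw)


class TestDeterminism:
    def test_identical_seed_bitwise_identical_experiment(self, small_config):
        a, ta = simulate_experiment(small_config, seed=5)
        b, tb = simulate_experiment(small_config, seed=5)
        for name in a.sessions:
            assert np.array_equal(
                a.sessions[name].matrix.values, b.sessions[name].matrix.values
            )
            if a.sessions[name].locomotion is not None:
                assert np.array_equal(
                    a.sessions[name].locomotion, b.sessions[name].locomotion
                )
        for mta, mtb in zip(a.match_tables, b.match_tables):
            assert mta.pairs == mtb.pairs
        assert ta.ensembles == tb.ensembles
        assert ta.recall_fractions == tb.recall_fractions

    def test_different_seed_differs(self, small_config):
        a, _ = simulate_experiment(small_config, seed=5)
        b, _ = simulate_experiment(small_config, seed=6)
        assert not np.array_equal(
            a.sessions["offline2"].matrix.values,
            b.sessions["offline2"].matrix.values,
        )

    def test_dropping_sessions_keeps_shared_sessions_identical(
            self, small_config):
        full, _ = simulate_experiment(small_config, seed=9)
        sub_cfg = dataclasses.replace(
            small_config,
            sessions=("neutral_encoding", "aversive_encoding", "offline2"),
        )
        sub, _ = simulate_experiment(sub_cfg, seed=9)
        assert np.array_equal(
            full.sessions["offline2"].matrix.values,
            sub.sessions["offline2"].matrix.values,
        )


class TestConfigValidation:
    def test_oversized_ensembles_rejected_before_generation(self):
        cfg = SimulationConfig(n_cells=10)
        with pytest.raises(ValueError, match="n_cells"):
            simulate_experiment(cfg, seed=0)

    def test_bad_probability_rejected(self):
        cfg = SimulationConfig()
        cfg.p_overlap_participation = 1.4
        with pytest.raises(ValueError, match="probabilities"):
            cfg.validate()

    def test_chemotag_requires_offline2(self):
        cfg = SimulationConfig()
        cfg.sessions = ("neutral_encoding", "aversive_encoding", "chemotag")
        with pytest.raises(ValueError, match="offline2"):
            simulate_experiment(cfg, seed=0)


class TestOfflineSession:
    def test_background_event_count_matches_poisson_expectation(self):
        cfg = offline_only(burst_rate_per_min=0.0, offline_s=600.0)
        labels = {i: "remaining" for i in range(100)}
        matrix, _, _, _ = simulate_offline_session(cfg, labels, seed=3)
        total = int((matrix.values > 0).sum())
        mean = 100 * 600.0 * cfg.background_rate
        sd = np.sqrt(mean)
        assert abs(total - mean) <= 3 * sd

    def test_no_bursts_means_counts_in_null_range(self):
        cfg = offline_only(burst_rate_per_min=0.0)
        exp, truth = simulate_experiment(cfg, seed=4)
        matrix = exp.sessions["offline2"].matrix
        assert truth.bursts["offline2"]["windows"].shape[0] == 0
        null = shuffle_null(matrix, n_shuffles=50, seed=0)
        lo, hi = np.percentile(null["null_counts"], [1, 99])
        assert null["observed_count"] <= hi

    def test_full_participation_probability_puts_every_cell_in_every_burst(
            self):
        cfg = offline_only()
        cfg.coincidence = {"neutral": 0.3, "aversive": 1.0}
        cfg.base_participation = {"neutral": 0.3, "aversive": 1.0}
        cfg.cell_participation_prob = {"neutral": 0.8, "aversive": 1.0,
                                       "overlap": 0.8}
        labels = ({i: "aversive" for i in range(20)}
                  | {i: "remaining" for i in range(20, 100)})
        matrix, _, _, truth = simulate_offline_session(cfg, labels, seed=7)
        for s, e in truth["windows"]:
            assert (matrix.values[:20, s:e] > 0).any(axis=1).all()

    def test_coincidence_joint_matches_binomial_expectation(self):
        # the hub model implies P(overlap and E) = p_overlap * coincidence[E]
        cfg = offline_only(offline_s=3000.0, burst_rate_per_min=4.0)
        labels = ({i: "overlap" for i in range(15)}
                  | {i: "neutral" for i in range(15, 35)}
                  | {i: "aversive" for i in range(35, 55)}
                  | {i: "remaining" for i in range(55, 100)})
        matrix, _, _, truth = simulate_offline_session(cfg, labels, seed=11)
        flags = truth["participation"]
        n = len(flags["overlap"])
        assert n >= 180
        for other, c in cfg.coincidence.items():
            joint = cfg.p_overlap_participation * c
            count = int((flags["overlap"] & flags[other]).sum())
            sd = np.sqrt(n * joint * (1 - joint))
            assert abs(count - n * joint) <= 3 * sd

    def test_locomotion_dip_depth_reproduced(self):
        cfg = offline_only(offline_s=900.0)
        labels = {i: "remaining" for i in range(100)}
        matrix, speed, loco_ts, truth = simulate_offline_session(
            cfg, labels, seed=2
        )
        at_dip = []
        for t0 in truth["center_times_ms"]:
            sel = np.abs(loco_ts - t0) < 100
            at_dip.append(speed[sel].mean())
        expect = cfg.locomotion_baseline * (1 - cfg.dip_depth)
        assert abs(np.mean(at_dip) - expect) < 0.4

    def test_raising_cell_participation_raises_measured_fraction(self):
        from coreact.bursts import BurstCatalog, cell_participation

        labels = ({i: "aversive" for i in range(30)}
                  | {i: "remaining" for i in range(30, 100)})
        fractions = []
        for p in (0.2, 0.5, 0.8):
            cfg = offline_only()
            cfg.cell_participation_prob = {"neutral": 0.8, "aversive": p,
                                           "overlap": 0.8}
            cfg.coincidence = {"neutral": 0.3, "aversive": 0.9}
            matrix, _, _, truth = simulate_offline_session(cfg, labels,
                                                           seed=13)
            w = truth["windows"]
            cat = BurstCatalog(
                population_trace(matrix),
                np.column_stack([w[:, 0], w[:, 0], w[:, 1]]),
            )
            part = cell_participation(matrix, cat)
            fractions.append(part[:30].mean())
        assert fractions[0] < fractions[1] < fractions[2]


class TestEEGEMG:
    def test_rem_theta_delta_ratio_above_nrem_in_99_percent_of_epochs(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        hyp = simulate_hypnogram(cfg, 7200.0, rng)
        record = simulate_eeg_emg(hyp, cfg, rng)
        epoch_len = int(6.0 * 100)
        theta = band_power_per_epoch(record.eeg, 100.0, epoch_len, THETA_BAND)
        delta = band_power_per_epoch(record.eeg, 100.0, epoch_len, DELTA_BAND)
        ratio = theta / delta
        rem = ratio[hyp.states == "REM"]
        nrem = ratio[hyp.states == "NREM"]
        assert (rem[:, None] > nrem[None, :]).mean() >= 0.99

    def test_all_wake_hypnogram_still_yields_valid_record(self):
        from coreact.sleep import Hypnogram, score_sleep

        cfg = SimulationConfig()
        hyp = Hypnogram(np.array(["wake"] * 100, dtype=object))
        record = simulate_eeg_emg(hyp, cfg, seed=1)
        assert record.n_samples == 100 * 600
        scored = score_sleep(record, 6.0)  # degenerate, handled by fallback
        assert scored.n_epochs == 100


class TestChemotag:
    def test_equal_response_rates_make_selection_chance_level(self):
        # with no CNO response every cell follows the same background
        # transient process, so the top-10% selection is unrelated to the
        # planted inhibitory identity
        cfg = SimulationConfig()
        cfg.inh_peak_rate_per_min = 0.0
        cfg.exc_peak_rate_per_min = 0.5
        labels = {i: ("overlap" if i < 20 else "remaining")
                  for i in range(150)}
        traces, inhibitory, _ = simulate_chemotag_session(cfg, labels, seed=3)
        ranking = rank_chemotag(traces)
        planted = {c for c, f in inhibitory.items() if f}
        flagged = set(ranking.flagged_ids())
        n = traces.n_cells
        k = len(flagged)
        overlap = len(planted & flagged)
        mean = k * len(planted) / n
        sd = np.sqrt(k * len(planted) / n * (1 - len(planted) / n))
        assert abs(overlap - mean) <= 3 * sd + 1

    def test_unmatched_offline_cell_absent_from_chemotag_session(
            self, small_experiment):
        exp, truth = small_experiment
        mt = exp.match_table("chemotag", "offline2")
        matched_offline = mt.matched_ids("offline2")
        all_offline = set(
            exp.sessions["offline2"].matrix.cell_ids.tolist())
        assert matched_offline < all_offline  # some cells have no match


class TestGeneratedInvariants:
    def test_every_burst_lies_within_its_session(self, small_experiment):
        _, truth = small_experiment
        for sess, b in truth.bursts.items():
            n_frames = int(round(truth.config.offline_s
                                 * truth.config.effective_frame_rate))
            for s, e in b["windows"]:
                assert 0 <= s < e <= n_frames

    def test_recall_truth_labels_cover_session_cells(self, small_experiment):
        exp, truth = small_experiment
        for sess in ("recall_neutral", "recall_novel", "recall_aversive"):
            cells = set(exp.sessions[sess].matrix.cell_ids.tolist())
            assert set(truth.ensembles[sess]) == cells

    def test_match_tables_reference_existing_cells(self, small_experiment):
        exp, _ = small_experiment
        for mt in exp.match_tables:
            ids_a = set(exp.sessions[mt.session_a].matrix.cell_ids.tolist())
            ids_b = set(exp.sessions[mt.session_b].matrix.cell_ids.tolist())
            assert {a for a, _ in mt.pairs} <= ids_a
            assert {b for _, b in mt.pairs} <= ids_b
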