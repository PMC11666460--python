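"""Cohort-level simulation studies.

Each function simulates a cohort of animals under configured study arms and
runs the corresponding analysis stage per animal, returning tidy per-animal
statistics. These are the building blocks behind the numbered analysis
scripts and the acceptance checks; problem sizes default to scaled-down
sessions (shorter than the in-vivo recordings) so a full cohort runs in
seconds to minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from coreact import bursts as bursts_mod
from coreact import coactivity as coact_mod
from coreact import decoding as decoding_mod
from coreact import reactivation as react_mod
from coreact import sleep as sleep_mod
from coreact.core import assign_ensembles
from coreact.simulate import SimulationConfig, simulate_experiment


def _mouse_seed(seed: int, i: int) -> int:
    return (int(seed) * 100003 + 7919 * i) % (2**31)


def small_cobursting_config(arm: str = "high_shock") -> SimulationConfig:
    """Scaled per-animal config for burst/co-bursting cohorts."""
    base = (SimulationConfig.high_shock() if arm == "high_shock"
            else SimulationConfig.low_shock())
    return dataclasses.replace(
        base,
        n_cells=100,
        ensemble_sizes={"neutral": 20, "aversive": 20, "overlap": 15,
                        "remaining": 45},
        n_shared_encoding=20,
        n_extra_encoding=5,
        neutral_encoding_s=60.0,
        aversive_encoding_s=60.0,
        offline_s=300.0,
        burst_rate_per_min=4.0,
        sessions=("neutral_encoding", "aversive_encoding", "offline2"),
    )


def cobursting_mouse(
    config: SimulationConfig, seed: int, burst_z: float = 2.0
) -> dict:
    """One animal: detect bursts offline and measure co-participation."""
    exp, truth = simulate_experiment(config, seed=seed)
    rec = exp.sessions["offline2"]
    assignment = assign_ensembles(
        "offline2", rec.matrix.cell_ids.tolist(),
        exp.match_table("offline2", "neutral_encoding"),
        exp.match_table("offline2", "aversive_encoding"),
    )
    trace = bursts_mod.population_trace(rec.matrix)
    catalog = bursts_mod.detect_bursts(trace, burst_z)
    traces = coact_mod.ensemble_mean_traces(rec.matrix, assignment)
    part = coact_mod.ensemble_event_participation(traces, catalog, burst_z)
    summ = coact_mod.coparticipation_fractions(part)
    nonburst = coact_mod.nonburst_coparticipation(traces, catalog, burst_z)
    out = {
        "n_events": catalog.n_events,
        "n_planted": int(truth.bursts["offline2"]["windows"].shape[0]),
        "overlap_neutral": summ.pairwise.get(("neutral", "overlap"), np.nan),
        "overlap_aversive": summ.pairwise.get(("aversive", "overlap"), np.nan),
        "nonburst_overlap_neutral": nonburst.pairwise.get(
            ("neutral", "overlap"), np.nan),
        "nonburst_overlap_aversive": nonburst.pairwise.get(
            ("aversive", "overlap"), np.nan),
    }
    cellpart = bursts_mod.cell_participation(rec.matrix, catalog)
    psumm = bursts_mod.ensemble_participation(
        cellpart, rec.matrix.cell_ids, assignment
    )
    for name, v in psumm.ensemble_fractions.items():
        out[f"participation_{name}"] = v
    return out


def cobursting_cohort(
    n_mice: int = 100, seed: int = 0, arms: tuple = ("high_shock", "low_shock")
) -> pd.DataFrame:
    """Simulate both study arms and measure per-animal co-bursting."""
    rows = []
    for arm in arms:
        config = small_cobursting_config(arm)
        for i in range(n_mice):
            row = cobursting_mouse(config, _mouse_seed(seed, i))
            row.update({"arm": arm, "mouse": i})
            rows.append(row)
    return pd.DataFrame(rows)


def reactivation_config(arm: str = "high_shock") -> SimulationConfig:
    base = (SimulationConfig.high_shock() if arm == "high_shock"
            else SimulationConfig.low_shock())
    return dataclasses.replace(
        base,
        neutral_encoding_s=60.0,
        aversive_encoding_s=60.0,
        recall_s=60.0,
        sessions=("neutral_encoding", "aversive_encoding",
                  "recall_neutral", "recall_novel"),
    )


def reactivation_cohort(
    n_mice: int = 100, seed: int = 0, arms: tuple = ("high_shock", "low_shock")
) -> pd.DataFrame:
    """Per-animal recall reactivation fractions and reactivation index."""
    rows = []
    for arm in arms:
        config = reactivation_config(arm)
        for i in range(n_mice):
            exp, truth = simulate_experiment(config, seed=_mouse_seed(seed, i))
            frac = {}
            for sess in ("recall_neutral", "recall_novel"):
                frac[sess] = react_mod.recall_reactivation_fractions(
                    exp.sessions[sess].matrix, sess,
                    exp.match_table(sess, "neutral_encoding"),
                    exp.match_table(sess, "aversive_encoding"),
                )
            ri = react_mod.reactivation_index(
                frac["recall_neutral"], frac["recall_novel"]
            )
            rows.append({
                "arm": arm, "mouse": i,
                **{f"index_{k}": v for k, v in ri.index.items()},
                **{f"neutral_recall_{k}": v
                   for k, v in ri.neutral_recall.items()},
            })
    return pd.DataFrame(rows)


def state_config() -> SimulationConfig:
    """EEG-paired config planting co-bursting asymmetry only during wake."""
    cfg = small_cobursting_config("high_shock")
    return dataclasses.replace(
        cfg,
        eeg_paired=True,
        offline_s=1200.0,
        burst_rate_per_min=6.0,
        coincidence_by_state={
            "wake": {"neutral": 0.8, "aversive": 0.2},
            "NREM": {"neutral": 0.4, "aversive": 0.4},
            "REM": {"neutral": 0.4, "aversive": 0.4},
        },
        coincidence={"neutral": 0.4, "aversive": 0.4},  # unknown-state bursts
    )


def state_mouse(config: SimulationConfig, seed: int) -> dict:
    """One EEG-paired animal: per-state co-participation differences.

    Uses the generator's ground-truth hypnogram for frame states so that the
    statistic isolates the state-resolved co-bursting machinery (the sleep
    scorer is validated separately).
    """
    exp, truth = simulate_experiment(config, seed=seed)
    rec = exp.sessions["offline2"]
    assignment = truth.assignment("offline2")
    trace = bursts_mod.population_trace(rec.matrix)
    catalog = bursts_mod.detect_bursts(trace)
    traces = coact_mod.ensemble_mean_traces(rec.matrix, assignment)
    states = sleep_mod.assign_states_to_frames(
        truth.hypnograms["offline2"], rec.matrix.timestamps
    )
    by_state = sleep_mod.coparticipation_by_state(traces, catalog, states)
    out = {}
    for state in ("wake", "NREM", "REM"):
        summ = by_state[state]
        if summ.empty:
            out[f"{state}_diff"] = np.nan
            out[f"{state}_n"] = 0
        else:
            out[f"{state}_diff"] = (
                summ.pairwise.get(("neutral", "overlap"), np.nan)
                - summ.pairwise.get(("aversive", "overlap"), np.nan)
            )
            out[f"{state}_n"] = summ.n_events
    return out


def state_cohort(n_mice: int = 100, seed: int = 0) -> pd.DataFrame:
    config = state_config()
    rows = []
    for i in range(n_mice):
        row = state_mouse(config, _mouse_seed(seed, i))
        row["mouse"] = i
        rows.append(row)
    return pd.DataFrame(rows)


def decoding_config(separable: bool = True) -> SimulationConfig:
    cfg = SimulationConfig.high_shock()
    cfg = dataclasses.replace(
        cfg,
        neutral_encoding_s=200.0,
        aversive_encoding_s=200.0,
        sessions=("neutral_encoding", "aversive_encoding"),
    )
    if not separable:
        # label-independent activity: every cell keeps one rate in both
        # contexts, so frames carry no context information
        cfg.encoding_rate_preferred = cfg.encoding_rate_base
        cfg.encoding_rate_nonpreferred = cfg.encoding_rate_base
    return cfg


def decoding_study(
    seed: int = 0, separable: bool = True, repeats: int = 50
) -> dict:
    """SVM decoding plus shuffled control on one simulated animal."""
    config = decoding_config(separable)
    exp, _ = simulate_experiment(config, seed=seed)
    dataset = decoding_mod.build_context_dataset(
        exp.sessions["neutral_encoding"].matrix,
        exp.sessions["aversive_encoding"].matrix,
        exp.match_table("neutral_encoding", "aversive_encoding"),
        "neutral_encoding", "aversive_encoding",
    )
    real = decoding_mod.svm_decode(dataset, repeats=repeats, seed=seed)
    shuf = decoding_mod.shuffled_control(dataset, repeats=repeats,
                                         seed=seed + 1)
    return {
        "mean_accuracy": real.mean_accuracy,
        "accuracy_sd": float(real.accuracies.std()),
        "shuffled_accuracy": shuf.mean_accuracy,
        "shuffled_sd": float(shuf.accuracies.std()),
        "n_cells": dataset.n_cells,
        "n_frames": int(dataset.X.shape[0]),
    }


def sleep_recovery_study(
    seed: int = 0, duration_s: float = 7200.0, noiseless: bool = False
) -> dict:
    """Score synthetic EEG/EMG and compare against the generating hypnogram."""
    from coreact.simulate import simulate_eeg_emg, simulate_hypnogram

    config = SimulationConfig()
    if noiseless:
        config.eeg_noise_sd = 0.0
        config.emg_noise_sd = 0.0
    rng = np.random.default_rng(seed)
    hyp = simulate_hypnogram(config, duration_s, rng)
    record = simulate_eeg_emg(hyp, config, rng)
    scored = sleep_mod.score_sleep(record, config.epoch_s, seed=seed)
    agree = float(np.mean(scored.states == hyp.states))
    return {
        "accuracy": agree,
        "n_epochs": hyp.n_epochs,
        "true_counts": {s: int(np.sum(hyp.states == s))
                        for s in ("wake", "NREM", "REM")},
        "scored_counts": {s: int(np.sum(scored.states == s))
                          for s in ("wake", "NREM", "REM")},
    }


def null_calibration_study(
    n_sims: int = 100,
    seed: int = 0,
    n_cells: int = 50,
    n_frames: int = 6000,
    rate: float = 0.1,
    n_shuffles: int = 100,
) -> pd.DataFrame:
    """Coverage of the circular-shift null on temporally independent activity.

    Each simulation draws an independent Bernoulli/log-normal event matrix
    (no planted synchrony), runs the shuffle null, and records whether the
    observed burst count lies within the central 95% of its null counts.
    """
    from coreact.core import EventMatrix

    rows = []
    frame_rate = 30.0
    for i in range(n_sims):
        rng = np.random.default_rng(_mouse_seed(seed, i))
        p = rate / frame_rate
        hits = rng.random((n_cells, n_frames)) < p
        values = np.zeros(hits.shape)
        idx = np.nonzero(hits)
        values[idx] = rng.lognormal(0.0, 0.5, idx[0].size)
        ts = np.arange(n_frames) * (1000.0 / frame_rate)
        matrix = EventMatrix(values, frame_rate, ts, np.arange(n_cells))
        null = bursts_mod.shuffle_null(
            matrix, n_shuffles, seed=_mouse_seed(seed + 1, i)
        )
        lo, hi = np.percentile(null["null_counts"], [2.5, 97.5])
        rows.append({
            "sim": i,
            "observed": null["observed_count"],
            "null_lo": lo,
            "null_hi": hi,
            "covered": bool(lo <= null["observed_count"] <= hi),
        })
    return pd.DataFrame(rows)


def chemotag_recovery_study(seed: int = 0) -> dict:
    """Recovery of planted inhibitory identity by the top-10% rule."""
    from coreact import chemotag as chemotag_mod

    config = dataclasses.replace(
        SimulationConfig.high_shock(),
        neutral_encoding_s=60.0, aversive_encoding_s=60.0, offline_s=60.0,
        burst_rate_per_min=0.0,
        sessions=("neutral_encoding", "aversive_encoding", "offline2",
                  "chemotag"),
    )
    exp, truth = simulate_experiment(config, seed=seed)
    ranking = chemotag_mod.rank_chemotag(exp.sessions["chemotag"].matrix)
    planted = {c for c, f in truth.inhibitory.items() if f}
    flagged = set(ranking.flagged_ids())
    recovered = len(planted & flagged) / max(1, len(planted))
    propagated = chemotag_mod.propagate_labels(
        ranking, exp.match_table("chemotag", "offline2"),
        "chemotag", "offline2",
        exp.sessions["offline2"].matrix.cell_ids.tolist(),
    )
    comp = chemotag_mod.ensemble_composition(
        truth.assignment("offline2"), propagated.flags
    )
    return {
        "recovered_fraction": recovered,
        "n_inhibitory": len(planted),
        "overlap_flag_fraction": comp.get("overlap", {}).get(
            "fraction", np.nan),
        "remaining_flag_fraction": comp.get("remaining", {}).get(
            "fraction", np.nan),
    }
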