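"""Sleep scoring from EEG/EMG and sleep-state-resolved burst statistics.

Scoring follows a two-stage Gaussian-mixture scheme on 6 s epochs: EMG power
separates wake from sleep (lower-power component = sleep), then the
theta (5-9 Hz) / delta (0.5-4 Hz) band-power ratio of the EEG separates REM
(high ratio) from NREM (low ratio) within the sleep epochs. Both mixtures
operate on log power, so the labels are invariant to a global gain applied
jointly to the recorded channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from sklearn.mixture import GaussianMixture

from coreact.bursts import BurstCatalog
from coreact.coactivity import (
    CoParticipationSummary,
    coparticipation_fractions,
    ensemble_event_participation,
)

logger = logging.getLogger(__name__)

SLEEP_STATES = ("wake", "NREM", "REM", "unknown")

THETA_BAND = (5.0, 9.0)
DELTA_BAND = (0.5, 4.0)


@dataclass
class EEGEMGRecord:
    """Synchronously sampled EEG and EMG at a fixed 100 Hz rate."""

    eeg: np.ndarray
    emg: np.ndarray
    start_ms: float = 0.0
    rate: float = 100.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise ValueError("eeg and emg must have equal length")

    @property
    def n_samples(self) -> int:
        return self.eeg.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass
class Hypnogram:
    """Per-epoch sleep state aligned to wall-clock time."""

    states: np.ndarray  # str array over SLEEP_STATES
    epoch_s: float = 6.0
    start_ms: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        bad = set(self.states.tolist()) - set(SLEEP_STATES)
        if bad:
            raise ValueError(f"unknown sleep states: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.states.size

    @property
    def epoch_starts_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(self.n_epochs) * self.epoch_s * 1000.0


def band_power_per_epoch(
    trace: np.ndarray, rate: float, epoch_len: int, band: tuple | None = None
) -> np.ndarray:
    """Mean squared amplitude per epoch, optionally band-pass filtered first.

    A 4th-order Butterworth band-pass (zero-phase) isolates the band; NaN
    samples propagate so that epochs with missing data can be flagged.
    """
    x = np.asarray(trace, dtype=float)
    n_epochs = x.size // epoch_len
    x = x[: n_epochs * epoch_len].reshape(n_epochs, epoch_len)
    finite = np.isfinite(x)
    if band is not None:
        # filter each epoch independently so that power from one sleep state
        # cannot leak into an adjacent epoch of a different state
        sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
        y = signal.sosfiltfilt(sos, np.where(finite, x, 0.0), axis=1)
    else:
        y = x
    nan_frac = np.mean(~finite, axis=1)
    sq = np.square(np.where(finite, y, np.nan))
    import warnings

    with warnings.catch_warnings():
        # fully-missing epochs yield all-NaN rows; they are flagged below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        power = np.nanmean(sq, axis=1)
    power[nan_frac > 0.5] = np.nan  # mostly-missing epochs are unscorable
    return power


def _two_state_gmm(
    log_values: np.ndarray, seed: int = 0, min_separation: float = 0.2
) -> tuple[Optional[np.ndarray], float]:
    """Fit a 2-component GMM; returns (is_upper_component, separation).

    Deterministic initialization at the data extremes, so a minority state
    (e.g. REM occupying a small share of sleep) still seeds its own
    component no matter how rare it is. Returns ``(None, sep)`` when the fit
    is degenerate (components closer than ``min_separation`` log10 units).
    """
    x = log_values.reshape(-1, 1)
    q_lo, q_hi = float(log_values.min()), float(log_values.max())
    gmm = GaussianMixture(
        n_components=2,
        random_state=seed,
        means_init=np.array([[q_lo], [q_hi]]),
        n_init=1,
    )
    gmm.fit(x)
    means = gmm.means_.ravel()
    separation = float(abs(means[1] - means[0]))
    if separation < min_separation:
        return None, separation
    upper = int(np.argmax(means))
    labels = gmm.predict(x)
    return labels == upper, separation


def score_sleep(
    record: EEGEMGRecord,
    epoch_s: float = 6.0,
    seed: int = 0,
    min_separation: float = 0.2,
) -> Hypnogram:
    """Score a continuous EEG/EMG record into wake / NREM / REM epochs.

    EMG log power per epoch -> 2-component mixture, lower component = sleep.
    Within sleep epochs, log theta/delta ratio -> 2-component mixture, higher
    component = REM. Epochs with mostly missing samples are ``unknown``.
    Degenerate mixtures (separation below ``min_separation`` log10 units) fall
    back to all-wake (EMG stage) or all-NREM (ratio stage) with a prominent
    warning.
    """
    epoch_len = int(round(epoch_s * record.rate))
    n_epochs = record.n_samples // epoch_len
    if n_epochs < 10:
        raise ValueError("need at least 10 full epochs to score sleep")
    emg_power = band_power_per_epoch(record.emg, record.rate, epoch_len)
    theta = band_power_per_epoch(record.eeg, record.rate, epoch_len, THETA_BAND)
    delta = band_power_per_epoch(record.eeg, record.rate, epoch_len, DELTA_BAND)

    states = np.full(n_epochs, "unknown", dtype=object)
    valid = np.isfinite(emg_power) & np.isfinite(theta) & np.isfinite(delta)
    meta = {"epoch_s": epoch_s, "min_separation": min_separation}
    if not valid.any():
        logger.warning("no scorable epochs; hypnogram is all unknown")
        return Hypnogram(states, epoch_s, record.start_ms, meta)

    log_emg = np.log10(emg_power[valid] + 1e-300)
    is_wake, emg_sep = _two_state_gmm(log_emg, seed, min_separation)
    meta["emg_separation"] = emg_sep
    if is_wake is None:
        logger.warning(
            "EMG mixture degenerate (separation %.3f); falling back to "
            "all-wake", emg_sep,
        )
        states[valid] = "wake"
        return Hypnogram(states, epoch_s, record.start_ms, meta)

    valid_idx = np.nonzero(valid)[0]
    states[valid_idx[is_wake]] = "wake"
    sleep_idx = valid_idx[~is_wake]
    if sleep_idx.size == 0:
        return Hypnogram(states, epoch_s, record.start_ms, meta)

    ratio = theta[sleep_idx] / np.maximum(delta[sleep_idx], 1e-300)
    log_ratio = np.log10(ratio + 1e-300)
    if sleep_idx.size < 2:
        states[sleep_idx] = "NREM"
        return Hypnogram(states, epoch_s, record.start_ms, meta)
    is_rem, ratio_sep = _two_state_gmm(log_ratio, seed, min_separation)
    meta["ratio_separation"] = ratio_sep
    if is_rem is None:
        logger.warning(
            "theta/delta mixture degenerate (separation %.3f); scoring all "
            "sleep as NREM", ratio_sep,
        )
        states[sleep_idx] = "NREM"
        return Hypnogram(states, epoch_s, record.start_ms, meta)
    states[sleep_idx[is_rem]] = "REM"
    states[sleep_idx[~is_rem]] = "NREM"
    return Hypnogram(states, epoch_s, record.start_ms, meta)


def assign_states_to_frames(
    hypnogram: Hypnogram, frame_timestamps: np.ndarray
) -> np.ndarray:
    """Sleep state of each calcium frame.

    A frame inside epoch ``[start, start + epoch)`` takes that epoch's state;
    frames before the first or at/after the end of the last epoch are
    ``unknown`` and are excluded from state-specific statistics downstream.
    """
    ts = np.asarray(frame_timestamps, dtype=float)
    starts = hypnogram.epoch_starts_ms
    epoch_ms = hypnogram.epoch_s * 1000.0
    idx = np.searchsorted(starts, ts, side="right") - 1
    out = np.full(ts.size, "unknown", dtype=object)
    ok = (idx >= 0) & (ts < starts[0] + hypnogram.n_epochs * epoch_ms)
    # frames falling in a gap past their epoch's end cannot occur with
    # contiguous epochs, so containment in [start_k, start_k + epoch) holds
    out[ok] = hypnogram.states[idx[ok]]
    return out


def sleep_features(hypnogram: Hypnogram) -> dict:
    """Summary statistics: per-state time, total sleep, bouts, transitions.

    A bout is a maximal run of one state; ``unknown`` epochs break bouts and
    the transition counts exclude any pair involving ``unknown``.
    """
    states = hypnogram.states
    epoch_s = hypnogram.epoch_s
    time_in_state = {
        s: float(np.sum(states == s) * epoch_s)
        for s in ("wake", "NREM", "REM", "unknown")
    }
    bouts: dict = {s: [] for s in ("wake", "NREM", "REM")}
    i = 0
    while i < states.size:
        s = states[i]
        j = i
        while j < states.size and states[j] == s:
            j += 1
        if s != "unknown":
            bouts[s].append((j - i) * epoch_s)
        i = j
    transitions: dict = {}
    for a, b in zip(states[:-1], states[1:]):
        if a == "unknown" or b == "unknown" or a == b:
            continue
        transitions[(a, b)] = transitions.get((a, b), 0) + 1
    return {
        "time_in_state_s": time_in_state,
        "total_sleep_s": time_in_state["NREM"] + time_in_state["REM"],
        "bout_lengths_s": bouts,
        "mean_bout_s": {
            s: (float(np.mean(v)) if v else np.nan) for s, v in bouts.items()
        },
        "transitions": transitions,
    }


def coparticipation_by_state(
    ensemble_traces: dict,
    catalog: BurstCatalog,
    frame_states: np.ndarray,
    threshold_z: float = 2.0,
) -> dict:
    """Ensemble co-participation computed separately per sleep state.

    Each burst event is assigned the state of its peak frame; fractions are
    then computed within each state's events. States with zero events are
    reported as empty summaries; events in ``unknown`` state are counted but
    excluded from the per-state statistics.
    """
    frame_states = np.asarray(frame_states, dtype=object)
    if frame_states.size != catalog.population_trace.size:
        raise ValueError("frame states and catalog frame count differ")
    participation = ensemble_event_participation(
        ensemble_traces, catalog, threshold_z
    )
    event_states = np.asarray(
        [frame_states[p] for _, p, _ in catalog.events], dtype=object
    )
    out = {"event_states": event_states}
    for state in ("wake", "NREM", "REM", "unknown"):
        sel = event_states == state
        if state == "unknown":
            out["n_unknown_events"] = int(sel.sum())
            continue
        if not sel.any():
            out[state] = CoParticipationSummary(empty=True)
            continue
        sub = {k: v[sel] for k, v in participation.items()}
        out[state] = coparticipation_fractions(sub)
    return out
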