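"""Synthetic multi-session calcium experiments with planted ground truth.

The generator emulates the retrospective memory-linking paradigm: neutral
encoding, aversive encoding two days later, offline home-cage recordings
after each encoding, recall sessions in the aversive / neutral / novel
contexts, and a CNO chemotag session. Deconvolved event matrices are sparse
Bernoulli-per-frame event trains with log-normal amplitudes; offline sessions
carry brief synchronous population bursts in which planted ensembles
participate with configured probabilities, locomotion dips around each burst,
and (optionally) a hypnogram with state-dependent EEG/EMG and state-dependent
co-bursting. Every quantity the analyses estimate is recorded as ground
truth.

Ensemble co-participation uses a hub model: the overlap ensemble (cells
active in both encodings, the most burst-active population) participates in
each burst with its own probability; the neutral and aversive ensembles then
participate with probability ``coincidence[label]`` when the overlap ensemble
participates and ``base_participation[label]`` otherwise, so
P(overlap and E co-burst) = p_overlap * coincidence[E].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from coreact.core import (
    EnsembleAssignment,
    EventMatrix,
    ExperimentSet,
    MatchTable,
    SessionRecord,
)
from coreact.sleep import EEGEMGRecord, Hypnogram, assign_states_to_frames

ALL_SESSIONS = (
    "neutral_encoding",
    "aversive_encoding",
    "offline1",
    "offline2",
    "recall_aversive",
    "recall_neutral",
    "recall_novel",
    "chemotag",
)

_SESSION_KIND = {
    "neutral_encoding": "neutral_encoding",
    "aversive_encoding": "aversive_encoding",
    "offline1": "offline",
    "offline2": "offline",
    "recall_aversive": "recall_aversive",
    "recall_neutral": "recall_neutral",
    "recall_novel": "recall_novel",
    "chemotag": "chemotag",
}

_MATCH_PAIRS = (
    ("offline1", "neutral_encoding"),
    ("offline2", "neutral_encoding"),
    ("offline2", "aversive_encoding"),
    ("neutral_encoding", "aversive_encoding"),
    ("recall_neutral", "neutral_encoding"),
    ("recall_neutral", "aversive_encoding"),
    ("recall_novel", "neutral_encoding"),
    ("recall_novel", "aversive_encoding"),
    ("recall_aversive", "neutral_encoding"),
    ("recall_aversive", "aversive_encoding"),
    ("chemotag", "offline2"),
    ("chemotag", "neutral_encoding"),
    ("chemotag", "aversive_encoding"),
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated animal.

    Durations are in seconds and rates in events/s unless noted. Offline
    durations and cell counts are scaled-down problem sizes relative to the
    hour-long recordings the paradigm uses in vivo; all are configurable.
    """

    # population structure
    n_cells: int = 150
    ensemble_sizes: dict = field(default_factory=lambda: {
        "neutral": 25, "aversive": 30, "overlap": 20, "remaining": 75,
    })
    n_shared_encoding: int = 100   # cells active in both encodings (>= overlap)
    n_extra_encoding: int = 20     # per-encoding cells never seen again
    n_recall_cells: int = 120
    chemotag_extra_cells: int = 15

    # session durations / rates
    frame_rate: float = 30.0       # 15 when eeg_paired
    neutral_encoding_s: float = 600.0
    aversive_encoding_s: float = 300.0
    offline_s: float = 600.0
    recall_s: float = 300.0
    chemotag_rate: float = 5.0
    chemotag_s: float = 2700.0     # 45 min

    # background event statistics
    background_rate: float = 0.1   # events/s per cell, offline
    amplitude_sigma: float = 0.5   # log-normal sigma, mean log 0

    # population bursts
    burst_rate_per_min: float = 3.0
    burst_duration_s: float = 0.5
    burst_margin_s: float = 6.0    # keep-out zone at session edges
    burst_separation_s: float = 2.0
    p_overlap_participation: float = 0.9
    coincidence: dict = field(default_factory=lambda: {
        "neutral": 0.8, "aversive": 0.2,
    })
    base_participation: dict = field(default_factory=lambda: {
        "neutral": 0.3, "aversive": 0.3,
    })
    coincidence_by_state: Optional[dict] = None  # state -> coincidence dict
    cell_participation_prob: dict = field(default_factory=lambda: {
        "neutral": 0.8, "aversive": 0.8, "overlap": 0.8,
    })
    burst_frame_prob: float = 0.5  # per-frame event prob of an engaged cell
    remaining_burst_prob: float = 0.1
    offline1_neutral_participation: float = 0.8

    # locomotion coupling
    locomotion_rate: float = 10.0  # Hz
    locomotion_baseline: float = 4.0  # cm/s
    locomotion_noise_sd: float = 0.5
    dip_depth: float = 0.7         # fractional slowdown at the dip minimum
    dip_width_s: float = 0.75
    dip_center_s: float = 0.0      # relative to burst-window centre

    # encoding context patterns
    encoding_rate_preferred: float = 2.0
    encoding_rate_nonpreferred: float = 0.01
    encoding_rate_base: float = 0.5

    # recall composition and rates
    recall_react_probs: dict = field(default_factory=lambda: {
        "recall_neutral": {"neutral": 0.6, "aversive": 0.3, "overlap": 0.7},
        "recall_novel": {"neutral": 0.25, "aversive": 0.3, "overlap": 0.3},
        "recall_aversive": {"neutral": 0.3, "aversive": 0.6, "overlap": 0.6},
    })
    recall_min_rate: float = 0.2
    recall_base_rate: float = 0.5

    # sleep / EEG-EMG
    eeg_paired: bool = False
    epoch_s: float = 6.0
    eeg_rate: float = 100.0
    state_mean_duration_s: dict = field(default_factory=lambda: {
        "wake": 120.0, "NREM": 180.0, "REM": 60.0,
    })
    state_switch_probs: dict = field(default_factory=lambda: {
        "wake": {"NREM": 1.0},
        "NREM": {"wake": 0.4, "REM": 0.6},
        "REM": {"wake": 0.7, "NREM": 0.3},
    })
    eeg_band_amplitudes: dict = field(default_factory=lambda: {
        "wake": {"delta": 10.0, "theta": 15.0},
        "NREM": {"delta": 40.0, "theta": 10.0},
        "REM": {"delta": 8.0, "theta": 30.0},
    })
    # muscle tone is low in both sleep states, matching the two-state
    # assumption of the EMG mixture
    emg_amplitude: dict = field(default_factory=lambda: {
        "wake": 1.0, "NREM": 0.1, "REM": 0.1,
    })
    eeg_noise_sd: float = 5.0
    emg_noise_sd: float = 0.05

    # chemotagging
    inhibitory_fraction: float = 0.10
    inhibitory_overlap_weight: float = 4.0
    inh_peak_rate_per_min: float = 1.5
    exc_peak_rate_per_min: float = 0.1
    cno_window_min: tuple = (10.0, 40.0)
    chemotag_match_frac: float = 0.9
    chemotag_trace_noise: float = 0.03
    transient_decay_s: float = 2.0

    # bookkeeping
    mismatch_rate: float = 0.0
    sessions: tuple = ALL_SESSIONS
    group_label: str = "high_shock"
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if sum(self.ensemble_sizes.values()) > self.n_cells:
            raise ValueError("ensemble sizes exceed n_cells")
        if sum(self.ensemble_sizes.values()) != self.n_cells:
            raise ValueError(
                "ensemble sizes (incl. remaining) must sum to n_cells"
            )
        if self.n_shared_encoding < self.ensemble_sizes["overlap"]:
            raise ValueError("n_shared_encoding must cover the overlap cells")
        probs = (
            [self.p_overlap_participation, self.remaining_burst_prob,
             self.offline1_neutral_participation, self.burst_frame_prob,
             self.inhibitory_fraction, self.chemotag_match_frac,
             self.mismatch_rate]
            + list(self.coincidence.values())
            + list(self.base_participation.values())
            + list(self.cell_participation_prob.values())
            + [p for d in self.recall_react_probs.values() for p in d.values()]
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        unknown = set(self.sessions) - set(ALL_SESSIONS)
        if unknown:
            raise ValueError(f"unknown sessions requested: {sorted(unknown)}")

    @property
    def effective_frame_rate(self) -> float:
        return 15.0 if self.eeg_paired else self.frame_rate

    # convenience study arms -------------------------------------------------
    @classmethod
    def high_shock(cls, **kw) -> "SimulationConfig":
        """Strong-shock arm: overlap co-bursts preferentially with neutral and
        the overlap ensemble is preferentially reactivated in neutral recall."""
        return cls(group_label="high_shock", **kw)

    @classmethod
    def low_shock(cls, **kw) -> "SimulationConfig":
        """Weak-shock arm: symmetric co-bursting and no overlap preference."""
        cfg = cls(group_label="low_shock", **kw)
        cfg.coincidence = {"neutral": 0.4, "aversive": 0.4}
        cfg.recall_react_probs = {
            "recall_neutral": {"neutral": 0.6, "aversive": 0.3, "overlap": 0.35},
            "recall_novel": {"neutral": 0.25, "aversive": 0.3, "overlap": 0.35},
            "recall_aversive": {"neutral": 0.3, "aversive": 0.6, "overlap": 0.6},
        }
        return cfg


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the way the analyses report."""

    ensembles: dict = field(default_factory=dict)   # session -> {cell: label}
    bursts: dict = field(default_factory=dict)      # session -> burst dict
    recall_fractions: dict = field(default_factory=dict)
    hypnograms: dict = field(default_factory=dict)  # session -> Hypnogram
    inhibitory: dict = field(default_factory=dict)  # chemotag cell -> bool
    dip: dict = field(default_factory=dict)
    config: Optional[SimulationConfig] = None

    def assignment(self, session: str) -> EnsembleAssignment:
        return EnsembleAssignment(session, dict(self.ensembles[session]))


# ---------------------------------------------------------------------------
# low-level generators
# ---------------------------------------------------------------------------


def _session_rng(seed: int, name: str) -> np.random.Generator:
    idx = ALL_SESSIONS.index(name) + 1 if name in ALL_SESSIONS else 0
    return np.random.default_rng([int(seed) % (2**31), idx])


def _event_matrix(
    rates: np.ndarray,
    n_frames: int,
    frame_rate: float,
    rng: np.random.Generator,
    amplitude_sigma: float,
    cell_ids: np.ndarray,
) -> EventMatrix:
    """Sparse Bernoulli-per-frame events with log-normal amplitudes."""
    p = np.clip(np.asarray(rates, dtype=float) / frame_rate, 0, 1)
    hits = rng.random((p.size, n_frames)) < p[:, None]
    values = np.zeros(hits.shape)
    idx = np.nonzero(hits)
    values[idx] = rng.lognormal(0.0, amplitude_sigma, size=idx[0].size)
    ts = np.arange(n_frames) * (1000.0 / frame_rate)
    return EventMatrix(values, frame_rate, ts, cell_ids)


def _place_bursts(
    n_frames: int, frame_rate: float, config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Non-overlapping burst windows as an (n, 2) array of [start, end)."""
    dur = max(1, int(round(config.burst_duration_s * frame_rate)))
    margin = int(round(config.burst_margin_s * frame_rate))
    sep = int(round(config.burst_separation_s * frame_rate))
    n_target = rng.poisson(
        config.burst_rate_per_min * n_frames / frame_rate / 60.0
    )
    starts: list[int] = []
    lo, hi = margin, n_frames - margin - dur
    if hi <= lo:
        return np.zeros((0, 2), dtype=int)
    attempts = 0
    while len(starts) < n_target and attempts < 100 * max(n_target, 1):
        s = int(rng.integers(lo, hi))
        if all(abs(s - t) >= dur + sep for t in starts):
            starts.append(s)
        attempts += 1
    starts.sort()
    return np.asarray([(s, s + dur) for s in starts], dtype=int)


def _burst_participation(
    n_bursts: int,
    model: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    burst_states: Optional[np.ndarray] = None,
) -> dict:
    """Per-burst ensemble participation flags under the hub model."""
    if model == "offline1":
        return {
            "neutral": rng.random(n_bursts)
            < config.offline1_neutral_participation,
        }
    overlap = rng.random(n_bursts) < config.p_overlap_participation
    neutral = np.zeros(n_bursts, dtype=bool)
    aversive = np.zeros(n_bursts, dtype=bool)
    for i in range(n_bursts):
        coin = config.coincidence
        if config.coincidence_by_state is not None and burst_states is not None:
            coin = config.coincidence_by_state.get(burst_states[i], coin)
        if overlap[i]:
            p_n, p_a = coin["neutral"], coin["aversive"]
        else:
            p_n = config.base_participation["neutral"]
            p_a = config.base_participation["aversive"]
        neutral[i] = rng.random() < p_n
        aversive[i] = rng.random() < p_a
    return {"overlap": overlap, "neutral": neutral, "aversive": aversive}


def simulate_offline_session(
    config: SimulationConfig,
    ensemble_labels: dict,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    model: str = "offline2",
    frame_states: Optional[np.ndarray] = None,
) -> tuple[EventMatrix, np.ndarray, np.ndarray, dict]:
    """One offline session: background events, planted bursts, locomotion.

    Returns ``(matrix, locomotion, locomotion_timestamps, burst_truth)``.
    ``burst_truth`` holds the planted windows, per-burst ensemble
    participation flags and the locomotion dip parameters.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.effective_frame_rate
    n_frames = int(round(config.offline_s * rate))
    cell_ids = np.arange(len(ensemble_labels))
    labels = np.asarray([ensemble_labels[c] for c in cell_ids.tolist()])

    matrix = _event_matrix(
        np.full(cell_ids.size, config.background_rate), n_frames, rate, rng,
        config.amplitude_sigma, cell_ids,
    )
    windows = _place_bursts(n_frames, rate, config, rng)
    burst_states = None
    if frame_states is not None and windows.size:
        burst_states = np.asarray(
            [frame_states[s] for s, _ in windows], dtype=object
        )
    flags = _burst_participation(
        windows.shape[0], model, config, rng, burst_states
    )
    tracked = set(flags)
    for i, (s, e) in enumerate(windows):
        w = e - s
        for row, lab in enumerate(labels):
            if lab in tracked:
                # cells of a tracked ensemble fire above background only when
                # their ensemble participates in this burst
                p_engage = (config.cell_participation_prob.get(lab, 0.8)
                            if flags[lab][i] else 0.0)
            else:
                p_engage = config.remaining_burst_prob
            if p_engage > 0 and rng.random() < p_engage:
                fire = rng.random(w) < config.burst_frame_prob
                if not fire.any():
                    fire[int(rng.integers(0, w))] = True  # engaged => >=1 event
                amps = rng.lognormal(
                    0.0, config.amplitude_sigma, int(fire.sum())
                )
                matrix.values[row, s:e][fire] += amps

    # locomotion with a dip around every burst
    n_loco = int(round(config.offline_s * config.locomotion_rate))
    loco_ts = np.arange(n_loco) * (1000.0 / config.locomotion_rate)
    speed = config.locomotion_baseline + config.locomotion_noise_sd * (
        rng.standard_normal(n_loco)
    )
    centers_ms = []
    for s, e in windows:
        center_ms = (s + e) / 2.0 * (1000.0 / rate) + config.dip_center_s * 1000
        centers_ms.append(center_ms)
        dt = (loco_ts - center_ms) / 1000.0
        speed *= 1.0 - config.dip_depth * np.exp(
            -0.5 * (dt / config.dip_width_s) ** 2
        )
    speed = np.clip(speed, 0.0, None)

    burst_truth = {
        "windows": windows,
        "participation": flags,
        "burst_states": burst_states,
        "center_times_ms": np.asarray(centers_ms),
        "dip": {
            "depth": config.dip_depth,
            "width_s": config.dip_width_s,
            "center_s": config.dip_center_s,
        },
    }
    return matrix, speed, loco_ts, burst_truth


def simulate_hypnogram(
    config: SimulationConfig, duration_s: float, rng: np.random.Generator
) -> Hypnogram:
    """Semi-Markov wake/NREM/REM sequence in fixed epochs."""
    n_epochs = int(duration_s // config.epoch_s)
    states = []
    state = "wake"
    while len(states) < n_epochs:
        mean_ep = max(1.0, config.state_mean_duration_s[state] / config.epoch_s)
        length = int(rng.geometric(1.0 / mean_ep))
        states.extend([state] * length)
        nxt = config.state_switch_probs[state]
        names = sorted(nxt)
        probs = np.asarray([nxt[k] for k in names])
        state = names[rng.choice(len(names), p=probs / probs.sum())]
    return Hypnogram(np.asarray(states[:n_epochs], dtype=object),
                     config.epoch_s, 0.0)


def simulate_eeg_emg(
    hypnogram: Hypnogram,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> EEGEMGRecord:
    """State-dependent EEG (delta + theta sinusoids) and EMG (modulated noise).

    Wake epochs carry high EMG power; NREM low EMG and high delta; REM low
    EMG and a high theta/delta ratio. Additive broadband Gaussian noise at
    the configured SDs; with both noise SDs at zero the scorer recovers the
    hypnogram exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.eeg_rate
    samples_per_epoch = int(round(hypnogram.epoch_s * rate))
    n = hypnogram.n_epochs * samples_per_epoch
    state_per_sample = np.repeat(hypnogram.states, samples_per_epoch)
    t = np.arange(n) / rate
    delta_amp = np.asarray([
        config.eeg_band_amplitudes[s]["delta"] if s != "unknown" else 0.0
        for s in state_per_sample
    ])
    theta_amp = np.asarray([
        config.eeg_band_amplitudes[s]["theta"] if s != "unknown" else 0.0
        for s in state_per_sample
    ])
    eeg = (
        delta_amp * np.sin(2 * np.pi * 2.5 * t)
        + theta_amp * np.sin(2 * np.pi * 7.0 * t)
        + config.eeg_noise_sd * rng.standard_normal(n)
    )
    emg_amp = np.asarray([
        config.emg_amplitude[s] if s != "unknown" else 0.0
        for s in state_per_sample
    ])
    emg = emg_amp * rng.standard_normal(n) + config.emg_noise_sd * (
        rng.standard_normal(n)
    )
    return EEGEMGRecord(eeg=eeg, emg=emg, start_ms=hypnogram.start_ms,
                        rate=rate)


def simulate_chemotag_session(
    config: SimulationConfig,
    offline_labels: dict,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[EventMatrix, dict, MatchTable]:
    """The 45 min CNO session as continuous traces, plus ground truth.

    A fraction of the offline-2 cells reappear (``chemotag_match_frac``);
    planted inhibitory cells (weighted toward the overlap ensemble) emit many
    high-prominence transients within the CNO window, the rest few small
    ones. Returns ``(traces, inhibitory_flags, match_table_to_offline2)``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    offline_cells = sorted(offline_labels)
    matched = [c for c in offline_cells
               if rng.random() < config.chemotag_match_frac]
    n_total = len(matched) + config.chemotag_extra_cells
    cell_ids = np.arange(n_total)
    pairs = [(int(cell_ids[i]), int(c)) for i, c in enumerate(matched)]
    match = MatchTable("chemotag", "offline2", pairs)

    # weighted inhibitory draw, enriched in overlap-matched cells
    weights = np.ones(n_total)
    for i, c in enumerate(matched):
        if offline_labels[c] == "overlap":
            weights[i] = config.inhibitory_overlap_weight
    n_inh = int(round(config.inhibitory_fraction * n_total))
    chosen = rng.choice(
        n_total, size=n_inh, replace=False, p=weights / weights.sum()
    )
    inhibitory = {int(c): False for c in cell_ids}
    for c in chosen:
        inhibitory[int(c)] = True

    rate = config.chemotag_rate
    n_frames = int(round(config.chemotag_s * rate))
    kernel_len = int(round(5 * config.transient_decay_s * rate))
    kernel = np.exp(
        -np.arange(kernel_len) / (config.transient_decay_s * rate)
    )
    lo = int(round(config.cno_window_min[0] * 60 * rate))
    hi = int(round(config.cno_window_min[1] * 60 * rate))
    values = config.chemotag_trace_noise * np.abs(
        rng.standard_normal((n_total, n_frames))
    )
    for i in range(n_total):
        spikes = np.zeros(n_frames)
        if inhibitory[int(cell_ids[i])]:
            n_peaks = rng.poisson(
                config.inh_peak_rate_per_min
                * (config.cno_window_min[1] - config.cno_window_min[0])
            )
            if n_peaks:
                at = rng.integers(lo, hi, size=n_peaks)
                spikes[at] += 1.0 + 0.1 * rng.standard_normal(n_peaks)
        # every cell has at least one transient: a transient-free trace would
        # be pure noise, which min-max normalization would stretch to [0, 1]
        n_bg = max(1, rng.poisson(
            config.exc_peak_rate_per_min * config.chemotag_s / 60.0
        ))
        if n_bg:
            at = rng.integers(0, n_frames, size=n_bg)
            spikes[at] += 0.4 + 0.1 * rng.standard_normal(n_bg)
        values[i] += np.convolve(spikes, kernel)[:n_frames]
    values = np.clip(values, 0.0, None)
    ts = np.arange(n_frames) * (1000.0 / rate)
    traces = EventMatrix(values, rate, ts, cell_ids)
    return traces, inhibitory, match


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------


def _local_ids(global_ids: list, rng: np.random.Generator) -> dict:
    """Assign per-session local ids in shuffled order: global -> local."""
    order = rng.permutation(len(global_ids))
    return {global_ids[int(j)]: int(i) for i, j in enumerate(order)}


def _match_table(
    name_a: str, gl_a: dict, name_b: str, gl_b: dict,
    mismatch_rate: float, rng: np.random.Generator,
) -> MatchTable:
    shared = sorted(set(gl_a) & set(gl_b))
    pairs = [(gl_a[g], gl_b[g]) for g in shared]
    if mismatch_rate > 0 and len(pairs) >= 2:
        corrupt = np.nonzero(rng.random(len(pairs)) < mismatch_rate)[0]
        if corrupt.size >= 2:
            b_side = [pairs[i][1] for i in corrupt]
            rolled = b_side[1:] + b_side[:1]
            for i, b in zip(corrupt, rolled):
                pairs[int(i)] = (pairs[int(i)][0], b)
    return MatchTable(name_a, name_b, pairs)


def simulate_experiment(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[ExperimentSet, GroundTruth]:
    """Generate one simulated animal's full experiment.

    Deterministic given ``(config, seed)``; per-session random streams are
    derived independently, so the same session is identical across configs
    that only drop other sessions. ``config.sessions`` selects which sessions
    (and the match tables among them) to generate.
    """
    config = config or SimulationConfig()
    config.validate()
    base_seed = config.seed if seed is None else int(seed)
    rng0 = np.random.default_rng([base_seed % (2**31), 0])
    sizes = config.ensemble_sizes

    # global registry -------------------------------------------------------
    nxt = 0

    def take(n: int) -> list:
        nonlocal nxt
        out = list(range(nxt, nxt + n))
        nxt += n
        return out

    g_overlap = take(sizes["overlap"])
    g_neutral = take(sizes["neutral"])
    g_aversive = take(sizes["aversive"])
    g_rem2 = take(sizes["remaining"])
    g_rem1 = take(config.n_cells - sizes["neutral"] - sizes["overlap"])
    g_shared_extra = take(config.n_shared_encoding - sizes["overlap"])
    g_extra_n = take(config.n_extra_encoding)
    g_extra_a = take(config.n_extra_encoding)

    shared = g_overlap + g_shared_extra
    pref_neutral = set(
        np.asarray(shared)[rng0.permutation(len(shared))[: len(shared) // 2]]
        .tolist()
    )

    def encoding_rates(globals_, context: str) -> np.ndarray:
        rates = np.full(len(globals_), config.encoding_rate_base)
        for i, g in enumerate(globals_):
            if g in set(shared):
                prefers_this = (g in pref_neutral) == (context == "neutral")
                rates[i] = (
                    config.encoding_rate_preferred if prefers_this
                    else config.encoding_rate_nonpreferred
                )
        return rates

    # recall composition (drawn up-front so ground truth is exact) ----------
    recall_members: dict = {}
    for sess in ("recall_aversive", "recall_neutral", "recall_novel"):
        probs = config.recall_react_probs[sess]
        members = []
        # g_shared_extra cells were active in both encodings, so for the
        # recall analysis they belong to the overlap ensemble just like the
        # offline-active overlap cells and share its reactivation preference
        for pool, lab in ((g_neutral, "neutral"), (g_aversive, "aversive"),
                          (g_overlap, "overlap"), (g_shared_extra, "overlap")):
            members += [g for g in pool if rng0.random() < probs[lab]]
        n_fresh = max(0, config.n_recall_cells - len(members))
        members += take(n_fresh)
        recall_members[sess] = members

    rate = config.effective_frame_rate
    sessions: dict = {}
    gl_maps: dict = {}
    truth = GroundTruth(config=dataclasses.replace(config))
    label_of = {}
    for g in g_overlap + g_shared_extra:
        label_of[g] = "overlap"
    for g in g_neutral:
        label_of[g] = "neutral"
    for g in g_aversive:
        label_of[g] = "aversive"

    def build_encoding(name: str, context: str, duration_s: float) -> None:
        rng = _session_rng(base_seed, name)
        if context == "neutral":
            globals_ = g_overlap + g_neutral + g_shared_extra + g_extra_n
        else:
            globals_ = g_overlap + g_aversive + g_shared_extra + g_extra_a
        gl = _local_ids(globals_, rng)
        ordered = sorted(gl, key=gl.get)
        rates = encoding_rates(ordered, context)
        n_frames = int(round(duration_s * rate))
        matrix = _event_matrix(
            rates, n_frames, rate, rng, config.amplitude_sigma,
            np.arange(len(ordered)),
        )
        # guarantee every encoding cell is active (defines the ensembles)
        silent = ~np.any(matrix.values > 0, axis=1)
        for row in np.nonzero(silent)[0]:
            f = int(rng.integers(0, n_frames))
            matrix.values[row, f] = rng.lognormal(0.0, config.amplitude_sigma)
        gl_maps[name] = gl
        sessions[name] = SessionRecord(kind=_SESSION_KIND[name], matrix=matrix)

    def build_offline(name: str) -> None:
        rng = _session_rng(base_seed, name)
        if name == "offline1":
            globals_ = g_neutral + g_overlap + g_rem1
            labels_g = {
                g: ("neutral" if g in set(g_neutral + g_overlap)
                    else "remaining")
                for g in globals_
            }
            model = "offline1"
        else:
            globals_ = g_overlap + g_neutral + g_aversive + g_rem2
            labels_g = {g: label_of.get(g, "remaining") for g in globals_}
            model = "offline2"
        gl = _local_ids(globals_, rng)
        labels_local = {gl[g]: labels_g[g] for g in globals_}

        hyp = None
        frame_states = None
        eeg = None
        if config.eeg_paired:
            hyp = simulate_hypnogram(config, config.offline_s, rng)
            eeg = simulate_eeg_emg(hyp, config, rng)
            n_frames = int(round(config.offline_s * rate))
            ts = np.arange(n_frames) * (1000.0 / rate)
            frame_states = assign_states_to_frames(hyp, ts)

        matrix, loco, loco_ts, burst_truth = simulate_offline_session(
            config, labels_local, rng=rng, model=model,
            frame_states=frame_states,
        )
        gl_maps[name] = gl
        sessions[name] = SessionRecord(
            kind="offline", matrix=matrix, locomotion=loco,
            locomotion_timestamps=loco_ts, eeg_emg=eeg,
        )
        truth.ensembles[name] = labels_local
        truth.bursts[name] = burst_truth
        if hyp is not None:
            truth.hypnograms[name] = hyp
        truth.dip = burst_truth["dip"]

    def build_recall(name: str) -> None:
        rng = _session_rng(base_seed, name)
        members = recall_members[name]
        gl = _local_ids(members, rng)
        ordered = sorted(gl, key=gl.get)
        if name == "recall_neutral":
            rates = encoding_rates(ordered, "neutral")
        elif name == "recall_aversive":
            rates = encoding_rates(ordered, "aversive")
        else:
            rates = np.full(len(ordered), config.recall_base_rate)
        rates = np.maximum(rates, config.recall_min_rate)
        n_frames = int(round(config.recall_s * rate))
        matrix = _event_matrix(
            rates, n_frames, rate, rng, config.amplitude_sigma,
            np.arange(len(ordered)),
        )
        silent = ~np.any(matrix.values > 0, axis=1)
        for row in np.nonzero(silent)[0]:
            f = int(rng.integers(0, n_frames))
            matrix.values[row, f] = rng.lognormal(0.0, config.amplitude_sigma)
        gl_maps[name] = gl
        sessions[name] = SessionRecord(kind=_SESSION_KIND[name], matrix=matrix)
        labels_local = {
            gl[g]: label_of.get(g, "remaining") for g in members
        }
        truth.ensembles[name] = labels_local
        n = len(members)
        truth.recall_fractions[name] = {
            lab: sum(v == lab for v in labels_local.values()) / n
            for lab in ("neutral", "aversive", "overlap")
        }

    def build_chemotag() -> None:
        rng = _session_rng(base_seed, "chemotag")
        labels_local = truth.ensembles.get("offline2")
        if labels_local is None:
            raise ValueError("chemotag session requires offline2")
        traces, inhibitory, match = simulate_chemotag_session(
            config, labels_local, rng=rng
        )
        sessions["chemotag"] = SessionRecord(kind="chemotag", matrix=traces)
        truth.inhibitory = inhibitory
        # chemotag local -> global, through offline2 locals
        inv_off2 = {v: k for k, v in gl_maps["offline2"].items()}
        gl_maps["chemotag"] = {
            inv_off2[off2_local]: chem_local
            for chem_local, off2_local in match.pairs
        }
        # extra chemotag-only cells get fresh globals
        seen = set(c for c, _ in match.pairs)
        extra = [int(c) for c in traces.cell_ids.tolist() if c not in seen]
        for g, c in zip(take(len(extra)), extra):
            gl_maps["chemotag"][g] = c

    wanted = [s for s in ALL_SESSIONS if s in config.sessions]
    if "chemotag" in wanted and "offline2" not in wanted:
        raise ValueError("chemotag session requires offline2 in sessions")
    for name in wanted:
        if name.endswith("encoding"):
            build_encoding(
                name,
                "neutral" if name.startswith("neutral") else "aversive",
                config.neutral_encoding_s if name.startswith("neutral")
                else config.aversive_encoding_s,
            )
        elif name.startswith("offline"):
            build_offline(name)
        elif name.startswith("recall"):
            build_recall(name)
        elif name == "chemotag":
            build_chemotag()

    rng_m = np.random.default_rng([base_seed % (2**31), 99])
    tables = []
    for a, b in _MATCH_PAIRS:
        if a in sessions and b in sessions:
            tables.append(
                _match_table(a, gl_maps[a], b, gl_maps[b],
                             config.mismatch_rate, rng_m)
            )
    exp = ExperimentSet(
        sessions=sessions, match_tables=tables,
        group_label=config.group_label,
    )
    return exp, truth
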