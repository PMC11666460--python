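"""Population burst detection and burst-participation statistics.

A population burst is a brief period in which many cells are synchronously
active. Each cell's deconvolved event train is first z-scored along time so
that no single high-amplitude cell dominates; the mean across cells is then
z-scored again, and maximal runs of frames where this population trace exceeds
a threshold (z = 2 by default) are burst events. Per-cell participation uses
the same z = 2 rule on the cell's own z-scored activity within the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from coreact.core import ENSEMBLE_LABELS, EnsembleAssignment, EventMatrix

logger = logging.getLogger(__name__)


@dataclass
class BurstCatalog:
    """Detected population burst events and the trace they were called on.

    ``events`` is an ``(n_events, 3)`` int array of ``(start, peak, end)``
    frames with half-open ``[start, end)`` bounds; events are ordered and
    non-overlapping, and the trace at each peak exceeds ``threshold_z``.
    """

    population_trace: np.ndarray
    events: np.ndarray
    threshold_z: float = 2.0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=int).reshape(-1, 3)
        if self.events.size:
            s, p, e = self.events.T
            if not (np.all(s <= p) and np.all(p < e)):
                raise ValueError("events must satisfy start <= peak < end")
            if np.any(e[:-1] > s[1:]):
                raise ValueError("events must be ordered and non-overlapping")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def durations(self) -> np.ndarray:
        if not self.n_events:
            return np.zeros(0, dtype=int)
        return self.events[:, 2] - self.events[:, 0]

    def burst_mask(self) -> np.ndarray:
        """Boolean per-frame mask, True inside any burst event."""
        mask = np.zeros(self.population_trace.size, dtype=bool)
        for s, _, e in self.events:
            mask[s:e] = True
        return mask


@dataclass
class ParticipationSummary:
    """Per-event per-cell participation and per-ensemble mean fractions."""

    participation: np.ndarray  # (n_cells, n_events) bool
    cell_ids: np.ndarray
    ensemble_fractions: dict = field(default_factory=dict)  # label -> float
    empty: bool = False


def zscore_cells(values: np.ndarray) -> np.ndarray:
    """Z-score each row (cell) along time; zero-variance rows become zeros.

    Silent or constant cells cannot be meaningfully normalized; mapping them
    to zero keeps them in ensemble denominators without contributing activity.
    """
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if np.any(flat):
        logger.info("%d zero-variance cell(s) z-scored to zeros", flat.sum())
    sd[flat] = 1.0
    out = (values - mu) / sd
    out[flat] = 0.0
    return out


def zscore_trace(trace: np.ndarray) -> np.ndarray:
    """Z-score a 1-D trace; a constant trace becomes zeros (with a warning)."""
    trace = np.asarray(trace, dtype=float)
    sd = trace.std()
    if sd == 0:
        logger.warning("constant population trace; returning zeros")
        return np.zeros_like(trace)
    return (trace - trace.mean()) / sd


def population_trace(matrix: EventMatrix) -> np.ndarray:
    """Doubly z-scored mean population activity.

    Each cell is z-scored along time, the mean across cells is taken, and the
    resulting 1-D trace is z-scored again.
    """
    if matrix.n_frames < 2 or matrix.n_cells < 1:
        raise ValueError("need at least 1 cell and 2 frames")
    return zscore_trace(zscore_cells(matrix.values).mean(axis=0))


def detect_bursts(trace: np.ndarray, threshold_z: float = 2.0) -> BurstCatalog:
    """Call burst events as maximal runs of frames with ``trace > threshold_z``.

    The peak is the argmax within the run (earliest frame on ties). Runs
    separated by at least one sub-threshold frame are distinct events; no
    merging and no minimum duration is applied.
    """
    trace = np.asarray(trace, dtype=float)
    above = trace > threshold_z
    if not above.any():
        return BurstCatalog(trace, np.zeros((0, 3), dtype=int), threshold_z)
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    events = []
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(trace[s:e]))
        events.append((s, peak, e))
    return BurstCatalog(trace, np.asarray(events, dtype=int), threshold_z)


def detect_bursts_with_boundaries(
    trace: np.ndarray,
    boundaries: np.ndarray,
    threshold_z: float = 2.0,
) -> BurstCatalog:
    """Burst detection on a concatenated trace, never crossing a session
    boundary: runs are split at each boundary frame before peak-finding."""
    trace = np.asarray(trace, dtype=float)
    cuts = set(int(b) for b in np.asarray(boundaries, dtype=int))
    base = detect_bursts(trace, threshold_z)
    events = []
    for s, _, e in base.events:
        inner = sorted(c for c in cuts if s < c < e)
        for a, b in zip([s] + inner, inner + [e]):
            peak = a + int(np.argmax(trace[a:b]))
            events.append((a, peak, b))
    return BurstCatalog(trace, np.asarray(events, dtype=int).reshape(-1, 3),
                        threshold_z)


def cell_participation(
    matrix: EventMatrix,
    catalog: BurstCatalog,
    cell_threshold_z: float = 2.0,
) -> np.ndarray:
    """Boolean ``(n_cells, n_events)``: cell participated in the event iff its
    z-scored activity exceeds ``cell_threshold_z`` on >= 1 frame of
    ``[start, end)``."""
    if catalog.population_trace.size != matrix.n_frames:
        raise ValueError("catalog and matrix disagree on frame count")
    z = zscore_cells(matrix.values)
    out = np.zeros((matrix.n_cells, catalog.n_events), dtype=bool)
    for k, (s, _, e) in enumerate(catalog.events):
        out[:, k] = (z[:, s:e] > cell_threshold_z).any(axis=1)
    return out


def ensemble_participation(
    participation: np.ndarray,
    cell_ids: np.ndarray,
    assignment: EnsembleAssignment,
) -> ParticipationSummary:
    """Mean fraction of each ensemble participating per burst event.

    For each ensemble the fraction of its cells participating is computed per
    event and averaged across events. Empty ensembles are omitted; with zero
    events the summary is flagged empty and no fractions are emitted.
    """
    participation = np.asarray(participation, dtype=bool)
    cell_ids = np.asarray(cell_ids)
    missing = set(cell_ids.tolist()) - set(assignment.labels)
    if missing:
        raise ValueError(f"assignment missing cells: {sorted(missing)!r}")
    summary = ParticipationSummary(
        participation=participation, cell_ids=cell_ids
    )
    if participation.shape[1] == 0:
        summary.empty = True
        logger.warning("no burst events; participation summary is empty")
        return summary
    labels = np.asarray([assignment.labels[c] for c in cell_ids.tolist()])
    for name in ENSEMBLE_LABELS:
        rows = labels == name
        if not rows.any():
            continue
        frac_per_event = participation[rows].mean(axis=0)
        summary.ensemble_fractions[name] = float(frac_per_event.mean())
    return summary


def shuffle_null(
    matrix: EventMatrix,
    n_shuffles: int = 500,
    seed: int = 0,
    threshold_z: float = 2.0,
) -> dict:
    """Circular-shift null for the burst count.

    Each shuffle independently rotates every cell's event train by a uniform
    random offset, preserving per-cell rate and autocorrelation while
    destroying across-cell synchrony, then reruns burst detection. Returns the
    null burst counts, null peak-z maxima, the observed values, and an
    empirical p-value ``(1 + #null >= observed) / (n_shuffles + 1)``.
    """
    rng = np.random.default_rng(seed)
    observed = detect_bursts(population_trace(matrix), threshold_z)
    obs_count = observed.n_events
    obs_dur = (float(observed.durations().mean())
               if observed.n_events else 0.0)
    null_counts = np.zeros(n_shuffles, dtype=int)
    null_peak_z = np.zeros(n_shuffles)
    null_mean_dur = np.zeros(n_shuffles)
    values = matrix.values
    n_frames = matrix.n_frames
    for i in range(n_shuffles):
        shifts = rng.integers(0, n_frames, size=matrix.n_cells)
        shuffled = np.empty_like(values)
        for r, s in enumerate(shifts):
            shuffled[r] = np.roll(values[r], int(s))
        trace = zscore_trace(zscore_cells(shuffled).mean(axis=0))
        cat = detect_bursts(trace, threshold_z)
        null_counts[i] = cat.n_events
        null_peak_z[i] = trace.max() if trace.size else 0.0
        null_mean_dur[i] = (float(cat.durations().mean())
                            if cat.n_events else 0.0)
    # Genuine synchrony consolidates the trace's supra-threshold mass into
    # few long events and inflates the trace SD, so structured sessions sit
    # in the LOWER tail of the null count (and the upper tail of duration);
    # both one-sided empirical p-values are reported.
    p_upper = (1 + int(np.sum(null_counts >= obs_count))) / (n_shuffles + 1)
    p_lower = (1 + int(np.sum(null_counts <= obs_count))) / (n_shuffles + 1)
    p_dur = (1 + int(np.sum(null_mean_dur >= obs_dur))) / (n_shuffles + 1)
    return {
        "observed_count": obs_count,
        "observed_peak_z": float(observed.population_trace.max()),
        "observed_mean_duration": obs_dur,
        "null_counts": null_counts,
        "null_peak_z": null_peak_z,
        "null_mean_duration": null_mean_dur,
        "p_count_upper": float(p_upper),
        "p_count_lower": float(p_lower),
        "p_duration": float(p_dur),
        "p_value": float(min(1.0, 2 * min(p_upper, p_lower))),
    }


def peri_burst_locomotion(
    locomotion: Optional[np.ndarray],
    locomotion_timestamps: Optional[np.ndarray],
    catalog: BurstCatalog,
    calcium_timestamps: np.ndarray,
    window_s: float = 5.0,
) -> dict:
    """Locomotion aligned to burst peaks in a ±``window_s`` window.

    The locomotion trace is linearly interpolated onto a regular grid centred
    on each burst-peak time (grid step = median locomotion sampling interval).
    Events whose window extends past either end of the locomotion recording
    are excluded. Returns the event x time matrix, its mean, and the time
    offsets; with no locomotion trace an explicit not-available result.
    """
    if locomotion is None:
        return {"available": False}
    loco = np.asarray(locomotion, dtype=float)
    loco_ts = np.asarray(locomotion_timestamps, dtype=float)
    cal_ts = np.asarray(calcium_timestamps, dtype=float)
    dt_ms = float(np.median(np.diff(loco_ts)))
    offsets_ms = np.arange(-window_s * 1000, window_s * 1000 + dt_ms / 2, dt_ms)
    rows = []
    for _, peak, _ in catalog.events:
        t0 = cal_ts[peak]
        grid = t0 + offsets_ms
        if grid[0] < loco_ts[0] or grid[-1] > loco_ts[-1]:
            continue  # truncated by the session edge
        rows.append(np.interp(grid, loco_ts, loco))
    if not rows:
        logger.warning("no burst events with a full peri-event window")
        return {
            "available": True,
            "empty": True,
            "aligned": np.zeros((0, offsets_ms.size)),
            "mean": np.full(offsets_ms.size, np.nan),
            "offsets_s": offsets_ms / 1000.0,
        }
    aligned = np.vstack(rows)
    return {
        "available": True,
        "empty": False,
        "aligned": aligned,
        "mean": aligned.mean(axis=0),
        "offsets_s": offsets_ms / 1000.0,
    }
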