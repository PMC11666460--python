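"""Ensemble co-participation in bursts and time-lagged cross-correlations.

Co-bursting asks whether two memory ensembles (e.g. the overlap ensemble and
the neutral ensemble) are synchronously active within the *same* population
burst events, versus participating independently in different events. The
analogous statistic over non-burst windows serves as the within-animal
control, and a lagged cross-correlation of the ensemble mean traces gives a
threshold-free measure of the same coupling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from coreact.bursts import BurstCatalog, zscore_cells, zscore_trace
from coreact.core import EnsembleAssignment, EventMatrix

logger = logging.getLogger(__name__)

#: ensembles whose joint burst behaviour is tracked (remaining cells ignored)
TRACKED_ENSEMBLES = ("neutral", "aversive", "overlap")


@dataclass
class CoParticipationSummary:
    """Independent and pairwise co-participation fractions over events.

    ``independent[E]`` is the fraction of events in which ensemble E
    participated while no other tracked ensemble did; ``pairwise[(E, F)]`` the
    fraction in which both participated (keys sorted alphabetically);
    ``total[E]`` the fraction in which E participated at all.
    """

    n_events: int = 0
    independent: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    total: dict = field(default_factory=dict)
    empty: bool = False


def ensemble_mean_traces(
    matrix: EventMatrix,
    assignment: EnsembleAssignment,
    ensembles: tuple = TRACKED_ENSEMBLES,
    final_zscore: bool = True,
) -> dict:
    """Mean activity trace per ensemble.

    Cells are z-scored along time, averaged within each ensemble, and (by
    default) the mean trace is z-scored again. ``final_zscore=False`` returns
    the un-normalized mean-of-z-scores, which is what multi-session
    concatenation consumes before its own global z-scoring. Empty ensembles
    are omitted with a warning.
    """
    z = zscore_cells(matrix.values)
    labels = np.asarray([assignment.labels[c] for c in matrix.cell_ids.tolist()])
    out = {}
    for name in ensembles:
        rows = labels == name
        if not rows.any():
            logger.warning("ensemble %r is empty; trace omitted", name)
            continue
        trace = z[rows].mean(axis=0)
        out[name] = zscore_trace(trace) if final_zscore else trace
    return out


def ensemble_event_participation(
    ensemble_traces: dict,
    catalog: BurstCatalog,
    threshold_z: float = 2.0,
) -> dict:
    """Per-ensemble boolean participation over the catalog's events.

    An ensemble participates in an event iff its mean trace exceeds
    ``threshold_z`` on at least one frame of ``[start, end)``.
    """
    out = {}
    for name, trace in ensemble_traces.items():
        if trace.size != catalog.population_trace.size:
            raise ValueError("ensemble trace and catalog frame count differ")
        flags = np.zeros(catalog.n_events, dtype=bool)
        for k, (s, _, e) in enumerate(catalog.events):
            flags[k] = bool((trace[s:e] > threshold_z).any())
        out[name] = flags
    return out


def coparticipation_fractions(participation: dict) -> CoParticipationSummary:
    """Fractions of events with independent vs coincident participation.

    "Independent" is relative to the tracked ensembles present in
    ``participation`` only. With zero events an empty summary is returned.
    """
    names = sorted(participation)
    if not names:
        return CoParticipationSummary(empty=True)
    n_events = int(np.asarray(participation[names[0]]).size)
    if n_events == 0:
        return CoParticipationSummary(empty=True)
    flags = {k: np.asarray(v, dtype=bool) for k, v in participation.items()}
    summary = CoParticipationSummary(n_events=n_events)
    for name in names:
        others = [flags[o] for o in names if o != name]
        none_other = (
            ~np.logical_or.reduce(others) if others
            else np.ones(n_events, dtype=bool)
        )
        summary.independent[name] = float((flags[name] & none_other).mean())
        summary.total[name] = float(flags[name].mean())
    for a, b in itertools.combinations(names, 2):
        summary.pairwise[(a, b)] = float((flags[a] & flags[b]).mean())
    return summary


def nonburst_windows(
    n_frames: int, catalog: BurstCatalog, window_len: int | None = None
) -> np.ndarray:
    """Partition non-burst frames into contiguous windows.

    Frames outside all burst events are split into maximal contiguous
    segments; each segment is chopped into windows of ``window_len`` frames
    (default: the catalog's median burst duration) and the remainder of each
    segment is dropped. Returns an ``(n_windows, 2)`` array of half-open
    bounds.
    """
    if window_len is None:
        dur = catalog.durations()
        window_len = max(1, int(round(float(np.median(dur))))) if dur.size else 1
    mask = np.zeros(n_frames, dtype=bool)
    for s, _, e in catalog.events:
        mask[s:e] = True
    windows = []
    i = 0
    while i < n_frames:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n_frames and not mask[j]:
            j += 1
        for w in range(i, j - window_len + 1, window_len):
            windows.append((w, w + window_len))
        i = j
    return np.asarray(windows, dtype=int).reshape(-1, 2)


def nonburst_coparticipation(
    ensemble_traces: dict,
    catalog: BurstCatalog,
    threshold_z: float = 2.0,
    window_len: int | None = None,
) -> CoParticipationSummary:
    """Co-participation over non-burst windows (the control statistic).

    Non-burst frames are windowed at the median burst duration and the same
    any-frame threshold rule as for burst events is applied per window.
    """
    if not ensemble_traces:
        return CoParticipationSummary(empty=True)
    n_frames = next(iter(ensemble_traces.values())).size
    wins = nonburst_windows(n_frames, catalog, window_len)
    if wins.shape[0] == 0:
        logger.warning("no non-burst windows available")
        return CoParticipationSummary(empty=True)
    pseudo = BurstCatalog(
        population_trace=np.zeros(n_frames),
        events=np.column_stack([wins[:, 0], wins[:, 0], wins[:, 1]]),
        threshold_z=threshold_z,
    )
    participation = ensemble_event_participation(
        ensemble_traces, pseudo, threshold_z
    )
    return coparticipation_fractions(participation)


def frame_exceedance_fractions(
    ensemble_traces: dict, catalog: BurstCatalog, threshold_z: float = 2.0
) -> CoParticipationSummary:
    """Alternative non-burst statistic: frame-wise threshold exceedance.

    Treats every non-burst frame as its own unit instead of windowing;
    provided as a config switch, not the default.
    """
    if not ensemble_traces:
        return CoParticipationSummary(empty=True)
    n_frames = next(iter(ensemble_traces.values())).size
    outside = ~catalog.burst_mask()[:n_frames]
    if not outside.any():
        return CoParticipationSummary(empty=True)
    participation = {
        k: np.asarray(v)[outside] > threshold_z
        for k, v in ensemble_traces.items()
    }
    return coparticipation_fractions(participation)


def lagged_crosscorr(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    frame_rate: float,
    bin_s: float = 120.0,
    max_lag_frames: int = 5,
) -> dict:
    """Mean max-over-lags Pearson correlation between two ensemble traces.

    The traces are broken into ``bin_s`` bins (trailing partial bin dropped).
    Within each bin the Pearson correlation is computed at every integer lag
    in ``[-max_lag, +max_lag]`` (overlapping portions only) and the maximum
    signed correlation over lags is kept; the per-bin maxima are averaged.
    Zero-variance sub-segments are skipped and the skip count reported.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.size != b.size:
        raise ValueError("traces must have equal length")
    n_bin = int(round(bin_s * frame_rate))
    if a.size < n_bin:
        raise ValueError("traces shorter than one bin")
    maxima = []
    skipped = 0
    for start in range(0, a.size - n_bin + 1, n_bin):
        seg_a = a[start:start + n_bin]
        seg_b = b[start:start + n_bin]
        best = -np.inf
        for lag in range(-max_lag_frames, max_lag_frames + 1):
            if lag >= 0:
                x, y = seg_a[lag:], seg_b[:n_bin - lag]
            else:
                x, y = seg_a[:n_bin + lag], seg_b[-lag:]
            if x.size < 2 or x.std() == 0 or y.std() == 0:
                continue
            best = max(best, float(np.corrcoef(x, y)[0, 1]))
        if np.isfinite(best):
            maxima.append(best)
        else:
            skipped += 1
    if not maxima:
        return {"mean_max_corr": np.nan, "per_bin": [], "skipped_bins": skipped}
    return {
        "mean_max_corr": float(np.mean(maxima)),
        "per_bin": maxima,
        "skipped_bins": skipped,
    }


def concatenate_offline(session_traces: list[dict]) -> tuple[dict, np.ndarray]:
    """Concatenate per-session ensemble mean traces into pseudocontinuous
    series, then z-score each concatenated trace.

    Sessions missing any ensemble of the first session are excluded with a
    warning. Returns ``(traces, boundaries)`` where ``boundaries`` holds the
    start frame of each retained session after the first, so burst detection
    can avoid events spanning a session boundary
    (:func:`coreact.bursts.detect_bursts_with_boundaries`).
    """
    if not session_traces:
        raise ValueError("no sessions to concatenate")
    ensembles = sorted(session_traces[0])
    kept = []
    for i, traces in enumerate(session_traces):
        if not all(e in traces for e in ensembles):
            logger.warning("session %d missing an ensemble; excluded", i)
            continue
        kept.append(traces)
    if not kept:
        raise ValueError("no session has all required ensembles")
    boundaries = np.cumsum(
        [next(iter(t.values())).size for t in kept[:-1]], dtype=int
    )
    out = {
        e: zscore_trace(np.concatenate([t[e] for t in kept]))
        for e in ensembles
    }
    return out, boundaries
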