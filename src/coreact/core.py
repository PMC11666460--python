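"""Core data model: recordings, cross-session match tables, ensemble labels,
and the timestamp-alignment rules shared by every downstream analysis stage.

Conventions used throughout the package:

* frame indexing is 0-based and intervals are half-open ``[start, end)``;
* timestamps are wall-clock milliseconds, strictly increasing;
* cell identifiers are per-session; identity across sessions exists only
  through :class:`MatchTable` objects (the output of a footprint
  cross-registration step, which is consumed here, never computed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The four ensemble labels used for offline and recall sessions.
ENSEMBLE_LABELS = ("neutral", "aversive", "overlap", "remaining")


@dataclass
class EventMatrix:
    """A cells x frames matrix of nonnegative deconvolved event amplitudes.

    Parameters
    ----------
    values
        ``(n_cells, n_frames)`` array, nonnegative. For chemotag sessions the
        same container holds continuous calcium traces (also nonnegative).
    frame_rate
        Nominal acquisition rate in frames/s (30, or 15 for EEG-paired
        sessions).
    timestamps
        Per-frame wall-clock time in ms, strictly increasing.
    cell_ids
        Stable per-session integer identifiers, unique.
    """

    values: np.ndarray
    frame_rate: float
    timestamps: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x frames array")
        if np.any(self.values < 0):
            raise ValueError("event amplitudes must be nonnegative")
        if self.timestamps.shape != (self.values.shape[1],):
            raise ValueError(
                f"timestamps length {self.timestamps.shape} does not match "
                f"frame count {self.values.shape[1]}"
            )
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.cell_ids.shape != (self.values.shape[0],):
            raise ValueError("cell_ids length must match cell count")
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def cell_index(self, cell_id) -> int:
        """Row index of a cell id; raises KeyError for unknown ids."""
        hits = np.nonzero(self.cell_ids == cell_id)[0]
        if hits.size == 0:
            raise KeyError(f"unknown cell id {cell_id!r}")
        return int(hits[0])


@dataclass
class MatchTable:
    """Cross-session cell correspondence (CellReg-style output, consumed as-is).

    ``pairs`` maps cells of ``session_a`` onto cells of ``session_b``; the
    matching must be injective on both sides.
    """

    session_a: str
    session_b: str
    pairs: list[tuple]

    def __post_init__(self) -> None:
        self.pairs = [(a, b) for a, b in self.pairs]
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError(
                f"match table {self.session_a}<->{self.session_b} is not "
                "injective: a cell id appears more than once on one side"
            )

    def mapping(self, from_session: str) -> dict:
        """Dict mapping cell ids of ``from_session`` to the other side."""
        if from_session == self.session_a:
            return {a: b for a, b in self.pairs}
        if from_session == self.session_b:
            return {b: a for a, b in self.pairs}
        raise KeyError(
            f"session {from_session!r} not in match table "
            f"({self.session_a}, {self.session_b})"
        )

    def matched_ids(self, session: str) -> set:
        """Set of cell ids of ``session`` that have a match."""
        return set(self.mapping(session))


@dataclass
class EnsembleAssignment:
    """Per-cell ensemble label for one offline or recall session."""

    session: str
    labels: dict  # cell_id -> label in ENSEMBLE_LABELS

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - set(ENSEMBLE_LABELS)
        if bad:
            raise ValueError(f"unknown ensemble labels: {sorted(bad)}")

    def cells_of(self, label: str) -> list:
        return [c for c, v in self.labels.items() if v == label]

    def counts(self) -> dict:
        out = {k: 0 for k in ENSEMBLE_LABELS}
        for v in self.labels.values():
            out[v] += 1
        return out


@dataclass
class SessionRecord:
    """One recording session: event matrix plus optional behaviour channels."""

    kind: str  # neutral_encoding | aversive_encoding | offline | recall_* | chemotag
    matrix: EventMatrix
    locomotion: Optional[np.ndarray] = None
    locomotion_timestamps: Optional[np.ndarray] = None
    eeg_emg: Optional[object] = None  # sleep.EEGEMGRecord

    KINDS = (
        "neutral_encoding",
        "aversive_encoding",
        "offline",
        "recall_aversive",
        "recall_neutral",
        "recall_novel",
        "chemotag",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown session kind {self.kind!r}")
        if (self.locomotion is None) != (self.locomotion_timestamps is None):
            raise ValueError("locomotion and its timestamps must come together")
        if self.locomotion is not None:
            self.locomotion = np.asarray(self.locomotion, dtype=float)
            self.locomotion_timestamps = np.asarray(
                self.locomotion_timestamps, dtype=float
            )
            if self.locomotion.shape != self.locomotion_timestamps.shape:
                raise ValueError("locomotion and timestamps length mismatch")


@dataclass
class ExperimentSet:
    """All sessions of one animal's paradigm plus cross-session match tables."""

    sessions: dict  # session name -> SessionRecord
    match_tables: list[MatchTable] = field(default_factory=list)
    group_label: str = "unspecified"  # e.g. low_shock | high_shock | no_shock

    def __post_init__(self) -> None:
        for mt in self.match_tables:
            for s in (mt.session_a, mt.session_b):
                if s not in self.sessions:
                    raise ValueError(
                        f"match table references unknown session {s!r}"
                    )

    def match_table(self, session_a: str, session_b: str) -> MatchTable:
        for mt in self.match_tables:
            if {mt.session_a, mt.session_b} == {session_a, session_b}:
                return mt
        raise KeyError(f"no match table between {session_a!r} and {session_b!r}")


@dataclass
class AlignmentMap:
    """Frame alignment result.

    ``index[k]`` is the source-frame index assigned to output frame ``k``;
    ``reuse_counts[j]`` counts how many output frames use source frame ``j``
    (never more than 2); ``max_displacement_frames`` is the largest time error
    of any assignment, in units of the output frame period.
    """

    index: np.ndarray
    reuse_counts: np.ndarray
    max_displacement_frames: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def assign_ensembles(
    offline_session: str,
    offline_cell_ids: Sequence,
    match_to_neutral: MatchTable,
    match_to_aversive: MatchTable,
) -> EnsembleAssignment:
    """Sort the cells of an offline (or recall) session into four ensembles.

    A cell matched only to neutral encoding is ``neutral``; only to aversive
    encoding, ``aversive``; to both, ``overlap``; to neither, ``remaining``.
    """
    known = set(offline_cell_ids)
    neutral_ids = match_to_neutral.matched_ids(offline_session)
    aversive_ids = match_to_aversive.matched_ids(offline_session)
    for name, ids in (("neutral", neutral_ids), ("aversive", aversive_ids)):
        stray = ids - known
        if stray:
            raise ValueError(
                f"match table to {name} encoding references cell id(s) "
                f"{sorted(stray)!r} absent from session {offline_session!r}"
            )
    labels = {}
    for cid in offline_cell_ids:
        in_n = cid in neutral_ids
        in_a = cid in aversive_ids
        if in_n and in_a:
            labels[cid] = "overlap"
        elif in_n:
            labels[cid] = "neutral"
        elif in_a:
            labels[cid] = "aversive"
        else:
            labels[cid] = "remaining"
    return EnsembleAssignment(session=offline_session, labels=labels)


def align_to_template(
    timestamps: np.ndarray, nominal_rate: float
) -> AlignmentMap:
    """Align recorded frames onto an ideal constant-rate template.

    The template grid starts at the first timestamp with period
    ``1000 / nominal_rate`` ms and spans the recording, so a jitter-free
    recording of 300 s at 30 frames/s maps onto exactly 9000 slots with the
    identity assignment. Each template slot takes the nearest recorded frame
    (ties to the earlier frame). A maximum displacement above 4 frame periods
    is logged as a warning: well-behaved behaviour recordings stay within it.
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.size == 0:
        raise ValueError("empty timestamp vector")
    if ts.size >= 2 and not np.all(np.diff(ts) > 0):
        raise ValueError("timestamps must be strictly increasing")
    period_ms = 1000.0 / nominal_rate
    n_slots = int(round((ts[-1] - ts[0]) / period_ms)) + 1
    grid = ts[0] + period_ms * np.arange(n_slots)
    index = _nearest_indices(ts, grid)
    displacement = np.abs(ts[index] - grid) / period_ms
    max_disp = float(displacement.max()) if n_slots else 0.0
    if max_disp > 4:
        logger.warning(
            "template alignment displacement %.2f frames exceeds 4", max_disp
        )
    reuse = np.bincount(index, minlength=ts.size)
    # template slots may reuse a frame freely when frames were dropped; the
    # <=2 reuse cap applies to the calcium->behaviour alignment only
    return AlignmentMap(
        index=index, reuse_counts=reuse, max_displacement_frames=max_disp
    )


def _nearest_indices(source_ts: np.ndarray, target_ts: np.ndarray) -> np.ndarray:
    """For each target time the index of the nearest source time (ties earlier)."""
    pos = np.searchsorted(source_ts, target_ts)
    pos = np.clip(pos, 1, len(source_ts) - 1) if len(source_ts) > 1 else np.zeros(
        len(target_ts), dtype=int
    )
    if len(source_ts) == 1:
        return np.zeros(len(target_ts), dtype=int)
    left = pos - 1
    right = pos
    d_left = np.abs(target_ts - source_ts[left])
    d_right = np.abs(source_ts[right] - target_ts)
    # strict '<' keeps the earlier frame on exact ties
    return np.where(d_right < d_left, right, left)


def align_calcium_to_target(
    calcium_timestamps: np.ndarray,
    target_timestamps: np.ndarray,
    max_reuse: int = 2,
) -> AlignmentMap:
    """Assign the nearest calcium frame to every target (behaviour) frame.

    No calcium frame may serve more than ``max_reuse`` target frames. When the
    cap binds, the assignments to the overloaded frame are ranked by time
    error; the best ``max_reuse`` stay and the rest are greedily reassigned
    (worst first) to their nearest calcium frame that still has capacity.
    """
    cal = np.asarray(calcium_timestamps, dtype=float)
    tgt = np.asarray(target_timestamps, dtype=float)
    if cal.size == 0 or tgt.size == 0:
        raise ValueError("empty timestamp vector")
    for ts in (cal, tgt):
        if ts.size >= 2 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
    if tgt.size > max_reuse * cal.size:
        raise ValueError(
            f"{tgt.size} target frames cannot be served by {cal.size} calcium "
            f"frames with reuse <= {max_reuse}"
        )

    index = _nearest_indices(cal, tgt)
    counts = np.bincount(index, minlength=cal.size)

    while True:
        over = np.nonzero(counts > max_reuse)[0]
        if over.size == 0:
            break
        c = int(over[0])
        assigned = np.nonzero(index == c)[0]
        err = np.abs(tgt[assigned] - cal[c])
        # keep the max_reuse best (smallest error, earlier target on ties)
        order = np.lexsort((assigned, err))
        evict = assigned[order[max_reuse:]]
        # reassign worst-first
        evict = evict[np.argsort(-err[order[max_reuse:]], kind="stable")]
        counts[c] = max_reuse
        for t in evict:
            dist = np.abs(cal - tgt[t])
            dist[counts >= max_reuse] = np.inf
            j = int(np.argmin(dist))  # argmin takes the earlier frame on ties
            if not np.isfinite(dist[j]):
                raise RuntimeError("no calcium frame with remaining capacity")
            index[t] = j
            counts[j] += 1

    err = np.abs(tgt - cal[index])
    period = float(np.median(np.diff(tgt))) if tgt.size > 1 else 1.0
    return AlignmentMap(
        index=index,
        reuse_counts=counts,
        max_displacement_frames=float(err.max() / period),
    )
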