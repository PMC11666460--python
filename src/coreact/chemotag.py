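"""Chemogenetic tagging: rank cells by CNO-session responsiveness.

On the tagging day, cells expressing the excitatory DREADD respond to CNO
with sustained calcium transients. Each cell's continuous trace is min-max
normalized to [0, 1] and its prominent peaks within minutes 10-40 of the
session are counted; the top fraction (10% by default, matching the expected
inhibitory share of the CA1 pyramidal layer) are flagged as putative
inhibitory neurons. Labels propagate to other sessions through match tables;
a cell with no match on tagging day counts as zero activity there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from coreact.core import EnsembleAssignment, EventMatrix, MatchTable

logger = logging.getLogger(__name__)


@dataclass
class ChemotagRanking:
    """Per-cell peak counts, ranks (1 = most responsive) and top-frac flags."""

    cell_ids: np.ndarray
    peak_counts: dict = field(default_factory=dict)  # cell_id -> int
    ranks: dict = field(default_factory=dict)        # cell_id -> 1..n
    flags: dict = field(default_factory=dict)        # cell_id -> bool
    top_frac: float = 0.10

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if n and sorted(self.ranks.values()) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..n")
        if n:
            expect = math.ceil(self.top_frac * n)
            if sum(self.flags.values()) != expect:
                raise ValueError(
                    f"flag count must be ceil(top_frac*n) = {expect}"
                )

    def flagged_ids(self) -> list:
        return [c for c, f in self.flags.items() if f]


def _rank_and_flag(
    cell_ids: np.ndarray,
    counts: dict,
    top_frac: float,
    order_key,
) -> ChemotagRanking:
    ordered = sorted(cell_ids.tolist(), key=order_key)
    n = len(ordered)
    n_flag = math.ceil(top_frac * n) if n else 0
    ranks = {c: i + 1 for i, c in enumerate(ordered)}
    flags = {c: (ranks[c] <= n_flag) for c in ordered}
    return ChemotagRanking(
        cell_ids=np.asarray(ordered),
        peak_counts={c: counts.get(c, 0) for c in ordered},
        ranks=ranks,
        flags=flags,
        top_frac=top_frac,
    )


def prominent_peak_indices(
    trace: np.ndarray,
    frame_rate: float,
    prominence: float = 0.3,
    min_spacing_s: float = 2.0,
) -> np.ndarray:
    """Indices of prominent peaks of a [0,1]-normalized trace.

    The whole trace is min-max normalized (flat traces have no peaks) and
    peaks with prominence >= ``prominence`` of the normalized range,
    separated by at least ``min_spacing_s``, are returned.
    """
    x = np.asarray(trace, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(0, dtype=int)
    x = (x - lo) / (hi - lo)
    distance = max(1, int(round(min_spacing_s * frame_rate)))
    peaks, _ = signal.find_peaks(x, prominence=prominence, distance=distance)
    return peaks


def count_prominent_peaks(
    trace: np.ndarray,
    frame_rate: float,
    prominence: float = 0.3,
    min_spacing_s: float = 2.0,
) -> int:
    """Number of prominent peaks over the whole normalized trace."""
    return int(
        prominent_peak_indices(trace, frame_rate, prominence,
                               min_spacing_s).size
    )


def rank_chemotag(
    traces: EventMatrix,
    window_min: tuple = (10.0, 40.0),
    prominence: float = 0.3,
    min_spacing_s: float = 2.0,
    top_frac: float = 0.10,
) -> ChemotagRanking:
    """Rank cells by prominent-peak count within the CNO analysis window.

    ``traces`` holds continuous calcium traces (not deconvolved events). The
    session must span the analysis window (40 min by default). Ties are
    broken by cell id; the top ``top_frac`` are flagged putative inhibitory.
    """
    if traces.duration_s < window_min[1] * 60.0:
        raise ValueError(
            f"session ({traces.duration_s:.0f} s) shorter than the "
            f"analysis window end ({window_min[1] * 60:.0f} s)"
        )
    lo = int(round(window_min[0] * 60.0 * traces.frame_rate))
    hi = int(round(window_min[1] * 60.0 * traces.frame_rate))
    counts = {}
    for i, cid in enumerate(traces.cell_ids.tolist()):
        # normalize over the whole session, then restrict to the window:
        # a windowed slice of a quiet cell would otherwise stretch noise
        peaks = prominent_peak_indices(
            traces.values[i], traces.frame_rate, prominence, min_spacing_s
        )
        counts[cid] = int(np.sum((peaks >= lo) & (peaks < hi)))
    return _rank_and_flag(
        traces.cell_ids, counts, top_frac,
        order_key=lambda c: (-counts[c], c),
    )


def propagate_labels(
    ranking: ChemotagRanking,
    match_table: MatchTable,
    tag_session: str,
    target_session: str,
    target_cells,
    top_frac: float | None = None,
) -> ChemotagRanking:
    """Carry tagging-day responsiveness onto another session's cells.

    Matched target cells inherit the tagging-day peak count and relative
    order; unmatched target cells get count 0 and rank after every matched
    cell (a responsive DREADD+ cell should have been seen on tagging day).
    Flags are recomputed over the target population.
    """
    if top_frac is None:
        top_frac = ranking.top_frac
    mapping = match_table.mapping(target_session)  # target id -> tag id
    target_cells = np.asarray(list(target_cells))
    counts = {}
    source_rank = {}
    for c in target_cells.tolist():
        tag_id = mapping.get(c)
        if tag_id is not None and tag_id in ranking.peak_counts:
            counts[c] = ranking.peak_counts[tag_id]
            source_rank[c] = ranking.ranks[tag_id]
        else:
            counts[c] = 0
    n_matched = len(source_rank)
    if n_matched == 0:
        logger.warning("no target cells matched to the tagging session")
    return _rank_and_flag(
        target_cells, counts, top_frac,
        order_key=lambda c: (
            (0, source_rank[c], c) if c in source_rank
            else (1, 0, c)
        ),
    )


def ensemble_composition(
    assignment: EnsembleAssignment, flags: dict
) -> dict:
    """Putative-inhibitory fraction per ensemble, with enrichment tests.

    Each ensemble is compared against the whole population with a
    hypergeometric test (one-sided, enrichment): with ``N`` cells of which
    ``K`` are flagged, an ensemble of size ``n`` containing ``k`` flagged
    cells has ``p = P[X >= k]``, ``X ~ Hypergeom(N, K, n)``. Empty ensembles
    are omitted.
    """
    missing = set(assignment.labels) - set(flags)
    if missing:
        raise ValueError(f"flags missing for cells: {sorted(missing)!r}")
    N = len(assignment.labels)
    K = sum(bool(flags[c]) for c in assignment.labels)
    out = {}
    for name in ("neutral", "aversive", "overlap", "remaining"):
        members = assignment.cells_of(name)
        n = len(members)
        if n == 0:
            continue
        k = sum(bool(flags[c]) for c in members)
        out[name] = {
            "n_cells": n,
            "n_flagged": k,
            "fraction": k / n,
            "global_fraction": K / N if N else np.nan,
            "p_enrichment": float(stats.hypergeom.sf(k - 1, N, K, n)),
        }
    return out
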