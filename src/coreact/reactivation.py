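"""Offline ensemble reactivation, recall reactivation index, and
population-vector correlation analyses.

Reactivation is measured at two scales: slow time courses of ensemble mean
activity across an offline session, and cell-identity overlap between recall
sessions and the encoding ensembles. The reactivation index contrasts a
familiar neutral context with a novel one: index = (fraction of neutral-recall
cells previously in the ensemble) - (same fraction during novel exposure), so
positive values mean context-specific reactivation. Population-vector
similarity between encoding and recall uses Kendall's tau-b, a rank
correlation robust to the many tied zeros of deconvolved activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from coreact.bursts import zscore_cells
from coreact.core import ENSEMBLE_LABELS, EnsembleAssignment, EventMatrix, MatchTable

logger = logging.getLogger(__name__)


@dataclass
class ReactivationIndex:
    """Per-ensemble recall reactivation fractions and their difference."""

    neutral_recall: dict = field(default_factory=dict)   # label -> fraction
    novel_recall: dict = field(default_factory=dict)
    index: dict = field(default_factory=dict)            # neutral - novel


@dataclass
class PVCorrelationSummary:
    """Encoding discriminability from a binned population-vector matrix."""

    matrix: np.ndarray = None          # (bins_total, bins_total) correlations
    n_bins_a: int = 0
    intra_a: float = np.nan
    intra_b: float = np.nan
    inter: float = np.nan


def active_cells(matrix: EventMatrix) -> np.ndarray:
    """Cell ids with at least one event in the session."""
    return matrix.cell_ids[np.any(matrix.values > 0, axis=1)]


def zscore_both_axes(values: np.ndarray) -> np.ndarray:
    """Z-score along time (per cell) and then along cells (per frame)."""
    z = zscore_cells(values)
    mu = z.mean(axis=0, keepdims=True)
    sd = z.std(axis=0, keepdims=True)
    sd_flat = sd[0] == 0
    sd[:, sd_flat] = 1.0
    out = (z - mu) / sd
    out[:, sd_flat] = 0.0
    return out


def offline_ensemble_activity(
    matrix: EventMatrix,
    assignment: EnsembleAssignment,
    bin_s: float = 60.0,
) -> dict:
    """Binned mean activity of each ensemble across an offline session.

    The event matrix is z-scored along both axes (time per cell, then cells
    per frame), averaged across the cells of each ensemble, and averaged
    within consecutive ``bin_s`` bins (trailing partial bin dropped). Empty
    ensembles are omitted.
    """
    n_bin = int(round(bin_s * matrix.frame_rate))
    n_full = matrix.n_frames // n_bin
    if n_full < 1:
        raise ValueError("session shorter than one bin")
    z = zscore_both_axes(matrix.values)
    labels = np.asarray([assignment.labels[c] for c in matrix.cell_ids.tolist()])
    out = {}
    for name in ENSEMBLE_LABELS:
        rows = labels == name
        if not rows.any():
            logger.warning("ensemble %r empty; omitted", name)
            continue
        trace = z[rows].mean(axis=0)[: n_full * n_bin]
        out[name] = trace.reshape(n_full, n_bin).mean(axis=1)
    return out


def recall_reactivation_fractions(
    recall_matrix: EventMatrix,
    recall_session: str,
    match_to_neutral_enc: MatchTable,
    match_to_aversive_enc: MatchTable,
) -> dict:
    """Fractions of recall-active cells previously in each encoding ensemble.

    Among cells active (>= 1 event) during the recall session: the fraction
    matched only to neutral encoding, only to aversive encoding, and to both
    (overlap). Fractions need not sum to 1; unmatched recall cells belong to
    no encoding ensemble.
    """
    act = set(active_cells(recall_matrix).tolist())
    if not act:
        raise ValueError("recall session has no active cells")
    in_n = match_to_neutral_enc.matched_ids(recall_session)
    in_a = match_to_aversive_enc.matched_ids(recall_session)
    n = len(act)
    return {
        "neutral": len([c for c in act if c in in_n and c not in in_a]) / n,
        "aversive": len([c for c in act if c in in_a and c not in in_n]) / n,
        "overlap": len([c for c in act if c in in_n and c in in_a]) / n,
    }


def reactivation_index(
    neutral_recall_fracs: dict, novel_recall_fracs: dict
) -> ReactivationIndex:
    """Per-ensemble difference: neutral-recall minus novel-exposure fraction."""
    out = ReactivationIndex(
        neutral_recall=dict(neutral_recall_fracs),
        novel_recall=dict(novel_recall_fracs),
    )
    for k in neutral_recall_fracs:
        out.index[k] = neutral_recall_fracs[k] - novel_recall_fracs.get(k, 0.0)
    return out


def _shared_rows(
    matrix_a: EventMatrix, matrix_b: EventMatrix, match_table: MatchTable,
    session_a: str, session_b: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of cells active in both sessions, aligned via the table."""
    act_a = set(active_cells(matrix_a).tolist())
    act_b = set(active_cells(matrix_b).tolist())
    mapping = match_table.mapping(session_a)
    rows_a, rows_b = [], []
    for ca in sorted(act_a, key=lambda c: matrix_a.cell_index(c)):
        cb = mapping.get(ca)
        if cb is not None and cb in act_b:
            rows_a.append(matrix_a.cell_index(ca))
            rows_b.append(matrix_b.cell_index(cb))
    return np.asarray(rows_a, dtype=int), np.asarray(rows_b, dtype=int)


def encoding_recall_pv_corr(
    encoding_matrix: EventMatrix,
    recall_matrix: EventMatrix,
    match_table: MatchTable,
    encoding_session: str,
    recall_session: str,
    bin_s: float = 30.0,
) -> dict:
    """Mean Kendall's tau between the encoding population vector and binned
    recall population vectors.

    The encoding vector is each shared cell's mean activity over the whole
    encoding session. The recall session is cut into ``bin_s`` bins (trailing
    partial bin dropped) and each bin's mean-activity vector is rank-
    correlated (tau-b) with the encoding vector; the per-bin taus are
    averaged.
    """
    rows_e, rows_r = _shared_rows(
        encoding_matrix, recall_matrix, match_table,
        encoding_session, recall_session,
    )
    if rows_e.size < 2:
        raise ValueError("need >= 2 shared active cells for a correlation")
    enc_vec = encoding_matrix.values[rows_e].mean(axis=1)
    n_bin = int(round(bin_s * recall_matrix.frame_rate))
    n_full = recall_matrix.n_frames // n_bin
    if n_full < 1:
        raise ValueError("recall session shorter than one bin")
    taus = []
    for k in range(n_full):
        rec_vec = recall_matrix.values[
            rows_r, k * n_bin:(k + 1) * n_bin
        ].mean(axis=1)
        tau = stats.kendalltau(enc_vec, rec_vec).statistic
        taus.append(float(tau) if np.isfinite(tau) else 0.0)
    return {"mean_tau": float(np.mean(taus)), "per_bin": taus,
            "n_shared_cells": int(rows_e.size)}


def encoding_pv_matrix(
    neutral_enc: EventMatrix,
    aversive_enc: EventMatrix,
    match_table: MatchTable,
    neutral_session: str,
    aversive_session: str,
    bin_s: float = 30.0,
) -> PVCorrelationSummary:
    """Intra- vs inter-session population-vector correlation matrix.

    Shared active cells are binned at ``bin_s`` in both encoding sessions and
    the full bin x bin Pearson correlation matrix of the concatenation is
    computed. Intra-session means exclude the diagonal self-comparisons; the
    inter-session mean covers the off-diagonal block.
    """
    rows_n, rows_a = _shared_rows(
        neutral_enc, aversive_enc, match_table, neutral_session,
        aversive_session,
    )
    if rows_n.size < 2:
        raise ValueError("need >= 2 shared active cells")

    def _binned(matrix: EventMatrix, rows: np.ndarray) -> np.ndarray:
        n_bin = int(round(bin_s * matrix.frame_rate))
        n_full = matrix.n_frames // n_bin
        if n_full < 1:
            raise ValueError("session shorter than one bin")
        vals = matrix.values[rows, : n_full * n_bin]
        return vals.reshape(rows.size, n_full, n_bin).mean(axis=2)

    va = _binned(neutral_enc, rows_n)   # cells x bins_a
    vb = _binned(aversive_enc, rows_a)
    both = np.concatenate([va, vb], axis=1)
    corr = np.corrcoef(both.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    na = va.shape[1]
    block_a = corr[:na, :na]
    block_b = corr[na:, na:]
    inter = corr[:na, na:]

    def _offdiag_mean(block: np.ndarray) -> float:
        n = block.shape[0]
        if n < 2:
            return np.nan
        return float((block.sum() - np.trace(block)) / (n * (n - 1)))

    return PVCorrelationSummary(
        matrix=corr,
        n_bins_a=na,
        intra_a=_offdiag_mean(block_a),
        intra_b=_offdiag_mean(block_b),
        inter=float(inter.mean()),
    )
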