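"""Linear-SVM discrimination of neutral vs aversive encoding activity.

Frame-by-frame activity vectors of cells active in both encoding sessions are
labelled by context; a linear SVM is fit on a random stratified half of the
vectors and scored on the held-out half, repeated (50 times by default) to
yield a distribution of accuracies, with matched shuffled-label controls.
A variant restricts the cells to 20% bands of chemotag responsiveness to ask
which cell class carries the context signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

from coreact.bursts import zscore_cells
from coreact.core import EventMatrix, MatchTable
from coreact.reactivation import _shared_rows

logger = logging.getLogger(__name__)


@dataclass
class DecodingDataset:
    """Labelled frame vectors with equal frame counts per context.

    ``X`` is ``(2 * n_frames, n_cells)`` with the neutral-context frames
    first; ``y`` holds 0 (neutral) / 1 (aversive); ``cell_ids`` are the
    encoding-session ids of the shared cells (neutral-session side).
    """

    X: np.ndarray
    y: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        classes, counts = np.unique(self.y, return_counts=True)
        if classes.size != 2 or counts[0] != counts[1]:
            raise ValueError("dataset must have two equally sized classes")

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]


@dataclass
class DecodingResult:
    """Held-out accuracies over repeats, plus metadata."""

    accuracies: np.ndarray
    mean_accuracy: float
    params: dict = field(default_factory=dict)


def build_context_dataset(
    neutral_enc: EventMatrix,
    aversive_enc: EventMatrix,
    match_table: MatchTable,
    neutral_session: str,
    aversive_session: str,
    bin_frames: int = 1,
) -> DecodingDataset:
    """Assemble labelled frame vectors from the shared active cells.

    Only cells active in both encoding sessions enter; the longer session is
    trimmed from the end to match the shorter one. ``bin_frames > 1``
    optionally averages consecutive frames (off by default).
    """
    rows_n, rows_a = _shared_rows(
        neutral_enc, aversive_enc, match_table, neutral_session,
        aversive_session,
    )
    if rows_n.size < 2:
        raise ValueError("need >= 2 shared active cells for decoding")
    n_frames = min(neutral_enc.n_frames, aversive_enc.n_frames)
    vn = neutral_enc.values[rows_n, :n_frames]
    va = aversive_enc.values[rows_a, :n_frames]
    if bin_frames > 1:
        n_full = n_frames // bin_frames
        vn = vn[:, : n_full * bin_frames].reshape(
            rows_n.size, n_full, bin_frames).mean(axis=2)
        va = va[:, : n_full * bin_frames].reshape(
            rows_a.size, n_full, bin_frames).mean(axis=2)
    X = np.concatenate([vn.T, va.T], axis=0)
    y = np.concatenate([
        np.zeros(vn.shape[1], dtype=int), np.ones(va.shape[1], dtype=int)
    ])
    return DecodingDataset(
        X=X, y=y, cell_ids=neutral_enc.cell_ids[rows_n]
    )


def _decode(
    X: np.ndarray,
    y: np.ndarray,
    train_frac: float,
    repeats: int,
    seed: int,
    shuffle_labels: bool,
    C: float = 1.0,
    normalize: bool = True,
) -> DecodingResult:
    if normalize:
        X = zscore_cells(X.T).T
    rng = np.random.default_rng(seed)
    accuracies = np.zeros(repeats)
    for r in range(repeats):
        labels = y
        if shuffle_labels:
            labels = rng.permutation(y)
        split_state = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, labels, train_size=train_frac, stratify=labels,
            random_state=split_state,
        )
        clf = LinearSVC(C=C)
        clf.fit(X_tr, y_tr)
        accuracies[r] = clf.score(X_te, y_te)
    return DecodingResult(
        accuracies=accuracies,
        mean_accuracy=float(accuracies.mean()),
        params={
            "train_frac": train_frac, "repeats": repeats, "seed": seed,
            "C": C, "normalize": normalize, "shuffled": shuffle_labels,
        },
    )


def svm_decode(
    dataset: DecodingDataset,
    train_frac: float = 0.5,
    repeats: int = 50,
    seed: int = 0,
    C: float = 1.0,
    normalize: bool = True,
) -> DecodingResult:
    """Stratified split-half linear-SVM decoding, repeated.

    Each repeat draws a random stratified ``train_frac`` split, fits a linear
    SVM (regularization ``C`` at the conventional default) and scores the
    held-out half. Per-cell z-scoring of the frame vectors is applied by
    default (``normalize=False`` disables it). Deterministic under a fixed
    seed.
    """
    return _decode(dataset.X, dataset.y, train_frac, repeats, seed,
                   shuffle_labels=False, C=C, normalize=normalize)


def shuffled_control(
    dataset: DecodingDataset,
    train_frac: float = 0.5,
    repeats: int = 50,
    seed: int = 0,
    C: float = 1.0,
    normalize: bool = True,
) -> DecodingResult:
    """As :func:`svm_decode` with labels permuted independently per repeat."""
    return _decode(dataset.X, dataset.y, train_frac, repeats, seed,
                   shuffle_labels=True, C=C, normalize=normalize)


def decode_by_chemotag_fraction(
    dataset: DecodingDataset,
    chemotag_ranks: dict,
    train_frac: float = 0.5,
    repeats: int = 50,
    seed: int = 0,
    n_bands: int = 5,
) -> dict:
    """Decode separately within 20% bands of chemotag responsiveness.

    Cells are ordered from most to least responsive on the tagging day (cells
    without a rank go last, ties broken by cell id) and split into ``n_bands``
    equal bands; each band is decoded with its own matched shuffled control.
    Bands with fewer than 2 cells are skipped with a warning.
    """
    ids = dataset.cell_ids.tolist()
    worst = max(chemotag_ranks.values(), default=0) + 1
    order = sorted(
        range(len(ids)),
        key=lambda i: (chemotag_ranks.get(ids[i], worst), ids[i]),
    )
    bands = np.array_split(np.asarray(order), n_bands)
    out = {}
    for b, cols in enumerate(bands):
        if cols.size < 2:
            logger.warning("chemotag band %d has < 2 cells; skipped", b)
            continue
        X = dataset.X[:, cols]
        out[b] = {
            "decoded": _decode(X, dataset.y, train_frac, repeats,
                               seed + b, shuffle_labels=False),
            "shuffled": _decode(X, dataset.y, train_frac, repeats,
                                seed + b, shuffle_labels=True),
            "n_cells": int(cols.size),
        }
    return out
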