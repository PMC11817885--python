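"""Iterative majority voting (IMV) across channels and greedy selection.

The per-channel prediction vectors are sorted by accuracy (descending,
stable).  For every pool size k = 3..n the voted vector is the
per-segment majority among the top-k channels, giving n - 2 voted
vectors (59 from 61 channels).  The greedy step then picks, among the
n channel vectors and the n - 2 voted vectors (120 candidates at full
channel count), the one with maximum accuracy.

Both steps consume the true labels, exactly as the protocol specifies;
results derived from them are therefore selection-optimistic and are
labelled as such in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import PredictionVector

__all__ = ["VotedVector", "BestPrediction", "iterative_majority_vote",
           "greedy_select"]


@dataclass
class VotedVector:
    """Majority-vote labels over an accuracy-ordered channel pool."""

    labels: np.ndarray
    pool: list[str]
    accuracy: float

    def __post_init__(self) -> None:
        if len(self.pool) < 3:
            raise ValueError("voting pool must contain at least 3 channels")


@dataclass
class BestPrediction:
    """Greedy winner among channel and voted prediction vectors."""

    labels: np.ndarray
    accuracy: float
    kind: str            # "channel" or "voted"
    source: str          # channel name or "vote@k"
    n_channels_used: int


def iterative_majority_vote(preds: list[PredictionVector],
                            y) -> list[VotedVector]:
    """Voted vectors for every pool size k = 3..n of accuracy-sorted channels.

    Even-pool ties are resolved towards the prediction of the
    highest-accuracy channel in the pool (deterministic and
    accuracy-weighted).
    """
    if len(preds) < 3:
        raise ValueError("iterative majority voting needs at least 3 "
                         "prediction vectors")
    y = np.asarray(y)
    order = sorted(range(len(preds)),
                   key=lambda i: (-preds[i].accuracy, i))  # stable on ties
    sorted_preds = [preds[i] for i in order]
    stacked = np.stack([p.labels for p in sorted_preds])   # (n_ch, n_seg)
    classes = np.unique(stacked)

    voted: list[VotedVector] = []
    for k in range(3, len(sorted_preds) + 1):
        pool = stacked[:k]
        counts = np.stack([(pool == c).sum(axis=0) for c in classes])
        top = counts.max(axis=0)
        tie = (counts == top).sum(axis=0) > 1
        labels = classes[np.argmax(counts, axis=0)]
        labels[tie] = pool[0][tie]  # best channel breaks even splits
        accuracy = float(np.mean(labels == y))
        voted.append(VotedVector(
            labels=labels, pool=[p.channel for p in sorted_preds[:k]],
            accuracy=accuracy))
    return voted


def greedy_select(channel_preds: list[PredictionVector],
                  voted: list[VotedVector], y) -> BestPrediction:
    """Highest-accuracy candidate among channel and voted vectors.

    Ties go to the candidate using the fewest channels, then to channel
    vectors over voted vectors, then to the earlier candidate.
    """
    if not channel_preds and not voted:
        raise ValueError("empty candidate pool")
    y = np.asarray(y)
    candidates: list[BestPrediction] = []
    for p in channel_preds:
        candidates.append(BestPrediction(
            labels=p.labels, accuracy=float(np.mean(p.labels == y)),
            kind="channel", source=p.channel, n_channels_used=1))
    for v in voted:
        candidates.append(BestPrediction(
            labels=v.labels, accuracy=float(np.mean(v.labels == y)),
            kind="voted", source=f"vote@{len(v.pool)}",
            n_channels_used=len(v.pool)))
    kind_rank = {"channel": 0, "voted": 1}
    best_idx = min(
        range(len(candidates)),
        key=lambda i: (-candidates[i].accuracy,
                       candidates[i].n_channels_used,
                       kind_rank[candidates[i].kind],
                       i))
    return candidates[best_idx]
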