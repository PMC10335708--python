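"""Prediction stacking and normalized majority voting.

All base-model probability matrices are collected into a
:class:`PredictionStack`.  The consensus ("metaphase") label of a cell is
the class maximizing the vote count divided by ``L_k`` — the number of
reference subsets whose reference contains class ``k``.  The
normalization lets a class carried by a single reference win with
proportionally fewer raw votes, so reference-specific cell types are not
drowned out by widely shared ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import CellTypeVocabulary, ReferenceSubset


def hard_labels(probs: np.ndarray) -> np.ndarray:
    """Per-cell argmax class index; ties resolve to the lowest index."""
    return np.argmax(probs, axis=1)


def subset_counts(
    subsets: Sequence[ReferenceSubset], vocabulary: CellTypeVocabulary | Sequence[str]
) -> np.ndarray:
    """L_k: how many subsets carry cells of class k.  Every vocabulary
    class must appear in at least one subset."""
    vocab = list(vocabulary.types if isinstance(vocabulary, CellTypeVocabulary) else vocabulary)
    label_sets = [s.label_set() for s in subsets]
    counts = np.array(
        [sum(k in ls for ls in label_sets) for k in vocab], dtype=np.int64
    )
    if np.any(counts == 0):
        missing = [k for k, c in zip(vocab, counts) if c == 0]
        raise AssertionError(
            f"vocabulary classes present in no subset: {missing}"
        )
    return counts


@dataclass
class PredictionStack:
    """All base predictions for one query.

    ``probs`` has shape (subsets, cells, classes); ``hard`` is its argmax;
    ``counts`` is the per-class subset count L.
    """

    probs: np.ndarray
    hard: np.ndarray
    counts: np.ndarray
    vocabulary: list[str]
    subset_names: list[str]

    def __post_init__(self) -> None:
        s, n, k = self.probs.shape
        if self.hard.shape != (s, n):
            raise ValueError("hard labels shape mismatch")
        if self.counts.shape != (k,):
            raise ValueError("counts shape mismatch")
        if np.any(self.counts < 1) or np.any(self.counts > s):
            raise ValueError("subset counts must lie in [1, n_subsets]")
        if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        if not np.array_equal(self.hard, np.argmax(self.probs, axis=2)):
            raise ValueError("hard labels inconsistent with probabilities")

    @property
    def n_subsets(self) -> int:
        return self.probs.shape[0]

    @property
    def n_cells(self) -> int:
        return self.probs.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probs.shape[2]

    @classmethod
    def from_predictions(
        cls,
        prob_list: Sequence[np.ndarray],
        subsets: Sequence[ReferenceSubset],
        vocabulary: CellTypeVocabulary | Sequence[str],
    ) -> "PredictionStack":
        vocab = list(
            vocabulary.types if isinstance(vocabulary, CellTypeVocabulary) else vocabulary
        )
        probs = np.stack(list(prob_list), axis=0)
        return cls(
            probs=probs,
            hard=np.argmax(probs, axis=2),
            counts=subset_counts(subsets, vocab),
            vocabulary=vocab,
            subset_names=[s.name for s in subsets],
        )

    def vote_table(self) -> np.ndarray:
        """Raw vote counts per (cell, class)."""
        s, n, k = self.probs.shape
        table = np.zeros((n, k), dtype=np.float64)
        for model_hard in self.hard:
            table[np.arange(n), model_hard] += 1.0
        return table


def majority_vote(stack: PredictionStack) -> np.ndarray:
    """Consensus class indices by L_k-normalized majority vote."""
    scores = stack.vote_table() / stack.counts[None, :]
    return np.argmax(scores, axis=1)


def vote_labels(stack: PredictionStack) -> np.ndarray:
    """Consensus labels as strings."""
    idx = majority_vote(stack)
    return np.array([stack.vocabulary[i] for i in idx], dtype=object)
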