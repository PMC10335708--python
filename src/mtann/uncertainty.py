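"""Entropy-based per-cell uncertainty metrics for unseen-type detection.

Cells of a type absent from every reference cannot be predicted
confidently, and the disagreement shows up in three complementary ways:

- ``m1`` (intra-model): the average entropy of each base model's own
  probability row — no class dominates within models,
- ``m2`` (inter-model): the entropy of the L_k-normalized average
  probability across models — no class dominates the pooled view,
- ``m3`` (inter-prediction): the entropy of the L_k-normalized hard-vote
  distribution — the models disagree about the winner.

Each metric is min-max scaled to [0, 1] over the query cells and the
ensemble score ``m`` is their average.  All entropies use log base 2.
"""

from __future__ import annotations

import numpy as np

from .containers import UncertaintyScores
from .ensemble import PredictionStack


def entropy(p: np.ndarray) -> float:
    """Shannon entropy (bits) of a probability vector; 0·log0 = 0."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _row_entropies(rows: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rows > 0, rows * np.log2(np.where(rows > 0, rows, 1.0)), 0.0)
    return -terms.sum(axis=-1)


def intra_model_metric(stack: PredictionStack) -> np.ndarray:
    """m1: mean over models of the entropy of each model's probability row."""
    return _row_entropies(stack.probs).mean(axis=0)


def inter_model_metric(stack: PredictionStack) -> np.ndarray:
    """m2: entropy of the row-normalized, L_k-weighted average probability."""
    q = stack.probs.sum(axis=0) / stack.counts[None, :]
    q = q / q.sum(axis=1, keepdims=True)
    return _row_entropies(q)


def inter_prediction_metric(stack: PredictionStack) -> np.ndarray:
    """m3: entropy of the row-normalized, L_k-weighted hard-vote table."""
    q = stack.vote_table() / stack.counts[None, :]
    row_sums = q.sum(axis=1, keepdims=True)
    assert np.all(row_sums > 0), "every cell receives at least one vote"
    q = q / row_sums
    return _row_entropies(q)


def minmax_scale(v: np.ndarray) -> np.ndarray:
    """Linear rescale to [0, 1]; a constant vector maps to all-zero."""
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def ensemble_metric(m1: np.ndarray, m2: np.ndarray, m3: np.ndarray) -> UncertaintyScores:
    """Min-max scale each metric over the query and average them."""
    if not (len(m1) == len(m2) == len(m3)):
        raise ValueError("metric vectors must have equal length")
    m1s, m2s, m3s = minmax_scale(m1), minmax_scale(m2), minmax_scale(m3)
    m = (m1s + m2s + m3s) / 3.0
    return UncertaintyScores(m1=m1, m2=m2, m3=m3, m1s=m1s, m2s=m2s, m3s=m3s, m=m)


def compute_uncertainty(stack: PredictionStack) -> UncertaintyScores:
    return ensemble_metric(
        intra_model_metric(stack),
        inter_model_metric(stack),
        inter_prediction_metric(stack),
    )
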