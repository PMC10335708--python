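"""Benchmark metrics and the leave-one-cell-type-out harness.

Unseen-type identification is scored by AUPRC (unseen cells positive, the
uncertainty score as ranking) and by the F1 of the "unassigned" call;
annotation quality by an accuracy that counts an unseen cell correct only
when it is called "unassigned".  The AR (accuracy-ratio) index compares
two settings across paired tests: wins divided by losses, ties dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from .containers import LabeledDataset

UNASSIGNED = "unassigned"


def auprc(scores: np.ndarray, unseen_mask: np.ndarray) -> float:
    """Area under precision–recall (step integration) for ranking unseen
    cells above shared ones."""
    unseen_mask = np.asarray(unseen_mask, dtype=bool)
    if unseen_mask.all() or not unseen_mask.any():
        raise ValueError("need at least one unseen and one shared cell")
    return float(average_precision_score(unseen_mask, np.asarray(scores, float)))


def f1_unassigned(pred_labels: Sequence[str], unseen_mask: np.ndarray) -> float:
    """F1 of the "unassigned" call against the true unseen mask.

    Conventions for degenerate cases: nothing predicted and nothing true
    -> 1.0; nothing predicted but positives exist (or vice versa) -> 0.0.
    """
    pred = np.asarray(pred_labels, dtype=object) == UNASSIGNED
    true = np.asarray(unseen_mask, dtype=bool)
    tp = float(np.sum(pred & true))
    fp = float(np.sum(pred & ~true))
    fn = float(np.sum(~pred & true))
    if tp == 0:
        return 1.0 if (fp == 0 and fn == 0) else 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def annotation_accuracy(
    pred_labels: Sequence[str],
    true_labels: Sequence[str],
    unseen_mask: np.ndarray,
) -> float:
    """Fraction of cells annotated correctly.

    A shared cell is correct when its predicted label matches the truth;
    an unseen cell is correct only when predicted "unassigned".
    """
    pred = np.asarray(pred_labels, dtype=object)
    true = np.asarray(true_labels, dtype=object)
    unseen = np.asarray(unseen_mask, dtype=bool)
    if not (len(pred) == len(true) == len(unseen)):
        raise ValueError("length mismatch")
    correct = np.where(unseen, pred == UNASSIGNED, pred == true)
    return float(correct.mean())


def ar_index(metric_a: Sequence[float], metric_b: Sequence[float]) -> float | None:
    """#(A>B) / #(A<B) over paired tests; ties excluded.  All ties ->
    None; wins without losses -> +inf."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must match in length")
    wins = int(np.sum(a > b))
    losses = int(np.sum(a < b))
    if wins == 0 and losses == 0:
        return None
    if losses == 0:
        return float("inf")
    return wins / losses


def threshold_from_true_proportion(
    m: np.ndarray, p: float, direction: str = "high"
) -> np.ndarray:
    """Flag the top (or bottom) p-fraction of cells by score.

    Nearest-rank: the k = ceil(p·n) most extreme cells are flagged; ties
    with the boundary value are all flagged (so the mask can exceed k).
    """
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    m = np.asarray(m, dtype=float)
    n = len(m)
    k = int(np.ceil(p * n))
    if k == 0:
        return np.zeros(n, dtype=bool)
    if direction == "high":
        boundary = np.sort(m)[n - k]
        return m >= boundary
    boundary = np.sort(m)[k - 1]
    return m <= boundary


@dataclass
class BenchmarkTest:
    """One leave-one-cell-type-out test: the held-out type is removed from
    every reference, making it unseen for the unchanged query."""

    references: list[LabeledDataset]
    query: LabeledDataset
    held_out_type: str
    unseen_mask: np.ndarray
    p: float


def make_benchmark_tests(
    references: Sequence[LabeledDataset], query: LabeledDataset
) -> list[BenchmarkTest]:
    """One test per cell type shared by all references and the query."""
    if query.labels is None:
        raise ValueError("query must carry true labels for benchmarking")
    shared = set(query.cell_types())
    for ref in references:
        shared &= set(ref.cell_types())
    if not shared:
        raise ValueError("no cell type is shared by every reference and the query")

    tests = []
    for held in sorted(shared):
        reduced = [
            ref.subset_cells(ref.labels != held) for ref in references
        ]
        remaining = set().union(*(set(r.cell_types()) for r in reduced))
        unseen = np.array(
            [l not in remaining for l in query.labels], dtype=bool
        )
        assert all(held not in r.cell_types() for r in reduced)
        tests.append(
            BenchmarkTest(
                references=reduced,
                query=query,
                held_out_type=held,
                unseen_mask=unseen,
                p=float(unseen.mean()),
            )
        )
    return tests
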