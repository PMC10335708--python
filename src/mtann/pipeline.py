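"""End-to-end orchestration: references + query in, annotation out.

``annotate`` wires the five stages together: reference-subset
construction (gene selection × references), base-model training, the
normalized majority vote, the three-part uncertainty score, and the
adaptive Gaussian-mixture "unassigned" call.  One master seed drives
everything; per-model seeds are master + subset index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .base_classifier import TrainedBaseModel, predict_proba, train_base_model
from .containers import AnnotationResult, CellTypeVocabulary, LabeledDataset
from .ensemble import PredictionStack, vote_labels
from .evaluation import (
    annotation_accuracy,
    auprc,
    f1_unassigned,
    make_benchmark_tests,
)
from .gene_selection import ALL_METHODS, build_reference_subsets
from .threshold import call_unassigned, finalize_annotation
from .uncertainty import compute_uncertainty


@dataclass
class AnnotateConfig:
    """Pipeline hyperparameters with desk-scale defaults."""

    methods: tuple[str, ...] = ALL_METHODS
    n_top: int = 500
    gene_floor: int = 10
    lam: float = 1.0
    epochs: int = 30
    batch_size: int = 128
    lr: float = 1e-3
    hidden: tuple[int, int] = (256, 64)
    mean_cutoff: float = 0.6
    strict_cutoff_only: bool = False
    moderated: bool = True


def annotate(
    references: Sequence[LabeledDataset],
    query: LabeledDataset,
    config: AnnotateConfig | None = None,
    seed: int = 0,
    gene_lists: dict[str, list[str]] | None = None,
) -> AnnotationResult:
    """Annotate a query against multiple labeled references.

    Returns an :class:`AnnotationResult` whose ``stack`` retains all base
    predictions for downstream inspection (per-model accuracy, ablations).
    """
    cfg = config or AnnotateConfig()
    vocabulary = CellTypeVocabulary.from_references(references)

    subsets = build_reference_subsets(
        references,
        query,
        methods=cfg.methods,
        n_top=cfg.n_top,
        gene_floor=cfg.gene_floor,
        gene_lists=gene_lists,
        moderated=cfg.moderated,
    )

    models: list[TrainedBaseModel] = []
    probs = []
    for s_idx, subset in enumerate(subsets):
        model = train_base_model(
            subset,
            vocabulary,
            lam=cfg.lam,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            lr=cfg.lr,
            hidden=cfg.hidden,
            seed=seed + s_idx,
        )
        models.append(model)
        probs.append(predict_proba(model, subset.query_matrix))

    stack = PredictionStack.from_predictions(probs, subsets, vocabulary)
    votes = vote_labels(stack)
    scores = compute_uncertainty(stack)
    mask, diagnostics = call_unassigned(
        scores.m,
        seed=seed,
        mean_cutoff=cfg.mean_cutoff,
        strict_cutoff_only=cfg.strict_cutoff_only,
    )
    final = finalize_annotation(votes, mask)

    return AnnotationResult(
        cells=list(query.cells),
        labels=final,
        vote_labels=votes,
        unassigned=mask,
        scores=scores,
        diagnostics=diagnostics,
        vocabulary=vocabulary.types,
        stack=stack,
        model_manifests=[
            {"subset": s.name} | m.manifest() for s, m in zip(subsets, models)
        ],
    )


def base_model_accuracies(
    stack: PredictionStack,
    true_labels: Sequence[str],
    unseen_mask: np.ndarray,
) -> np.ndarray:
    """Annotation accuracy of each base model's hard labels on its own
    (base models never predict "unassigned")."""
    out = []
    for s in range(stack.n_subsets):
        labels = np.array([stack.vocabulary[i] for i in stack.hard[s]], dtype=object)
        out.append(annotation_accuracy(labels, true_labels, unseen_mask))
    return np.array(out)


def run_benchmark(
    references: Sequence[LabeledDataset],
    query: LabeledDataset,
    config: AnnotateConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-cell-type-out benchmark: one row of metrics per test."""
    rows = []
    for test in make_benchmark_tests(references, query):
        result = annotate(test.references, test.query, config=config, seed=seed)
        rows.append(
            benchmark_row(result, test.query.labels, test.unseen_mask)
            | {"held_out_type": test.held_out_type, "p": test.p}
        )
    return pd.DataFrame(rows)


def benchmark_row(
    result: AnnotationResult,
    true_labels: np.ndarray,
    unseen_mask: np.ndarray,
) -> dict:
    """Standard metric set for one annotated query with known truth."""
    base_acc = base_model_accuracies(result.stack, true_labels, unseen_mask)
    return {
        "auprc": auprc(result.scores.m, unseen_mask),
        "f1": f1_unassigned(result.labels, unseen_mask),
        "accuracy": annotation_accuracy(result.labels, true_labels, unseen_mask),
        "unassigned_fraction": float(result.unassigned.mean()),
        "median_base_accuracy": float(np.median(base_acc)),
        "auprc_m1": auprc(result.scores.m1s, unseen_mask),
        "auprc_m2": auprc(result.scores.m2s, unseen_mask),
        "auprc_m3": auprc(result.scores.m3s, unseen_mask),
    }
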