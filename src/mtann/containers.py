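"""Core in-memory containers shared across the annotation pipeline.

Expression data travels through the pipeline as a :class:`LabeledDataset`,
a thin cells × genes matrix wrapper that tracks which preprocessing stage
it has reached.  The stage machine only moves forward:

    raw -> libnorm -> selected -> log -> zscore -> minmax

Library-size normalization happens on the full gene set; gene selection
restricts the matrix; log / z-score / min-max are applied afterwards, per
gene-selected view.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class Stage(enum.IntEnum):
    """Preprocessing stages, ordered; transitions are forward-only."""

    raw = 0
    libnorm = 1
    selected = 2
    log = 3
    zscore = 4
    minmax = 5


class StageError(RuntimeError):
    """Raised when a preprocessing step is applied out of order."""


@dataclass
class LabeledDataset:
    """A cells × genes expression matrix with ids and optional labels.

    Parameters
    ----------
    matrix
        Dense nonnegative float array, one row per cell.
    genes
        Unique gene identifiers, one per column.
    cells
        Unique cell identifiers, one per row.
    labels
        Optional per-cell cell-type strings (references have them, the
        query usually does not).
    stage
        Preprocessing stage reached so far.
    """

    matrix: np.ndarray
    genes: list[str]
    cells: list[str]
    labels: np.ndarray | None = None
    stage: Stage = Stage.raw

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        self._validate()

    def _validate(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-D (cells × genes)")
        n, p = self.matrix.shape
        if len(self.cells) != n:
            raise ValueError(f"{len(self.cells)} cell ids for {n} matrix rows")
        if len(self.genes) != p:
            raise ValueError(f"{len(self.genes)} gene ids for {p} matrix columns")
        if len(set(self.genes)) != p:
            raise ValueError("gene identifiers must be unique")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError(
                f"labels length {len(self.labels)} does not match {n} cells"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")

    # -- convenience ------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def cell_types(self) -> list[str]:
        """Distinct labels present, lexicographically sorted."""
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return sorted(set(self.labels))

    def with_matrix(self, matrix: np.ndarray, stage: Stage) -> "LabeledDataset":
        """Copy with a new matrix and an advanced stage."""
        if stage < self.stage:
            raise StageError(
                f"stage transition {self.stage.name} -> {stage.name} goes backwards"
            )
        return replace(self, matrix=matrix, stage=stage)

    def subset_genes(self, genes: Sequence[str]) -> "LabeledDataset":
        """Restrict to ``genes`` in the given order (all must be present)."""
        index = {g: i for i, g in enumerate(self.genes)}
        cols = [index[g] for g in genes]
        # gene selection on normalized data advances the stage machine;
        # quality filtering of raw data does not
        stage = Stage.selected if self.stage == Stage.libnorm else self.stage
        return replace(
            self, matrix=self.matrix[:, cols], genes=list(genes), stage=stage
        )

    def subset_cells(self, mask: np.ndarray) -> "LabeledDataset":
        mask = np.asarray(mask, dtype=bool)
        labels = self.labels[mask] if self.labels is not None else None
        return replace(
            self,
            matrix=self.matrix[mask],
            cells=[c for c, keep in zip(self.cells, mask) if keep],
            labels=labels,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cells, columns=self.genes)


def require_stage(ds: LabeledDataset, *allowed: Stage) -> None:
    if ds.stage not in allowed:
        names = "/".join(s.name for s in allowed)
        raise StageError(f"expected stage {names}, dataset is at {ds.stage.name}")


@dataclass
class CellTypeVocabulary:
    """Ordered union of cell types across references.

    ``types`` is lexicographically sorted so the global class ordering is
    deterministic; ``per_reference_presence`` records which reference
    contributes which type.
    """

    types: list[str]
    per_reference_presence: pd.DataFrame  # references × types, bool

    @classmethod
    def from_references(cls, references: Sequence[LabeledDataset]) -> "CellTypeVocabulary":
        if not references:
            raise ValueError("at least one reference required")
        per_ref = [set(r.cell_types()) for r in references]
        types = sorted(set().union(*per_ref))
        table = pd.DataFrame(
            [[t in s for t in types] for s in per_ref],
            index=[f"ref{i}" for i in range(len(references))],
            columns=types,
            dtype=bool,
        )
        return cls(types=types, per_reference_presence=table)

    def index_of(self, label: str) -> int:
        try:
            return self.types.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in vocabulary") from None

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.index_of(l) for l in labels], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.types)


@dataclass
class ReferenceSubset:
    """One (reference, gene-selection-method) view of the data.

    Both matrices are restricted to ``gene_set`` (selected genes present in
    the query) in identical order and fully preprocessed (log, z-score,
    min-max — each matrix standardized on its own cells).
    """

    ref_index: int
    method: str
    gene_set: list[str]
    ref_matrix: np.ndarray
    query_matrix: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.ref_matrix.shape[1] != len(self.gene_set):
            raise ValueError("reference matrix does not match gene_set")
        if self.query_matrix.shape[1] != len(self.gene_set):
            raise ValueError("query matrix does not match gene_set")
        if len(self.labels) != self.ref_matrix.shape[0]:
            raise ValueError("labels do not match reference cells")

    @property
    def name(self) -> str:
        return f"ref{self.ref_index}_{self.method}"

    def label_set(self) -> set[str]:
        return set(self.labels)


@dataclass
class UncertaintyScores:
    """Per-cell unseen-type uncertainty metrics.

    ``m1``/``m2``/``m3`` are the raw intra-model, inter-model and
    inter-prediction entropies; ``m1s``/``m2s``/``m3s`` their min-max
    scaled versions; ``m`` their average, in [0, 1].
    """

    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray
    m1s: np.ndarray
    m2s: np.ndarray
    m3s: np.ndarray
    m: np.ndarray

    def to_frame(self, cells: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"m1": self.m1, "m2": self.m2, "m3": self.m3, "m": self.m}
        )
        if cells is not None:
            df.index = list(cells)
        return df


@dataclass
class ThresholdDiagnostics:
    """Outcome of the adaptive Gaussian-mixture threshold selection."""

    chosen_k: int
    aic_per_k: dict[int, float]
    group_means: np.ndarray
    uncertain_groups: list[int]
    implied_threshold: float | None

    def to_dict(self) -> dict:
        return {
            "chosen_k": int(self.chosen_k),
            "aic_per_k": {int(k): float(v) for k, v in self.aic_per_k.items()},
            "group_means": [float(x) for x in self.group_means],
            "uncertain_groups": [int(g) for g in self.uncertain_groups],
            "implied_threshold": (
                None if self.implied_threshold is None else float(self.implied_threshold)
            ),
        }


@dataclass
class AnnotationResult:
    """Final per-cell annotation with uncertainty diagnostics."""

    cells: list[str]
    labels: np.ndarray            # final labels, "unassigned" where masked
    vote_labels: np.ndarray       # majority-vote labels before masking
    unassigned: np.ndarray        # boolean mask
    scores: UncertaintyScores
    diagnostics: ThresholdDiagnostics
    vocabulary: list[str] = field(default_factory=list)
    stack: object | None = None  # PredictionStack, kept for base-model analysis
    model_manifests: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cells,
                "predicted_label": self.labels,
                "vote_label": self.vote_labels,
                "m1": self.scores.m1,
                "m2": self.scores.m2,
                "m3": self.scores.m3,
                "m": self.scores.m,
                "unassigned": self.unassigned,
            }
        )
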