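"""Synthetic multi-reference scRNA-seq collections for testing the
annotation pipeline end to end.

The generator emulates the statistical structure the method assumes:
cell-type-specific marker programs shared across datasets, multiplicative
per-(dataset, gene) batch factors standing in for technology differences,
negative-binomial counts with zero inflation, and a query from a distinct
batch that may contain a cell type absent from every reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LabeledDataset
from .io import read_expression

NB_DISPERSION = 0.3  # var = mu + dispersion * mu^2


@dataclass
class SimulationConfig:
    """Parameters of one synthetic collection.

    ``marker_effect`` is the log-scale mean shift of a type's markers;
    ``batch_shift_sd`` the log-sd of per-(dataset, gene) multiplicative
    batch factors; ``dropout_rate`` the zero-inflation probability.
    """

    n_refs: int = 3
    n_types: int = 5
    cells_per_type: int = 50
    n_genes: int = 2000
    n_markers_per_type: int = 30
    marker_effect: float = 1.5
    batch_shift_sd: float = 0.2
    dropout_rate: float = 0.1
    cell_size_sd: float = 0.2
    base_mean: float = 0.5
    types_per_ref: list[list[str]] | None = None
    unseen_type: str | None = None
    unseen_fraction: float = 0.2
    query_type_weights: list[float] | None = None
    seed: int = 0

    def type_names(self) -> list[str]:
        return [f"type{i}" for i in range(self.n_types)]

    def validate(self) -> None:
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValueError("more marker genes requested than genes available")
        for rate in (self.dropout_rate, self.unseen_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.unseen_type is not None and self.unseen_type not in self.type_names():
            raise ValueError(f"unseen type {self.unseen_type!r} not in type list")
        if self.types_per_ref is not None:
            if len(self.types_per_ref) != self.n_refs:
                raise ValueError("types_per_ref must list one set per reference")
            known = set(self.type_names())
            for ts in self.types_per_ref:
                if not set(ts) <= known:
                    raise ValueError("types_per_ref contains unknown types")
        if self.query_type_weights is not None:
            if len(self.query_type_weights) != self.n_types:
                raise ValueError("query_type_weights must list one weight per type")
            if min(self.query_type_weights) < 0 or sum(self.query_type_weights) <= 0:
                raise ValueError("query_type_weights must be nonnegative, not all zero")


EASY = SimulationConfig()
HARD = SimulationConfig(
    n_genes=800,
    cells_per_type=30,
    n_markers_per_type=15,
    marker_effect=0.8,
    batch_shift_sd=0.4,
    dropout_rate=0.3,
)
PRESETS = {"easy": EASY, "hard": HARD}


@dataclass
class QueryTruth:
    labels: np.ndarray
    unseen_mask: np.ndarray
    p: float


def _sample_counts(
    rng: np.random.Generator,
    mean: np.ndarray,
    n_cells: int,
    dropout: float,
    cell_size_sd: float,
) -> np.ndarray:
    """Zero-inflated negative-binomial counts for one homogeneous block."""
    size = np.exp(rng.normal(0.0, cell_size_sd, size=(n_cells, 1)))
    mu = np.maximum(mean[None, :] * size, 1e-8)
    r = 1.0 / NB_DISPERSION
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p).astype(np.float64)
    if dropout > 0:
        counts *= rng.random(counts.shape) >= dropout
    return counts


def simulate_collection(
    cfg: SimulationConfig,
) -> tuple[list[LabeledDataset], LabeledDataset, QueryTruth]:
    """Draw references and a query from one marker model, separate batches.

    References exclude ``cfg.unseen_type`` (when set); the query contains
    it at fraction ``cfg.unseen_fraction``, with the remaining cells split
    evenly across the other types.  Fully determined by ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    types = cfg.type_names()
    genes = [f"g{j:05d}" for j in range(cfg.n_genes)]

    base = np.exp(rng.normal(np.log(cfg.base_mean), 1.0, size=cfg.n_genes))
    marker_pool = rng.permutation(cfg.n_genes)[: cfg.n_markers_per_type * cfg.n_types]
    type_mean = np.tile(base, (cfg.n_types, 1))
    for t in range(cfg.n_types):
        markers = marker_pool[
            t * cfg.n_markers_per_type : (t + 1) * cfg.n_markers_per_type
        ]
        type_mean[t, markers] *= np.exp(cfg.marker_effect)

    if cfg.types_per_ref is not None:
        ref_types = [list(ts) for ts in cfg.types_per_ref]
    else:
        ref_types = [list(types) for _ in range(cfg.n_refs)]
    if cfg.unseen_type is not None:
        ref_types = [[t for t in ts if t != cfg.unseen_type] for ts in ref_types]

    def make_dataset(
        type_list: list[str], counts_per_type: dict[str, int], prefix: str
    ) -> LabeledDataset:
        batch = np.exp(rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_genes))
        blocks, labels = [], []
        for t in type_list:
            n = counts_per_type[t]
            if n == 0:
                continue
            mean = type_mean[types.index(t)] * batch
            blocks.append(
                _sample_counts(rng, mean, n, cfg.dropout_rate, cfg.cell_size_sd)
            )
            labels.extend([t] * n)
        matrix = np.vstack(blocks)
        cells = [f"{prefix}_c{i:05d}" for i in range(matrix.shape[0])]
        return LabeledDataset(
            matrix=matrix, genes=genes, cells=cells,
            labels=np.array(labels, dtype=object),
        )

    references = [
        make_dataset(ts, {t: cfg.cells_per_type for t in ts}, prefix=f"ref{i}")
        for i, ts in enumerate(ref_types)
    ]

    n_query = cfg.cells_per_type * cfg.n_types

    def split_counts(total: int, names: list[str]) -> dict[str, int]:
        """Apportion cells across types by the configured weights."""
        if cfg.query_type_weights is not None:
            w = np.array(
                [cfg.query_type_weights[types.index(t)] for t in names], float
            )
        else:
            w = np.ones(len(names))
        w = w / w.sum()
        counts = np.floor(w * total).astype(int)
        counts[np.argmax(w)] += total - counts.sum()
        return dict(zip(names, counts))

    if cfg.unseen_type is not None:
        n_unseen = int(round(cfg.unseen_fraction * n_query))
        shared = [t for t in types if t != cfg.unseen_type]
        counts = split_counts(n_query - n_unseen, shared)
        counts[cfg.unseen_type] = n_unseen
        query = make_dataset(types, counts, prefix="query")
    else:
        query = make_dataset(types, split_counts(n_query, types), "query")

    unseen_mask = (
        query.labels == cfg.unseen_type
        if cfg.unseen_type is not None
        else np.zeros(query.n_cells, dtype=bool)
    )
    truth = QueryTruth(
        labels=query.labels.copy(),
        unseen_mask=np.asarray(unseen_mask, dtype=bool),
        p=float(np.mean(unseen_mask)),
    )
    return references, query, truth


def write_fixture(
    references: list[LabeledDataset],
    query: LabeledDataset,
    out_dir: str | Path,
    format: str = "csv",
) -> dict[str, Path]:
    """Write a collection to disk in a form the readers round-trip exactly.

    CSV: one ``<name>.csv`` (cells × genes) plus ``<name>_labels.tsv``.
    MTX: one directory per dataset with ``matrix.mtx`` (genes × cells)
    and ``genes.tsv``/``barcodes.tsv`` sidecars.
    """
    import scipy.io
    import scipy.sparse

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_one(ds: LabeledDataset, name: str) -> None:
        if format == "csv":
            path = out_dir / f"{name}.csv"
            ds.to_frame().to_csv(path)
            paths[name] = path
        elif format == "mtx":
            sub = out_dir / name
            sub.mkdir(exist_ok=True)
            scipy.io.mmwrite(
                sub / "matrix.mtx", scipy.sparse.csr_matrix(ds.matrix.T)
            )
            pd.Series(ds.genes).to_csv(
                sub / "genes.tsv", sep="\t", header=False, index=False
            )
            pd.Series(ds.cells).to_csv(
                sub / "barcodes.tsv", sep="\t", header=False, index=False
            )
            paths[name] = sub / "matrix.mtx"
        else:
            raise ValueError(f"unsupported fixture format {format!r}")
        if ds.labels is not None:
            lp = out_dir / f"{name}_labels.tsv"
            pd.DataFrame({"cell": ds.cells, "label": ds.labels}).to_csv(
                lp, sep="\t", header=False, index=False
            )
            paths[f"{name}_labels"] = lp

    for i, ref in enumerate(references):
        write_one(ref, f"ref{i}")
    write_one(query, "query")
    return paths


def read_fixture(
    fixture_dir: str | Path, n_refs: int, format: str = "csv"
) -> tuple[list[LabeledDataset], LabeledDataset]:
    """Load a collection written by :func:`write_fixture`."""
    fixture_dir = Path(fixture_dir)
    datasets = []
    for name in [f"ref{i}" for i in range(n_refs)] + ["query"]:
        labels = fixture_dir / f"{name}_labels.tsv"
        labels_path = labels if labels.exists() else None
        if format == "csv":
            ds = read_expression(fixture_dir / f"{name}.csv", labels_path=labels_path)
        else:
            ds = read_expression(
                fixture_dir / name / "matrix.mtx", format="mtx",
                labels_path=labels_path,
            )
        datasets.append(ds)
    return datasets[:-1], datasets[-1]
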