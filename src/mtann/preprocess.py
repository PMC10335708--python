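"""Dataset filtering and the four-step expression preprocessing recipe.

The recipe: (1) library-size normalization to 10 000 counts per cell on the
raw data, then — after gene selection — (2) log2(x+1), (3) per-gene z-score,
(4) per-gene min-max to [0, 1].  The stage machine in
:mod:`mtann.containers` enforces this ordering.
"""

from __future__ import annotations

import numpy as np

from .containers import LabeledDataset, Stage, require_stage

SCALE_FACTOR = 10_000.0


def filter_dataset(
    ds: LabeledDataset,
    min_cells_per_type: int = 10,
    min_cells_per_gene: int = 100,
    min_genes_per_cell: int = 100,
) -> LabeledDataset:
    """Apply quality filters, in order: rare cell types, sparse genes,
    sparse cells.

    Cell types with fewer than ``min_cells_per_type`` cells are dropped,
    then genes expressed (value > 0) in fewer than ``min_cells_per_gene``
    cells, then cells expressing fewer than ``min_genes_per_cell`` genes.
    Set a threshold to 0 to skip that filter.
    """
    require_stage(ds, Stage.raw)
    out = ds
    if min_cells_per_type > 0:
        if out.labels is None:
            raise ValueError("cell-type filter requires labels")
        types, counts = np.unique(out.labels, return_counts=True)
        keep_types = set(types[counts >= min_cells_per_type])
        mask = np.array([l in keep_types for l in out.labels], dtype=bool)
        out = out.subset_cells(mask)
    if out.n_cells == 0:
        raise ValueError("all cells removed by the cell-type filter")

    if min_cells_per_gene > 0:
        expressed_in = (out.matrix > 0).sum(axis=0)
        keep = expressed_in >= min_cells_per_gene
        if not keep.any():
            raise ValueError(
                f"all {out.n_genes} genes removed (gene filter at "
                f"{min_cells_per_gene} cells)"
            )
        out = out.subset_genes([g for g, k in zip(out.genes, keep) if k])

    if min_genes_per_cell > 0:
        genes_per_cell = (out.matrix > 0).sum(axis=1)
        mask = genes_per_cell >= min_genes_per_cell
        if not mask.any():
            raise ValueError(
                f"all {out.n_cells} cells removed (cell filter at "
                f"{min_genes_per_cell} genes)"
            )
        out = out.subset_cells(mask)
    return out


def library_size_normalize(ds: LabeledDataset) -> LabeledDataset:
    """Scale each cell to a total of 10 000 counts."""
    require_stage(ds, Stage.raw)
    totals = ds.matrix.sum(axis=1)
    zero = np.where(totals <= 0)[0]
    if zero.size:
        names = ", ".join(ds.cells[i] for i in zero[:5])
        raise ValueError(f"cells with zero total expression: {names}")
    out = ds.matrix / totals[:, None] * SCALE_FACTOR
    return ds.with_matrix(out, Stage.libnorm)


def log_transform(ds: LabeledDataset) -> LabeledDataset:
    """Elementwise log2(x + 1)."""
    require_stage(ds, Stage.libnorm, Stage.selected)
    return ds.with_matrix(np.log2(ds.matrix + 1.0), Stage.log)


def zscore_genes(ds: LabeledDataset) -> LabeledDataset:
    """Per-gene standardization to mean 0, sd 1 (population sd).

    Constant genes carry no information and are mapped to all-zero.
    """
    require_stage(ds, Stage.log)
    mean = ds.matrix.mean(axis=0)
    sd = ds.matrix.std(axis=0)  # ddof=0
    centered = ds.matrix - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return ds.with_matrix(out, Stage.zscore)


def minmax_genes(ds: LabeledDataset) -> LabeledDataset:
    """Per-gene linear rescale to [0, 1]; constant genes map to 0."""
    require_stage(ds, Stage.zscore)
    lo = ds.matrix.min(axis=0)
    hi = ds.matrix.max(axis=0)
    span = hi - lo
    out = np.where(span > 0, (ds.matrix - lo) / np.where(span > 0, span, 1.0), 0.0)
    return ds.with_matrix(out, Stage.minmax)


def preprocess_selected(ds: LabeledDataset) -> LabeledDataset:
    """log2 -> z-score -> min-max on a gene-selected, library-normalized view."""
    return minmax_genes(zscore_genes(log_transform(ds)))
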