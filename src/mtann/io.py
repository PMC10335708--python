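"""Readers and writers for expression matrices and annotation results.

Supported input formats: dense CSV/TSV (cells in rows by default, genes in
columns), MatrixMarket MTX triplets with ``genes.tsv``/``barcodes.tsv``
sidecars (genes × cells orientation, as emitted by common 10x-style
exporters), and AnnData ``.h5ad`` containers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import AnnotationResult, LabeledDataset

_FORMATS = {"csv", "tsv", "mtx", "h5ad"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _dedupe_genes(matrix: np.ndarray, genes: list[str]) -> tuple[np.ndarray, list[str]]:
    """Sum columns sharing a gene id, keeping first-occurrence order."""
    if len(set(genes)) == len(genes):
        return matrix, genes
    warnings.warn("duplicate gene identifiers found; summing duplicates")
    order: dict[str, int] = {}
    for g in genes:
        order.setdefault(g, len(order))
    out = np.zeros((matrix.shape[0], len(order)), dtype=np.float64)
    for j, g in enumerate(genes):
        out[:, order[g]] += matrix[:, j]
    return out, list(order)


def read_labels(path: str | Path) -> np.ndarray:
    """Read per-cell labels: one label per line, or a two-column
    (cell id, label) TSV/CSV whose second column is used."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    col = df.columns[-1]
    return df[col].to_numpy(dtype=object)


def read_expression(
    path: str | Path,
    format: str | None = None,
    labels_path: str | Path | None = None,
    genes_in_rows: bool = False,
    label_column: str = "cell_type",
) -> LabeledDataset:
    """Read an expression matrix into a raw-stage :class:`LabeledDataset`.

    Parameters
    ----------
    path
        Matrix file. For ``mtx``, sidecars ``genes.tsv`` and
        ``barcodes.tsv`` must sit in the same directory.
    format
        One of ``csv``, ``tsv``, ``mtx``, ``h5ad``; inferred from the
        extension when omitted.
    labels_path
        Optional per-cell label file (ignored for ``h5ad`` if the obs
        column ``label_column`` is present).
    genes_in_rows
        For CSV/TSV: transpose after reading (matrix stored genes × cells).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    labels = None
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        # read the header ourselves: pandas mangles duplicate column names,
        # which must instead be summed downstream
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        df = pd.read_csv(path, sep=sep, index_col=0, header=None, skiprows=1)
        df.columns = header
        if genes_in_rows:
            df = df.T
        matrix = df.to_numpy(dtype=np.float64)
        genes = [str(g) for g in df.columns]
        cells = [str(c) for c in df.index]
    elif fmt == "mtx":
        genes_file = path.parent / "genes.tsv"
        cells_file = path.parent / "barcodes.tsv"
        for sidecar in (genes_file, cells_file):
            if not sidecar.exists():
                raise FileNotFoundError(f"missing MTX sidecar {sidecar}")
        m = scipy.io.mmread(path)
        matrix = np.asarray(
            m.todense() if scipy.sparse.issparse(m) else m, dtype=np.float64
        ).T  # stored genes × cells
        genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_file, sep="\t", header=None)[0].astype(str).tolist()
        if matrix.shape != (len(cells), len(genes)):
            raise ValueError(
                f"MTX shape {m.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} cells)"
            )
    elif fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        x = adata.X
        matrix = np.asarray(
            x.todense() if scipy.sparse.issparse(x) else x, dtype=np.float64
        )
        genes = [str(g) for g in adata.var_names]
        cells = [str(c) for c in adata.obs_names]
        if label_column in adata.obs:
            labels = adata.obs[label_column].to_numpy(dtype=object)
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    if np.any(matrix < 0):
        raise ValueError("expression matrix contains negative values")
    matrix, genes = _dedupe_genes(matrix, genes)

    if labels_path is not None:
        labels = read_labels(labels_path)
        if len(labels) != matrix.shape[0]:
            raise ValueError(
                f"labels file has {len(labels)} rows for {matrix.shape[0]} cells"
            )
    return LabeledDataset(matrix=matrix, genes=genes, cells=cells, labels=labels)


def apply_rename_map(labels: np.ndarray, path: str | Path) -> np.ndarray:
    """Apply a two-column (old label, new label) TSV rename map.

    Harmonizing cell-type terminology across references (e.g. "PP" vs
    "gamma") is the user's responsibility; this is the hook for it.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    mapping = dict(zip(df[0], df[1]))
    return np.array([mapping.get(l, l) for l in labels], dtype=object)


def write_annotation(result: AnnotationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write annotations TSV, threshold diagnostics JSON and a run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "annotation.tsv"
    result.to_frame().to_csv(tsv, sep="\t", index=False)
    thr = out_dir / "threshold.json"
    thr.write_text(json.dumps(result.diagnostics.to_dict(), indent=2))
    report = out_dir / "report.json"
    report.write_text(
        json.dumps(
            {
                "n_cells": len(result.cells),
                "n_unassigned": int(result.unassigned.sum()),
                "unassigned_fraction": float(result.unassigned.mean()),
                "vocabulary": result.vocabulary,
            },
            indent=2,
        )
    )
    if result.model_manifests:
        models_dir = out_dir / "models"
        models_dir.mkdir(exist_ok=True)
        for manifest in result.model_manifests:
            (models_dir / f"{manifest['subset']}.json").write_text(
                json.dumps(manifest, indent=2)
            )
    return {"annotation": tsv, "threshold": thr, "report": report}


def save_stack(stack, path: str | Path) -> None:
    """Persist a prediction stack as a compressed array container with a
    JSON vocabulary sidecar."""
    path = Path(path)
    np.savez_compressed(
        path, probs=stack.probs, hard=stack.hard, counts=stack.counts
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"vocabulary": stack.vocabulary, "subset_names": stack.subset_names}
        )
    )


def load_stack(path: str | Path):
    from .ensemble import PredictionStack

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return PredictionStack(
        probs=arrays["probs"],
        hard=arrays["hard"],
        counts=arrays["counts"],
        vocabulary=meta["vocabulary"],
        subset_names=meta["subset_names"],
    )
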