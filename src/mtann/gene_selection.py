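"""Eight per-gene informativeness scores and reference-subset construction.

Five supervised scores compare each cell type against the rest and keep the
best (most discriminative) comparison per gene:

- ``DE``  — moderated t statistic on the mean (empirical-Bayes shrunken
  residual variance, limma-style; plain Welch t available as a fallback),
- ``DV``  — Bartlett variance-homogeneity statistic,
- ``DD``  — two-sample Kolmogorov–Smirnov statistic,
- ``DP``  — Pearson chi-squared on the 2×2 detection table (value > 0),
- ``BI``  — bimodality index, δ·sqrt(π(1−π)) from a two-component fit.

Three unsupervised highly-variable-gene scores:

- ``GC``   — Gini coefficient of expression across cells,
- ``Disp`` — mean-bin-normalized log variance/mean dispersion,
- ``Vst``  — standardized variance after a variance-stabilizing
  mean–variance trend fit, clipped at sqrt(n).

Supervised scores operate on log-transformed library-normalized data,
unsupervised scores on library-normalized (pre-log) data.  Each selected
gene set is intersected with the query's genes to form one
:class:`~mtann.containers.ReferenceSubset` per (reference, method) pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .containers import LabeledDataset, ReferenceSubset, Stage, require_stage
from .preprocess import library_size_normalize, log_transform, preprocess_selected

SUPERVISED_METHODS = ("DE", "DV", "DD", "DP", "BI")
UNSUPERVISED_METHODS = ("GC", "Disp", "Vst")
ALL_METHODS = SUPERVISED_METHODS + UNSUPERVISED_METHODS


@dataclass
class GeneScoreTable:
    genes: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


# ---------------------------------------------------------------------------
# supervised scores (one-vs-rest, aggregated by max across cell types)
# ---------------------------------------------------------------------------


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on 1/trigamma, monotone)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _moderated_t(x1: np.ndarray, x0: np.ndarray, moderated: bool = True) -> np.ndarray:
    """|t| per gene for a two-group comparison with pooled, optionally
    empirical-Bayes-shrunken, residual variance."""
    n1, n0 = x1.shape[0], x0.shape[0]
    d = n1 + n0 - 2
    m1, m0 = x1.mean(axis=0), x0.mean(axis=0)
    ss = x1.var(axis=0, ddof=0) * n1 + x0.var(axis=0, ddof=0) * n0
    s2 = ss / d
    scale = np.sqrt(1.0 / n1 + 1.0 / n0)

    if not moderated:
        v = x1.var(axis=0, ddof=1) / n1 + x0.var(axis=0, ddof=1) / n0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(m1 - m0) / np.sqrt(v)
        return np.nan_to_num(t, nan=0.0, posinf=0.0)

    ok = s2 > 0
    if ok.sum() < 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(m1 - m0) / (np.sqrt(s2) * scale)
        return np.nan_to_num(t, nan=0.0, posinf=0.0)

    # Smyth moment estimator of the scaled-inv-chisq variance prior
    e = np.log(s2[ok]) - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    resid = e_var - float(_trigamma(d / 2.0))
    if resid > 0:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s0_sq = np.inf, float(np.exp(e_mean))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m0) / (np.sqrt(s2_post) * scale)
    return np.nan_to_num(t, nan=0.0, posinf=0.0)


def _bartlett(x1: np.ndarray, x0: np.ndarray) -> np.ndarray:
    n1, n0 = x1.shape[0], x0.shape[0]
    s1 = x1.var(axis=0, ddof=1)
    s0 = x0.var(axis=0, ddof=1)
    sp = ((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2)
    c = 1.0 + (1.0 / 3.0) * (
        1.0 / (n1 - 1) + 1.0 / (n0 - 1) - 1.0 / (n1 + n0 - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (
            (n1 + n0 - 2) * np.log(sp)
            - (n1 - 1) * np.log(s1)
            - (n0 - 1) * np.log(s0)
        ) / c
    stat[(s1 <= 0) | (s0 <= 0)] = 0.0
    return np.nan_to_num(stat, nan=0.0, posinf=0.0)


def _ks_statistic(x: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized two-sample KS statistic per gene column.

    Evaluates |F1 - F2| at block boundaries of the pooled sorted values so
    ties are handled exactly as in the classical statistic.
    """
    n, p = x.shape
    n1 = int(in_group.sum())
    n0 = n - n1
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    member = in_group[order]  # (n, p) bool
    c1 = np.cumsum(member, axis=0) / n1
    c0 = np.cumsum(~member, axis=0) / n0
    diff = np.abs(c1 - c0)
    valid = np.ones((n, p), dtype=bool)
    valid[:-1] = sorted_vals[:-1] != sorted_vals[1:]
    diff[~valid] = 0.0
    return diff.max(axis=0)


def _detection_chi2(x: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Pearson chi-squared (no continuity correction) on the 2×2 table of
    detection (value > 0) vs group membership, per gene."""
    det = x > 0
    n = x.shape[0]
    n1 = int(in_group.sum())
    n0 = n - n1
    a = det[in_group].sum(axis=0).astype(float)      # detected, in group
    c = det[~in_group].sum(axis=0).astype(float)     # detected, rest
    b, d = n1 - a, n0 - c
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = num / den
    return np.nan_to_num(stat, nan=0.0, posinf=0.0)


def _two_means_1d(x: np.ndarray, n_iter: int = 30) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-cluster 1-D k-means over gene columns.

    Returns (low means, high means, high-cluster membership).  Centers are
    initialized at the 10th/90th percentiles, which is deterministic.
    """
    lo = np.quantile(x, 0.1, axis=0)
    hi = np.quantile(x, 0.9, axis=0)
    same = hi <= lo
    hi = np.where(same, lo + 1.0, hi)  # degenerate columns resolved later
    for _ in range(n_iter):
        high = np.abs(x - hi) < np.abs(x - lo)  # ties to low cluster
        cnt_hi = high.sum(axis=0)
        cnt_lo = x.shape[0] - cnt_hi
        sum_hi = np.where(high, x, 0.0).sum(axis=0)
        sum_lo = np.where(~high, x, 0.0).sum(axis=0)
        new_hi = np.where(cnt_hi > 0, sum_hi / np.maximum(cnt_hi, 1), hi)
        new_lo = np.where(cnt_lo > 0, sum_lo / np.maximum(cnt_lo, 1), lo)
        if np.allclose(new_hi, hi) and np.allclose(new_lo, lo):
            hi, lo = new_hi, new_lo
            break
        hi, lo = new_hi, new_lo
    high = np.abs(x - hi) < np.abs(x - lo)
    return lo, hi, high


def _bimodality_index(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    lo, hi, high = _two_means_1d(x)
    cnt_hi = high.sum(axis=0)
    pi = cnt_hi / n
    dev = np.where(high, x - hi, x - lo)
    sigma = np.sqrt((dev**2).sum(axis=0) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.abs(hi - lo) / sigma
        bi = delta * np.sqrt(pi * (1.0 - pi))
    bi[(cnt_hi == 0) | (cnt_hi == n) | (sigma <= 0)] = 0.0
    return np.nan_to_num(bi, nan=0.0, posinf=0.0)


def score_genes_supervised(
    ds: LabeledDataset,
    method: str,
    labels: np.ndarray | None = None,
    moderated: bool = True,
) -> GeneScoreTable:
    """Score genes with a label-aware method on log-stage data.

    One-vs-rest comparisons are run for every cell type and a gene's score
    is the maximum across comparisons (markers are type-specific).  The
    bimodality index is fit once per gene on all cells; labels gate only
    the precondition.
    """
    if method not in SUPERVISED_METHODS:
        raise ValueError(f"unknown supervised method {method!r}")
    require_stage(ds, Stage.log)
    y = ds.labels if labels is None else np.asarray(labels, dtype=object)
    if y is None:
        raise ValueError("supervised gene selection requires labels")
    types, counts = np.unique(y, return_counts=True)
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    small = types[counts < 2]
    if small.size:
        raise ValueError(f"cell types with fewer than 2 cells: {list(small)}")

    x = ds.matrix
    if method == "BI":
        scores = _bimodality_index(x)
    else:
        per_type = np.zeros((len(types), x.shape[1]))
        for t_idx, t in enumerate(types):
            in_group = y == t
            if method == "DE":
                per_type[t_idx] = _moderated_t(x[in_group], x[~in_group], moderated)
            elif method == "DV":
                per_type[t_idx] = _bartlett(x[in_group], x[~in_group])
            elif method == "DD":
                per_type[t_idx] = _ks_statistic(x, in_group)
            elif method == "DP":
                per_type[t_idx] = _detection_chi2(x, in_group)
        scores = per_type.max(axis=0)

    scores[~np.any(x > 0, axis=0)] = 0.0  # all-zero genes are uninformative
    return GeneScoreTable(genes=list(ds.genes), scores=scores, method=method)


# ---------------------------------------------------------------------------
# unsupervised scores (on library-normalized, pre-log data)
# ---------------------------------------------------------------------------


def _gini(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    s = np.sort(x, axis=0)
    idx = np.arange(1, n + 1)[:, None]
    totals = s.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = ((2 * idx - n - 1) * s).sum(axis=0) / (n * totals)
    return np.nan_to_num(g, nan=0.0)


def _dispersion_norm(x: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-bin-normalized log dispersion (Seurat 'dispersion' flavor).

    Dispersion is log(var/mean) of normalized expression; genes are binned
    into ``n_bins`` equal-width bins of log1p(mean) and the dispersion is
    z-scored within each bin (single-gene bins map to 1 when the
    dispersion is nonzero, matching the reference recipe).
    """
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    mean_safe = np.where(mean == 0, 1e-12, mean)
    disp = var / mean_safe
    with np.errstate(divide="ignore"):
        disp = np.where(disp == 0, np.nan, disp)
        log_disp = np.log(disp)
    log_mean = np.log1p(mean)

    df = pd.DataFrame({"mean": log_mean, "disp": log_disp})
    df["bin"] = pd.cut(df["mean"], bins=n_bins)
    grouped = df.groupby("bin", observed=True)["disp"]
    stats = grouped.agg(avg="mean", dev="std")
    single = stats["dev"].isnull()
    stats.loc[single, "dev"] = stats.loc[single, "avg"]
    stats.loc[single, "avg"] = 0.0
    avg = df["bin"].map(stats["avg"]).to_numpy(dtype=float)
    dev = df["bin"].map(stats["dev"]).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = (log_disp - avg) / dev
    return np.nan_to_num(norm, nan=0.0, posinf=0.0, neginf=0.0)


def _vst_standardized_variance(x: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Clipped standardized variance after a lowess mean–variance trend fit.

    The trend log10(var) ~ log10(mean) is fit on genes with positive mean
    and variance; per-cell standardized values are clipped at sqrt(n) and
    their (uncentered) variance is the score.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    n = x.shape[0]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    score = np.zeros(x.shape[1])
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 3:
        return score
    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    fitted = lowess(ly, lx, frac=span, return_sorted=False)
    sd_exp = np.sqrt(10.0**fitted)
    clip = np.sqrt(n)
    z = (x[:, ok] - mean[ok]) / sd_exp
    np.clip(z, -clip, clip, out=z)
    score[ok] = (z**2).sum(axis=0) / (n - 1)
    return score


def score_genes_unsupervised(ds: LabeledDataset, method: str) -> GeneScoreTable:
    """Score genes with a label-free highly-variable-gene method."""
    if method not in UNSUPERVISED_METHODS:
        raise ValueError(f"unknown unsupervised method {method!r}")
    require_stage(ds, Stage.libnorm, Stage.raw)
    if ds.n_cells < 2:
        raise ValueError("need at least two cells")
    x = ds.matrix
    if method == "GC":
        scores = _gini(x)
    elif method == "Disp":
        scores = _dispersion_norm(x)
    else:
        scores = _vst_standardized_variance(x)
    scores[~np.any(x > 0, axis=0)] = 0.0
    return GeneScoreTable(genes=list(ds.genes), scores=scores, method=method)


def score_genes(
    libnorm: LabeledDataset,
    logged: LabeledDataset,
    method: str,
    moderated: bool = True,
) -> GeneScoreTable:
    """Dispatch to the right scorer with the right input stage."""
    if method in SUPERVISED_METHODS:
        return score_genes_supervised(logged, method, moderated=moderated)
    return score_genes_unsupervised(libnorm, method)


# ---------------------------------------------------------------------------
# selection and subset construction
# ---------------------------------------------------------------------------


def select_top_genes(
    table: GeneScoreTable, n_top: int, threshold: float | None = None
) -> list[str]:
    """Pick the ``n_top`` highest-scoring genes (stable: ties keep input
    order).  Passing ``threshold`` switches to score-cutoff selection."""
    if len(table.genes) == 0:
        raise ValueError("empty score table")
    if threshold is not None:
        return [g for g, s in zip(table.genes, table.scores) if s >= threshold]
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > len(table.genes):
        warnings.warn(
            f"n_top={n_top} exceeds {len(table.genes)} genes; returning all"
        )
        n_top = len(table.genes)
    order = np.argsort(-table.scores, kind="stable")[:n_top]
    order = np.sort(order)  # keep input gene order within the selection
    return [table.genes[i] for i in order]


def build_reference_subsets(
    references: Sequence[LabeledDataset],
    query: LabeledDataset,
    methods: Sequence[str] = ALL_METHODS,
    n_top: int = 500,
    gene_floor: int = 10,
    gene_lists: dict[str, list[str]] | None = None,
    moderated: bool = True,
) -> list[ReferenceSubset]:
    """Build one fully preprocessed subset per (reference, method) pair.

    Each reference is library-normalized, scored per method, its top
    ``n_top`` genes intersected with the query's genes, and both matrices
    restricted to that gene set then log/z-score/min-max transformed
    (each matrix standardized on its own cells).  Subsets whose gene set
    falls below ``gene_floor`` are dropped with a warning.

    ``gene_lists`` maps a method name to a user-supplied gene list that
    replaces computed selection for that method.
    """
    if not references:
        raise ValueError("at least one reference required")
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown gene-selection method {m!r}")

    query_ln = query if query.stage >= Stage.libnorm else library_size_normalize(query)
    query_genes = set(query.genes)

    subsets: list[ReferenceSubset] = []
    for i, ref in enumerate(references):
        if ref.labels is None:
            raise ValueError(f"reference {i} has no labels")
        ref_ln = ref if ref.stage >= Stage.libnorm else library_size_normalize(ref)
        ref_log = log_transform(ref_ln)
        for method in methods:
            if gene_lists and method in gene_lists:
                selected = [g for g in gene_lists[method] if g in set(ref.genes)]
            else:
                table = score_genes(ref_ln, ref_log, method, moderated=moderated)
                selected = select_top_genes(table, n_top)
            gene_set = [g for g in selected if g in query_genes]
            if len(gene_set) < gene_floor:
                warnings.warn(
                    f"subset ref{i}/{method} dropped: only {len(gene_set)} "
                    f"genes shared with the query (floor {gene_floor})"
                )
                continue
            ref_view = preprocess_selected(ref_ln.subset_genes(gene_set))
            query_view = preprocess_selected(query_ln.subset_genes(gene_set))
            subsets.append(
                ReferenceSubset(
                    ref_index=i,
                    method=method,
                    gene_set=gene_set,
                    ref_matrix=ref_view.matrix,
                    query_matrix=query_view.matrix,
                    labels=ref.labels.copy(),
                )
            )
    if not subsets:
        raise ValueError("all reference subsets were dropped (gene floor)")
    return subsets
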