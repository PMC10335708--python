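"""Autoencoder-regularized base classifiers, one per reference subset.

Each base model shares an encoder between a linear softmax classifier head
and a mirrored decoder.  The training objective is

    L = L_ce + lambda * L_re

where ``L_ce`` is the cross-entropy of the classifier on the labeled
reference cells and ``L_re`` is the mean-squared reconstruction error of
*both* reference and query cells — the query participates in training only
through reconstruction, never through pseudo-labels.  Probabilities are
produced over the global cell-type vocabulary (the union across
references); classes a reference never saw receive no supervision from it
but still get softmax mass, which the vote normalization downweights.

The network is a small dense NumPy implementation (manual backprop, Adam)
— exactly reproducible from a seed, and fast at the few-hundred-cell,
few-hundred-gene scale of one reference subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import CellTypeVocabulary, ReferenceSubset


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(
    probs: np.ndarray, labels: Sequence[str], vocabulary: Sequence[str]
) -> float:
    """Mean negative log-likelihood (natural log) of the true classes."""
    vocab = list(vocabulary)
    idx = []
    for l in labels:
        if l not in vocab:
            raise ValueError(f"label {l!r} outside vocabulary")
        idx.append(vocab.index(l))
    p = probs[np.arange(len(idx)), idx]
    return float(-np.mean(np.log(p)))


def reconstruction_loss(
    xhat_ref: np.ndarray,
    x_ref: np.ndarray,
    xhat_query: np.ndarray,
    x_query: np.ndarray,
) -> float:
    """Frobenius MSE of reference plus query reconstructions, each
    normalized by its own cell count times the gene count."""
    if xhat_ref.shape != x_ref.shape or xhat_query.shape != x_query.shape:
        raise ValueError("reconstruction shapes do not match inputs")
    term_r = np.sum((xhat_ref - x_ref) ** 2) / x_ref.size
    term_q = np.sum((xhat_query - x_query) ** 2) / x_query.size
    return float(term_r + term_q)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class AutoencoderClassifier:
    """Dense encoder (p -> h1 -> h2), linear classifier (h2 -> K) and
    mirrored decoder (h2 -> h1 -> p), ReLU activations."""

    def __init__(
        self,
        n_genes: int,
        n_classes: int,
        hidden: tuple[int, int] = (256, 64),
        seed: int = 0,
    ):
        self.n_genes, self.n_classes, self.hidden = n_genes, n_classes, hidden
        rng = np.random.default_rng(seed)
        h1, h2 = hidden

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        self.params: dict[str, np.ndarray] = {
            "We1": glorot(n_genes, h1), "be1": np.zeros(h1),
            "We2": glorot(h1, h2), "be2": np.zeros(h2),
            "Wc": glorot(h2, n_classes), "bc": np.zeros(n_classes),
            "Wd1": glorot(h2, h1), "bd1": np.zeros(h1),
            "Wd2": glorot(h1, n_genes), "bd2": np.zeros(n_genes),
        }

    # -- forward ---------------------------------------------------------

    def encode(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        h1 = np.maximum(x @ p["We1"] + p["be1"], 0.0)
        return np.maximum(h1 @ p["We2"] + p["be2"], 0.0)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        return softmax(self.encode(x) @ p["Wc"] + p["bc"])

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        d1 = np.maximum(self.encode(x) @ p["Wd1"] + p["bd1"], 0.0)
        return d1 @ p["Wd2"] + p["bd2"]

    # -- training --------------------------------------------------------

    def _forward_cache(self, x: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        a1 = x @ p["We1"] + p["be1"]
        h1 = np.maximum(a1, 0.0)
        a2 = h1 @ p["We2"] + p["be2"]
        z = np.maximum(a2, 0.0)
        a3 = z @ p["Wd1"] + p["bd1"]
        d1 = np.maximum(a3, 0.0)
        xhat = d1 @ p["Wd2"] + p["bd2"]
        return {"x": x, "a1": a1, "h1": h1, "a2": a2, "z": z,
                "a3": a3, "d1": d1, "xhat": xhat}

    def _backprop_decoder(
        self, cache: dict[str, np.ndarray], dxhat: np.ndarray,
        grads: dict[str, np.ndarray],
    ) -> np.ndarray:
        """Accumulate decoder grads; return the gradient wrt the embedding."""
        p = self.params
        grads["Wd2"] += cache["d1"].T @ dxhat
        grads["bd2"] += dxhat.sum(axis=0)
        dd1 = (dxhat @ p["Wd2"].T) * (cache["a3"] > 0)
        grads["Wd1"] += cache["z"].T @ dd1
        grads["bd1"] += dd1.sum(axis=0)
        return dd1 @ p["Wd1"].T

    def _backprop_encoder(
        self, cache: dict[str, np.ndarray], dz: np.ndarray,
        grads: dict[str, np.ndarray],
    ) -> None:
        p = self.params
        dz = dz * (cache["a2"] > 0)
        grads["We2"] += cache["h1"].T @ dz
        grads["be2"] += dz.sum(axis=0)
        dh1 = (dz @ p["We2"].T) * (cache["a1"] > 0)
        grads["We1"] += cache["x"].T @ dh1
        grads["be1"] += dh1.sum(axis=0)

    def train_step(
        self,
        x_ref: np.ndarray,
        y_ref: np.ndarray,
        x_query: np.ndarray,
        lam: float,
        optimizer: _Adam,
    ) -> float:
        """One joint gradient step; returns the batch objective value."""
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        cr = self._forward_cache(x_ref)
        logits = cr["z"] @ p["Wc"] + p["bc"]
        probs = softmax(logits)
        n_r = x_ref.shape[0]
        ce = float(-np.mean(np.log(probs[np.arange(n_r), y_ref] + 1e-300)))

        onehot = np.zeros_like(probs)
        onehot[np.arange(n_r), y_ref] = 1.0
        dlogits = (probs - onehot) / n_r
        grads["Wc"] += cr["z"].T @ dlogits
        grads["bc"] += dlogits.sum(axis=0)
        dz_ref = dlogits @ p["Wc"].T

        re_ref = float(np.sum((cr["xhat"] - x_ref) ** 2) / x_ref.size)
        dxhat_r = lam * 2.0 * (cr["xhat"] - x_ref) / x_ref.size
        dz_ref = dz_ref + self._backprop_decoder(cr, dxhat_r, grads)
        self._backprop_encoder(cr, dz_ref, grads)

        cq = self._forward_cache(x_query)
        re_q = float(np.sum((cq["xhat"] - x_query) ** 2) / x_query.size)
        dxhat_q = lam * 2.0 * (cq["xhat"] - x_query) / x_query.size
        dz_q = self._backprop_decoder(cq, dxhat_q, grads)
        self._backprop_encoder(cq, dz_q, grads)

        optimizer.step(p, grads)
        return ce + lam * (re_ref + re_q)


@dataclass
class TrainedBaseModel:
    """A trained base classifier plus everything needed to reuse it."""

    net: AutoencoderClassifier
    genes: list[str]
    vocabulary: list[str]
    seed: int
    training_log: list[float] = field(default_factory=list)
    initial_loss: float = float("nan")
    final_loss: float = float("nan")

    def manifest(self) -> dict:
        return {
            "genes": self.genes,
            "vocabulary": self.vocabulary,
            "seed": self.seed,
            "initial_loss": self.initial_loss,
            "final_loss": self.final_loss,
            "training_log": self.training_log,
        }


def _full_objective(
    net: AutoencoderClassifier,
    x_ref: np.ndarray,
    y_idx: np.ndarray,
    x_query: np.ndarray,
    lam: float,
) -> float:
    probs = net.predict_proba(x_ref)
    ce = float(-np.mean(np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-300)))
    re = reconstruction_loss(
        net.reconstruct(x_ref), x_ref, net.reconstruct(x_query), x_query
    )
    return ce + lam * re


def train_base_model(
    subset: ReferenceSubset,
    vocabulary: CellTypeVocabulary | Sequence[str],
    lam: float = 1.0,
    epochs: int = 30,
    batch_size: int = 128,
    lr: float = 1e-3,
    hidden: tuple[int, int] = (256, 64),
    seed: int = 0,
) -> TrainedBaseModel:
    """Train one base model on a reference subset.

    The classifier head spans the global vocabulary.  Mini-batches pair a
    slice of reference cells (classification + reconstruction) with a
    cycling slice of query cells (reconstruction only).  Fully
    deterministic given ``seed``.
    """
    vocab = list(vocabulary.types if isinstance(vocabulary, CellTypeVocabulary) else vocabulary)
    if len(set(subset.labels)) < 2:
        raise ValueError("reference subset contains a single class")
    label_to_idx = {l: k for k, l in enumerate(vocab)}
    try:
        y_idx = np.array([label_to_idx[l] for l in subset.labels], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"label {err} outside vocabulary") from None

    x_ref, x_query = subset.ref_matrix, subset.query_matrix
    net = AutoencoderClassifier(
        n_genes=len(subset.gene_set), n_classes=len(vocab), hidden=hidden, seed=seed
    )
    opt = _Adam(net.params, lr=lr)
    rng = np.random.default_rng(seed + 1)

    initial = _full_objective(net, x_ref, y_idx, x_query, lam)
    n_r, n_q = x_ref.shape[0], x_query.shape[0]
    log: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n_r)
        q_order = rng.permutation(n_q)
        q_pos = 0
        batch_losses = []
        for start in range(0, n_r, batch_size):
            rows = order[start : start + batch_size]
            q_take = min(len(rows), n_q)
            if q_pos + q_take > n_q:
                q_order = rng.permutation(n_q)
                q_pos = 0
            q_rows = q_order[q_pos : q_pos + q_take]
            q_pos += q_take
            loss = net.train_step(x_ref[rows], y_idx[rows], x_query[q_rows], lam, opt)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss ({loss}) in subset {subset.name}"
                )
            batch_losses.append(loss)
        log.append(float(np.mean(batch_losses)))
    final = _full_objective(net, x_ref, y_idx, x_query, lam)

    return TrainedBaseModel(
        net=net,
        genes=list(subset.gene_set),
        vocabulary=vocab,
        seed=seed,
        training_log=log,
        initial_loss=initial,
        final_loss=final,
    )


def predict_proba(
    model: TrainedBaseModel,
    x_query: np.ndarray,
    genes: Sequence[str] | None = None,
) -> np.ndarray:
    """Query probabilities over the model's vocabulary (rows sum to 1)."""
    if genes is not None and list(genes) != model.genes:
        raise ValueError("query gene list does not match the model's genes")
    if x_query.shape[1] != len(model.genes):
        raise ValueError(
            f"query has {x_query.shape[1]} genes, model expects {len(model.genes)}"
        )
    return model.net.predict_proba(x_query)
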