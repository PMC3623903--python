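"""Linear-chain conditional random field over the three DHB labels.

The model scores a label path y for an observation sequence x as

    score(y | x) = sum_i  w[f, y_i]  (f active at position i)
                 + sum_i  T[y_i, y_{i+1}]

with P(y|x) = exp(score) / Z(x).  Features are the categorical identifiers
produced by :mod:`hingecrf.features`; each carries one weight per label.
Transitions are label-pair parameters independent of the observations.

Training maximizes the L2-penalized conditional log-likelihood

    sum_n log P(y_n | x_n)  -  ||w||^2 / (2 sigma^2)

by L-BFGS from a zero start; the objective is concave, so the optimum does
not depend on initialization.  Inference uses the scaled forward-backward
recursion (Rabiner normalization) for posterior marginals and the Viterbi
recursion for the argmax path, with ties broken toward the lower label
code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .features import FeatureSequence
from .labels import LabelString
from .profile import CODE_OF_COL, COL_OF_CODE

N_LABELS = 3


@dataclass
class TrainConfig:
    l2_sigma: float = 1.0
    max_iter: int = 200
    grad_tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l2_sigma <= 0 or self.grad_tol <= 0:
            raise ValueError("l2_sigma and grad_tol must be positive")


@dataclass
class CRFModel:
    """Feature vocabulary plus a flat weight vector.

    The weight of (feature f, label s) lives at ``3*feature_index[f] + s``;
    the 9 transition weights follow the feature block, row-major by
    (from_label, to_label).
    """

    feature_index: dict[str, int]
    weights: np.ndarray
    history: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    @property
    def W(self) -> np.ndarray:
        return self.weights[: 3 * self.n_features].reshape(self.n_features, 3)

    @property
    def T(self) -> np.ndarray:
        return self.weights[3 * self.n_features :].reshape(3, 3)

    def encode(self, x: FeatureSequence) -> np.ndarray:
        """Map feature ids to vocabulary rows; unseen features become the
        padding row (index n_features, weight 0)."""
        pad = self.n_features
        return np.array(
            [[self.feature_index.get(f, pad) for f in feats] for feats in x],
            dtype=np.intp,
        ).reshape(len(x), -1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "hingecrf-crf-1",
                "labels": [0, 1, 2],
                "feature_index": self.feature_index,
                "weights": self.weights.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CRFModel":
        obj = json.loads(text)
        if obj.get("format") != "hingecrf-crf-1":
            raise ValueError("unrecognized model format")
        return cls(
            feature_index={str(k): int(v) for k, v in obj["feature_index"].items()},
            weights=np.asarray(obj["weights"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CRFModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class MarginalMatrix:
    """L x 3 posterior marginals, columns ordered (domain, hinge, boundary)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 3:
            raise ValueError("marginals must be L x 3")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("marginal rows must sum to 1")
        if values.min() < -1e-12 or values.max() > 1 + 1e-12:
            raise ValueError("marginal entries must lie in [0,1]")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.shape[0])

    def by_code(self) -> np.ndarray:
        """Columns reordered to label-code order (domain, boundary, hinge)."""
        return self.values[:, COL_OF_CODE]


def _node_scores(model: CRFModel, X: np.ndarray) -> np.ndarray:
    W_pad = np.vstack([model.W, np.zeros((1, 3))])
    return W_pad[X].sum(axis=1)


def _forward_backward(S: np.ndarray, T: np.ndarray):
    """Scaled forward-backward.

    Returns (log_Z, node_marginals, edge_marginals) where edge_marginals has
    shape (L-1, 3, 3).
    """
    L = S.shape[0]
    m = S.max(axis=1, keepdims=True)
    e = np.exp(S - m)
    M = np.exp(T)
    alpha = np.empty((L, 3))
    c = np.empty(L)
    a = e[0].copy()
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for i in range(1, L):
        a = (alpha[i - 1] @ M) * e[i]
        c[i] = a.sum()
        alpha[i] = a / c[i]
    log_z = float(np.log(c).sum() + m.sum())
    beta = np.empty((L, 3))
    beta[L - 1] = 1.0
    for i in range(L - 2, -1, -1):
        beta[i] = (M @ (e[i + 1] * beta[i + 1])) / c[i + 1]
    node = alpha * beta
    node /= node.sum(axis=1, keepdims=True)
    if L > 1:
        edge = (
            alpha[:-1, :, None]
            * M[None, :, :]
            * (e[1:] * beta[1:])[:, None, :]
            / c[1:, None, None]
        )
        edge /= edge.sum(axis=(1, 2), keepdims=True)
    else:
        edge = np.zeros((0, 3, 3))
    return log_z, node, edge


def log_partition(model: CRFModel, x: FeatureSequence) -> float:
    X = model.encode(x)
    log_z, _, _ = _forward_backward(_node_scores(model, X), model.T)
    return log_z


def posterior_marginals(model: CRFModel, x: FeatureSequence) -> MarginalMatrix:
    """Per-position P(y_i = s | x), columns (domain, hinge, boundary)."""
    X = model.encode(x)
    _, node, _ = _forward_backward(_node_scores(model, X), model.T)
    return MarginalMatrix(node[:, CODE_OF_COL])


def viterbi_path(model: CRFModel, x: FeatureSequence) -> LabelString:
    """Argmax label path; ties broken toward the lower label code."""
    X = model.encode(x)
    S = _node_scores(model, X)
    T = model.T
    L = S.shape[0]
    delta = S[0].copy()
    back = np.zeros((L, 3), dtype=np.int8)
    for i in range(1, L):
        cand = delta[:, None] + T  # cand[prev, cur]
        back[i] = np.argmax(cand, axis=0)  # first max -> lowest code
        delta = cand[back[i], np.arange(3)] + S[i]
    path = np.empty(L, dtype=np.int8)
    path[L - 1] = int(np.argmax(delta))
    for i in range(L - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return LabelString(path, arity=3)


def sequence_log_likelihood(model: CRFModel, x: FeatureSequence, y: LabelString) -> float:
    X = model.encode(x)
    S = _node_scores(model, X)
    codes = y.codes
    score = float(S[np.arange(len(x)), codes].sum())
    if len(x) > 1:
        score += float(model.T[codes[:-1], codes[1:]].sum())
    log_z, _, _ = _forward_backward(S, model.T)
    return score - log_z


class _Batch:
    """Training sequences padded to a common length for vectorized
    forward-backward across the whole dataset."""

    def __init__(self, Xs: list[np.ndarray], ys: list[np.ndarray], n_feats: int):
        self.n_feats = n_feats
        self.lengths = np.array([X.shape[0] for X in Xs], dtype=np.intp)
        N, Lmax, K = len(Xs), int(self.lengths.max()), Xs[0].shape[1]
        self.X = np.full((N, Lmax, K), n_feats, dtype=np.intp)  # pad row
        self.y = np.zeros((N, Lmax), dtype=np.intp)
        for i, (X, y) in enumerate(zip(Xs, ys)):
            self.X[i, : X.shape[0]] = X
            self.y[i, : y.shape[0]] = y
        self.mask = np.arange(Lmax)[None, :] < self.lengths[:, None]
        self.edge_mask = np.arange(Lmax - 1)[None, :] < (self.lengths - 1)[:, None]


def _batch_forward_backward(S: np.ndarray, T: np.ndarray, batch: _Batch):
    """Scaled forward-backward over a padded batch.

    Returns (log_z per sequence, node marginals (N,Lmax,3), edge marginals
    (N,Lmax-1,3,3)); entries at padded positions are meaningless and must be
    read through the batch masks.
    """
    N, Lmax, _ = S.shape
    mask = batch.mask
    m = S.max(axis=2, keepdims=True)
    e = np.exp(S - m)
    M = np.exp(T)
    alpha = np.zeros((N, Lmax, 3))
    c = np.ones((N, Lmax))
    a = e[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, Lmax):
        active = mask[:, t]
        if not active.any():
            break
        a = (alpha[:, t - 1] @ M) * e[:, t]
        ct = a.sum(axis=1)
        c[:, t] = np.where(active, ct, 1.0)
        alpha[:, t] = np.where(active[:, None], a / np.maximum(ct, 1e-300)[:, None], 0.0)
    log_z = (np.log(c) * mask).sum(axis=1) + (m[:, :, 0] * mask).sum(axis=1)
    beta = np.zeros((N, Lmax, 3))
    beta[np.arange(N), batch.lengths - 1] = 1.0
    for t in range(Lmax - 2, -1, -1):
        interior = mask[:, t + 1]  # position t+1 exists => recursion applies at t
        if not interior.any():
            continue
        b = (e[:, t + 1] * beta[:, t + 1]) @ M.T / c[:, t + 1, None]
        beta[:, t] = np.where(interior[:, None], b, beta[:, t])
    node = alpha * beta
    node_sum = np.maximum(node.sum(axis=2, keepdims=True), 1e-300)
    node = node / node_sum
    if Lmax > 1:
        edge = (
            alpha[:, :-1, :, None]
            * M[None, None, :, :]
            * (e[:, 1:] * beta[:, 1:])[:, :, None, :]
            / np.maximum(c[:, 1:, None, None], 1e-300)
        )
        edge_sum = np.maximum(edge.sum(axis=(2, 3), keepdims=True), 1e-300)
        edge = edge / edge_sum
    else:
        edge = np.zeros((N, 0, 3, 3))
    return log_z, node, edge


def _objective(w: np.ndarray, batch: _Batch, sigma: float):
    """Negative penalized log-likelihood and its gradient (batched)."""
    n_feats = batch.n_feats
    W = w[: 3 * n_feats].reshape(n_feats, 3)
    T = w[3 * n_feats :].reshape(3, 3)
    W_pad = np.vstack([W, np.zeros((1, 3))])
    N, Lmax, K = batch.X.shape
    S = W_pad[batch.X].sum(axis=2)
    log_z, node, edge = _batch_forward_backward(S, T, batch)
    rows = np.arange(Lmax)[None, :]
    obs_node = np.where(batch.mask, S[np.arange(N)[:, None], rows, batch.y], 0.0)
    obs_trans = np.where(batch.edge_mask, T[batch.y[:, :-1], batch.y[:, 1:]], 0.0)
    nll = float(log_z.sum() - obs_node.sum() - obs_trans.sum())
    # gradient: expected minus observed counts
    diff = np.where(batch.mask[:, :, None], node, 0.0)
    onehot = np.zeros_like(diff)
    onehot[np.arange(N)[:, None], rows, batch.y] = 1.0
    diff -= np.where(batch.mask[:, :, None], onehot, 0.0)
    flatX = batch.X.ravel()
    gW = np.empty((n_feats + 1, 3))
    for s in range(3):
        gW[:, s] = np.bincount(
            flatX, weights=np.repeat(diff[:, :, s].ravel(), K), minlength=n_feats + 1
        )
    gT = (edge * batch.edge_mask[:, :, None, None]).sum(axis=(0, 1))
    obs_pairs = 3 * batch.y[:, :-1] + batch.y[:, 1:]
    gT -= np.bincount(
        obs_pairs.ravel(), weights=batch.edge_mask.ravel().astype(float), minlength=9
    ).reshape(3, 3)
    grad = np.concatenate([gW[:-1].ravel(), gT.ravel()])
    nll += float(w @ w) / (2.0 * sigma * sigma)
    grad += w / (sigma * sigma)
    return nll, grad


def build_vocabulary(dataset: list[tuple[FeatureSequence, LabelString]]) -> dict[str, int]:
    vocab: dict[str, int] = {}
    for x, _y in dataset:
        for feats in x:
            for f in feats:
                if f not in vocab:
                    vocab[f] = len(vocab)
    return vocab


def train_crf(
    dataset: list[tuple[FeatureSequence, LabelString]],
    cfg: TrainConfig = TrainConfig(),
) -> CRFModel:
    """Fit weights by penalized maximum likelihood (L-BFGS, zero start)."""
    if not dataset:
        raise ValueError("training dataset is empty")
    for x, y in dataset:
        if len(x) != len(y):
            raise ValueError("feature sequence and label string lengths differ")
        if y.arity != 3:
            raise ValueError("training labels must be three-state")
    vocab = build_vocabulary(dataset)
    n_feats = len(vocab)
    model = CRFModel(feature_index=vocab, weights=np.zeros(3 * n_feats + 9))
    if cfg.max_iter == 0:
        return model
    batch = _Batch(
        [model.encode(x) for x, _ in dataset],
        [y.codes.astype(np.intp) for _, y in dataset],
        n_feats,
    )
    history: list[float] = []

    def record(wk: np.ndarray) -> None:
        history.append(-_objective(wk, batch, cfg.l2_sigma)[0])

    res = minimize(
        _objective,
        model.weights,
        args=(batch, cfg.l2_sigma),
        method="L-BFGS-B",
        jac=True,
        callback=record,
        options={"maxiter": cfg.max_iter, "gtol": cfg.grad_tol, "ftol": 1e-12},
    )
    model.weights = np.asarray(res.x, dtype=float)
    model.history = history
    return model
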