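"""Hierarchical multi-label phenotype classifier.

The predictor is a fully connected network over sparse binary GO features
(plus optional expression features): a dense reduction layer with ReLU and
dropout, expression concatenated after the reduction, a sigmoid
multi-label output — one unit per predictable phenotype class — and, in
hierarchical mode, a *hierarchical classification layer* that replaces
each class score with the maximum score among its reflexive descendants.
The layer is a masked max-reduction over the subclass indicator matrix, so
its output is consistent with the ontology by construction (an ancestor
never scores below a descendant) and gradients flow through the maximising
descendant during training.

The network is implemented directly on numpy with hand-written gradients
(binary cross-entropy, Adam, early stopping on validation loss), which is
ample for the annotation-corpus scales this package targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .data import AnnotationSet, FeatureMatrix
from .ontology import Ontology, SubclassMatrix, subclass_matrix

__all__ = [
    "PredictionMatrix",
    "ModelConfig",
    "PhenotypeClassifier",
    "hierarchical_layer",
    "true_path_fix",
    "random_search",
]

#: unit-count grid for random hyperparameter search
UNIT_GRID = tuple(range(250, 4001, 250))
DROPOUT_GRID = (0.2, 0.5)
LR_GRID = (0.01, 0.001, 0.0001)


@dataclass
class PredictionMatrix:
    """genes × phenotype-class scores in [0, 1].

    ``consistent`` is True once scores respect the hierarchy: every
    ancestor scores at least as high as each of its descendants within
    ``class_order``.
    """

    gene_ids: list[str]
    class_order: list[str]
    scores: np.ndarray
    consistent: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.gene_ids), len(self.class_order)):
            raise ValueError("scores shape does not match gene/class lists")
        if self.scores.size and (
            self.scores.min() < -1e-9 or self.scores.max() > 1 + 1e-9
        ):
            raise ValueError("scores outside [0, 1]")

    def row(self, gene: str) -> dict[str, float]:
        i = self.gene_ids.index(gene)
        return dict(zip(self.class_order, self.scores[i]))

    def to_tsv(self, path, threshold: float = 0.0) -> None:
        """Write long-format (gene, class, score) rows with score > threshold."""
        with open(path, "w") as fh:
            fh.write("gene_id\tclass_id\tscore\n")
            for i, g in enumerate(self.gene_ids):
                for j, c in enumerate(self.class_order):
                    s = self.scores[i, j]
                    if s > threshold:
                        fh.write(f"{g}\t{c}\t{s:.6f}\n")

    @classmethod
    def from_tsv(cls, path, gene_ids=None, class_order=None) -> "PredictionMatrix":
        """Read long-format (gene, class, score) rows written by :meth:`to_tsv`.

        Pairs absent from the file score 0.  ``gene_ids``/``class_order``
        fix the output axes (and order); by default they are taken from
        the file in first-seen / sorted order respectively.
        """
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        gcol, ccol, scol = df.columns[:3]
        if gene_ids is None:
            gene_ids = list(dict.fromkeys(df[gcol]))
        if class_order is None:
            class_order = sorted(df[ccol].unique())
        gi = {g: i for i, g in enumerate(gene_ids)}
        ci = {c: j for j, c in enumerate(class_order)}
        scores = np.zeros((len(gene_ids), len(class_order)))
        for g, c, s in df[[gcol, ccol, scol]].itertuples(index=False):
            if g in gi and c in ci:
                scores[gi[g], ci[c]] = float(s)
        return cls(gene_ids=list(gene_ids), class_order=list(class_order), scores=scores)

    def check_consistency(self, S: SubclassMatrix, atol: float = 1e-9) -> bool:
        """True iff no descendant outscores its ancestor under ``S``."""
        fixed = _descendant_max(self.scores, _descendant_index(S))
        return bool(np.all(self.scores >= fixed - atol))


def _descendant_index(S: SubclassMatrix) -> list[np.ndarray]:
    """Per-class integer index arrays of reflexive descendants."""
    return [np.flatnonzero(S.matrix[i]) for i in range(len(S.class_order))]


def _descendant_max(scores: np.ndarray, desc_idx: list[np.ndarray]) -> np.ndarray:
    out = np.empty_like(scores)
    for i, idx in enumerate(desc_idx):
        out[:, i] = scores[:, idx].max(axis=1)
    return out


def _descendant_argmax(
    scores: np.ndarray, desc_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Max over descendants plus the column index attaining it."""
    out = np.empty_like(scores)
    arg = np.empty(scores.shape, dtype=np.int64)
    for i, idx in enumerate(desc_idx):
        block = scores[:, idx]
        k = block.argmax(axis=1)
        out[:, i] = block[np.arange(block.shape[0]), k]
        arg[:, i] = idx[k]
    return out, arg


def hierarchical_layer(x: np.ndarray, S: SubclassMatrix) -> np.ndarray:
    """Replace each class score by the max over its reflexive descendants.

    Accepts a single score vector (length k) or a genes × k matrix over
    ``S.class_order``.  Idempotent, monotone, and never decreases a score
    (the diagonal of ``S`` is 1).
    """
    x = np.asarray(x, dtype=np.float64)
    vector = x.ndim == 1
    if vector:
        x = x[None, :]
    if x.shape[1] != len(S.class_order):
        raise ValueError(
            f"score length {x.shape[1]} != class count {len(S.class_order)}"
        )
    out = _descendant_max(x, _descendant_index(S))
    return out[0] if vector else out


def true_path_fix(preds: PredictionMatrix, ont: Ontology) -> PredictionMatrix:
    """Post-hoc hierarchical fix for a flat predictor's scores.

    Score-level generalization of propagating positive predictions to all
    superclasses: each class's score becomes the maximum over its
    reflexive descendants within ``preds.class_order``.
    """
    S = subclass_matrix(ont, preds.class_order)
    fixed = hierarchical_layer(preds.scores, S)
    return PredictionMatrix(
        gene_ids=list(preds.gene_ids),
        class_order=list(preds.class_order),
        scores=fixed,
        consistent=True,
    )


@dataclass
class ModelConfig:
    """Training hyperparameters.

    Defaults are a desk-scale configuration inside the random-search grid:
    one 1024-unit reduction layer, dropout 0.5, Adam at 1e-3, mini-batches
    of 32, early stopping with patience 5.
    """

    hidden_layers: list[int] = field(default_factory=lambda: [1024])
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 5
    seed: int = 0
    search_trials: int = 0

    def validate(self) -> None:
        if not self.hidden_layers:
            raise ValueError("need at least one hidden layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate outside [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("bad learning_rate or batch_size")


def _labels_to_matrix(
    labels: AnnotationSet, gene_ids: Sequence[str], class_order: Sequence[str]
) -> np.ndarray:
    idx = {c: j for j, c in enumerate(class_order)}
    Y = np.zeros((len(gene_ids), len(class_order)), dtype=np.float64)
    for i, g in enumerate(gene_ids):
        for c in labels.assignments.get(g, ()):
            j = idx.get(c)
            if j is not None:
                Y[i, j] = 1.0
    return Y


def _bce(pred: np.ndarray, truth: np.ndarray) -> float:
    p = np.clip(pred, 1e-7, 1 - 1e-7)
    return float(-np.mean(truth * np.log(p) + (1 - truth) * np.log(1 - p)))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class PhenotypeClassifier:
    """Fully connected multi-label classifier with an optional hierarchy layer.

    ``mode='hierarchical'`` applies the descendant-max layer both during
    training (the loss sees ontology-consistent scores) and at prediction;
    ``mode='flat'`` trains on the raw sigmoid outputs, which can be fixed
    post hoc with :func:`true_path_fix`.
    """

    def __init__(
        self,
        config: ModelConfig | None = None,
        mode: Literal["flat", "hierarchical"] = "hierarchical",
    ) -> None:
        if mode not in ("flat", "hierarchical"):
            raise ValueError(f"unknown mode {mode!r}")
        self.config = config or ModelConfig()
        self.config.validate()
        self.mode = mode
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.class_order_: list[str] | None = None
        self.go_vocab_: list[str] | None = None
        self.n_tissues_: int = 0
        self.S_: SubclassMatrix | None = None
        self.history_: dict[str, list[float]] = {}

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        features: FeatureMatrix,
        labels: AnnotationSet,
        S: SubclassMatrix,
        valid_features: FeatureMatrix | None = None,
        valid_labels: AnnotationSet | None = None,
    ) -> "PhenotypeClassifier":
        cfg = self.config
        class_order = list(S.class_order)
        Y = _labels_to_matrix(labels, features.gene_ids, class_order)
        if Y.sum() == 0:
            raise ValueError("no positive labels for any class")
        X_go = features.go_block.astype(np.float64)
        X_ex = (
            features.expr_block
            if features.expr_block is not None
            else np.zeros((len(features.gene_ids), 0))
        )
        self.class_order_ = class_order
        self.go_vocab_ = list(features.go_vocab)
        self.n_tissues_ = X_ex.shape[1]
        self.S_ = S
        desc_idx = _descendant_index(S)

        rng = np.random.default_rng(cfg.seed)
        sizes = [X_go.shape[1], *cfg.hidden_layers]
        W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        b = [np.zeros(s) for s in sizes[1:]]
        k = len(class_order)
        d_out_in = cfg.hidden_layers[-1] + self.n_tissues_
        W.append(rng.normal(0.0, np.sqrt(1.0 / d_out_in), (d_out_in, k)))
        b.append(np.zeros(k))

        if valid_features is not None and valid_labels is not None:
            Xv_go = valid_features.go_block.astype(np.float64)
            Xv_ex = (
                valid_features.expr_block
                if valid_features.expr_block is not None
                else np.zeros((len(valid_features.gene_ids), 0))
            )
            Yv = _labels_to_matrix(valid_labels, valid_features.gene_ids, class_order)
        else:
            # hold out 10% of the training genes as a validation split
            n = X_go.shape[0]
            perm = rng.permutation(n)
            n_val = max(1, n // 10)
            vi, ti = perm[:n_val], perm[n_val:]
            Xv_go, Xv_ex, Yv = X_go[vi], X_ex[vi], Y[vi]
            X_go, X_ex, Y = X_go[ti], X_ex[ti], Y[ti]

        params = W + b
        opt = _Adam(params, cfg.learning_rate)
        best_loss = np.inf
        best_params: list[np.ndarray] | None = None
        wait = 0
        n = X_go.shape[0]
        history: dict[str, list[float]] = {"train_loss": [], "valid_loss": []}

        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                loss = self._train_batch(
                    X_go[sel], X_ex[sel], Y[sel], W, b, desc_idx, opt, rng
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {_epoch}; "
                        f"lr={cfg.learning_rate}, batch={cfg.batch_size}"
                    )
                epoch_loss += loss * len(sel)
            history["train_loss"].append(epoch_loss / n)

            val_scores = self._forward_inference(Xv_go, Xv_ex, W, b, desc_idx)
            val_loss = _bce(val_scores, Yv)
            history["valid_loss"].append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = [p.copy() for p in W + b]
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break

        if best_params is not None:
            nw = len(W)
            W = best_params[:nw]
            b = best_params[nw:]
        self.weights_, self.biases_ = W, b
        self.history_ = history
        self.history_["best_valid_loss"] = [best_loss]
        return self

    def _train_batch(self, Xg, Xe, Yb, W, b, desc_idx, opt, rng) -> float:
        cfg = self.config
        # forward
        acts = [Xg]
        for Wi, bi in zip(W[:-1], b[:-1]):
            acts.append(np.maximum(acts[-1] @ Wi + bi, 0.0))
        h = acts[-1]
        if cfg.dropout_rate > 0:
            mask = (rng.random(h.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
            h = h * mask
        else:
            mask = None
        z_in = np.hstack([h, Xe]) if Xe.shape[1] else h
        logits = z_in @ W[-1] + b[-1]
        y = 1.0 / (1.0 + np.exp(-logits))
        if self.mode == "hierarchical":
            out, arg = _descendant_argmax(y, desc_idx)
        else:
            out, arg = y, None
        loss = _bce(out, Yb)

        # backward
        nB, k = out.shape
        p = np.clip(out, 1e-7, 1 - 1e-7)
        d_out = (p - Yb) / (p * (1 - p)) / (nB * k)
        if arg is not None:
            d_y = np.zeros_like(y)
            rows = np.repeat(np.arange(nB), k)
            np.add.at(d_y, (rows, arg.ravel()), d_out.ravel())
        else:
            d_y = d_out
        d_logits = d_y * y * (1 - y)
        gW_out = z_in.T @ d_logits
        gb_out = d_logits.sum(axis=0)
        d_zin = d_logits @ W[-1].T
        d_h = d_zin[:, : h.shape[1]]
        if mask is not None:
            d_h = d_h * mask
        gW, gb = [], []
        grad = d_h
        for li in range(len(W) - 2, -1, -1):
            grad = grad * (acts[li + 1] > 0)
            gW.append(acts[li].T @ grad)
            gb.append(grad.sum(axis=0))
            if li > 0:
                grad = grad @ W[li].T
        gW.reverse()
        gb.reverse()
        opt.step(W + b, gW + [gW_out] + gb + [gb_out])
        return loss

    def _forward_inference(self, Xg, Xe, W, b, desc_idx) -> np.ndarray:
        a = Xg
        for Wi, bi in zip(W[:-1], b[:-1]):
            a = np.maximum(a @ Wi + bi, 0.0)
        z_in = np.hstack([a, Xe]) if Xe.shape[1] else a
        y = 1.0 / (1.0 + np.exp(-(z_in @ W[-1] + b[-1])))
        if self.mode == "hierarchical":
            y = _descendant_max(y, desc_idx)
        return y

    # -------------------------------------------------------------- predict

    def predict(self, features: FeatureMatrix) -> PredictionMatrix:
        if self.weights_ is None:
            raise RuntimeError("fit before predict")
        if list(features.go_vocab) != self.go_vocab_:
            raise ValueError("feature GO vocabulary differs from training vocabulary")
        if features.n_tissues != self.n_tissues_:
            raise ValueError(
                f"expression width {features.n_tissues} != training {self.n_tissues_}"
            )
        Xg = features.go_block.astype(np.float64)
        Xe = (
            features.expr_block
            if features.expr_block is not None
            else np.zeros((len(features.gene_ids), 0))
        )
        scores = self._forward_inference(
            Xg, Xe, self.weights_, self.biases_, _descendant_index(self.S_)
        )
        return PredictionMatrix(
            gene_ids=list(features.gene_ids),
            class_order=list(self.class_order_),
            scores=scores,
            consistent=self.mode == "hierarchical",
        )

    # ---------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Serialize weights + vocab + class order + config to one .npz."""
        meta = {
            "mode": self.mode,
            "config": asdict(self.config),
            "class_order": self.class_order_,
            "go_vocab": self.go_vocab_,
            "n_tissues": self.n_tissues_,
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        arrays["S"] = self.S_.matrix
        for i, w in enumerate(self.weights_):
            arrays[f"W{i}"] = w
        for i, bb in enumerate(self.biases_):
            arrays[f"b{i}"] = bb
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "PhenotypeClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            model = cls(config=ModelConfig(**meta["config"]), mode=meta["mode"])
            model.class_order_ = meta["class_order"]
            model.go_vocab_ = meta["go_vocab"]
            model.n_tissues_ = meta["n_tissues"]
            model.S_ = SubclassMatrix(
                class_order=tuple(meta["class_order"]), matrix=z["S"]
            )
            nW = len([k for k in z.files if k.startswith("W")])
            model.weights_ = [z[f"W{i}"] for i in range(nW)]
            model.biases_ = [z[f"b{i}"] for i in range(nW)]
        return model


def random_search(
    features: FeatureMatrix,
    labels: AnnotationSet,
    S: SubclassMatrix,
    valid_features: FeatureMatrix,
    valid_labels: AnnotationSet,
    mode: Literal["flat", "hierarchical"] = "hierarchical",
    n_trials: int = 50,
    n_layers_choices: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    base_config: ModelConfig | None = None,
) -> tuple[PhenotypeClassifier, list[dict]]:
    """Random hyperparameter search over the unit/dropout/learning-rate grid.

    Samples layer widths from {250, 500, ..., 4000}, dropout from
    {0.2, 0.5} and Adam learning rate from {0.01, 0.001, 0.0001}; the model
    with the lowest validation loss wins.
    """
    rng = np.random.default_rng(seed)
    base = base_config or ModelConfig()
    best_model: PhenotypeClassifier | None = None
    best_loss = np.inf
    trials: list[dict] = []
    for t in range(n_trials):
        cfg = ModelConfig(
            hidden_layers=[
                int(rng.choice(UNIT_GRID))
                for _ in range(int(rng.choice(list(n_layers_choices))))
            ],
            dropout_rate=float(rng.choice(DROPOUT_GRID)),
            learning_rate=float(rng.choice(LR_GRID)),
            batch_size=base.batch_size,
            max_epochs=base.max_epochs,
            patience=base.patience,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        model = PhenotypeClassifier(cfg, mode=mode).fit(
            features, labels, S, valid_features, valid_labels
        )
        loss = model.history_["best_valid_loss"][0]
        trials.append({"config": asdict(cfg), "valid_loss": loss})
        if loss < best_loss:
            best_loss = loss
            best_model = model
    return best_model, trials
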