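"""Deep belief network: stacked-RBM pretraining and supervised fine-tuning.

The network is trained in two stages.  (i) Pretraining: each restricted
Boltzmann machine (a visible and a hidden layer with no within-layer
connections) is trained by contrastive divergence (CD-k, default k=1)
with momentum-accelerated minibatch updates; the hidden activation
probabilities of one RBM become the visible input of the next.
(ii) Fine-tuning: a softmax read-out is appended after the last RBM and
the whole stack is trained end-to-end by backpropagation on the
cross-entropy loss.

Visible units take real values in [0, 1], treated as Bernoulli
probabilities, so descriptor tables are min-max scaled per feature
before entering the network (see :func:`scale_unit_interval`).

The three stack architectures compared in the study, parameterized by
the input dimension p, are available via :func:`architecture_presets`:
``[p, 500]`` (one RBM, the best performer), ``[p, 2000, 500]`` and
``[p, 2000, 1000, 500]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DescriptorTable, FoldAssignment, LabeledDataset, ValidationError


def architecture_presets(p: int) -> dict[str, list[int]]:
    """The three compared layer-size stacks for input dimension ``p``."""
    return {
        "rbm1": [p, 500],
        "rbm2": [p, 2000, 500],
        "rbm3": [p, 2000, 1000, 500],
    }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class UnitIntervalScaler:
    """Per-feature min-max scaling to [0, 1] with stored train statistics.

    Constant features map to 0; test-set values outside the training
    range are clipped back into [0, 1].
    """

    mins: np.ndarray | None = None
    ranges: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "UnitIntervalScaler":
        values = np.asarray(values, dtype=float)
        self.mins = values.min(axis=0)
        self.ranges = values.max(axis=0) - self.mins
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise ValidationError("scaler not fitted")
        rng = np.where(self.ranges > 0, self.ranges, 1.0)
        out = (np.asarray(values, dtype=float) - self.mins) / rng
        out[:, self.ranges == 0] = 0.0
        return np.clip(out, 0.0, 1.0)


def scale_unit_interval(table: DescriptorTable) -> tuple[DescriptorTable, UnitIntervalScaler]:
    """Min-max scale an (imputed) table to [0, 1]; returns the scaler for reuse."""
    if table.missing_mask.any():
        raise ValidationError("impute missing values before scaling")
    scaler = UnitIntervalScaler().fit(table.values)
    out = table.copy()
    out.values = scaler.transform(table.values)
    return out, scaler


class RBM:
    """Restricted Boltzmann machine trained by contrastive divergence."""

    def __init__(
        self,
        n_visible: int,
        n_hidden: int,
        learning_rate: float = 0.05,
        momentum: float = 0.5,
        cd_steps: int = 1,
        epochs: int = 50,
        batch_size: int = 32,
        seed: int = 0,
    ) -> None:
        if learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if not 0.0 <= momentum < 1.0:
            raise ValidationError("momentum must lie in [0, 1)")
        if min(n_visible, n_hidden, cd_steps, epochs, batch_size) < 1:
            raise ValidationError("counts must be >= 1")
        self.n_visible = n_visible
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.cd_steps = cd_steps
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.weights = rng.normal(0.0, 0.01, size=(n_visible, n_hidden))
        self.visible_bias = np.zeros(n_visible)
        self.hidden_bias = np.zeros(n_hidden)
        self.reconstruction_errors: list[float] = []

    # -- conditionals ----------------------------------------------------
    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        return _sigmoid(v @ self.weights + self.hidden_bias)

    def visible_probs(self, h: np.ndarray) -> np.ndarray:
        return _sigmoid(h @ self.weights.T + self.visible_bias)

    def free_energy(self, v: np.ndarray) -> np.ndarray:
        """F(v) = -v.b_v - sum_j log(1 + exp(v.W_j + b_h_j)), per row."""
        x = v @ self.weights + self.hidden_bias
        return -(v @ self.visible_bias) - np.logaddexp(0.0, x).sum(axis=1)

    # -- contrastive divergence ------------------------------------------
    def cd_gradient(self, v0: np.ndarray, h0: np.ndarray):
        """CD-1 gradient statistics for a batch and *given* hidden sample h0.

        The hidden sample is injected rather than drawn internally so
        the exact expectation over the (enumerable) hidden states can be
        computed in tests.  Following common CD practice the positive
        statistics use the hidden probabilities p(h|v0), the
        reconstruction uses visible probabilities, and the negative
        statistics use p(h|v1).

        Returns ``(dW, dvb, dhb)``, the *ascent* direction on the log
        likelihood (to be added, scaled by the learning rate).
        """
        v0 = np.atleast_2d(v0)
        h0 = np.atleast_2d(h0)
        b = v0.shape[0]
        ph0 = self.hidden_probs(v0)
        v1 = self.visible_probs(h0)
        ph1 = self.hidden_probs(v1)
        dW = (v0.T @ ph0 - v1.T @ ph1) / b
        dvb = (v0 - v1).mean(axis=0)
        dhb = (ph0 - ph1).mean(axis=0)
        return dW, dvb, dhb

    def _cd_k(self, v0: np.ndarray, rng: np.random.Generator):
        """CD-k gradient for a batch, sampling hidden states along the chain."""
        ph = self.hidden_probs(v0)
        pos_W = v0.T @ ph
        pos_v = v0.sum(axis=0)
        pos_h = ph.sum(axis=0)
        v = v0
        for _ in range(self.cd_steps):
            h = (rng.random(ph.shape) < ph).astype(float)
            v = self.visible_probs(h)
            ph = self.hidden_probs(v)
        b = v0.shape[0]
        dW = (pos_W - v.T @ ph) / b
        dvb = (pos_v - v.sum(axis=0)) / b
        dhb = (pos_h - ph.sum(axis=0)) / b
        return dW, dvb, dhb, v

    def fit(self, data: np.ndarray) -> "RBM":
        """Train by minibatch CD with momentum; logs per-epoch reconstruction MSE."""
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[1] != self.n_visible:
            raise ValidationError(
                f"data shape {data.shape} incompatible with n_visible={self.n_visible}"
            )
        if data.min() < 0.0 or data.max() > 1.0:
            raise ValidationError("RBM input must lie in [0, 1]")
        rng = np.random.default_rng(self.seed + 1)
        vW = np.zeros_like(self.weights)
        vv = np.zeros_like(self.visible_bias)
        vh = np.zeros_like(self.hidden_bias)
        n = data.shape[0]
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            sq_err = 0.0
            for start in range(0, n, self.batch_size):
                batch = data[perm[start:start + self.batch_size]]
                dW, dvb, dhb, v1 = self._cd_k(batch, rng)
                vW = self.momentum * vW + self.learning_rate * dW
                vv = self.momentum * vv + self.learning_rate * dvb
                vh = self.momentum * vh + self.learning_rate * dhb
                self.weights += vW
                self.visible_bias += vv
                self.hidden_bias += vh
                sq_err += float(((batch - v1) ** 2).sum())
            if not np.isfinite(self.weights).all() or np.abs(self.weights).max() > 1e4:
                raise ValidationError(
                    f"RBM weights exploded at epoch {epoch}; lower the learning rate"
                )
            self.reconstruction_errors.append(sq_err / (n * self.n_visible))
        return self


@dataclass
class DBN:
    """A pretrained RBM stack plus (after fine-tuning) a softmax read-out."""

    layer_sizes: list[int]
    rbms: list[RBM]
    head_weights: np.ndarray | None = None
    head_bias: np.ndarray | None = None
    vocabulary: list[str] | None = None
    scaler: UnitIntervalScaler | None = None
    training_accuracy: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        if len(sizes) < 2:
            raise ValidationError("need at least input and one hidden layer")
        for i, rbm in enumerate(self.rbms):
            if (rbm.n_visible, rbm.n_hidden) != (sizes[i], sizes[i + 1]):
                raise ValidationError("RBM shapes do not chain with layer_sizes")

    def hidden_representation(self, X: np.ndarray) -> np.ndarray:
        """Top-layer activation probabilities (the compressed representation)."""
        h = np.asarray(X, dtype=float)
        for rbm in self.rbms:
            h = rbm.hidden_probs(h)
        return h

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [np.asarray(X, dtype=float)]
        for rbm in self.rbms:
            acts.append(_sigmoid(acts[-1] @ rbm.weights + rbm.hidden_bias))
        logits = acts[-1] @ self.head_weights + self.head_bias
        logits -= logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return acts, probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.head_weights is None:
            raise ValidationError("DBN has no classifier head; fine-tune first")
        return self._forward(X)[1]

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def predict(self, X: np.ndarray) -> list[str]:
        if self.vocabulary is None:
            raise ValidationError("DBN has no label vocabulary")
        return [self.vocabulary[i] for i in self.predict_indices(X)]


def save_dbn(dbn: DBN, path) -> None:
    """Persist a DBN (layer sizes, RBM weights/biases, head, scaler) as npz."""
    arrays: dict[str, np.ndarray] = {
        "format_version": np.array([1]),
        "layer_sizes": np.array(dbn.layer_sizes),
    }
    for i, rbm in enumerate(dbn.rbms):
        arrays[f"W{i}"] = rbm.weights
        arrays[f"vb{i}"] = rbm.visible_bias
        arrays[f"hb{i}"] = rbm.hidden_bias
    if dbn.head_weights is not None:
        arrays["head_W"] = dbn.head_weights
        arrays["head_b"] = dbn.head_bias
        arrays["vocabulary"] = np.array(dbn.vocabulary, dtype=object)
    if dbn.scaler is not None:
        arrays["scaler_mins"] = dbn.scaler.mins
        arrays["scaler_ranges"] = dbn.scaler.ranges
    np.savez(path, **arrays, allow_pickle=True)


def load_dbn(path) -> DBN:
    blob = np.load(path, allow_pickle=True)
    sizes = [int(s) for s in blob["layer_sizes"]]
    rbms = []
    for i in range(len(sizes) - 1):
        rbm = RBM(sizes[i], sizes[i + 1])
        rbm.weights = blob[f"W{i}"]
        rbm.visible_bias = blob[f"vb{i}"]
        rbm.hidden_bias = blob[f"hb{i}"]
        rbms.append(rbm)
    dbn = DBN(layer_sizes=sizes, rbms=rbms)
    if "head_W" in blob:
        dbn.head_weights = blob["head_W"]
        dbn.head_bias = blob["head_b"]
        dbn.vocabulary = [str(v) for v in blob["vocabulary"]]
    if "scaler_mins" in blob:
        dbn.scaler = UnitIntervalScaler(mins=blob["scaler_mins"],
                                        ranges=blob["scaler_ranges"])
    return dbn


def train_rbm(data: np.ndarray, **hyper) -> RBM:
    """Construct and fit a single RBM on data in [0, 1]."""
    data = np.asarray(data, dtype=float)
    rbm = RBM(n_visible=data.shape[1], **hyper)
    return rbm.fit(data)


def pretrain_stack(
    data: np.ndarray,
    layer_sizes: list[int],
    learning_rate: float = 0.05,
    momentum: float = 0.5,
    cd_steps: int = 1,
    epochs: int = 50,
    batch_size: int = 32,
    seed: int = 0,
) -> DBN:
    """Greedy bottom-up pretraining: layer i+1 trains on layer i's hidden probabilities."""
    data = np.asarray(data, dtype=float)
    if data.shape[1] != layer_sizes[0]:
        raise ValidationError("layer_sizes[0] must equal the input dimension")
    rbms: list[RBM] = []
    h = data
    for i in range(len(layer_sizes) - 1):
        rbm = RBM(
            layer_sizes[i], layer_sizes[i + 1],
            learning_rate=learning_rate, momentum=momentum, cd_steps=cd_steps,
            epochs=epochs, batch_size=batch_size, seed=seed + i,
        ).fit(h)
        rbms.append(rbm)
        h = rbm.hidden_probs(h)
    return DBN(layer_sizes=list(layer_sizes), rbms=rbms)


def _loss_and_gradients(dbn: DBN, X: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and gradients w.r.t. all weights and biases.

    Returns ``(loss, grads)`` with ``grads`` a list of (dW, db) from the
    bottom RBM up, ending with the head.  Used both by the fine-tuning
    loop and by finite-difference gradient checks.
    """
    acts, probs = dbn._forward(X)
    n = X.shape[0]
    loss = float(-np.log(probs[np.arange(n), y] + 1e-300).mean())
    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    grads: list[tuple[np.ndarray, np.ndarray]] = []
    dW_head = acts[-1].T @ delta
    db_head = delta.sum(axis=0)
    back = delta @ dbn.head_weights.T
    layer_grads: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(len(dbn.rbms) - 1, -1, -1):
        a = acts[i + 1]
        local = back * a * (1.0 - a)
        layer_grads.append((acts[i].T @ local, local.sum(axis=0)))
        back = local @ dbn.rbms[i].weights.T
    grads = list(reversed(layer_grads)) + [(dW_head, db_head)]
    return loss, grads


def fine_tune(
    dbn: DBN,
    train: LabeledDataset | tuple[np.ndarray, np.ndarray, list[str]],
    epochs: int = 100,
    learning_rate: float = 0.1,
    momentum: float = 0.5,
    batch_size: int = 32,
    seed: int = 0,
) -> DBN:
    """Backpropagation fine-tuning of the whole stack with a softmax head.

    With ``epochs=0`` the head is initialized but never trained, so
    predictions reflect the pretrained features alone.  Deterministic
    under ``seed``.
    """
    if isinstance(train, LabeledDataset):
        X = train.table.values
        y = train.y
        vocab = list(train.vocabulary)
    else:
        X, y, vocab = train
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    n_classes = len(vocab)
    top = dbn.layer_sizes[-1]
    dbn.head_weights = rng.normal(0.0, 0.01, size=(top, n_classes))
    dbn.head_bias = np.zeros(n_classes)
    dbn.vocabulary = vocab
    vel = None
    n = X.shape[0]
    for epoch in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            b = perm[start:start + batch_size]
            loss, grads = _loss_and_gradients(dbn, X[b], y[b])
            if not np.isfinite(loss):
                raise ValidationError(f"fine-tuning diverged at epoch {epoch}")
            if vel is None:
                vel = [(np.zeros_like(gW), np.zeros_like(gb)) for gW, gb in grads]
            for i, (gW, gb) in enumerate(grads):
                vW = momentum * vel[i][0] - learning_rate * gW
                vb = momentum * vel[i][1] - learning_rate * gb
                vel[i] = (vW, vb)
                if i < len(dbn.rbms):
                    dbn.rbms[i].weights += vW
                    dbn.rbms[i].hidden_bias += vb
                else:
                    dbn.head_weights += vW
                    dbn.head_bias += vb
        acc = float(np.mean(dbn.predict_indices(X) == y))
        dbn.training_accuracy.append(acc)
    return dbn


def grid_search(
    dataset: LabeledDataset,
    folds: FoldAssignment,
    lr_grid: list[float] = (0.001, 0.01, 0.05, 0.1),
    momentum_grid: list[float] = (0.0, 0.5, 0.9),
    layer_sizes: list[int] | None = None,
    pretrain_epochs: int = 20,
    finetune_epochs: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Cross-validated accuracy surface over learning rate x momentum.

    Each grid point trains a DBN per fold (pretraining and fine-tuning
    both use that point's learning rate and momentum).  Returns a
    long-format frame (lr, momentum, fold, accuracy) and the (lr,
    momentum) pair with the best mean accuracy.
    """
    if len(lr_grid) == 0 or len(momentum_grid) == 0:
        raise ValidationError("grids must be non-empty")
    p = dataset.table.n_features
    layer_sizes = list(layer_sizes) if layer_sizes else [p, 500]
    rows = []
    for lr in lr_grid:
        for mom in momentum_grid:
            for f in range(folds.k):
                tr, te = folds.split(f)
                train = dataset.subset_rows(tr)
                test = dataset.subset_rows(te)
                scaled, scaler = scale_unit_interval(train.table)
                try:
                    dbn = pretrain_stack(
                        scaled.values, layer_sizes, learning_rate=lr, momentum=mom,
                        epochs=pretrain_epochs, seed=seed,
                    )
                    dbn.scaler = scaler
                    fine_tune(
                        dbn, (scaled.values, train.y, list(train.vocabulary)),
                        epochs=finetune_epochs, learning_rate=lr, momentum=mom,
                        seed=seed,
                    )
                    Xte = scaler.transform(test.table.values)
                    acc = float(np.mean(dbn.predict_indices(Xte) == test.y))
                except ValidationError:
                    acc = 0.0  # diverged at this grid point
                    # a diverged run scores below any trained one
                rows.append({"lr": lr, "momentum": mom, "fold": f, "accuracy": acc})
    surface = pd.DataFrame(rows)
    means = surface.groupby(["lr", "momentum"])["accuracy"].mean()
    best = means.idxmax()
    return surface, (float(best[0]), float(best[1]))
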