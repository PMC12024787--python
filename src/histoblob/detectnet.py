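"""Dense detection network over candidate features, plus evaluation metrics.

The detector is a small feed-forward network — one input dense layer, three
hidden dense layers and one output dense layer, with a dropout layer after
each hidden dense (eight layers in total).  It is trained with categorical
cross-entropy under the Adam optimizer (learning rate 1e-4, batch size 32,
dropout rate 0.2, 30 epochs) with optional early stopping that restores the
best-validation weights.  Inputs are per-candidate feature vectors, not raw
pixels: the upstream pipeline reduces each image to a list of scored blob
candidates, and the network classifies those.

The implementation is plain numpy (forward/backward passes written out),
which keeps training exactly reproducible from a seed on a single thread.

Detection quality is measured by greedy one-to-one centroid matching within
a distance gate, yielding precision, recall and F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "NetConfig",
    "DenseNet",
    "EvalReport",
    "TrainingError",
    "candidate_features",
    "train",
    "evaluate_detections",
    "split_dataset",
]


@dataclass
class NetConfig:
    """Widths are (input_dense, hidden1, hidden2, hidden3); the output dense
    layer has one unit per class.  A dropout layer follows each hidden dense
    layer, so the stack is 5 dense + 3 dropout = 8 layers."""

    widths: tuple[int, ...] = (64, 64, 32, 16)
    n_classes: int = 2
    dropout_rate: float = 0.2
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 30
    early_stopping: bool = True
    patience: int = 5
    val_frac: float = 0.2


class TrainingError(ArithmeticError):
    pass


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DenseNet:
    """Feed-forward ReLU network with inverted dropout and Adam."""

    def __init__(self, n_features: int, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dims = [n_features, *config.widths, config.n_classes]
        self.W = [
            rng.normal(0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        # dropout applies after hidden dense layers 1..3 (not the input dense)
        self._dropout_after = set(range(1, 4))
        self._adam_m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._adam_t = 0

    # -- inference ---------------------------------------------------------
    def forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Returns (probs, cache); dropout is active only when rng is given."""
        acts = [np.asarray(X, float)]
        masks: list[np.ndarray | None] = []
        a = acts[0]
        n_layers = len(self.W)
        for i in range(n_layers - 1):
            z = a @ self.W[i] + self.b[i]
            a = np.maximum(z, 0.0)
            if rng is not None and i in self._dropout_after and self.config.dropout_rate > 0:
                keep = 1.0 - self.config.dropout_rate
                m = (rng.random(a.shape) < keep) / keep
                a = a * m
                masks.append(m)
            else:
                masks.append(None)
            acts.append(a)
        logits = a @ self.W[-1] + self.b[-1]
        return _softmax(logits), (acts, masks)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- training ----------------------------------------------------------
    def _adam_step(self, grads_W, grads_b):
        cfg = self.config
        self._adam_t += 1
        t = self._adam_t
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.W + self.b
        grads = grads_W + grads_b
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
            self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g**2
            mhat = self._adam_m[i] / (1 - b1**t)
            vhat = self._adam_v[i] / (1 - b2**t)
            p -= cfg.lr * mhat / (np.sqrt(vhat) + eps)

    def train_batch(self, X: np.ndarray, Y: np.ndarray, rng: np.random.Generator) -> float:
        probs, (acts, masks) = self.forward(X, rng=rng)
        n = len(X)
        loss = -np.mean(np.log(np.clip(probs[np.arange(n), Y], 1e-12, None)))
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), Y] = 1.0
        delta = (probs - onehot) / n
        grads_W = [np.zeros_like(w) for w in self.W]
        grads_b = [np.zeros_like(b) for b in self.b]
        grads_W[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        da = delta @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            if masks[i] is not None:
                da = da * masks[i]
            dz = da * (acts[i + 1] > 0)
            grads_W[i] = acts[i].T @ dz
            grads_b[i] = dz.sum(axis=0)
            if i > 0:
                da = dz @ self.W[i].T
        self._adam_step(grads_W, grads_b)
        return float(loss)

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


def _loss_acc(model: DenseNet, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = model.predict_proba(X)
    loss = -np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return float(loss), acc


def train(
    features: np.ndarray,
    labels: np.ndarray,
    config: NetConfig | None = None,
    seed: int = 0,
) -> tuple[DenseNet, dict[str, list[float]]]:
    """Fit the detector; returns (model, per-epoch history).

    Features should be standardized by the caller.  The history dict holds
    train/validation loss and accuracy per epoch; with early stopping the
    best-validation weights are restored at the end.
    """
    if config is None:
        config = NetConfig()
    X = np.asarray(features, float)
    y = np.asarray(labels, int).ravel()
    if len(np.unique(y)) < 2 and config.epochs > 0:
        raise ValueError("training needs at least two classes")
    rng = np.random.default_rng(seed)
    model = DenseNet(X.shape[1], config, seed=int(rng.integers(2**31)))
    history: dict[str, list[float]] = {
        "train_loss": [], "val_loss": [], "train_acc": [], "val_acc": [],
    }
    if config.epochs == 0:
        return model, history

    n = len(X)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_frac * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = model.train_batch(Xtr[idx], ytr[idx], rng)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
        tr_loss, tr_acc = _loss_acc(model, Xtr, ytr)
        val_loss, val_acc = _loss_acc(model, Xval, yval)
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(val_loss)
        history["train_acc"].append(tr_acc)
        history["val_acc"].append(val_acc)
        if config.early_stopping:
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = model.get_weights()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if config.early_stopping:
        model.set_weights(best_weights)
    return model, history


# -- candidate features ----------------------------------------------------

def candidate_features(cand, h_conc: np.ndarray) -> np.ndarray:
    """Fixed-order feature vector for one blob candidate.

    (size, blobness_mean, blobness_max, ls, eccentricity, solidity,
    h_mean, h_max); ``ls`` is 0.5 when the candidate has not been scored.
    """
    rows, cols = cand.pixels[:, 0], cand.pixels[:, 1]
    r0, c0 = rows.min(), cols.min()
    local = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), bool)
    local[rows - r0, cols - c0] = True
    props = measure.regionprops(local.astype(int))[0]
    hvals = h_conc[rows, cols]
    ls = cand.ls if cand.ls is not None else 0.5
    return np.array(
        [
            float(cand.size),
            float(cand.blobness_mean),
            float(cand.blobness_max),
            float(ls),
            float(props.eccentricity),
            float(props.solidity),
            float(hvals.mean()),
            float(hvals.max()),
        ]
    )


# -- evaluation ------------------------------------------------------------

@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    match_dist: float
    precision_defined: bool = True
    recall_defined: bool = True


def evaluate_detections(
    pred_centroids, truth_centroids, match_dist: float = 5.0
) -> EvalReport:
    """Greedy one-to-one matching by ascending centroid distance.

    A prediction matches at most one truth point, valid only within
    ``match_dist`` pixels.  Undefined rates (empty denominators) are
    reported as 0 with the corresponding ``*_defined`` flag cleared.
    """
    pred = np.asarray(list(pred_centroids), float).reshape(-1, 2)
    truth = np.asarray(list(truth_centroids), float).reshape(-1, 2)
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("centroids must be finite")
    pairs = []
    for i, p in enumerate(pred):
        d = np.linalg.norm(truth - p, axis=1) if len(truth) else np.empty(0)
        for j in np.flatnonzero(d <= match_dist):
            pairs.append((d[j], i, j))
    pairs.sort(key=lambda t: t[0])
    used_p: set[int] = set()
    used_t: set[int] = set()
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
    tp = len(used_p)
    fp = len(pred) - tp
    fn = len(truth) - tp
    p_def, r_def = len(pred) > 0, len(truth) > 0
    precision = tp / len(pred) if p_def else 0.0
    recall = tp / len(truth) if r_def else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EvalReport(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
        match_dist=match_dist,
        precision_defined=p_def, recall_defined=r_def,
    )


def split_dataset(items, train_frac: float = 0.75, seed: int = 0):
    """Seeded disjoint train/test split; train size = round(n * train_frac)."""
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    items = list(items)
    n = len(items)
    if n < 2:
        raise ValueError("need at least two items to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_frac))
    train_items = [items[i] for i in perm[:n_train]]
    test_items = [items[i] for i in perm[n_train:]]
    return train_items, test_items
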