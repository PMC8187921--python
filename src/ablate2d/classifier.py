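"""CNN strategy classifier, implemented on numpy.

No deep-learning framework is assumed: the network (four 3x3
convolutions of 32 filters with ReLU and max-norm constraints, one 2x2
max-pool, a 512-unit ReLU dense layer, dropout 0.9 and a 3-way
softmax) and its training loop (Adam, class-weighted categorical
cross-entropy, plateau learning-rate decay, best-epoch checkpointing)
are written out with im2col convolutions.  Sizes are small enough —
tissue label images downsampled to a single channel — that this is
practical on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize
from sklearn.metrics import auc, confusion_matrix, precision_score, recall_score, roc_curve
from sklearn.utils.class_weight import compute_class_weight

from .labelling import CLASSES, LabelledSample
from .tissue import VOID, HEALTHY, FIBROTIC

# pixel encoding keeps healthy<->fibrotic inversion an involution around void
ENCODING = {VOID: 0.5, HEALTHY: 0.0, FIBROTIC: 1.0}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer stack of the strategy classifier."""

    input_shape: tuple[int, int, int] = (128, 128, 1)
    conv_blocks: int = 4
    filters: int = 32
    kernel_size: int = 3
    dense_units: int = 512
    dropout_rate: float = 0.9
    max_norm: float = 3.0
    n_classes: int = 3

    def feature_shape(self) -> tuple[int, int, int]:
        """Shape after the conv stack and the single 2x2 max-pool."""
        h, w, _ = self.input_shape
        for _ in range(self.conv_blocks):
            h -= self.kernel_size - 1
            w -= self.kernel_size - 1
        if h <= 0 or w <= 0:
            raise ValueError("input too small for the conv stack")
        return (h // 2, w // 2, self.filters)

    def parameter_count(self) -> int:
        k, f = self.kernel_size, self.filters
        c_in = self.input_shape[2]
        n = 0
        for b in range(self.conv_blocks):
            cin = c_in if b == 0 else f
            n += k * k * cin * f + f
        fh, fw, fc = self.feature_shape()
        n += fh * fw * fc * self.dense_units + self.dense_units
        n += self.dense_units * self.n_classes + self.n_classes
        return n


@dataclass
class TrainingConfig:
    """Optimiser and schedule settings."""

    max_epochs: int = 500
    monitor_every: int = 200      # plateau patience (epochs) for LR decay
    min_delta: float = 1e-3       # "significant" validation-loss decrease
    decay_factor: float = 0.8
    learning_rate: float = 1e-4
    class_weighting: bool = True
    batch_size: int = 32
    seed: int = 0


# ---------------------------------------------------------------------------
# the network


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


class Model:
    """Sequential CNN with explicit forward/backward passes."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k, f = spec.kernel_size, spec.filters
        self.params: dict[str, np.ndarray] = {}
        c_in = spec.input_shape[2]
        for b in range(spec.conv_blocks):
            cin = c_in if b == 0 else f
            self.params[f"Wc{b}"] = _he_init(rng, (k, k, cin, f), k * k * cin)
            self.params[f"bc{b}"] = np.zeros(f)
        fh, fw, fc = spec.feature_shape()
        flat = fh * fw * fc
        self.params["Wd"] = _he_init(rng, (flat, spec.dense_units), flat)
        self.params["bd"] = np.zeros(spec.dense_units)
        self.params["Wo"] = _he_init(rng, (spec.dense_units, spec.n_classes),
                                     spec.dense_units)
        self.params["bo"] = np.zeros(spec.n_classes)
        self._rng = rng

    # -- layers --------------------------------------------------------

    @staticmethod
    def _conv_forward(x, w, b):
        k = w.shape[0]
        cols = sliding_window_view(x, (k, k), axis=(1, 2))   # N,H',W',C,k,k
        cols = np.moveaxis(cols, 3, 5)                       # N,H',W',k,k,C
        n, ho, wo = cols.shape[:3]
        cols2 = cols.reshape(n, ho, wo, -1)
        out = cols2 @ w.reshape(-1, w.shape[-1]) + b
        return out, cols2

    @staticmethod
    def _conv_backward(dout, cols2, w, x_shape):
        k = w.shape[0]
        n, ho, wo, _ = dout.shape
        dw = np.tensordot(cols2, dout, axes=([0, 1, 2], [0, 1, 2]))
        dw = dw.reshape(w.shape)
        db = dout.sum(axis=(0, 1, 2))
        dcols = dout @ w.reshape(-1, w.shape[-1]).T
        dcols = dcols.reshape(n, ho, wo, k, k, x_shape[3])
        dx = np.zeros(x_shape)
        for di in range(k):
            for dj in range(k):
                dx[:, di:di + ho, dj:dj + wo, :] += dcols[:, :, :, di, dj, :]
        return dx, dw, db

    @staticmethod
    def _pool_forward(x):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        return out, (mask, x.shape)

    @staticmethod
    def _pool_backward(dout, cache):
        mask, x_shape = cache
        n, h2, _, w2, _, c = mask.shape
        # split gradient equally among ties (rare)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        grad = mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros(x_shape)
        dx[:, : h2 * 2, : w2 * 2, :] = grad.reshape(n, h2 * 2, w2 * 2, c)
        return dx

    # -- passes --------------------------------------------------------

    def forward(self, x, training: bool = False, dropout_rng=None):
        spec = self.spec
        cache = {"x": x}
        a = x
        for b in range(spec.conv_blocks):
            z, cols = self._conv_forward(a, self.params[f"Wc{b}"],
                                         self.params[f"bc{b}"])
            r = np.maximum(z, 0.0)
            cache[f"cols{b}"] = cols
            cache[f"relu{b}"] = z > 0
            cache[f"in{b}"] = a.shape
            a = r
        p, pool_cache = self._pool_forward(a)
        cache["pool"] = pool_cache
        n = x.shape[0]
        flat = p.reshape(n, -1)
        cache["flat"] = flat
        zd = flat @ self.params["Wd"] + self.params["bd"]
        rd = np.maximum(zd, 0.0)
        cache["relud"] = zd > 0
        if training and spec.dropout_rate > 0:
            rng = dropout_rng or self._rng
            keep = 1.0 - spec.dropout_rate
            mask = (rng.random(rd.shape) < keep) / keep
            rd = rd * mask
            cache["drop"] = mask
        cache["rd"] = rd
        logits = rd @ self.params["Wo"] + self.params["bo"]
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return probs, cache

    def backward(self, probs, y_onehot, sample_weights, cache):
        spec = self.spec
        n = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        wsum = sample_weights.sum()
        dlogits = (probs - y_onehot) * sample_weights[:, None] / wsum
        grads["Wo"] = cache["rd"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        drd = dlogits @ self.params["Wo"].T
        if "drop" in cache:
            drd = drd * cache["drop"]
        dzd = drd * cache["relud"]
        grads["Wd"] = cache["flat"].T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd"].T
        fh, fw, fc = spec.feature_shape()
        dp = dflat.reshape(n, fh, fw, fc)
        da = self._pool_backward(dp, cache["pool"])
        for b in reversed(range(spec.conv_blocks)):
            dz = da * cache[f"relu{b}"]
            da, dw, db = self._conv_backward(dz, cache[f"cols{b}"],
                                             self.params[f"Wc{b}"],
                                             cache[f"in{b}"])
            grads[f"Wc{b}"] = dw
            grads[f"bc{b}"] = db
        return grads

    def apply_max_norm(self):
        c = self.spec.max_norm
        if c <= 0:
            return
        for b in range(self.spec.conv_blocks):
            w = self.params[f"Wc{b}"]
            norms = np.sqrt((w**2).sum(axis=(0, 1, 2), keepdims=True))
            np.multiply(w, np.minimum(1.0, c / np.maximum(norms, 1e-12)), out=w)
        w = self.params["Wd"]
        norms = np.sqrt((w**2).sum(axis=0, keepdims=True))
        np.multiply(w, np.minimum(1.0, c / np.maximum(norms, 1e-12)), out=w)

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            probs, _ = self.forward(x[i:i + batch_size], training=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snapshot: dict[str, np.ndarray]) -> None:
        for k, v in snapshot.items():
            self.params[k] = v.copy()


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> Model:
    """Deterministically initialised classifier for the given spec."""
    return Model(spec or ArchitectureSpec(), seed=seed)


# ---------------------------------------------------------------------------
# data encoding


def encode_images(images: list[np.ndarray], size: tuple[int, int]) -> np.ndarray:
    """Label grids -> float tensor (N, H, W, 1), nearest-neighbour resize.

    Encoding: healthy 0, fibrotic 1, void 0.5 — symmetric around void so
    that image inversion flips the signal but not the anatomy.
    """
    lut = np.zeros(3)
    for k, v in ENCODING.items():
        lut[k] = v
    out = np.empty((len(images), size[0], size[1], 1))
    for i, img in enumerate(images):
        small = resize(img, size, order=0, preserve_range=True,
                       anti_aliasing=False).astype(np.uint8)
        out[i, :, :, 0] = lut[small]
    return out


def encode_samples(samples: list[LabelledSample],
                   size: tuple[int, int] = (32, 32)):
    """(X, y) tensors for a sample list; y indexes into CLASSES."""
    x = encode_images([s.image for s in samples], size)
    y = np.array([CLASSES.index(s.label) for s in samples], dtype=int)
    return x, y


# ---------------------------------------------------------------------------
# training


def class_weights(labels) -> dict[int, float]:
    """Balanced class weights w_c = N / (K * n_c) over present classes."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label list")
    present = np.unique(labels)
    weights = compute_class_weight("balanced", classes=present, y=labels)
    return {int(c): float(w) for c, w in zip(present, weights)}


@dataclass
class TrainResult:
    history: dict[str, list[float]]
    best_epoch: int
    best_val_accuracy: float
    best_weights: dict[str, np.ndarray]
    final_lr: float
    diverged: bool = False


def _one_hot(y, k):
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y] = 1.0
    return out


def train(model: Model, x_train, y_train, x_val, y_val,
          config: TrainingConfig | None = None) -> TrainResult:
    """Train with Adam + class-weighted cross-entropy.

    Applies the max-norm constraint after every update, decays the
    learning rate by ``decay_factor`` whenever the validation loss has
    not dropped by ``min_delta`` within the last ``monitor_every``
    epochs, and checkpoints the epoch with the highest validation
    accuracy.  Divergence (non-finite loss) aborts, returning the last
    good checkpoint.
    """
    config = config or TrainingConfig()
    k = model.spec.n_classes
    rng = np.random.default_rng(config.seed)
    if config.class_weighting:
        cw = class_weights(y_train)
    else:
        cw = {c: 1.0 for c in range(k)}
    sw_train = np.array([cw.get(int(c), 1.0) for c in y_train])
    y1h = _one_hot(y_train, k)
    adam_m = {key: np.zeros_like(v) for key, v in model.params.items()}
    adam_v = {key: np.zeros_like(v) for key, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_adam = 0
    lr = config.learning_rate
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": [],
               "lr": []}
    best_val_acc = -1.0
    best_val_loss = np.inf
    best_epoch = -1
    best_weights = model.snapshot()
    epochs_since_improve = 0
    diverged = False
    n = len(x_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0.0
        wsum_total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb, swb = x_train[idx], y1h[idx], sw_train[idx]
            probs, cache = model.forward(xb, training=True, dropout_rng=rng)
            p_true = np.clip((probs * yb).sum(axis=1), 1e-12, None)
            loss = -(swb * np.log(p_true)).sum() / swb.sum()
            if not np.isfinite(loss):
                diverged = True
                break
            epoch_loss += loss * swb.sum()
            wsum_total += swb.sum()
            epoch_correct += (probs.argmax(1) == y_train[idx]).sum()
            grads = model.backward(probs, yb, swb, cache)
            t_adam += 1
            for key, g in grads.items():
                adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g
                adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g * g
                mhat = adam_m[key] / (1 - beta1**t_adam)
                vhat = adam_v[key] / (1 - beta2**t_adam)
                model.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)
            model.apply_max_norm()
        if diverged:
            break
        val_probs = model.predict_proba(x_val)
        val_p_true = np.clip(val_probs[np.arange(len(y_val)), y_val], 1e-12, None)
        val_loss = float(-np.log(val_p_true).mean())
        val_acc = float((val_probs.argmax(1) == y_val).mean())
        history["loss"].append(float(epoch_loss / max(wsum_total, 1e-12)))
        history["accuracy"].append(float(epoch_correct / n))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        history["lr"].append(lr)
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_epoch = epoch
            best_weights = model.snapshot()
        if val_loss < best_val_loss - config.min_delta:
            best_val_loss = val_loss
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve >= config.monitor_every:
                lr *= config.decay_factor
                epochs_since_improve = 0
    return TrainResult(history=history, best_epoch=best_epoch,
                       best_val_accuracy=best_val_acc,
                       best_weights=best_weights, final_lr=lr,
                       diverged=diverged)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Metrics on one labelled sample set (percentages where noted)."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    confusion_percent: np.ndarray     # rows: true class, row-normalised to 100
    roc: dict[str, tuple[np.ndarray, np.ndarray]]
    auc: dict[str, float]
    macro_auc: float
    classes: tuple[str, ...] = CLASSES


def evaluate(model: Model, x, y, classes=CLASSES) -> EvalReport:
    """Accuracy, per-class precision/recall, row-% confusion, OvR ROC/AUC.

    Classes absent from ``y`` get NaN AUC (flagged undefined) and an
    absent confusion row.
    """
    probs = model.predict_proba(x)
    pred = probs.argmax(1)
    labels_idx = np.arange(len(classes))
    acc = float((pred == y).mean())
    prec = precision_score(y, pred, labels=labels_idx, average=None,
                           zero_division=0)
    rec = recall_score(y, pred, labels=labels_idx, average=None,
                       zero_division=0)
    cm = confusion_matrix(y, pred, labels=labels_idx).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_pct = 100.0 * cm / row_sums
    roc: dict[str, tuple] = {}
    aucs: dict[str, float] = {}
    for i, name in enumerate(classes):
        y_bin = (y == i).astype(int)
        if y_bin.min() == y_bin.max():
            aucs[name] = float("nan")
            roc[name] = (np.array([]), np.array([]))
            continue
        fpr, tpr, _ = roc_curve(y_bin, probs[:, i])
        roc[name] = (fpr, tpr)
        aucs[name] = float(auc(fpr, tpr))
    defined = [a for a in aucs.values() if np.isfinite(a)]
    macro = float(np.mean(defined)) if defined else float("nan")
    return EvalReport(
        accuracy=acc,
        precision={name: float(p) for name, p in zip(classes, prec)},
        recall={name: float(r) for name, r in zip(classes, rec)},
        confusion_percent=cm_pct, roc=roc, auc=aucs, macro_auc=macro,
        classes=tuple(classes),
    )


def select_best_fold(results: list[TrainResult]) -> int:
    """Index of the fold with the highest validation accuracy (ties ->
    lowest fold index)."""
    if not results:
        raise ValueError("no fold results")
    accs = [r.best_val_accuracy for r in results]
    return int(np.argmax(accs))


def run_cross_validation(samples, split, spec: ArchitectureSpec,
                         config: TrainingConfig,
                         image_size=(32, 32)):
    """Train one model per fold; returns (results, models, best_index)."""
    x_all, y_all = encode_samples(samples, image_size)
    results, models = [], []
    for f, (tr, va) in enumerate(split.folds):
        model = build_model(spec, seed=config.seed + f)
        res = train(model, x_all[tr], y_all[tr], x_all[va], y_all[va], config)
        model.restore(res.best_weights)
        results.append(res)
        models.append(model)
    best = select_best_fold(results)
    return results, models, best
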