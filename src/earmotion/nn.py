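"""Feedforward ANN for binary emotion-level classification.

A compact numpy multilayer perceptron with manual backpropagation:
softmax output, categorical cross-entropy with optional L2 weight
penalty, Adam optimization (lr 1e-3), early stopping on validation loss
(patience 20, max 200 epochs).  Backprop is written out explicitly
because the attribution methods in :mod:`earmotion.xai` need gradients
of the class logits with respect to the inputs.

The hyperparameter grid spans 14 node arrangements — every strictly
decreasing width tuple over {16, 32, 64, 128} with 1–3 hidden layers —
times 2 activations × 2 batch sizes × 2 L2 settings = 112
configurations.  Evaluation follows a stratified 10-fold protocol:
folds are rotated through 6 train / 2 validation / 2 test assignments
(5 rotations cover every fold as test once), which realizes the 60/20/20
split; features are standardized with training-fold statistics only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

WIDTHS = (16, 32, 64, 128)


@dataclass(frozen=True)
class NetConfig:
    hidden_widths: tuple[int, ...] = (64,)
    activation: str = "relu"
    batch_size: int = 128
    l2_lambda: float = 0.0

    @property
    def config_id(self) -> str:
        widths = "-".join(map(str, self.hidden_widths))
        return f"{widths}_{self.activation}_bs{self.batch_size}_l2{self.l2_lambda:g}"

    @property
    def n_parameters(self) -> int:
        sizes = (39, *self.hidden_widths, 2)
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


def node_arrangements() -> list[tuple[int, ...]]:
    """The 14 strictly decreasing width tuples over {16, 32, 64, 128}."""
    out: list[tuple[int, ...]] = []
    for depth in (1, 2, 3):
        for combo in itertools.combinations(sorted(WIDTHS, reverse=True), depth):
            out.append(combo)
    return out


def grid_configs(
    arrangements: list[tuple[int, ...]] | None = None,
) -> list[NetConfig]:
    """Full 112-member grid (14 arrangements × 8 hyperparameter settings)."""
    arrangements = arrangements if arrangements is not None else node_arrangements()
    return [
        NetConfig(widths, act, bs, l2)
        for widths in arrangements
        for act in ("relu", "tanh")
        for bs in (128, 256)
        for l2 in (0.0, 5e-4)
    ]


class MLP:
    """Numpy MLP with explicit forward/backward passes."""

    def __init__(self, n_inputs: int, config: NetConfig, seed: int = 0, n_classes: int = 2):
        self.config = config
        self.sizes = (n_inputs, *config.hidden_widths, n_classes)
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- forward / backward -------------------------------------------------

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.config.activation == "relu" else np.tanh(z)

    def _act_grad(self, z: np.ndarray, a: np.ndarray) -> np.ndarray:
        return (z > 0).astype(float) if self.config.activation == "relu" else 1.0 - a**2

    def forward(self, x: np.ndarray):
        """Return (logits, cache of (pre-activations, activations))."""
        a = np.asarray(x, dtype=float)
        zs, acts = [], [a]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            zs.append(z)
            a = z if i == len(self.weights) - 1 else self._act(z)
            acts.append(a)
        return acts[-1], (zs, acts)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.logits(x)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(x), axis=1)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(x)
        ce = -np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))
        l2 = self.config.l2_lambda * sum(float(np.sum(w**2)) for w in self.weights)
        return float(ce + l2)

    def _backward_params(self, x: np.ndarray, y: np.ndarray):
        """Gradients of mean CE + L2 w.r.t. weights and biases."""
        logits, (zs, acts) = self.forward(x)
        n = len(y)
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        delta = p.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        grads_w, grads_b = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w.append(acts[i].T @ delta + 2 * self.config.l2_lambda * self.weights[i])
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * self._act_grad(zs[i - 1], acts[i])
        return grads_w[::-1], grads_b[::-1]

    def input_gradients(self, x: np.ndarray, class_idx: int) -> np.ndarray:
        """d logit_c / d x for every row of x (pre-softmax target)."""
        _, (zs, acts) = self.forward(x)
        delta = np.zeros((x.shape[0], self.sizes[-1]))
        delta[:, class_idx] = 1.0
        for i in range(len(self.weights) - 1, 0, -1):
            delta = (delta @ self.weights[i].T) * self._act_grad(zs[i - 1], acts[i])
        return delta @ self.weights[0].T

    # -- training -----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        lr: float = 1e-3,
        max_epochs: int = 200,
        patience: int = 20,
        seed: int = 0,
    ) -> dict:
        rng = np.random.default_rng(seed)
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_state = None
        best_epoch = 0
        bad_epochs = 0
        bs = min(self.config.batch_size, len(y))
        for epoch in range(max_epochs):
            order = rng.permutation(len(y))
            for start in range(0, len(y), bs):
                idx = order[start : start + bs]
                gw, gb = self._backward_params(x[idx], y[idx])
                t += 1
                for i in range(len(self.weights)):
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw[i]
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw[i] ** 2
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb[i]
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb[i] ** 2
                    mw_hat = m_w[i] / (1 - beta1**t)
                    vw_hat = v_w[i] / (1 - beta2**t)
                    mb_hat = m_b[i] / (1 - beta1**t)
                    vb_hat = v_b[i] / (1 - beta2**t)
                    self.weights[i] -= lr * mw_hat / (np.sqrt(vw_hat) + eps)
                    self.biases[i] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)
            val_loss = self.loss(x_val, y_val)
            if not np.isfinite(val_loss):
                raise FloatingPointError(
                    f"non-finite validation loss in config {self.config.config_id}"
                )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = ([w.copy() for w in self.weights], [b.copy() for b in self.biases])
                best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break
        if best_state is not None:
            self.weights, self.biases = best_state
        return {"best_epoch": best_epoch, "best_val_loss": float(best_val)}


@dataclass
class TrainOutcome:
    config: NetConfig
    train_accuracy: float
    val_accuracy: float
    test_accuracy: float
    train_loss: float
    val_loss: float
    test_loss: float
    confusion: np.ndarray
    per_class: dict
    selected_epoch: int
    model: MLP | None = None
    scaler: StandardScaler | None = None
    train_index: np.ndarray | None = None
    rotation_metrics: list[dict] = field(default_factory=list)


def rotation_splits(y: np.ndarray, seed: int, n_folds: int = 10, n_rotations: int = 5):
    """Yield (train_idx, val_idx, test_idx) for each fold rotation."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
    for r in range(n_rotations):
        test = np.concatenate([folds[(2 * r) % n_folds], folds[(2 * r + 1) % n_folds]])
        val = np.concatenate([folds[(2 * r + 2) % n_folds], folds[(2 * r + 3) % n_folds]])
        train = np.concatenate(
            [folds[i] for i in range(n_folds) if i not in {j % n_folds for j in (2 * r, 2 * r + 1, 2 * r + 2, 2 * r + 3)}]
        )
        yield train, val, test


def train_ann(
    config: NetConfig,
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_rotations: int = 5,
    n_folds: int = 10,
    max_epochs: int = 200,
    patience: int = 20,
) -> TrainOutcome:
    """Train/evaluate one configuration over the rotated stratified folds.

    Returns mean metrics across rotations plus the fitted model, scaler
    and training index of the best-test-accuracy rotation (used later
    for attribution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    min_class = int(np.bincount(y).min())
    if min_class < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold protocol needs at least {n_folds} rows per "
            f"class; smallest class has {min_class}"
        )
    rot_metrics = []
    best = None
    confusion_total = np.zeros((2, 2), dtype=int)
    for r, (tr, va, te) in enumerate(rotation_splits(y, seed, n_folds, n_rotations)):
        scaler = StandardScaler().fit(x[tr])
        xs_tr, xs_va, xs_te = scaler.transform(x[tr]), scaler.transform(x[va]), scaler.transform(x[te])
        model = MLP(x.shape[1], config, seed=seed + 1000 * r)
        info = model.fit(
            xs_tr, y[tr], xs_va, y[va], max_epochs=max_epochs, patience=patience, seed=seed + 1000 * r
        )
        pred_te = model.predict(xs_te)
        metrics = {
            "rotation": r,
            "train_accuracy": float(np.mean(model.predict(xs_tr) == y[tr])),
            "val_accuracy": float(np.mean(model.predict(xs_va) == y[va])),
            "test_accuracy": float(np.mean(pred_te == y[te])),
            "train_loss": model.loss(xs_tr, y[tr]),
            "val_loss": model.loss(xs_va, y[va]),
            "test_loss": model.loss(xs_te, y[te]),
            "selected_epoch": info["best_epoch"],
        }
        rot_metrics.append(metrics)
        confusion_total += confusion_matrix(y[te], pred_te, labels=(0, 1))
        if best is None or metrics["test_accuracy"] > best[0]["test_accuracy"]:
            best = (metrics, model, scaler, tr, y[te], pred_te)
    prec, rec, f1, _ = precision_recall_fscore_support(
        best[4], best[5], labels=(0, 1), zero_division=0
    )
    mean = lambda k: float(np.mean([m[k] for m in rot_metrics]))
    return TrainOutcome(
        config=config,
        train_accuracy=mean("train_accuracy"),
        val_accuracy=mean("val_accuracy"),
        test_accuracy=mean("test_accuracy"),
        train_loss=mean("train_loss"),
        val_loss=mean("val_loss"),
        test_loss=mean("test_loss"),
        confusion=confusion_total,
        per_class={
            "precision": prec.tolist(),
            "recall": rec.tolist(),
            "f1": f1.tolist(),
        },
        selected_epoch=int(best[0]["selected_epoch"]),
        model=best[1],
        scaler=best[2],
        train_index=best[3],
        rotation_metrics=rot_metrics,
    )


def select_best_model(outcomes: list[TrainOutcome], min_train_acc: float = 0.90):
    """Highest test accuracy among models whose training accuracy reaches
    ``min_train_acc``; ties by fewer parameters, then grid order.
    Falls back (with a warning flag) to the overall argmax when no model
    clears the gate."""
    if not outcomes:
        raise ValueError("no outcomes")

    def key(item):
        i, o = item
        return (-o.test_accuracy, o.config.n_parameters, i)

    gated = [(i, o) for i, o in enumerate(outcomes) if o.train_accuracy >= min_train_acc]
    warning = not gated
    pool = gated if gated else list(enumerate(outcomes))
    _, best = min(pool, key=key)
    return best, warning


def baseline_classifiers(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_rotations: int = 5,
    n_folds: int = 10,
) -> dict[str, float]:
    """Mean test accuracies of SVM-RBF, kNN(5) and LR(max_iter=1000)
    under the same rotation protocol as the ANN (fit on training folds)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    makers = {
        "svm_rbf": lambda: SVC(kernel="rbf"),
        "knn5": lambda: KNeighborsClassifier(n_neighbors=5),
        "logreg": lambda: LogisticRegression(max_iter=1000),
    }
    accs: dict[str, list[float]] = {name: [] for name in makers}
    for tr, _va, te in rotation_splits(y, seed, n_folds, n_rotations):
        scaler = StandardScaler().fit(x[tr])
        for name, make in makers.items():
            clf = make().fit(scaler.transform(x[tr]), y[tr])
            accs[name].append(float(np.mean(clf.predict(scaler.transform(x[te])) == y[te])))
    return {name: float(np.mean(v)) for name, v in accs.items()}


def build_dataset(
    features_df,
    labeled,
    dimension: str,
    mode: str = "binary",
):
    """Assemble the classification matrix from a FeatureMatrix and a
    balanced selection (V videos per label, first E_min windows each).

    Binary mode keeps labels {0, 2} mapped to {0, 1} (low vs high);
    three-class mode keeps all labels.  Features are returned raw —
    standardization happens inside the split machinery with
    training-fold statistics only.
    """
    from .features import FEATURE_NAMES

    sel = labeled.selection
    e_min = labeled.windows_per_video
    parts = []
    for _, row in sel.iterrows():
        sub = features_df[
            (features_df["subject"] == row["subject"])
            & (features_df["video_id"] == row["video_id"])
        ].sort_values("window_idx").head(e_min)
        sub = sub.assign(label=row["label"])
        parts.append(sub)
    df = pd.concat(parts, ignore_index=True) if parts else None
    if df is None or df.empty:
        raise ValueError("empty dataset after balanced selection")
    if mode == "binary":
        df = df[df["label"].isin((0, 2))]
        df = df.assign(label=df["label"].map({0: 0, 2: 1}))
    for lab in sorted(df["label"].unique()):
        if (df["label"] == lab).sum() == 0:
            raise ValueError(f"class {lab} has zero rows")
    for subject in df["subject"].unique():
        for lab in df["label"].unique():
            if ((df["subject"] == subject) & (df["label"] == lab)).sum() == 0:
                raise ValueError(f"subject {subject} has zero rows for class {lab}")
    x = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    yv = df["label"].to_numpy(dtype=int)
    meta = df[["subject", "video_id", "window_idx"]].reset_index(drop=True)
    return x, yv, meta
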