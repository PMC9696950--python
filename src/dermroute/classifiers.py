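"""The seven "players" and their training recipe.

One 3-class classifier (``s3``), three one-vs-all classifiers
(``sB``, ``sM``, ``sN``) used only for confidence scoring, and three
one-vs-one classifiers (``sBM``, ``sBN``, ``sMN``) used to refine
difficult predictions.  All share the same backbone and recipe:

* weighted cross-entropy with inverse-sample-count class weights;
* Adam, learning rate scheduled by cyclical "triangular2" (range
  1e-5 .. 1e-3, step size 2000 iterations by default);
* early stopping when validation balanced accuracy stalls;
* partial-depth fine-tuning: only the deepest fraction of parameterized
  layers is updated (64% by default).

The backbone is pluggable; the bundled desk-scale backbone is the tiny
CNN from :mod:`dermroute.nn`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nn import Adam, Sequential, softmax, tiny_cnn
from .routing import CLASSES, ClassifierBundle, OVA_NAMES, OVO_NAMES

__all__ = [
    "ClassifierSpec",
    "TrainingConfig",
    "SEVEN_SPECS",
    "CNNClassifier",
    "inverse_frequency_weights",
    "weighted_cross_entropy",
    "clr_triangular2",
    "relabel_for_task",
    "train_classifier",
    "train_bundle",
]

LOG_EPS = 1e-12  # clamp for log in the loss


@dataclass(frozen=True)
class ClassifierSpec:
    """Identity of one player: name, task type, classes, input size."""

    name: str
    task: str  # "multiclass" | "ova" | "ovo"
    positive_classes: tuple[str, ...]
    input_size: int = 456

    def __post_init__(self) -> None:
        if self.task not in ("multiclass", "ova", "ovo"):
            raise ValueError(f"unknown task {self.task!r}")
        n = {"multiclass": 3, "ova": 1, "ovo": 2}[self.task]
        if len(self.positive_classes) != n:
            raise ValueError(
                f"{self.task} player needs {n} positive class(es), "
                f"got {self.positive_classes}"
            )
        if not set(self.positive_classes) <= set(CLASSES):
            raise ValueError(f"classes must be among {CLASSES}")

    @property
    def n_outputs(self) -> int:
        return 3 if self.task == "multiclass" else 2

    @property
    def output_classes(self) -> tuple[str, ...]:
        """Label attached to each output node, in order."""
        if self.task == "multiclass":
            return CLASSES
        if self.task == "ova":
            return (self.positive_classes[0], "rest")
        return self.positive_classes


def seven_specs(input_size: int = 456) -> dict[str, ClassifierSpec]:
    """The full roster: s3, sB, sM, sN, sBM, sBN, sMN."""
    specs = {"s3": ClassifierSpec("s3", "multiclass", CLASSES, input_size)}
    for c, name in OVA_NAMES.items():
        specs[name] = ClassifierSpec(name, "ova", (c,), input_size)
    for pair, name in OVO_NAMES.items():
        a, b = sorted(pair)
        specs[name] = ClassifierSpec(name, "ovo", (a, b), input_size)
    return specs


SEVEN_SPECS = seven_specs()


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the shared training recipe.

    Defaults follow the full-scale recipe (batch 32, 150 epochs, CLR
    1e-5..1e-3 with step 2000, patience 15, 64% of layers fine-tuned);
    desk-scale runs shrink epochs and step size, not the recipe.
    """

    batch_size: int = 32
    max_epochs: int = 150
    base_lr: float = 1e-5
    max_lr: float = 1e-3
    clr_step_size: int = 2000
    patience: int = 15
    finetune_fraction: float = 0.64

    def __post_init__(self) -> None:
        if not 0 < self.base_lr < self.max_lr:
            raise ValueError("need 0 < base_lr < max_lr")
        if not 0 <= self.patience < self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if not 0.0 <= self.finetune_fraction <= 1.0:
            raise ValueError("finetune_fraction must be in [0, 1]")


def inverse_frequency_weights(class_counts: Mapping[str, int]) -> dict[str, float]:
    """Class weights proportional to 1/count, rescaled to mean 1.

    Inverse-sample-count weighting counteracts class imbalance in the
    cross-entropy loss; the mean-1 rescale keeps loss magnitudes
    comparable across the seven tasks.
    """
    for c, n in class_counts.items():
        if n <= 0:
            raise ValueError(f"class {c!r} has non-positive count {n}")
    inv = {c: 1.0 / n for c, n in class_counts.items()}
    mean = sum(inv.values()) / len(inv)
    return {c: v / mean for c, v in inv.items()}


def weighted_cross_entropy(
    q: Sequence[float], label_idx: int, weight: float = 1.0
) -> float:
    """-w * log(q_label) for a one-hot ground truth, q clamped at 1e-12."""
    q = np.asarray(q, dtype=float)
    if not 0 <= label_idx < q.shape[-1]:
        raise ValueError(f"label index {label_idx} out of range")
    return float(-weight * np.log(max(q[label_idx], LOG_EPS)))


def clr_triangular2(iteration: int, cfg: TrainingConfig) -> float:
    """Cyclical learning rate, "triangular2" policy.

    Triangular wave between ``base_lr`` and ``max_lr`` with half-period
    ``clr_step_size`` iterations; the wave's amplitude halves each cycle.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    step = cfg.clr_step_size
    cycle = np.floor(1 + iteration / (2 * step))
    x = abs(iteration / step - 2 * cycle + 1)
    lr = cfg.base_lr + (cfg.max_lr - cfg.base_lr) * max(0.0, 1 - x) / (2.0 ** (cycle - 1))
    return float(lr)


# ---------------------------------------------------------------------------
# Dataset relabeling for ova / ovo tasks
# ---------------------------------------------------------------------------

def relabel_for_task(images: np.ndarray, labels: Sequence[str],
                     spec: ClassifierSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map a 3-class dataset onto one player's task.

    multiclass: labels -> indices in (B, M, N) order.
    ova: positive class -> 0, everything else -> 1 ("rest").
    ovo: samples of the third class dropped; kept labels -> 0/1 by the
    player's class order.
    """
    labels = np.asarray(labels)
    if spec.task == "multiclass":
        idx = np.array([CLASSES.index(l) for l in labels])
        return images, idx
    if spec.task == "ova":
        pos = spec.positive_classes[0]
        return images, (labels != pos).astype(int)
    keep = np.isin(labels, spec.positive_classes)
    sub = labels[keep]
    idx = np.array([spec.positive_classes.index(l) for l in sub])
    return images[keep], idx


# ---------------------------------------------------------------------------
# Trained-classifier wrapper and the training loop
# ---------------------------------------------------------------------------

class CNNClassifier:
    """A trained player: backbone + spec, satisfying the bundle contract."""

    def __init__(self, spec: ClassifierSpec, model: Sequential):
        self.spec = spec
        self.model = model

    @property
    def classes(self) -> tuple[str, ...]:
        return self.spec.output_classes

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probabilities for one image (C, H, W) or (H, W, C)."""
        arr = np.asarray(x, dtype=np.float32)
        if arr.ndim == 3 and arr.shape[-1] == 3 and arr.shape[0] != 3:
            arr = arr.transpose(2, 0, 1)
        return self.model.predict_proba_batch(arr[None])[0]

    def predict_proba_batch(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba_batch(np.asarray(x, dtype=np.float32))

    def save(self, path: Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model.state_dict())
        meta = asdict(self.spec)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: Path, backbone_factory=None) -> "CNNClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        meta["positive_classes"] = tuple(meta["positive_classes"])
        spec = ClassifierSpec(**meta)
        factory = backbone_factory or (
            lambda s: tiny_cnn(s.n_outputs, rng=np.random.default_rng(0))
        )
        model = factory(spec)
        with np.load(path.with_suffix(".npz")) as state:
            model.load_state_dict(dict(state))
        return cls(spec, model)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    classes = np.unique(y_true)
    sens = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(sens))


def train_classifier(
    spec: ClassifierSpec,
    train_images: np.ndarray,
    train_labels: Sequence[str],
    val_images: np.ndarray,
    val_labels: Sequence[str],
    cfg: TrainingConfig,
    seed: int,
    backbone_factory=None,
) -> tuple[CNNClassifier, pd.DataFrame]:
    """Train one player; returns the best-validation-BACC checkpoint.

    Deterministic given ``seed``: the backbone init, batch shuffling and
    everything downstream use one seeded generator.  The training log has
    one row per epoch: epoch, mean train loss, validation BACC, last lr.
    """
    rng = np.random.default_rng(seed)
    x_tr, y_tr = relabel_for_task(np.asarray(train_images, np.float32), train_labels, spec)
    x_va, y_va = relabel_for_task(np.asarray(val_images, np.float32), val_labels, spec)
    uniq, counts = np.unique(y_tr, return_counts=True)
    if len(uniq) < spec.n_outputs:
        raise ValueError(
            f"player {spec.name}: training data missing a class "
            f"(present: {uniq.tolist()})"
        )
    w_by_class = inverse_frequency_weights(dict(zip(uniq.tolist(), counts.tolist())))
    weights = np.array([w_by_class[i] for i in range(spec.n_outputs)])

    factory = backbone_factory or (lambda s: tiny_cnn(s.n_outputs, rng=rng))
    model = factory(spec)
    opt = Adam(model.params)

    # partial-depth fine-tuning: freeze the shallowest layers
    players = model.parameterized_layers()
    n_frozen = int(np.floor((1.0 - cfg.finetune_fraction) * len(players)))
    for layer in players[:n_frozen]:
        opt.freeze(layer.params)

    n = len(x_tr)
    it = 0
    best_bacc, best_state, best_epoch = -1.0, None, -1
    log_rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        lr = clr_triangular2(it, cfg)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model.forward(xb)
            probs = softmax(logits, axis=1)
            wb = weights[yb]
            batch_losses = -wb * np.log(np.clip(probs[np.arange(len(yb)), yb], LOG_EPS, None))
            losses.append(batch_losses.mean())
            # gradient of mean weighted CE w.r.t. logits
            dlogits = probs * wb[:, None]
            dlogits[np.arange(len(yb)), yb] -= wb
            dlogits /= len(yb)
            model.backward(dlogits)
            lr = clr_triangular2(it, cfg)
            opt.step(model.grads, lr)
            it += 1
        val_pred = model.predict_proba_batch(x_va).argmax(axis=1)
        bacc = _balanced_accuracy(y_va, val_pred)
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                         "val_bacc": bacc, "lr": lr})
        if bacc > best_bacc:
            best_bacc, best_epoch = bacc, epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return CNNClassifier(spec, model), pd.DataFrame(log_rows)


def train_bundle(
    train_images: np.ndarray,
    train_labels: Sequence[str],
    val_images: np.ndarray,
    val_labels: Sequence[str],
    cfg: TrainingConfig,
    seed: int,
    input_size: Optional[int] = None,
    backbone_factory=None,
) -> tuple[ClassifierBundle, dict[str, pd.DataFrame]]:
    """Train all seven players on one dataset; per-player derived seeds."""
    size = input_size or train_images.shape[-2]
    members, logs = {}, {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(7) % (2**31)
    for s, (name, spec) in zip(child_seeds, seven_specs(size).items()):
        clf, log = train_classifier(
            spec, train_images, train_labels, val_images, val_labels,
            cfg, int(s), backbone_factory,
        )
        members[name] = clf
        logs[name] = log
    return ClassifierBundle(members), logs
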