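"""End-to-end desk-scale experiment glue.

Chains the modules in the order the method runs: synthesize (or load) a
dataset, split 70/10/20, augment the training split to per-class
targets, train the seven players, tune the confidence thresholds on the
validation split, and evaluate the routed framework against the 3-class
player alone on the test split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .classifiers import TrainingConfig, train_bundle
from .evaluation import (
    ConfusionMatrix,
    DEFAULT_GRID,
    auroc_ovr,
    bacc,
    grid_search_thresholds,
)
from .preprocess import (
    LabeledImageSet,
    SplitFractions,
    augment_to_target,
    split_dataset,
    to_tensor,
)
from .routing import CLASSES, ConfidenceThresholds, predict
from .synthetic import SyntheticConfig, generate_images

__all__ = ["DeskExperimentResult", "run_desk_experiment"]


@dataclass
class DeskExperimentResult:
    thresholds: ConfidenceThresholds
    framework_bacc: float
    s3_bacc: float
    per_class_auroc: dict[str, float]
    mean_auroc: float
    traces: list
    logs: dict


def run_desk_experiment(
    seed: int = 0,
    n_per_class: int = 100,
    image_size: int = 32,
    separability: float = 0.8,
    augment_target: Optional[int] = 150,
    training: Optional[TrainingConfig] = None,
    grid=DEFAULT_GRID,
    objective: str = "BACC",
    data: Optional[LabeledImageSet] = None,
) -> DeskExperimentResult:
    """Run the whole pipeline at desk scale on synthetic lesions.

    Defaults are the package's reference study conditions: 100 images
    per class at 32 px, separability 0.8, training augmented to 150 per
    class, tiny-CNN backbone.  Deterministic given ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_gen, s_split, s_aug, s_train = (int(v) for v in ss.generate_state(4) % (2**31))

    if data is None:
        data = generate_images(
            SyntheticConfig(
                {c: n_per_class for c in CLASSES}, image_size, separability, s_gen
            )
        )
    data = split_dataset(data, SplitFractions(), s_split)
    train_set, val_set, test_set = (data.subset(s) for s in ("train", "val", "test"))

    train_items = list(train_set.items)
    if augment_target is not None:
        augmented = []
        for j, c in enumerate(CLASSES):
            cls_items = [it for it in train_items if it[2] == c]
            augmented.extend(
                augment_to_target(cls_items, max(augment_target, len(cls_items)),
                                  seed=s_aug + j)
            )
        train_items = augmented
    train_aug = LabeledImageSet(train_items)

    x_tr, y_tr, _ = to_tensor(train_aug, image_size)
    x_va, y_va, _ = to_tensor(val_set, image_size)
    x_te, y_te, te_ids = to_tensor(test_set, image_size)

    cfg = training or TrainingConfig(
        batch_size=16, max_epochs=25, clr_step_size=80, patience=8
    )
    bundle, logs = train_bundle(x_tr, y_tr, x_va, y_va, cfg, s_train, image_size)

    gs = grid_search_thresholds(bundle, list(x_va), y_va, grid, objective)
    thresholds = ConfidenceThresholds(*gs.best)

    traces = [
        predict(x, bundle, thresholds, image_id=i)
        for x, i in zip(x_te, te_ids)
    ]
    fw_pred = [t.final_class for t in traces]
    fw_probs = np.vstack([t.final_probs.as_array() for t in traces])
    fw_bacc = bacc(ConfusionMatrix.from_labels(y_te, fw_pred))
    s3_pred = [t.top_class for t in traces]
    s3_bacc = bacc(ConfusionMatrix.from_labels(y_te, s3_pred))
    per_class, mean_auroc = auroc_ovr(fw_probs, y_te)

    return DeskExperimentResult(
        thresholds, fw_bacc, s3_bacc, per_class, mean_auroc, traces, logs
    )
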