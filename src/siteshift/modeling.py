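"""Classifier training with a plateau-decay schedule, plus pipeline stages.

The classifier is the small CAM-compatible CNN from :mod:`siteshift.nn`,
trained with SGD (momentum 0.9, weight decay 1e-4, initial learning rate
0.01). "Improvement" means a strict decrease of the tune loss relative to
the best seen so far; after each epoch without improvement the learning
rate is divided by 10, and training halts after three consecutive
non-improving epochs, keeping the best-tune-loss parameters. The same
schedule drives the finding classifier, the frontal/lateral view filter
and the site/department detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .interpret import FeatureMapStack, HeadWeights
from .nn import SmallCAMNet
from .synthetic import FINDINGS, StudyRecord


@dataclass
class ClassifierSpec:
    task: str = "multilabel"  # multilabel | multiclass
    n_outputs: int = 9
    bottleneck_dim: int = 15
    channels: tuple[int, ...] = (8, 16, 32, 32)
    input_size: int = 64

    def __post_init__(self) -> None:
        if self.n_outputs < 1 or self.bottleneck_dim < 1:
            raise ValueError("n_outputs and bottleneck_dim must be >= 1")


@dataclass
class TrainSchedule:
    initial_lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_decay_factor: float = 10.0
    patience_decay: int = 1  # epochs without improvement before each decay
    patience_stop: int = 3  # consecutive non-improving epochs before stopping
    max_epochs: int = 30
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience_stop < self.patience_decay:
            raise ValueError("patience_stop must be >= patience_decay")
        for name in ("initial_lr", "momentum", "weight_decay", "lr_decay_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class PlateauSchedule:
    """Reference step-through of the plateau decay / early-stop policy.

    Feed it one tune loss per epoch; it reports the learning rate to use
    for the *next* epoch and whether training should stop. Kept separate
    from the training loop so its behaviour can be tested on arbitrary
    loss sequences.
    """

    def __init__(self, schedule: TrainSchedule) -> None:
        self.schedule = schedule
        self.lr = schedule.initial_lr
        self.best_loss = np.inf
        self.stagnant = 0  # consecutive non-improving epochs

    def step(self, tune_loss: float) -> tuple[float, bool, bool]:
        """Returns (next_lr, improved, stop)."""
        improved = tune_loss < self.best_loss
        if improved:
            self.best_loss = tune_loss
            self.stagnant = 0
        else:
            self.stagnant += 1
            if self.stagnant % self.schedule.patience_decay == 0:
                self.lr /= self.schedule.lr_decay_factor
        stop = self.stagnant >= self.schedule.patience_stop
        return self.lr, improved, stop


@dataclass
class TrainedClassifier:
    net: SmallCAMNet
    spec: ClassifierSpec
    schedule: TrainSchedule
    log: list[dict] = field(default_factory=list)

    def predict_proba(self, images) -> np.ndarray:
        return self.net.predict_proba(np.asarray(images))

    def predict_logits(self, images) -> np.ndarray:
        return self.net.predict_logits(np.asarray(images))

    def extract_final_features(self, image) -> tuple[FeatureMapStack, list[HeadWeights]]:
        """X_{k,i,j} for one image plus the per-class linear head (B, B0).

        The bottleneck and classification layers are both linear, so they
        compose into a single read-out over pooled channels; applying it
        cellwise yields exact class activation maps whose spatial average
        equals the model's own logits.
        """
        image = np.asarray(image)
        if image.ndim != 2:
            raise ValueError("extract_final_features expects a single HxW image")
        fmap = self.net.final_feature_map(image)[0]  # (K, g, g)
        b, b0 = self.net.effective_head()
        heads = [HeadWeights(weights=b[c], bias=b0[c]) for c in range(b.shape[0])]
        return FeatureMapStack(x=fmap.astype(float)), heads

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_dict())
        sidecar = {
            "spec": asdict(self.spec),
            "schedule": asdict(self.schedule),
            "log": self.log,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec = ClassifierSpec(**{**sidecar["spec"], "channels": tuple(sidecar["spec"]["channels"])})
        schedule = TrainSchedule(**sidecar["schedule"])
        net = _build_net(spec, schedule.seed)
        with np.load(path.with_suffix(".npz")) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return cls(net=net, spec=spec, schedule=schedule, log=sidecar["log"])


def _build_net(spec: ClassifierSpec, seed: int) -> SmallCAMNet:
    return SmallCAMNet(
        n_outputs=spec.n_outputs,
        task=spec.task,
        channels=spec.channels,
        bottleneck_dim=spec.bottleneck_dim,
        input_size=spec.input_size,
        seed=seed,
    )


def train_classifier(
    train_images,
    train_labels,
    tune_images,
    tune_labels,
    spec: ClassifierSpec,
    schedule: TrainSchedule,
) -> TrainedClassifier:
    """Train the small CNN under the plateau-decay schedule.

    Keeps the parameters from the best-tune-loss epoch. Patient-level
    disjointness of train and tune is the caller's responsibility (the
    cohorts module provides it). Raises on empty inputs or NaN loss.
    """
    x_train = np.asarray(train_images, dtype=np.float32)
    x_tune = np.asarray(tune_images, dtype=np.float32)
    if len(x_train) == 0 or len(x_tune) == 0:
        raise ValueError("train and tune sets must be non-empty")
    y_train = np.asarray(train_labels)
    y_tune = np.asarray(tune_labels)

    net = _build_net(spec, schedule.seed)
    rng = np.random.default_rng(schedule.seed + 1)
    policy = PlateauSchedule(schedule)
    lr = schedule.initial_lr
    log: list[dict] = []
    best_state = net.state_dict()
    best_loss = np.inf

    for epoch in range(1, schedule.max_epochs + 1):
        order = rng.permutation(len(x_train))
        for start in range(0, len(order), schedule.batch_size):
            batch = order[start : start + schedule.batch_size]
            loss, grads = net.loss_and_grads(x_train[batch], y_train[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={lr}); try a smaller learning rate"
                )
            net.sgd_step(grads, lr, schedule.momentum, schedule.weight_decay)
        tune_loss = net.tune_loss(x_tune, y_tune)
        if not np.isfinite(tune_loss):
            raise RuntimeError(f"non-finite tune loss at epoch {epoch}")
        next_lr, improved, stop = policy.step(tune_loss)
        log.append({"epoch": epoch, "tune_loss": float(tune_loss), "lr": float(lr)})
        if improved:
            best_state = net.state_dict()
            best_loss = tune_loss
        lr = next_lr
        if stop:
            break

    net.load_state_dict(best_state)
    return TrainedClassifier(net=net, spec=spec, schedule=schedule, log=log)


def predict_proba(model: TrainedClassifier, images) -> np.ndarray:
    return model.predict_proba(images)


# ---------------------------------------------------------------------------
# Pipeline stages over study records


def records_to_arrays(records: list[StudyRecord], label: str | list[str] | None = None):
    """Stack record images (and optionally labels) into arrays."""
    x = np.stack([r.image for r in records]).astype(np.float32)
    if label is None:
        return x
    if isinstance(label, str):
        y = np.array([r.labels[label] for r in records], dtype=int)
    else:
        y = np.array([[r.labels[f] for f in label] for r in records], dtype=int)
    return x, y


def multilabel_targets(records: list[StudyRecord]) -> np.ndarray:
    return np.array([[r.labels[f] for f in FINDINGS] for r in records], dtype=int)


def view_filter(
    records: list[StudyRecord],
    labeled_sizes: tuple[int, int, int] = (200, 100, 102),
    schedule: TrainSchedule | None = None,
) -> tuple[list[StudyRecord], float | None]:
    """Filter a study set to (predicted) frontal views.

    A labeled subset of the given sizes (train/tune/test) is drawn from the
    records, a small binary view CNN is trained on it, its held-out view
    accuracy is reported, and the remaining records are filtered to those
    predicted frontal. If the input contains no laterals at all the input
    is returned unchanged with accuracy None.
    """
    views = np.array([r.view for r in records])
    if (views == "frontal").all():
        return list(records), None
    if (views == "lateral").all():
        raise ValueError("labeled subset would contain a single view class")
    schedule = schedule or TrainSchedule(max_epochs=10)
    n_train, n_tune, n_test = labeled_sizes
    n_label = n_train + n_tune + n_test
    if n_label > len(records):
        raise ValueError("not enough records for the labeled view subset")
    rng = np.random.default_rng(schedule.seed)
    order = rng.permutation(len(records))
    subset_idx = order[:n_label]
    rest_idx = order[n_label:]
    sub = [records[i] for i in subset_idx]
    y = np.array([1 if r.view == "frontal" else 0 for r in sub])
    if len(np.unique(y[:n_train])) < 2 or len(np.unique(y[n_train : n_train + n_tune])) < 2:
        raise ValueError("labeled subset would contain a single view class")
    size = records[0].image.shape[0]
    spec = ClassifierSpec(task="multiclass", n_outputs=2, input_size=size)
    x = np.stack([r.image for r in sub])
    model = train_classifier(
        x[:n_train], y[:n_train],
        x[n_train : n_train + n_tune], y[n_train : n_train + n_tune],
        spec, schedule,
    )
    test_slice = slice(n_train + n_tune, n_label)
    acc = None
    if n_test:
        pred = model.predict_proba(x[test_slice]).argmax(axis=1)
        acc = float(np.mean(pred == y[test_slice]))
    kept = [records[i] for i in subset_idx if records[i].view == "frontal"]
    if len(rest_idx):
        rest_images = np.stack([records[i].image for i in rest_idx])
        pred_rest = model.predict_proba(rest_images).argmax(axis=1)
        kept += [records[i] for i, p in zip(rest_idx, pred_rest) if p == 1]
    order_index = {r.study_id: k for k, r in enumerate(records)}
    kept.sort(key=lambda r: order_index[r.study_id])
    return kept, acc
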