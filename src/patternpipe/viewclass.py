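"""Binary view classifiers: standing/not-standing and left/right flank.

Both classifiers share one architecture family: an optional factor-4
average-pooling front end (used by the flank model, which is more prone to
overfitting), one to three 3x3 convolutional layers with 16/32/64 filters
each followed by 2x2 max pooling, 50% dropout, a flatten, a hidden dense
layer, and a two-way score layer.  Hyperparameters are found by random
search over the layer-count x filter grid (20 trials by default, picking
the highest validation accuracy), followed by a learning-rate sweep over
{1e-3, 1e-4, 1e-5} at the chosen depth.

The canonical best configurations from field use are exposed as
:func:`best_pose_spec` (conv [32, 64], lr 1e-5) and :func:`best_flank_spec`
(avg-pool front, conv [64, 32, 32], lr 1e-4).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import nn

__all__ = [
    "ClassifierSpec",
    "TrainedClassifier",
    "best_pose_spec",
    "best_flank_spec",
    "build_classifier",
    "spec_grid",
    "tune",
    "train",
    "classify",
    "accuracy_ci",
]

ALLOWED_FILTERS = (16, 32, 64)
ALLOWED_LR = (1e-3, 1e-4, 1e-5)


@dataclass(frozen=True)
class ClassifierSpec:
    conv_layers: tuple[int, ...] = (32, 64)
    learning_rate: float = 1e-4
    avg_pool_front: bool = False
    dropout_rate: float = 0.5
    epochs: int = 70
    input_size: int = 64
    dense_units: int = 64
    kernel: int = 3  # fixed 3x3

    def __post_init__(self) -> None:
        if not 1 <= len(self.conv_layers) <= 3:
            raise ValueError("between one and three convolutional layers")
        if any(f not in ALLOWED_FILTERS for f in self.conv_layers):
            raise ValueError(f"filter counts must be in {ALLOWED_FILTERS}")
        if not any(np.isclose(self.learning_rate, lr) for lr in ALLOWED_LR):
            raise ValueError(f"learning rate must be one of {ALLOWED_LR}")
        if self.kernel != 3:
            raise ValueError("kernel is fixed at 3x3")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def best_pose_spec(**overrides) -> ClassifierSpec:
    """Best standing/not-standing architecture: conv [32, 64], lr 1e-5."""
    base = dict(conv_layers=(32, 64), learning_rate=1e-5, epochs=70)
    base.update(overrides)
    return ClassifierSpec(**base)


def best_flank_spec(**overrides) -> ClassifierSpec:
    """Best left/right flank architecture: average-pool front end plus
    conv [64, 32, 32], lr 1e-4."""
    base = dict(conv_layers=(64, 32, 32), learning_rate=1e-4,
                avg_pool_front=True, epochs=100)
    base.update(overrides)
    return ClassifierSpec(**base)


def build_classifier(spec: ClassifierSpec, seed: int = 0,
                     channels: int = 1) -> nn.Sequential:
    """Assemble the untrained network for ``spec``.

    Layer order: [optional avg-pool /4] -> (conv3x3 -> ReLU -> max-pool)xL
    -> dropout -> flatten -> dense -> ReLU -> two-way score layer.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 77]))
    layers: list[nn.Layer] = []
    size = spec.input_size
    if spec.avg_pool_front:
        layers.append(nn.AvgPool(4))
        size //= 4
    c_in = channels
    for f in spec.conv_layers:
        layers.append(nn.Conv3x3(c_in, f, rng))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2())
        size //= 2
        c_in = f
    if size < 1:
        raise ValueError("input_size too small for this depth")
    layers.append(nn.Dropout(spec.dropout_rate, rng))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(size * size * c_in, spec.dense_units, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(spec.dense_units, 2, rng))
    return nn.Sequential(layers)


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    weights: bytes
    label_map: dict[int, str]
    metrics: dict = field(default_factory=dict)
    channels: int = 1

    def model(self) -> nn.Sequential:
        m = build_classifier(self.spec, channels=self.channels)
        m.load_state_bytes(self.weights)
        return m


def accuracy_ci(n_correct: int, n_total: int, alpha: float = 0.05) -> tuple[float, float, float]:
    """Point accuracy with a Wilson 95% binomial interval."""
    lo, hi = proportion_confint(n_correct, n_total, alpha=alpha, method="wilson")
    return n_correct / n_total, float(lo), float(hi)


def _accuracy(model: nn.Sequential, X: np.ndarray, y: np.ndarray) -> int:
    pred = model.predict_proba(X).argmax(axis=1)
    return int((pred == y).sum())


def train(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    batch_size: int = 32,
    label_map: dict[int, str] | None = None,
    epochs: int | None = None,
) -> TrainedClassifier:
    """Train ``spec`` on ``(X, y)`` with a seeded train/val/test split.

    ``X`` is (n, s, s, c) float32 in [0, 1]; ``y`` binary labels.  Reports
    train/val/test accuracies with Wilson 95% CIs.  Raises on single-class
    training data.
    """
    if X.ndim != 4:
        raise ValueError("X must be (n, size, size, channels)")
    n = len(X)
    fractions = np.asarray(split, dtype=float)
    if fractions.min() < 0 or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("split fractions must be nonnegative and sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 13]))
    order = rng.permutation(n)
    n_tr = int(round(fractions[0] * n))
    n_va = int(round(fractions[1] * n))
    idx_tr, idx_va, idx_te = order[:n_tr], order[n_tr : n_tr + n_va], order[n_tr + n_va :]
    if len(np.unique(y[idx_tr])) < 2:
        raise ValueError("training data contains a single class")
    model = build_classifier(spec, seed=seed, channels=X.shape[3])
    trainer = nn.AdamTrainer(model, lr=spec.learning_rate)
    trainer.fit(X[idx_tr], y[idx_tr], epochs=epochs or spec.epochs,
                batch_size=batch_size,
                rng=np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 29])))
    metrics = {}
    for name, idx in (("train", idx_tr), ("val", idx_va), ("test", idx_te)):
        if len(idx) == 0:
            continue
        correct = _accuracy(model, X[idx], y[idx])
        point, lo, hi = accuracy_ci(correct, len(idx))
        metrics[name] = {"accuracy": point, "ci95": (lo, hi), "n": int(len(idx))}
    return TrainedClassifier(
        spec=spec,
        weights=model.state_bytes(),
        label_map=label_map or {0: "negative", 1: "positive"},
        metrics=metrics,
        channels=X.shape[3],
    )


def spec_grid() -> list[tuple[int, ...]]:
    """All layer-count x filter combinations: 3 + 9 + 27 = 39 cells."""
    cells: list[tuple[int, ...]] = []
    for depth in (1, 2, 3):
        cells.extend(itertools.product(ALLOWED_FILTERS, repeat=depth))
    return cells


def _n_parameters(spec: ClassifierSpec, channels: int = 1) -> int:
    return build_classifier(spec, seed=0, channels=channels).n_parameters()


def tune(
    X: np.ndarray,
    y: np.ndarray,
    n_trials: int = 20,
    epochs: int = 70,
    seed: int = 0,
    avg_pool_front: bool = False,
    input_size: int | None = None,
    base_lr: float = 1e-4,
    batch_size: int = 32,
    split: tuple[float, float, float] = (0.8, 0.2, 0.0),
) -> tuple[ClassifierSpec, list[dict]]:
    """Random architecture search then learning-rate sweep.

    Samples ``n_trials`` distinct cells uniformly (without replacement when
    the grid is large enough) from the 39-cell layer/filter grid, trains
    each at ``base_lr`` and keeps the architecture with the highest
    validation accuracy — ties broken by fewer parameters, then earlier
    trial.  The learning rate is then swept over {1e-3, 1e-4, 1e-5} at the
    chosen depth.  Returns the winning spec and the trial history.
    """
    if len(X) == 0:
        raise ValueError("empty data")
    if input_size is None:
        input_size = X.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 101]))
    grid = spec_grid()
    if n_trials <= len(grid):
        chosen = [grid[i] for i in rng.choice(len(grid), size=n_trials, replace=False)]
    else:
        chosen = [grid[i] for i in rng.choice(len(grid), size=n_trials, replace=True)]
    history: list[dict] = []

    def run(spec: ClassifierSpec, trial: int) -> dict:
        fitted = train(spec, X, y, split=split, seed=seed + trial,
                       batch_size=batch_size, epochs=epochs)
        rec = {
            "trial": trial,
            "conv_layers": spec.conv_layers,
            "learning_rate": spec.learning_rate,
            "val_accuracy": fitted.metrics["val"]["accuracy"],
            "n_parameters": _n_parameters(spec, X.shape[3]),
        }
        history.append(rec)
        return rec

    best_rec = None
    for t, cell in enumerate(chosen):
        spec = ClassifierSpec(conv_layers=tuple(cell), learning_rate=base_lr,
                              avg_pool_front=avg_pool_front, epochs=epochs,
                              input_size=input_size)
        rec = run(spec, t)
        key = (-rec["val_accuracy"], rec["n_parameters"], rec["trial"])
        if best_rec is None or key < best_key:
            best_rec, best_key = rec, key

    best_arch = tuple(best_rec["conv_layers"])
    best_lr, best_lr_acc = base_lr, best_rec["val_accuracy"]
    for t, lr in enumerate(ALLOWED_LR):
        if np.isclose(lr, base_lr):
            continue
        spec = ClassifierSpec(conv_layers=best_arch, learning_rate=lr,
                              avg_pool_front=avg_pool_front, epochs=epochs,
                              input_size=input_size)
        rec = run(spec, len(chosen) + t)
        if rec["val_accuracy"] > best_lr_acc:
            best_lr, best_lr_acc = lr, rec["val_accuracy"]

    winner = ClassifierSpec(conv_layers=best_arch, learning_rate=best_lr,
                            avg_pool_front=avg_pool_front, epochs=epochs,
                            input_size=input_size)
    return winner, history


def classify(
    trained: TrainedClassifier, X: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Apply a trained classifier; returns (labels, class-1 scores).
    Deterministic given the stored weights."""
    if len(X) == 0:
        return [], np.zeros(0)
    model = trained.model()
    probs = model.predict_proba(X)
    labels = [trained.label_map[int(k)] for k in probs.argmax(axis=1)]
    return labels, probs[:, 1]
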