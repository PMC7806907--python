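"""Fold construction, augmentation, SVM and CNN training, and evaluation.

The evaluation protocol is a 4-way rotation: items are randomly divided
into four equal-as-possible subsets; each rotation uses two subsets for
training, one for validation (hyper-parameter selection) and one for
testing, and the roles rotate so every subset is the test set exactly
once.  Test predictions are pooled over all four rotations into a single
confusion matrix ("total accuracy and all the images").

Training images are augmented eight-fold with the dihedral transforms
(4 rotations x optional horizontal flip), strictly after the split.  CNN
inputs follow the random-resized-crop (train) / resize-then-centre-crop
(eval) protocol, one patch per image.  The SVM is a radial-basis-function
machine grid-searched over gamma 1e-1..1e-5 and cost 1..1e5 in decade
steps on z-scored features (training-fold statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cnn import SmallCNN
from .synthforest import CLASS_NAMES

__all__ = [
    "FoldPlan",
    "TrainConfig",
    "EvaluationReport",
    "SVMResult",
    "CNNResult",
    "make_fold_plan",
    "augment_dihedral",
    "preprocess_patch",
    "train_svm_grid",
    "train_cnn",
    "evaluate_predictions",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_COST_GRID",
]

DEFAULT_GAMMA_GRID = tuple(10.0 ** -e for e in range(1, 6))   # 1e-1 .. 1e-5
DEFAULT_COST_GRID = tuple(10.0 ** e for e in range(0, 6))     # 1 .. 1e5


@dataclass(frozen=True)
class FoldPlan:
    """Four disjoint subsets and the four train/validation/test rotations."""

    subsets: tuple[tuple, ...]       # 4 tuples of item ids
    seed: int

    def __post_init__(self) -> None:
        if len(self.subsets) != 4:
            raise ValueError("fold plan needs exactly 4 subsets")
        flat = [i for s in self.subsets for i in s]
        if len(flat) != len(set(flat)):
            raise ValueError("subsets must be disjoint")

    @property
    def n_rotations(self) -> int:
        return 4

    def rotation(self, r: int) -> tuple[list, list, list]:
        """(train_ids, validation_ids, test_ids) for rotation ``r`` in 0..3."""
        if not 0 <= r < 4:
            raise ValueError("rotation index must be in 0..3")
        order = [(r + k) % 4 for k in range(4)]
        train = [i for k in order[:2] for i in self.subsets[k]]
        val = list(self.subsets[order[2]])
        test = list(self.subsets[order[3]])
        return train, val, test


def make_fold_plan(item_ids, seed: int = 0) -> FoldPlan:
    """Seeded random partition of items into 4 subsets plus role rotations."""
    ids = list(item_ids)
    if len(ids) < 4:
        raise ValueError("need at least 4 items for a 4-fold plan")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    subsets = tuple(tuple(ids[i] for i in perm[k::4]) for k in range(4))
    return FoldPlan(subsets, seed)


def augment_dihedral(image: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral transforms of an image (original included).

    Accepts (rows, cols) or (bands, rows, cols); spatial axes are the last
    two either way.
    """
    img = np.asarray(image)
    out = []
    for flip in (False, True):
        base = img[..., :, ::-1] if flip else img
        for rot in range(4):
            out.append(np.rot90(base, rot, axes=(-2, -1)).copy())
    return out


def _resize_chw(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a (bands, rows, cols) image."""
    return np.stack([
        _sk_resize(band.astype(float), shape, order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
        for band in img])


@dataclass(frozen=True)
class TrainConfig:
    """Patch protocol and CNN training knobs."""

    patch_size: int = 224
    resize_size: int = 256
    augment: bool = True
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    channels: tuple[int, ...] = (16, 32, 32)
    seed: int = 0
    # random-resized-crop bounds (common convention)
    crop_area: tuple[float, float] = (0.08, 1.0)
    crop_aspect: tuple[float, float] = (3 / 4, 4 / 3)

    def __post_init__(self) -> None:
        if self.patch_size > self.resize_size:
            raise ValueError("patch_size must be <= resize_size")


def preprocess_patch(image: np.ndarray, mode: str,
                     cfg: TrainConfig = TrainConfig(),
                     seed: int = 0) -> np.ndarray:
    """Produce exactly one ``patch_size`` square patch from an object image.

    ``train``: seeded random-resized crop (random area and aspect within the
    configured bounds) resized to ``patch_size``.  ``eval``: shorter side
    resized to ``resize_size`` then a centre crop of ``patch_size``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    _, h, w = img.shape
    if h == 0 or w == 0:
        raise ValueError("empty image")
    ps = cfg.patch_size
    if mode == "train":
        rng = np.random.default_rng(seed)
        for _ in range(10):
            area = rng.uniform(*cfg.crop_area) * h * w
            log_aspect = rng.uniform(*np.log(cfg.crop_aspect))
            aspect = float(np.exp(log_aspect))
            cw = int(round(np.sqrt(area * aspect)))
            ch = int(round(np.sqrt(area / aspect)))
            if 0 < cw <= w and 0 < ch <= h:
                top = int(rng.integers(0, h - ch + 1))
                left = int(rng.integers(0, w - cw + 1))
                crop = img[:, top:top + ch, left:left + cw]
                return _resize_chw(crop, (ps, ps))
        # fallback: centre square
        side = min(h, w)
        top, left = (h - side) // 2, (w - side) // 2
        return _resize_chw(img[:, top:top + side, left:left + side], (ps, ps))
    if mode == "eval":
        scale = cfg.resize_size / min(h, w)
        nh, nw = max(int(round(h * scale)), cfg.resize_size), \
            max(int(round(w * scale)), cfg.resize_size)
        resized = _resize_chw(img, (nh, nw))
        top, left = (nh - ps) // 2, (nw - ps) // 2
        return resized[:, top:top + ps, left:left + ps]
    raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion matrix (ground truth rows) and the summary metrics."""

    confusion: np.ndarray
    overall_accuracy: float
    kappa: float
    macro_f1: float
    per_class_f1: np.ndarray
    class_names: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        names = self.class_names or tuple(
            str(i + 1) for i in range(self.confusion.shape[0]))
        return pd.DataFrame(self.confusion, index=names, columns=names)


def evaluate_predictions(truth, predictions, n_classes: int = 7,
                         class_names: tuple[str, ...] = ()) -> EvaluationReport:
    """Overall accuracy, Cohen's Kappa, macro and per-class F1.

    Labels are 1-based class codes.  Kappa is (p_o - p_e) / (1 - p_e) with
    the chance agreement p_e from the row/column marginals; per-class F1 is
    the harmonic mean of precision and recall (0 where undefined); macro F1
    is their unweighted mean.
    """
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth and predictions must have equal length")
    if ((t < 1) | (t > n_classes) | (p < 1) | (p > n_classes)).any():
        raise ValueError(f"labels must lie in 1..{n_classes}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t - 1, p - 1), 1)
    total = cm.sum()
    p_o = np.trace(cm) / total
    row = cm.sum(axis=1) / total
    col = cm.sum(axis=0) / total
    p_e = float((row * col).sum())
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    tp = np.diag(cm).astype(float)
    precision = np.divide(tp, cm.sum(axis=0), out=np.zeros(n_classes),
                          where=cm.sum(axis=0) > 0)
    recall = np.divide(tp, cm.sum(axis=1), out=np.zeros(n_classes),
                       where=cm.sum(axis=1) > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros(n_classes),
                   where=denom > 0)
    if not class_names and n_classes == 7:
        class_names = tuple(CLASS_NAMES[i] for i in range(1, 8))
    return EvaluationReport(cm, float(p_o), float(kappa), float(f1.mean()),
                            f1, class_names)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclass
class SVMResult:
    models: list                     # fitted pipeline per rotation
    best_params: list[tuple[float, float]]   # (gamma, cost) per rotation
    validation_accuracies: list[float]
    test_truth: np.ndarray
    test_predictions: np.ndarray
    report: EvaluationReport | None = None


def train_svm_grid(features: pd.DataFrame, plan: FoldPlan,
                   gamma_grid=None, cost_grid=None, seed: int = 0,
                   n_classes: int = 7) -> SVMResult:
    """RBF SVM with a (gamma, cost) grid search per rotation.

    ``features`` is an object-feature table indexed by object id with a
    ``label`` column.  Features are z-scored with training-fold statistics.
    Test predictions of all rotations are pooled into one report.
    """
    gamma_grid = tuple(gamma_grid or DEFAULT_GAMMA_GRID)
    cost_grid = tuple(cost_grid or DEFAULT_COST_GRID)
    X = features.drop(columns=["label"])
    y = features["label"]
    models, best_params, val_accs = [], [], []
    pooled_t, pooled_p = [], []
    for r in range(plan.n_rotations):
        train_ids, val_ids, test_ids = plan.rotation(r)
        train_ids = [i for i in train_ids if i in X.index]
        val_ids = [i for i in val_ids if i in X.index]
        test_ids = [i for i in test_ids if i in X.index]
        y_train = y.loc[train_ids]
        if y_train.nunique() < 2:
            raise ValueError(f"rotation {r}: training fold has a single class")
        scaler = StandardScaler().fit(X.loc[train_ids])
        Xt = scaler.transform(X.loc[train_ids])
        Xv = scaler.transform(X.loc[val_ids])
        best = (-1.0, None, None)
        for gamma in gamma_grid:
            for cost in cost_grid:
                svc = SVC(kernel="rbf", gamma=gamma, C=cost,
                          random_state=seed)
                svc.fit(Xt, y_train)
                acc = float((svc.predict(Xv) == y.loc[val_ids]).mean())
                if acc > best[0]:
                    best = (acc, gamma, cost)
        val_acc, gamma, cost = best
        svc = SVC(kernel="rbf", gamma=gamma, C=cost, random_state=seed)
        svc.fit(Xt, y_train)
        models.append((scaler, svc))
        best_params.append((gamma, cost))
        val_accs.append(val_acc)
        pooled_t.append(y.loc[test_ids].to_numpy())
        pooled_p.append(svc.predict(scaler.transform(X.loc[test_ids])))
    truth = np.concatenate(pooled_t)
    preds = np.concatenate(pooled_p)
    report = evaluate_predictions(truth, preds, n_classes=n_classes)
    return SVMResult(models, best_params, val_accs, truth, preds, report)


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

@dataclass
class CNNResult:
    models: list[SmallCNN]
    test_truth: np.ndarray
    test_predictions: np.ndarray
    report: EvaluationReport | None = None
    test_ids: list = field(default_factory=list)


def train_cnn(images: dict, labels: dict, plan: FoldPlan,
              cfg: TrainConfig = TrainConfig(), n_classes: int = 7) -> CNNResult:
    """Train the small CNN per rotation and pool the test predictions.

    ``images`` maps item id to a (3, h, w) array (masked object image);
    ``labels`` maps item id to a 1-based class code.  Training folds are
    augmented eight-fold with the dihedral group before cropping; the
    output layer width equals ``n_classes``.
    """
    models = []
    pooled_t, pooled_p, pooled_ids = [], [], []
    for r in range(plan.n_rotations):
        train_ids, val_ids, test_ids = plan.rotation(r)
        train_labels = {labels[i] for i in train_ids}
        missing = set(labels[i] for i in labels) - train_labels
        if missing:
            raise ValueError(
                f"rotation {r}: classes absent from training folds: {sorted(missing)}")
        Xtr, ytr = [], []
        for n_item, item in enumerate(train_ids):
            variants = (augment_dihedral(images[item]) if cfg.augment
                        else [images[item]])
            for v_i, variant in enumerate(variants):
                patch = preprocess_patch(
                    variant, "train", cfg,
                    seed=(cfg.seed * 1000003 + r * 9176 + n_item * 8 + v_i)
                    % (2 ** 31))
                Xtr.append(patch / 255.0)
                ytr.append(labels[item] - 1)
        model = SmallCNN(in_channels=3, n_classes=n_classes,
                         channels=cfg.channels, seed=cfg.seed + r)
        model.fit(np.asarray(Xtr), np.asarray(ytr), epochs=cfg.epochs,
                  lr=cfg.learning_rate, batch_size=cfg.batch_size,
                  seed=cfg.seed + 17 * r)
        models.append(model)
        Xte = np.asarray([preprocess_patch(images[i], "eval", cfg) / 255.0
                          for i in test_ids])
        preds = model.predict(Xte) + 1
        pooled_t.append(np.asarray([labels[i] for i in test_ids]))
        pooled_p.append(preds)
        pooled_ids.extend(test_ids)
    truth = np.concatenate(pooled_t)
    preds = np.concatenate(pooled_p)
    report = evaluate_predictions(truth, preds, n_classes=n_classes)
    return CNNResult(models, truth, preds, report, pooled_ids)
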