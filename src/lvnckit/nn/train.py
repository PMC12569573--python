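"""Training loop, rotation augmentation and patient-level CV splitting.

Training minimises ``L = L_lovasz + L_bce`` with RAdam (initial learning
rate 0.005).  Augmentation applies one of the three right-angle rotations
with probability 0.25, jointly to image and mask.  Cross-validation splits
are made at patient granularity — never by slice — holding out 20 % of
patients for testing and stratifying both the hold-out and the 5 folds by
the LVNC label (TV% > 27.4).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from ..quantify import LVNC_TV_THRESHOLD, classify_lvnc, dice
from .losses import total_loss
from .optim import RAdam
from .vitunet import ViTUNet

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "augment",
    "split_patients",
    "auto_class_weights",
    "train",
    "studies_to_arrays",
    "write_history_csv",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters; defaults follow the training recipe."""

    lr: float = 0.005
    rot_prob: float = 0.25
    epochs: int = 10
    batch_size: int = 8
    bce_class_weights: Sequence[float] | Literal["auto"] = "auto"
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0.0 <= self.rot_prob <= 1.0):
            raise ValueError("rot_prob must lie in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class FoldSplit:
    """Hold-out test patients plus 5 stratified folds over the remainder."""

    test_patients: set[str]
    folds: list[tuple[set[str], set[str]]] = field(default_factory=list)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    rot_prob: float = 0.25,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """With probability ``rot_prob``, rotate image and mask jointly.

    The rotation is chosen uniformly from {90, 180, 270} degrees; otherwise
    both arrays pass through unchanged.
    """
    if not (0.0 <= rot_prob <= 1.0):
        raise ValueError("rot_prob must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    if rng.random() < rot_prob:
        k = int(rng.integers(1, 4))
        return np.rot90(image, k).copy(), np.rot90(mask, k).copy()
    return image, mask


def split_patients(
    studies: Sequence,
    seed: int = 0,
    threshold: float = LVNC_TV_THRESHOLD,
    n_folds: int = 5,
    test_fraction: float = 0.2,
) -> FoldSplit:
    """Patient-level stratified split: 20 % test, 5 CV folds on the rest.

    Stratification uses the boolean LVNC label ``tv_percent_truth >
    threshold``; the validation folds partition the 80 % exactly and each
    keeps the label mix within one patient of proportional.
    """
    if len(studies) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} patients to form {n_folds} folds")
    ids = np.array([s.patient_id for s in studies])
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    labels = np.array([classify_lvnc(s.tv_percent_truth, threshold) for s in studies])
    strat = labels if 0 < labels.sum() < len(labels) else None
    dev_ids, test_ids, dev_labels, _ = train_test_split(
        ids, labels, test_size=test_fraction, stratify=strat, random_state=seed
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_labels = dev_labels if 0 < dev_labels.sum() < len(dev_labels) else np.zeros_like(dev_labels)
    folds = [
        (set(dev_ids[tr]), set(dev_ids[va]))
        for tr, va in skf.split(dev_ids, fold_labels)
    ]
    return FoldSplit(test_patients=set(test_ids), folds=folds)


def studies_to_arrays(studies: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Stack all slices of the given patients: z-scored images and masks."""
    images, masks = [], []
    for study in studies:
        for img, msk in study.slices:
            std = img.std()
            images.append((img - img.mean()) / std if std > 1e-12 else img * 0.0)
            masks.append(msk)
    return np.stack(images), np.stack(masks)


def auto_class_weights(masks: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """Inverse relative pixel frequency per class, normalised to mean 1."""
    counts = np.array(
        [max(1, int(np.count_nonzero(masks == c))) for c in range(n_classes)],
        dtype=float,
    )
    w = counts.sum() / counts
    return w / w.mean()


def train(
    model: ViTUNet,
    studies: Sequence,
    cfg: TrainConfig = TrainConfig(),
    val_studies: Sequence | None = None,
) -> list[dict]:
    """Train the network on the slices of ``studies``.

    Returns the per-epoch history: dicts with ``epoch``, ``train_loss`` and,
    when a validation set is given, ``val_loss`` and ``val_dice`` (mean
    foreground Dice).  Early stopping monitors the validation loss with the
    configured patience.  Augmentation touches training samples only; runs
    are fully reproducible from ``cfg.seed``.
    """
    images, masks = studies_to_arrays(studies)
    if images.shape[0] == 0:
        raise ValueError("training set is empty")
    if cfg.bce_class_weights == "auto":
        weights = auto_class_weights(masks)
    else:
        weights = np.asarray(cfg.bce_class_weights, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    opt = RAdam(model.parameters(), lr=cfg.lr)
    history: list[dict] = []
    best_val = np.inf
    stale = 0
    val_data = (
        studies_to_arrays(val_studies) if val_studies is not None else None
    )
    n = images.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_imgs, batch_masks = [], []
            for i in idx:
                im, mk = augment(images[i], masks[i], cfg.rot_prob, rng)
                batch_imgs.append(im)
                batch_masks.append(mk)
            x = np.stack(batch_imgs)
            y = np.stack(batch_masks)
            probs = model.forward(x, train=True)
            loss, dprobs = total_loss(probs, y, weights)
            opt.zero_grad()
            model.backward(dprobs)
            opt.step()
            epoch_losses.append(loss)
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "lr": cfg.lr,
        }
        if val_data is not None:
            vx, vy = val_data
            v_losses, v_dices = [], []
            for start in range(0, vx.shape[0], cfg.batch_size):
                xb = vx[start : start + cfg.batch_size]
                yb = vy[start : start + cfg.batch_size]
                probs = model.forward(xb, train=False)
                v_losses.append(total_loss(probs, yb, weights)[0])
                pred = probs.argmax(axis=1)
                for p_i, y_i in zip(pred, yb):
                    v_dices.append(np.mean([dice(p_i, y_i, c) for c in (1, 2, 3)]))
            row["val_loss"] = float(np.mean(v_losses))
            row["val_dice"] = float(np.mean(v_dices))
            if row["val_loss"] < best_val - 1e-9:
                best_val = row["val_loss"]
                stale = 0
            else:
                stale += 1
        history.append(row)
        if val_data is not None and stale > cfg.patience:
            break
    return history


def write_history_csv(history: Sequence[dict], path: str | Path) -> None:
    """Persist a training history as CSV (epoch, losses, metrics)."""
    fields = sorted({k for row in history for k in row}, key=lambda k: (k != "epoch", k))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(history)
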