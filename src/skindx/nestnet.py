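"""Dermal-nest typing: dataset construction, classifier, DMN partition.

Dermal nests are the key discriminator between a melanocytic nevus and
invasive melanoma: benign-class cases (MMD, MIS) can only contain nevus
dermal nests, because any melanoma dermal nest would move the case into
an invasive category.  That diagnostic logic is exploited twice here:

* ``relabel_dmn_by_class`` bulk-relabels segmented dermal nests on
  benign-class cases as nevus type (and *refuses* invasive-class cases,
  whose nests are of unknown mixed type), producing extra nevus samples
  to correct the heavy class imbalance of annotated nests;
* ``split_dmn`` partitions a dermal-nest mask into melanoma and nevus
  parts with a trained window classifier, where nevus is the complement:
  melanoma must be positively detected.

Nest samples are 100 x 100 windows at the nominal base scale with all
non-nest pixels zeroed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from . import nn
from .labels import DiagnosisClass
from .synthdata import SlideCase

logger = logging.getLogger(__name__)

#: Sampling window side length (pixels at the nominal 20x base).
PATCH_SIZE = 100

NEVUS, MELANOMA = "nevus", "melanoma"


@dataclass
class NestPatch:
    """A 100 x 100 nest window: non-nest pixels zeroed, with its label."""

    image: np.ndarray                       # (100, 100, 3)
    label: str                              # "nevus" | "melanoma"
    source: Tuple = ()                      # (case_id, slice_id, (row, col))
    provenance: str = "annotated"           # "annotated" | "relabeled"

    def __post_init__(self):
        if self.image.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"nest patch must be {PATCH_SIZE}x{PATCH_SIZE}, "
                f"got {self.image.shape[:2]}")
        if self.label not in (NEVUS, MELANOMA):
            raise ValueError(f"label must be nevus/melanoma, got {self.label!r}")


@dataclass
class NestTrainSet:
    """Training pool of nest patches with per-label bookkeeping."""

    patches: List[NestPatch] = field(default_factory=list)

    @property
    def counts(self) -> Dict[str, int]:
        c = {NEVUS: 0, MELANOMA: 0}
        for p in self.patches:
            c[p.label] += 1
        return c

    def __len__(self) -> int:
        return len(self.patches)


def sample_nests(rgb: np.ndarray, dmn_mask: np.ndarray, label: str,
                 stride: int = PATCH_SIZE, min_coverage: float = 0.05,
                 source: Tuple = ()) -> List[NestPatch]:
    """Slide a 100 x 100 window over the slice and emit nest patches.

    A window is emitted when its dermal-nest coverage is at least
    ``min_coverage`` (fraction of window pixels); non-nest pixels are
    zeroed so the patch shows only the nest.  A raster smaller than the
    window yields an empty list with a warning.
    """
    rgb = np.asarray(rgb)
    dmn_mask = np.asarray(dmn_mask)
    if rgb.shape[:2] != dmn_mask.shape:
        raise ValueError(f"shape mismatch: rgb {rgb.shape[:2]} vs mask {dmn_mask.shape}")
    h, w = dmn_mask.shape
    if h < PATCH_SIZE or w < PATCH_SIZE:
        warnings.warn(
            f"raster {h}x{w} smaller than the {PATCH_SIZE}x{PATCH_SIZE} "
            f"sampling window; no nest patches emitted")
        return []
    patches = []
    thresh = min_coverage * PATCH_SIZE * PATCH_SIZE
    for r in range(0, h - PATCH_SIZE + 1, stride):
        for c in range(0, w - PATCH_SIZE + 1, stride):
            win = dmn_mask[r:r + PATCH_SIZE, c:c + PATCH_SIZE]
            if win.sum() >= max(thresh, 1):
                img = rgb[r:r + PATCH_SIZE, c:c + PATCH_SIZE].copy()
                img *= win[..., None].astype(img.dtype)
                patches.append(NestPatch(image=img, label=label,
                                         source=source + ((r, c),)))
    return patches


def relabel_dmn_by_class(case: SlideCase,
                         dmn_mask: np.ndarray) -> Optional[np.ndarray]:
    """Re-type a dermal-nest mask as all-nevus, or refuse.

    Benign-class cases (MMD, MIS) can only contain nevus dermal nests, so
    their DMN mask is returned re-typed DMN-N in full.  For invasive
    cases (T1a, T1b) the mask is unusable for relabeling — its nests may
    mix both types — and ``None`` is returned.
    """
    dmn_mask = np.asarray(dmn_mask)
    shapes = {s[1].shape for s in case.slices}
    if dmn_mask.shape not in shapes:
        raise ValueError(
            f"dmn_mask shape {dmn_mask.shape} matches no slice of case "
            f"{case.case_id} (slice shapes: {sorted(shapes)})")
    if case.diagnosis >= DiagnosisClass.T1a:
        return None
    return (dmn_mask > 0).astype(np.uint8)


def rebalance(annotated: NestTrainSet, relabeled_pool: Sequence[NestPatch],
              rng_seed: int = 0) -> NestTrainSet:
    """Balance nevus/melanoma counts using relabeled nevus patches.

    Uniformly samples (without replacement) nevus patches from the pool
    until the counts match.  If the pool cannot cover the deficit, the
    majority class is subsampled down instead and the shortfall logged.
    All annotated patches are kept whenever balancing upward succeeds.
    """
    for p in relabeled_pool:
        if p.label != NEVUS:
            raise ValueError("relabeled pool must contain only nevus patches")
    rng = np.random.default_rng(rng_seed)
    counts = annotated.counts
    n_nev, n_mel = counts[NEVUS], counts[MELANOMA]
    patches = list(annotated.patches)
    if n_mel > n_nev:
        deficit = n_mel - n_nev
        take = min(deficit, len(relabeled_pool))
        idx = rng.choice(len(relabeled_pool), size=take, replace=False)
        patches.extend(relabeled_pool[i] for i in sorted(idx))
        n_nev += take
        if take < deficit:
            logger.warning(
                "relabeled pool short by %d nevus patches; balancing "
                "downward to %d per class", deficit - take, n_nev)
            patches = _subsample_label(patches, MELANOMA, n_nev, rng)
    elif n_nev > n_mel:
        logger.warning(
            "nevus already the majority (%d vs %d); balancing downward",
            n_nev, n_mel)
        patches = _subsample_label(patches, NEVUS, n_mel, rng)
    return NestTrainSet(patches=patches)


def _subsample_label(patches: List[NestPatch], label: str, keep: int,
                     rng: np.random.Generator) -> List[NestPatch]:
    idx = [i for i, p in enumerate(patches) if p.label == label]
    drop = set(rng.choice(idx, size=len(idx) - keep, replace=False).tolist())
    return [p for i, p in enumerate(patches) if i not in drop]


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

class _TinyNestNet(nn.Module):
    """Small CNN: two strided 3x3 convolutions, GAP, linear head."""

    def __init__(self, in_channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(in_channels, 8, 3, rng, stride=2, pad=1)
        self.conv2 = nn.Conv2d(8, 16, 3, rng, stride=2, pad=1)
        self.head = nn.Linear(16, 2, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        return self.head(h.mean(axis=(1, 2)))


class NestClassifier(BaseEstimator, ClassifierMixin):
    """Binary nevus/melanoma CNN on 100 x 100 nest windows.

    Only the self-contained ``tiny`` backbone is available: the
    densenet/shufflenet/resnet options of the full-scale study rely on
    pretrained torchvision weights that are not bundled with this
    package.  Training applies random crop (pad-and-crop), random
    90-degree rotation, horizontal flip and per-channel normalization,
    and minimizes cross-entropy with Adam.  Fully deterministic in
    ``seed``.
    """

    _ALLOWED_BACKBONES = ("tiny", "densenet", "shufflenet", "resnet")

    def __init__(self, backbone: str = "tiny", epochs: int = 20,
                 lr: float = 0.001, batch_size: int = 32, seed: int = 0,
                 augment: bool = True):
        self.backbone = backbone
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed
        self.augment = augment

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], NestPatch):
            X = np.stack([p.image for p in X])
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4:
            raise ValueError(f"expected (N, H, W, C) patches, got {X.shape}")
        return X / 255.0 - 0.5

    def _augment_batch(self, xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty_like(xb)
        pad = 6
        for i, x in enumerate(xb):
            k = int(rng.integers(4))
            x = np.rot90(x, k, axes=(0, 1))
            if rng.random() < 0.5:
                x = x[:, ::-1]
            xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)), mode="edge")
            r = int(rng.integers(2 * pad + 1))
            c = int(rng.integers(2 * pad + 1))
            out[i] = xp[r:r + x.shape[0], c:c + x.shape[1]]
        return out

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y) -> "NestClassifier":
        if self.backbone not in self._ALLOWED_BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.backbone != "tiny":
            raise RuntimeError(
                f"backbone {self.backbone!r} needs pretrained weights that "
                f"are not bundled; use backbone='tiny'")
        Xf = self._as_array(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError(
                f"training set contains a single class {self.classes_!r}; "
                f"both nest types are required")
        yi = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.seed)
        net = _TinyNestNet(Xf.shape[-1], rng)
        opt = nn.Adam(net.parameters(), lr=self.lr)
        n = len(Xf)
        onehot = np.eye(2, dtype=np.float32)[yi]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = Xf[idx]
                if self.augment:
                    xb = self._augment_batch(xb, rng)
                logits = net(nn.Tensor(xb))
                loss = nn.cross_entropy_soft(logits, onehot[idx])
                net.zero_grad()
                loss.backward()
                opt.step()
        self.net_ = net
        self.n_channels_ = Xf.shape[-1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        Xf = self._as_array(X)
        logits = self.net_(nn.Tensor(Xf)).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                   positive: str = MELANOMA) -> Dict[str, float]:
    """F-score, precision, sensitivity, specificity with melanoma positive."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {"f_score": f, "precision": prec, "sensitivity": sens,
            "specificity": spec}


def train_nest_classifier(train: NestTrainSet, backbone: str = "tiny",
                          epochs: int = 20, lr: float = 0.001, seed: int = 0,
                          holdout: float = 0.2
                          ) -> Tuple[NestClassifier, Dict[str, float]]:
    """Train the nest classifier and report held-out binary metrics."""
    X = np.stack([p.image for p in train.patches])
    y = np.asarray([p.label for p in train.patches])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both nest types")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout, random_state=seed, stratify=y)
    model = NestClassifier(backbone=backbone, epochs=epochs, lr=lr, seed=seed)
    model.fit(X_tr, y_tr)
    metrics = binary_metrics(y_te, model.predict(X_te))
    return model, metrics


def split_dmn(rgb: np.ndarray, dmn_mask: np.ndarray,
              model) -> Tuple[np.ndarray, np.ndarray]:
    """Partition a DMN mask into (DMN-M, DMN-N) via window classification.

    The mask is tiled into 100 x 100 windows at stride 100 (with a final
    window anchored to each border so every pixel is covered when the
    raster is at least window-sized).  DMN pixels inside windows the model
    calls melanoma go to the melanoma mask; every remaining DMN pixel —
    including any on rasters smaller than a window — defaults to nevus.
    OR of the outputs equals the input mask and their AND is empty.
    """
    rgb = np.asarray(rgb)
    dmn_mask = (np.asarray(dmn_mask) > 0).astype(np.uint8)
    if rgb.shape[:2] != dmn_mask.shape:
        raise ValueError(f"shape mismatch: rgb {rgb.shape[:2]} vs mask {dmn_mask.shape}")
    h, w = dmn_mask.shape
    dmn_m = np.zeros_like(dmn_mask)
    if h >= PATCH_SIZE and w >= PATCH_SIZE and dmn_mask.any():
        rows = list(range(0, h - PATCH_SIZE + 1, PATCH_SIZE))
        cols = list(range(0, w - PATCH_SIZE + 1, PATCH_SIZE))
        if rows[-1] != h - PATCH_SIZE:
            rows.append(h - PATCH_SIZE)
        if cols[-1] != w - PATCH_SIZE:
            cols.append(w - PATCH_SIZE)
        windows, origins = [], []
        for r in rows:
            for c in cols:
                win = dmn_mask[r:r + PATCH_SIZE, c:c + PATCH_SIZE]
                if win.any():
                    img = rgb[r:r + PATCH_SIZE, c:c + PATCH_SIZE].copy()
                    img *= win[..., None].astype(img.dtype)
                    windows.append(img)
                    origins.append((r, c))
        if windows:
            preds = model.predict(np.stack(windows))
            for (r, c), pred in zip(origins, preds):
                if pred == MELANOMA:
                    sl = (slice(r, r + PATCH_SIZE), slice(c, c + PATCH_SIZE))
                    dmn_m[sl] |= dmn_mask[sl]
    dmn_n = dmn_mask & ~dmn_m
    return dmn_m, dmn_n
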