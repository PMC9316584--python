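"""Scale-aware transformer aggregation of patch embeddings to a diagnosis.

The aggregator ("scale-aware transformer network") maps, per slice, the
per-scale bags of 1280-d patch embeddings to a 4-class score vector:

1. a shared linear projection to a 128-d model space;
2. per scale: a learned positional signal plus a prepended scale token,
   through a stack of two transformer units (four attention heads,
   feed-forward width 512); the scale summary is the token output;
3. across scales: the summaries plus learned scale embeddings through a
   second two-unit stack of the same geometry; mean pooling and a linear
   head give the class scores.

Slices without an expert ROI train against *soft labels*: a mixture of
the case's class and the lowest-severity class weighted by the slice's
similarity to the ROI slice along the first singular direction of the
centered slice-feature matrix.  Training uses Adam with linear warmup
and step decay, records a checkpoint per epoch scored by case-level
validation micro F, and averages the best five checkpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .featext import EMBED_DIM, ScaleBag, get_scale
from .labels import DIAGNOSIS_CLASSES, DiagnosisClass
from .synthdata import SlideCase

logger = logging.getLogger(__name__)

N_CLASSES = len(DIAGNOSIS_CLASSES)


@dataclass(frozen=True)
class ScatConfig:
    """Aggregator geometry and training schedule.

    Defaults are the full-scale profile (200 epochs); ``desk_profile``
    returns the reduced-epoch configuration used for CPU-scale runs.
    """

    scales: Tuple[str, ...] = ("7.5x",)
    n_transformer_units: int = 2
    n_heads: int = 4
    ff_dim: int = 512
    model_dim: int = 128
    n_classes: int = N_CLASSES
    epochs: int = 200
    lr: float = 1e-3
    warmup_epochs: Optional[int] = None      # default: 5% of epochs
    decay_every: Optional[int] = None        # default: 25% of epochs
    decay_factor: float = 0.5
    batch_size: int = 16
    seed: int = 0
    use_positions: bool = True

    def __post_init__(self):
        if not self.scales:
            raise ValueError("at least one scale is required")
        if self.model_dim % self.n_heads:
            raise ValueError(
                f"model_dim {self.model_dim} not divisible by n_heads "
                f"{self.n_heads}")
        object.__setattr__(self, "scales",
                           tuple(get_scale(s).name for s in self.scales))

    @property
    def warmup(self) -> int:
        if self.warmup_epochs is not None:
            return self.warmup_epochs
        return max(1, round(0.05 * self.epochs))

    @property
    def decay_step(self) -> int:
        if self.decay_every is not None:
            return self.decay_every
        return max(1, round(0.25 * self.epochs))

    def lr_at(self, epoch: int) -> float:
        return nn.lr_at_epoch(epoch, self.lr, self.warmup, self.decay_step,
                              self.decay_factor)


def desk_profile(epochs: int = 30, scales: Tuple[str, ...] = ("7.5x",),
                 seed: int = 0, **kw) -> ScatConfig:
    """CPU-scale training profile: same geometry, fewer epochs."""
    return ScatConfig(scales=scales, epochs=epochs, seed=seed, **kw)


# ---------------------------------------------------------------------------
# Soft labels
# ---------------------------------------------------------------------------

def assign_soft_labels(case: SlideCase, slice_features: np.ndarray,
                       strategy: str = "svd") -> np.ndarray:
    """Per-slice soft labels (n_slices x 4 rows on the simplex).

    The ROI-bearing slice is one-hot at the case class.  With the ``svd``
    strategy each non-ROI slice i gets ``alpha * onehot(case class) +
    (1 - alpha) * onehot(MMD)`` where alpha in [0, 1] maps the cosine of
    slice i's and the ROI slice's projections onto the first singular
    direction of the centered slice-feature matrix (projections of equal
    sign give alpha 1, opposite sign 0, a vanishing projection 1/2; two
    vanishing projections mean the slices are indistinguishable along the
    principal direction and give 1).  The ``onehot`` strategy labels every
    slice one-hot at the case class.
    """
    feats = np.asarray(slice_features, dtype=np.float64)
    n = case.n_slices
    if feats.ndim != 2 or feats.shape[0] != n:
        raise ValueError(
            f"slice_features must be ({n}, d), got {feats.shape}")
    if case.roi is None:
        raise ValueError(f"case {case.case_id} has no ROI slice")
    roi_idx = case.roi[0]
    cls = int(case.diagnosis)
    onehot = np.zeros((n, N_CLASSES))
    onehot[:, cls] = 1.0
    if strategy == "onehot" or n == 1:
        return onehot
    if strategy != "svd":
        raise ValueError(f"unknown soft-label strategy {strategy!r}")

    centered = feats - feats.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]                     # score along the 1st direction
    eps = 1e-9 * max(1.0, float(np.abs(t).max()))
    labels = np.zeros((n, N_CLASSES))
    for i in range(n):
        if i == roi_idx:
            labels[i, cls] = 1.0
            continue
        if abs(t[i]) <= eps and abs(t[roi_idx]) <= eps:
            alpha = 1.0
        elif abs(t[i]) <= eps or abs(t[roi_idx]) <= eps:
            alpha = 0.5
        else:
            cos = np.sign(t[i] * t[roi_idx])
            alpha = (1.0 + cos) / 2.0
        labels[i, cls] += alpha
        labels[i, int(DiagnosisClass.MMD)] += 1.0 - alpha
    return labels


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class ScatNet(nn.Module):
    """The aggregator network (see module docstring for the data path)."""

    def __init__(self, config: ScatConfig, rng: np.random.Generator):
        self.config = config
        d = config.model_dim
        self.proj = nn.Linear(EMBED_DIM, d, rng)
        self.pos = [nn.Tensor(rng.normal(0, 0.02, (get_scale(s).n_patches, d)),
                              requires_grad=True) for s in config.scales]
        self.tokens = [nn.Tensor(rng.normal(0, 0.02, (1, d)), requires_grad=True)
                       for _ in config.scales]
        self.scale_emb = [nn.Tensor(rng.normal(0, 0.02, (1, d)), requires_grad=True)
                          for _ in config.scales]
        self.encoder = nn.TransformerStack(config.n_transformer_units, d,
                                           config.n_heads, config.ff_dim, rng)
        self.cross = nn.TransformerStack(config.n_transformer_units, d,
                                         config.n_heads, config.ff_dim, rng)
        self.head = nn.Linear(d, config.n_classes, rng)

    def forward(self, scale_arrays: Dict[str, np.ndarray]) -> nn.Tensor:
        """Batched forward: {scale: (B, n_patches, 1280)} -> logits (B, K)."""
        cfg = self.config
        missing = set(cfg.scales) - set(scale_arrays)
        if missing:
            raise ValueError(f"missing scales in input: {sorted(missing)}")
        summaries = []
        for i, s in enumerate(cfg.scales):
            arr = np.asarray(scale_arrays[s], dtype=np.float32)
            want = get_scale(s).n_patches
            if arr.ndim != 3 or arr.shape[1] != want or arr.shape[2] != EMBED_DIM:
                raise ValueError(
                    f"scale {s}: expected (B, {want}, {EMBED_DIM}), got {arr.shape}")
            B = arr.shape[0]
            x = self.proj(nn.Tensor(arr))                      # (B,T,d)
            if cfg.use_positions:
                x = x + self.pos[i]
            tok = nn.Tensor(np.ones((B, 1, 1), dtype=np.float32)) * self.tokens[i]
            x = nn.concat([tok, x], axis=1)                    # (B,T+1,d)
            x = self.encoder(x)
            summaries.append(nn.take(x, 0, axis=1).reshape(B, 1, cfg.model_dim))
        z = nn.concat(summaries, axis=1)                       # (B,S,d)
        z = z + nn.concat(self.scale_emb, axis=0)
        z = self.cross(z)
        return self.head(z.mean(axis=1))

    __call__ = forward

    def describe(self) -> Dict[str, int]:
        """Report the architecture geometry (units, heads, FF width)."""
        cfg = self.config
        return {
            "n_transformer_units": len(self.encoder.units),
            "n_heads": self.encoder.units[0].attn.n_heads,
            "ff_dim": self.encoder.units[0].ff1.w.shape[1],
            "model_dim": cfg.model_dim,
            "n_classes": cfg.n_classes,
            "n_scales": len(cfg.scales),
        }


def scat_forward(bags: Dict[str, ScaleBag], model: ScatNet) -> np.ndarray:
    """Score one slice: per-scale bags -> 4-class score vector."""
    arrays = {name: bag.embeddings[None] for name, bag in bags.items()}
    return model.forward(arrays).data[0]


# ---------------------------------------------------------------------------
# Training and checkpoint averaging
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    epoch: int
    weights: Dict[str, np.ndarray]
    score: float


@dataclass
class CheckpointSet:
    checkpoints: List[Checkpoint] = field(default_factory=list)

    def __post_init__(self):
        epochs = [c.epoch for c in self.checkpoints]
        if len(set(epochs)) != len(epochs):
            raise ValueError("checkpoint epochs must be unique")
        if not all(np.isfinite(c.score) for c in self.checkpoints):
            raise ValueError("checkpoint scores must be finite")

    def __len__(self) -> int:
        return len(self.checkpoints)

    def append(self, ck: Checkpoint) -> None:
        if any(c.epoch == ck.epoch for c in self.checkpoints):
            raise ValueError(f"duplicate checkpoint epoch {ck.epoch}")
        if not np.isfinite(ck.score):
            raise ValueError("checkpoint score must be finite")
        self.checkpoints.append(ck)


def average_checkpoints(cs: CheckpointSet, k: int = 5) -> Dict[str, np.ndarray]:
    """Elementwise mean of the weights of the top-k checkpoints.

    Ranked by validation score with ties broken toward the later epoch
    (more-trained weights).  With fewer than k checkpoints all are
    averaged and the shortfall logged.
    """
    if len(cs) < 1:
        raise ValueError("need at least one checkpoint")
    ranked = sorted(cs.checkpoints, key=lambda c: (c.score, c.epoch),
                    reverse=True)
    if len(ranked) < k:
        logger.warning("only %d checkpoints available; averaging all "
                       "(requested top %d)", len(ranked), k)
    top = ranked[:k]
    keys = top[0].weights.keys()
    return {key: np.mean([c.weights[key] for c in top], axis=0) for key in keys}


#: One slice's features: {scale name: (n_patches, 1280) embeddings}.
SliceFeatures = Dict[str, np.ndarray]


def _stack_scales(slices: Sequence[SliceFeatures],
                  scales: Sequence[str]) -> Dict[str, np.ndarray]:
    return {s: np.stack([np.asarray(sl[s], dtype=np.float32) for sl in slices])
            for s in scales}


class ScatClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style estimator around the transformer aggregator.

    ``X`` is a sequence of per-slice feature dicts ``{scale: (n_patches,
    1280)}`` and ``y`` a matrix of per-slice soft labels.  ``fit`` needs a
    validation set of whole cases (disjoint from the training cases):
    after every epoch the case-level micro F — slice predictions reduced
    by severity max-voting — is recorded with a snapshot of the weights,
    and the final model is the mean of the best five checkpoints.
    """

    def __init__(self, config: Optional[ScatConfig] = None,
                 checkpoint_k: int = 5):
        self.config = config
        self.checkpoint_k = checkpoint_k

    def fit(self, X: Sequence[SliceFeatures], y: np.ndarray, *,
            train_case_ids: Optional[Sequence[str]] = None,
            val_cases: Dict[str, List[SliceFeatures]] = None,
            val_labels: Dict[str, DiagnosisClass] = None) -> "ScatClassifier":
        from .evalrep import confusion, micro_metrics  # deferred: no cycle

        cfg = self.config or ScatConfig()
        y = np.asarray(y, dtype=np.float32)
        if y.ndim != 2 or y.shape[1] != cfg.n_classes:
            raise ValueError(f"y must be (n_slices, {cfg.n_classes}), got {y.shape}")
        if not np.allclose(y.sum(axis=1), 1.0, atol=1e-5):
            raise ValueError("soft labels must sum to 1 per slice")
        if not val_cases or not val_labels:
            raise ValueError("a non-empty validation split is required")
        if train_case_ids is not None:
            overlap = set(train_case_ids) & set(val_cases)
            if overlap:
                raise ValueError(
                    f"train/validation case overlap: {sorted(overlap)}")

        rng = np.random.default_rng(cfg.seed)
        net = ScatNet(cfg, rng)
        opt = nn.Adam(net.parameters(), lr=cfg.lr)
        train = _stack_scales(X, cfg.scales)
        n = len(X)
        checkpoints = CheckpointSet()
        val_ids = sorted(val_cases)
        val_stacks = {cid: _stack_scales(val_cases[cid], cfg.scales)
                      for cid in val_ids}
        reference = [val_labels[cid] for cid in val_ids]

        for epoch in range(cfg.epochs):
            opt.lr = cfg.lr_at(epoch)
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = {s: arr[idx] for s, arr in train.items()}
                logits = net.forward(batch)
                loss = nn.cross_entropy_soft(logits, y[idx])
                net.zero_grad()
                loss.backward()
                opt.step()
            predicted = [self._vote(net, val_stacks[cid]) for cid in val_ids]
            score = micro_metrics(confusion(reference, predicted)).micro_f
            checkpoints.append(Checkpoint(epoch=epoch,
                                          weights=net.state_dict(),
                                          score=float(score)))

        self.checkpoints_ = checkpoints
        net.load_state_dict(average_checkpoints(checkpoints, self.checkpoint_k))
        self.net_ = net
        self.classes_ = np.array(list(DIAGNOSIS_CLASSES))
        return self

    @staticmethod
    def _vote(net: ScatNet, case_stack: Dict[str, np.ndarray]) -> DiagnosisClass:
        from .evalrep import max_vote
        logits = net.forward(case_stack).data
        return max_vote([DiagnosisClass(int(i)) for i in logits.argmax(axis=1)])

    def decision_function(self, X: Sequence[SliceFeatures]) -> np.ndarray:
        return self.net_.forward(_stack_scales(X, self.net_.config.scales)).data

    def predict(self, X: Sequence[SliceFeatures]) -> List[DiagnosisClass]:
        scores = self.decision_function(X)
        return [DiagnosisClass(int(i)) for i in scores.argmax(axis=1)]

    def predict_case(self, case_slices: Sequence[SliceFeatures]) -> DiagnosisClass:
        """Slice predictions reduced to a case diagnosis by max-voting."""
        from .evalrep import max_vote
        return max_vote(self.predict(case_slices))


def train_diagnosis(X: Sequence[SliceFeatures], y: np.ndarray,
                    val_cases: Dict[str, List[SliceFeatures]],
                    val_labels: Dict[str, DiagnosisClass],
                    config: Optional[ScatConfig] = None,
                    train_case_ids: Optional[Sequence[str]] = None
                    ) -> Tuple[ScatClassifier, CheckpointSet]:
    """Train the aggregator; returns the fitted estimator and checkpoints."""
    clf = ScatClassifier(config=config)
    clf.fit(X, y, train_case_ids=train_case_ids, val_cases=val_cases,
            val_labels=val_labels)
    return clf, clf.checkpoints_
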