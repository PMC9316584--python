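"""Multi-scale pyramid, patch grids, and per-patch embeddings.

Slices are generated (or scanned) at a nominal 20x magnification; lower
working resolutions of 7.5x, 10x and 12.5x are produced by resizing.  At
each scale the slice is cut into a fixed ``g x g`` grid of near-equal
tiles (5x5 = 25 at 7.5x, 7x7 = 49 at 10x, 9x9 = 81 at 12.5x) and every
tile is embedded into a 1280-dimensional vector by a CNN encoder with
global average pooling, whose first convolution accepts any channel count
C >= 3 so that binary tissue-mask channels can ride along with RGB.

The 10x grid side is not fixed by the printed 5x5/9x9 pair; 7x7 follows
the arithmetic progression and is recorded as an inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .maskops import MultiChannelImage


@dataclass(frozen=True)
class ScaleSpec:
    """A working magnification: resize factor from 20x and its patch grid."""

    name: str
    resize_factor: float
    grid_side: int

    def __post_init__(self):
        if not 0 < self.resize_factor <= 1:
            raise ValueError(f"resize_factor must be in (0,1], got {self.resize_factor}")
        if self.grid_side < 1:
            raise ValueError(f"grid_side must be >= 1, got {self.grid_side}")

    @property
    def n_patches(self) -> int:
        return self.grid_side ** 2


#: The three analysis scales plus the 20x base (identity resize).
SCALES: Dict[str, ScaleSpec] = {
    "7.5x": ScaleSpec("7.5x", 7.5 / 20, 5),
    "10x": ScaleSpec("10x", 10 / 20, 7),
    "12.5x": ScaleSpec("12.5x", 12.5 / 20, 9),
    "20x": ScaleSpec("20x", 1.0, 9),
}


def get_scale(name: Union[str, ScaleSpec]) -> ScaleSpec:
    if isinstance(name, ScaleSpec):
        return name
    key = str(name).replace("×", "x").strip().lower()
    if not key.endswith("x"):
        key += "x"
    if key not in SCALES:
        raise KeyError(f"unknown scale {name!r}; known: {sorted(SCALES)}")
    return SCALES[key]


# ---------------------------------------------------------------------------
# Pyramid and grid
# ---------------------------------------------------------------------------

def build_pyramid(image: MultiChannelImage,
                  scales: Iterable[Union[str, ScaleSpec]]) -> Dict[str, MultiChannelImage]:
    """Resize a 20x multi-channel slice to each requested scale.

    RGB channels are resized with bilinear interpolation; mask channels
    with nearest-neighbour and re-thresholded so they stay strictly {0,1}.
    A factor-1 scale returns the input pixels unchanged.
    """
    out: Dict[str, MultiChannelImage] = {}
    h, w = image.pixels.shape[:2]
    for sc in (get_scale(s) for s in scales):
        h2, w2 = int(round(h * sc.resize_factor)), int(round(w * sc.resize_factor))
        if (h2, w2) == (h, w):
            out[sc.name] = MultiChannelImage(image.pixels.copy(), image.legend)
            continue
        rgb = resize(image.rgb.astype(np.float32), (h2, w2), order=1,
                     preserve_range=True, anti_aliasing=True)
        planes = [rgb]
        for c in range(3, image.n_channels):
            m = resize(image.pixels[..., c].astype(np.float32), (h2, w2),
                       order=0, preserve_range=True, anti_aliasing=False)
            planes.append((m > 0.5).astype(np.float32)[..., None])
        out[sc.name] = MultiChannelImage(
            np.concatenate([planes[0]] + planes[1:], axis=2), image.legend)
    return out


def grid_edges(n: int, g: int) -> List[int]:
    """Tile boundaries cutting n pixels into g near-equal runs.

    The first ``g - (n mod g)`` tiles have length n//g and the remaining
    tiles one pixel more, so remainder pixels sit in the last rows/columns
    and tile lengths differ by at most one.
    """
    if n < g:
        raise ValueError(f"cannot cut {n} pixels into {g} tiles")
    base, rem = divmod(n, g)
    sizes = [base] * (g - rem) + [base + 1] * rem
    edges = [0]
    for s in sizes:
        edges.append(edges[-1] + s)
    return edges


def patch_grid(image: Union[MultiChannelImage, np.ndarray],
               scale: Union[str, ScaleSpec]) -> List[np.ndarray]:
    """Cut an image into the scale's grid_side x grid_side patches.

    Patches are returned in row-major order and tile the image exactly:
    reassembling them reconstructs the input pixel-for-pixel.
    """
    sc = get_scale(scale) if isinstance(scale, str) else scale
    pixels = image.pixels if isinstance(image, MultiChannelImage) else np.asarray(image)
    h, w = pixels.shape[:2]
    g = sc.grid_side
    re_, ce = grid_edges(h, g), grid_edges(w, g)
    return [pixels[re_[i]:re_[i + 1], ce[j]:ce[j + 1]]
            for i in range(g) for j in range(g)]


# ---------------------------------------------------------------------------
# Patch encoder
# ---------------------------------------------------------------------------

EMBED_DIM = 1280


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                  stride: int = 1, pad: int = 0) -> np.ndarray:
    """Forward-only channels-last convolution (inference path)."""
    k = w.shape[0]
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    B, H, W, C = x.shape
    ho = (H - k) // stride + 1
    wo = (W - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * ho * wo, k * k * C)
    y = cols @ w.reshape(k * k * C, -1) + b
    return y.reshape(B, ho, wo, -1)


def expand_first_layer(rgb_kernels: np.ndarray, in_channels: int) -> np.ndarray:
    """Adapt pretrained 3-channel first-layer kernels to C input channels.

    Channels 1-3 keep the RGB kernels; each extra channel's kernels are the
    mean of the RGB kernels, so an all-ones mask channel perturbs the first
    layer's activations at the scale of an average colour channel.
    """
    rgb_kernels = np.asarray(rgb_kernels)
    if rgb_kernels.ndim != 4 or rgb_kernels.shape[2] != 3:
        raise ValueError(
            f"expected kernels of shape (k, k, 3, c_out), got {rgb_kernels.shape}")
    if in_channels < 3:
        raise ValueError("in_channels must be >= 3")
    extra = rgb_kernels.mean(axis=2, keepdims=True)
    return np.concatenate(
        [rgb_kernels] + [extra] * (in_channels - 3), axis=2)


class PatchEncoder(BaseEstimator, TransformerMixin):
    """CNN patch embedder: C-channel patch -> 1280-vector via GAP.

    A compact randomly initialized CNN honouring the same contract as a
    large pretrained backbone (first convolution with ``in_channels``
    inputs, 1280 feature maps before global average pooling).  Weights are
    frozen at construction from ``seed``, so identical patches always map
    to identical embeddings.  ``base_first_layer`` supplies pretrained
    3-channel first-layer kernels to be channel-expanded; requesting
    ``pretrained=True`` without them is an error because no weight files
    ship with the package.
    """

    def __init__(self, in_channels: int = 3, hidden: int = 32, seed: int = 0,
                 pretrained: bool = False,
                 base_first_layer: Optional[np.ndarray] = None):
        self.in_channels = in_channels
        self.hidden = hidden
        self.seed = seed
        self.pretrained = pretrained
        self.base_first_layer = base_first_layer
        self._build()

    def _build(self) -> None:
        if self.in_channels < 3:
            raise ValueError(f"in_channels must be >= 3, got {self.in_channels}")
        if self.pretrained and self.base_first_layer is None:
            raise RuntimeError(
                "pretrained=True requires base_first_layer kernels; no "
                "pretrained weight files ship with this package")
        rng = np.random.default_rng(self.seed)
        k = 3
        if self.base_first_layer is not None:
            w1 = expand_first_layer(self.base_first_layer, self.in_channels)
            if w1.shape[3] != self.hidden:
                raise ValueError(
                    f"base_first_layer has {w1.shape[3]} output maps, "
                    f"expected hidden={self.hidden}")
        else:
            w1 = rng.normal(0, np.sqrt(2 / (k * k * self.in_channels)),
                            (k, k, self.in_channels, self.hidden))
        self.w1_ = w1.astype(np.float32)
        self.b1_ = np.zeros(self.hidden, dtype=np.float32)
        self.w2_ = rng.normal(0, np.sqrt(2 / self.hidden),
                              (1, 1, self.hidden, EMBED_DIM)).astype(np.float32)
        self.b2_ = np.zeros(EMBED_DIM, dtype=np.float32)

    # stateless w.r.t. data: weights are fixed by the constructor seed
    def fit(self, X=None, y=None) -> "PatchEncoder":
        return self

    def _encode_batch(self, batch: np.ndarray) -> np.ndarray:
        if batch.shape[-1] != self.in_channels:
            raise ValueError(
                f"patch has {batch.shape[-1]} channels, encoder expects "
                f"{self.in_channels}")
        h = np.maximum(_conv_forward(batch.astype(np.float32), self.w1_,
                                     self.b1_, stride=2, pad=1), 0.0)
        h = np.maximum(_conv_forward(h, self.w2_, self.b2_), 0.0)
        return h.mean(axis=(1, 2))          # global average pooling -> 1280

    def transform(self, patches: Union[np.ndarray, Sequence[np.ndarray]]) -> np.ndarray:
        """Embed patches (stacked array or list of H x W x C arrays)."""
        if isinstance(patches, np.ndarray) and patches.ndim == 4:
            return self._encode_batch(patches)
        if isinstance(patches, np.ndarray) and patches.ndim == 3:
            return self._encode_batch(patches[None])[0]
        # group equally-shaped patches so each group runs as one batch
        out = np.empty((len(patches), EMBED_DIM), dtype=np.float32)
        groups: Dict[Tuple[int, ...], List[int]] = {}
        for i, p in enumerate(patches):
            groups.setdefault(np.asarray(p).shape, []).append(i)
        for shape, idx in groups.items():
            batch = np.stack([np.asarray(patches[i]) for i in idx])
            out[idx] = self._encode_batch(batch)
        return out


def make_extractor(in_channels: int, pretrained: bool = False,
                   base_first_layer: Optional[np.ndarray] = None,
                   seed: int = 0) -> PatchEncoder:
    """Build a patch encoder whose first layer accepts ``in_channels`` inputs."""
    return PatchEncoder(in_channels=in_channels, pretrained=pretrained,
                        base_first_layer=base_first_layer, seed=seed)


class LinearProjection:
    """Learnable-shape linear map from 1280-d embeddings to 128-d."""

    def __init__(self, out_dim: int = 128, seed: int = 0, bias: bool = False):
        rng = np.random.default_rng(seed)
        self.w = rng.normal(0, np.sqrt(1 / EMBED_DIM),
                            (EMBED_DIM, out_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32) if bias else None

    def __call__(self, embeddings: np.ndarray) -> np.ndarray:
        return project(embeddings, self.w, self.b)


def project(embeddings: np.ndarray, w: np.ndarray,
            b: Optional[np.ndarray] = None) -> np.ndarray:
    """Apply one shared linear map to 1280-d embedding row(s)."""
    e = np.asarray(embeddings)
    if e.shape[-1] != EMBED_DIM:
        raise ValueError(f"expected {EMBED_DIM}-d embeddings, got {e.shape[-1]}")
    y = e @ w
    return y + b if b is not None else y


# ---------------------------------------------------------------------------
# Slice-level extraction
# ---------------------------------------------------------------------------

@dataclass
class ScaleBag:
    """Per-scale sequence of per-patch embeddings for one slice."""

    scale: ScaleSpec
    embeddings: np.ndarray          # (grid_side**2, 1280)
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float32)
        if self.embeddings.shape[0] != self.scale.n_patches:
            raise ValueError(
                f"{self.scale.name}: expected {self.scale.n_patches} patch "
                f"embeddings, got {self.embeddings.shape[0]}")


@dataclass
class RGBNormalizer:
    """Per-channel standardization for RGB; mask channels pass through."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, rgb_images: Sequence[np.ndarray]) -> "RGBNormalizer":
        stacked = np.concatenate([np.asarray(im, dtype=np.float32).reshape(-1, 3)
                                  for im in rgb_images]) / 255.0
        return cls(mean=stacked.mean(axis=0),
                   sd=np.maximum(stacked.std(axis=0), 1e-6))

    def apply(self, image: MultiChannelImage) -> MultiChannelImage:
        px = image.pixels.astype(np.float32).copy()
        px[..., :3] = (px[..., :3] / 255.0 - self.mean) / self.sd
        return MultiChannelImage(px, image.legend)


def slice_scale_bags(image: MultiChannelImage,
                     scales: Iterable[Union[str, ScaleSpec]],
                     encoder: PatchEncoder,
                     provenance: Optional[Dict[str, object]] = None
                     ) -> Dict[str, ScaleBag]:
    """Full per-slice path: pyramid -> patch grid -> encoder -> bags."""
    bags = {}
    for name, img in build_pyramid(image, scales).items():
        sc = get_scale(name)
        patches = patch_grid(img, sc)
        emb = encoder.transform(patches)
        bags[name] = ScaleBag(scale=sc, embeddings=emb,
                              provenance=dict(provenance or {}))
    return bags
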