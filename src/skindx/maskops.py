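"""Binary tissue masks and RGB+mask channel fusion.

An integer-coded tissue label mask is split into per-tissue 0/1 rasters,
and any subset of those rasters can be concatenated onto the RGB image as
extra channels, giving the feature extractor direct access to the tissue
structure (e.g. R, G, B, EPN, DMN-M for a five-channel input).

Conventions: 0-based row-major pixel coordinates with the origin at the
top-left; rectangles are half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
from PIL import Image

from .labels import MAX_MASK_CODE, TissueKind

PathLike = Union[str, Path]


def binarize(label_mask: np.ndarray, tissue: Union[TissueKind, str]) -> np.ndarray:
    """Binary raster: 1 where the label code belongs to the tissue's code set.

    The union view ``DMN`` matches both nest codes {5, 6}.  Raises
    ``ValueError`` listing the offending codes if the mask contains codes
    outside the declared table.
    """
    if isinstance(tissue, str):
        tissue = TissueKind.from_string(tissue)
    mask = np.asarray(label_mask)
    if mask.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {mask.shape}")
    bad = np.setdiff1d(np.unique(mask), np.arange(MAX_MASK_CODE + 1))
    if bad.size:
        raise ValueError(f"unknown label codes present: {bad.tolist()}")
    return np.isin(mask, list(tissue.code_set)).astype(np.uint8)


@dataclass
class MultiChannelImage:
    """H x W x C raster whose first three channels are the source RGB.

    ``legend`` names every channel in order, e.g. ("R","G","B","EPN","DMN_M").
    Appended mask channels hold only {0, 1}.
    """

    pixels: np.ndarray
    legend: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"expected H x W x C raster, got {self.pixels.shape}")
        if not self.legend:
            self.legend = ("R", "G", "B") + tuple(
                f"ch{i}" for i in range(3, self.pixels.shape[2]))
        if len(self.legend) != self.pixels.shape[2]:
            raise ValueError(
                f"legend length {len(self.legend)} != channel count "
                f"{self.pixels.shape[2]}")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.pixels.shape

    @property
    def rgb(self) -> np.ndarray:
        return self.pixels[..., :3]

    @property
    def mask_channels(self) -> np.ndarray:
        return self.pixels[..., 3:]


def concat_channels(
    rgb: np.ndarray,
    masks: Sequence[np.ndarray],
    names: Sequence[str] = (),
) -> MultiChannelImage:
    """Append binary mask rasters to an RGB image as extra channels.

    The RGB bytes are carried over unchanged; each mask must be a 0/1
    raster of the same height and width.  With an empty mask list the
    result is the 3-channel image itself.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"rgb must be H x W x 3, got {rgb.shape}")
    if names and len(names) != len(masks):
        raise ValueError("names must match masks in length")
    planes: List[np.ndarray] = [rgb]
    for i, m in enumerate(masks):
        m = np.asarray(m)
        if m.shape != rgb.shape[:2]:
            raise ValueError(
                f"mask {i} shape {m.shape} does not match image {rgb.shape[:2]}")
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask {i} is not binary; values {vals.tolist()}")
        planes.append(m.reshape(*m.shape, 1).astype(rgb.dtype))
    legend = ("R", "G", "B") + tuple(
        names if names else (f"mask{i}" for i in range(len(masks))))
    return MultiChannelImage(np.concatenate(planes, axis=2), legend)


# ---------------------------------------------------------------------------
# PNG dialect: masks are 8-bit single-channel; binary masks stored as {0,255}.
# ---------------------------------------------------------------------------

def read_mask(path: PathLike) -> np.ndarray:
    """Read an integer-coded label mask from a single-channel PNG."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    with Image.open(path) as im:
        if im.mode != "L":
            raise ValueError(
                f"mask PNG must be 8-bit grayscale (mode 'L'), got mode "
                f"{im.mode!r}: {path}")
        return np.array(im, dtype=np.uint8)  # writable copy


def write_mask(path: PathLike, raster: np.ndarray) -> None:
    """Write an integer-coded label mask as a single-channel PNG."""
    raster = np.asarray(raster, dtype=np.uint8)
    Image.fromarray(raster, mode="L").save(Path(path))


def read_binary(path: PathLike) -> np.ndarray:
    """Read a {0,255}-coded binary mask PNG back to a {0,1} raster."""
    raw = read_mask(path)
    vals = np.unique(raw)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError(
            f"binary mask PNG must contain only 0/255, got {vals.tolist()}: {path}")
    return (raw > 0).astype(np.uint8)


def write_binary(path: PathLike, raster: np.ndarray) -> None:
    """Write a {0,1} raster as a {0,255} single-channel PNG."""
    raster = np.asarray(raster)
    vals = np.unique(raster)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"raster is not binary; values {vals.tolist()}")
    write_mask(path, raster.astype(np.uint8) * 255)


def read_rgb(path: PathLike) -> np.ndarray:
    """Read an 8-bit RGB image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_rgb(path: PathLike, raster: np.ndarray) -> None:
    Image.fromarray(np.asarray(raster, dtype=np.uint8), mode="RGB").save(Path(path))
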