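"""Whole-image inference: overlap tiling, dihedral test-time augmentation,
max aggregation, normalization and thresholding.

A large image is cut into overlapping patch-sized tiles (90% overlap by
default). Each tile is predicted under all 8 symmetries of the square
(dihedral group of order 4); the aligned outputs are combined per pixel by
maximum. Tile outputs are combined the same way, the aggregate map is
min-max normalized to [0, 1], and pixels above the threshold (default 0.2)
form the binary boundary mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import MicrosectionImage, as_probability_map


@dataclass
class InferenceConfig:
    patch_size: int = 256
    overlap_fraction: float = 0.9
    tta_enabled: bool = True
    threshold: float = 0.2
    aggregate: str = "max"  # across overlapping tiles: "max" or "mean"
    batch_size: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.aggregate not in ("max", "mean"):
            raise ValueError("aggregate must be 'max' or 'mean'")


def tile_plan(
    height: int, width: int, patch_size: int, overlap_fraction: float
) -> list[tuple[int, int]]:
    """Origins of overlapping tiles covering every pixel.

    The stride is ``max(1, round(patch_size * (1 - overlap)))``; the final
    origin on each axis is clamped to ``dim - patch_size``.
    """
    if height < patch_size or width < patch_size:
        raise ValueError("image smaller than the patch size; pad first")
    stride = max(1, round(patch_size * (1.0 - overlap_fraction)))

    def axis(dim: int) -> list[int]:
        pos = list(range(0, dim - patch_size + 1, stride))
        if pos[-1] != dim - patch_size:
            pos.append(dim - patch_size)
        return pos

    return [(r, c) for r in axis(height) for c in axis(width)]


# The 8 elements of D4 as (quarter-turns, horizontal flip): t(x) = flip^f(rot90^k(x)).
DIHEDRAL_IDS = [(k, f) for f in (0, 1) for k in (0, 1, 2, 3)]


def apply_dihedral(arr: np.ndarray, transform_id: tuple[int, int]) -> np.ndarray:
    k, f = transform_id
    out = np.rot90(arr, k, axes=(0, 1))
    if f:
        out = np.flip(out, axis=1)
    return out


def inverse_dihedral(arr: np.ndarray, transform_id: tuple[int, int]) -> np.ndarray:
    k, f = transform_id
    out = np.flip(arr, axis=1) if f else arr
    return np.rot90(out, -k, axes=(0, 1))


def dihedral_orbit(patch: np.ndarray) -> list[np.ndarray]:
    """The 8 images of a square patch under the dihedral group of order 4."""
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("dihedral orbit requires a square patch")
    return [apply_dihedral(patch, t) for t in DIHEDRAL_IDS]


def tta_predict(network, patch: np.ndarray, tta_enabled: bool = True) -> np.ndarray:
    """Per-pixel max over the 8 aligned dihedral predictions of one patch.

    ``network`` must expose ``predict_proba((B, S, S, 3)) -> (B, S, S)``.
    """
    if not tta_enabled:
        return as_probability_map(network.predict_proba(patch[None])[0])
    orbit = np.stack(dihedral_orbit(patch))
    probs = network.predict_proba(orbit)
    aligned = [inverse_dihedral(p, t) for p, t in zip(probs, DIHEDRAL_IDS)]
    return as_probability_map(np.max(aligned, axis=0))


def minmax_normalize(arr: np.ndarray) -> np.ndarray:
    """Rescale to span [0, 1]; an all-constant map collapses to 0."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr, dtype=float)
    return (arr - lo) / (hi - lo)


def predict_image(
    network, image: MicrosectionImage | np.ndarray, cfg: InferenceConfig = InferenceConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Tiled TTA prediction for a whole microsection.

    Returns ``(probability_map, mask)`` where the map is the min-max
    normalized per-pixel aggregate and ``mask = probability > threshold``.
    Images smaller than the patch are reflect-padded and cropped back.
    """
    pixels = image.pixels if isinstance(image, MicrosectionImage) else image
    arr = pixels.astype(float) / 255.0 if pixels.dtype == np.uint8 else np.asarray(pixels, float)
    h, w = arr.shape[:2]
    ps = cfg.patch_size
    pad_r, pad_c = max(0, ps - h), max(0, ps - w)
    if pad_r or pad_c:
        arr = np.pad(arr, ((0, pad_r), (0, pad_c), (0, 0)), mode="reflect")
    hp, wp = arr.shape[:2]

    if cfg.aggregate == "max":
        agg = np.zeros((hp, wp))
    else:
        agg = np.zeros((hp, wp))
        hits = np.zeros((hp, wp))
    for r, c in tile_plan(hp, wp, ps, cfg.overlap_fraction):
        tile = arr[r : r + ps, c : c + ps]
        prob = tta_predict(network, tile, cfg.tta_enabled)
        view = agg[r : r + ps, c : c + ps]
        if cfg.aggregate == "max":
            np.maximum(view, prob, out=view)
        else:
            view += prob
            hits[r : r + ps, c : c + ps] += 1
    if cfg.aggregate == "mean":
        agg = agg / hits
    agg = agg[:h, :w]
    prob_map = minmax_normalize(agg)
    mask = (prob_map > cfg.threshold).astype(np.uint8)
    return prob_map, mask
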