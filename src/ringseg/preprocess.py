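"""Training-patch preparation: tiling, pairing with masks, augmentation.

Images are cut into fixed-size patches (default 256x256) paired with
rasterized boundary masks; augmentation applies horizontal flips, small
rotations (+-20 deg) to patch and mask jointly, and Gaussian blur to the
patch only, mirroring common practice for boundary segmentation training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import MicrosectionImage


@dataclass
class PatchPair:
    """One training example: a normalized RGB patch and its binary mask."""

    patch: np.ndarray  # (S, S, 3) float in [0, 1]
    mask: np.ndarray  # (S, S) uint8 in {0, 1}
    origin: tuple[int, int] = (0, 0)
    sample_id: str = ""


@dataclass
class AugmentConfig:
    """Stochastic augmentation policy.

    Each transform fires independently with its probability. The blur kernel
    side is drawn uniformly from the odd integers in ``blur_kernel_range``
    and converted to a Gaussian sigma with the standard
    ``0.3 * ((k - 1) / 2 - 1) + 0.8`` rule.
    """

    p_hflip: float = 0.5
    p_rotate: float = 0.5
    rotate_degrees: tuple[float, float] = (-20.0, 20.0)
    p_blur: float = 0.5
    blur_kernel_range: tuple[int, int] = (3, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_hflip, self.p_rotate, self.p_blur):
            if not 0 <= p <= 1:
                raise ValueError("augmentation probabilities must lie in [0, 1]")
        if self.blur_kernel_range[0] > self.blur_kernel_range[1]:
            raise ValueError("blur_kernel_range min must be <= max")


def grid_origins(dim: int, patch: int, stride: int) -> list[int]:
    """1-D tiling origins with the final origin clamped to ``dim - patch``."""
    if dim < patch:
        raise ValueError(f"dimension {dim} smaller than patch size {patch}")
    origins = list(range(0, dim - patch + 1, max(1, stride)))
    if origins[-1] != dim - patch:
        origins.append(dim - patch)
    return origins


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to [0, 1] (v -> v / 255)."""
    return np.asarray(patch, dtype=np.float64) / 255.0


def crop_training_patches(
    image: MicrosectionImage | np.ndarray,
    mask: np.ndarray,
    patch_size: int = 256,
    stride: int = 256,
    sample_id: str = "",
) -> list[PatchPair]:
    """Cut image and mask into aligned patches on a clamped regular grid.

    Every pixel of the source is covered by at least one patch; patch values
    are normalized to [0, 1], masks are cropped at identical origins.
    """
    pixels = image.pixels if isinstance(image, MicrosectionImage) else image
    if not sample_id and isinstance(image, MicrosectionImage):
        sample_id = image.sample_id
    if pixels.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    h, w = mask.shape
    pairs = []
    for r in grid_origins(h, patch_size, stride):
        for c in grid_origins(w, patch_size, stride):
            pairs.append(
                PatchPair(
                    patch=normalize_patch(pixels[r : r + patch_size, c : c + patch_size]),
                    mask=mask[r : r + patch_size, c : c + patch_size].astype(np.uint8),
                    origin=(r, c),
                    sample_id=sample_id,
                )
            )
    return pairs


def _blur_sigma(kernel_side: int) -> float:
    return 0.3 * ((kernel_side - 1) / 2.0 - 1.0) + 0.8


def augment_pair(pair: PatchPair, cfg: AugmentConfig, rng: np.random.Generator) -> PatchPair:
    """Apply one random augmentation draw to a patch/mask pair.

    Geometric transforms (horizontal flip; rotation by an angle uniform in
    ``rotate_degrees`` with reflective padding) act on patch and mask
    identically; the mask is resampled at order 0 and re-thresholded so it
    stays binary. Blur acts on the patch only.
    """
    patch, mask = pair.patch, pair.mask
    if rng.uniform() < cfg.p_hflip:
        patch = patch[:, ::-1]
        mask = mask[:, ::-1]
    if rng.uniform() < cfg.p_rotate:
        angle = rng.uniform(*cfg.rotate_degrees)
        patch = ndimage.rotate(
            patch, angle, axes=(1, 0), reshape=False, order=1, mode="reflect"
        )
        mask = ndimage.rotate(
            mask.astype(float), angle, axes=(1, 0), reshape=False, order=0, mode="reflect"
        )
        mask = (mask > 0.5).astype(np.uint8)
        patch = np.clip(patch, 0.0, 1.0)
    if rng.uniform() < cfg.p_blur:
        lo, hi = cfg.blur_kernel_range
        odd = [k for k in range(lo, hi + 1) if k % 2 == 1]
        k = int(rng.choice(odd))
        sigma = _blur_sigma(k)
        radius = (k - 1) // 2
        patch = np.stack(
            [
                ndimage.gaussian_filter(
                    patch[..., ch], sigma, truncate=max(radius, 1) / sigma
                )
                for ch in range(patch.shape[-1])
            ],
            axis=-1,
        )
    return PatchPair(np.ascontiguousarray(patch), np.ascontiguousarray(mask),
                     pair.origin, pair.sample_id)
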