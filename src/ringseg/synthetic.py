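"""Synthetic stained-microsection generator with exact ground truth.

Emulates the geometry of transverse beech core images: a tall, narrow RGB
image crossed by roughly horizontal ring boundaries (bands of narrow dark
fibers) separating rings filled with bright vessel lumina whose diameter
shrinks from the start to the end of each ring (semi-ring-porous pattern).
Every sample carries its boundary polylines, vessel centers with generative
ring indices, and a rasterized boundary mask, so segmentation and the
downstream ring-assignment metrics can be exercised against known truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import dilation, footprint_rectangle

from .types import AnnotatedSample, BoundaryPath, MicrosectionImage, VesselRecord

# Tissue palette (RGB), loosely safranin/alcian-like: pale ground tissue,
# darker fiber bands at ring boundaries, near-white open vessel lumina.
_GROUND = np.array([196, 148, 154], float)
_BAND = np.array([96, 52, 72], float)
_LUMEN = np.array([244, 240, 238], float)


@dataclass
class SynthConfig:
    """Generative parameters of one synthetic microsection.

    Defaults emulate the source imagery scale: 1.63 µm/px resolution, rings
    about 1110 µm (~680 px) wide, and 120 vessels per ring, on a desk-scale
    512x2048 (W x H) canvas standing in for full ~1468x24000 px cores.
    """

    height_px: int = 2048
    width_px: int = 512
    n_boundaries: int = 2
    mean_ring_width_px: float = 680.0
    ring_width_cv: float = 0.2
    boundary_waviness_px: float = 6.0
    fiber_band_halfwidth_px: int = 3
    vessels_per_ring_mean: float = 120.0
    vessel_radius_range_px: tuple[float, float] = (4.0, 14.0)
    noise_sd: float = 6.0
    resolution_um_per_px: float = 1.63
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_boundaries < 0:
            raise ValueError("n_boundaries must be non-negative")
        if not 0 <= self.ring_width_cv < 1:
            raise ValueError("ring_width_cv must lie in [0, 1)")
        if self.mean_ring_width_px <= 0:
            raise ValueError("mean_ring_width_px must be positive")
        if self.fiber_band_halfwidth_px < 1:
            raise ValueError("fiber_band_halfwidth_px must be a positive integer")
        rmin, rmax = self.vessel_radius_range_px
        if not 0 < rmin <= rmax:
            raise ValueError("vessel_radius_range_px must satisfy 0 < min <= max")
        if self.vessels_per_ring_mean <= 0:
            raise ValueError("vessels_per_ring_mean must be positive")
        if self.noise_sd < 0 or self.boundary_waviness_px < 0:
            raise ValueError("noise_sd and boundary_waviness_px must be >= 0")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        if self.n_boundaries * self.mean_ring_width_px > self.height_px:
            raise ValueError(
                f"infeasible config: {self.n_boundaries} boundaries at mean ring "
                f"width {self.mean_ring_width_px} px do not fit in "
                f"{self.height_px} px of height"
            )


def rasterize_boundaries(
    paths: list[BoundaryPath], shape: tuple[int, int], stroke_px: int = 1
) -> np.ndarray:
    """Rasterize polylines into a {0,1} mask with a square stroke.

    Consecutive path points are connected by Bresenham segments, then the
    line set is dilated with a ``stroke_px`` x ``stroke_px`` square (so every
    foreground pixel is within Chebyshev distance ``stroke_px // 2`` of a
    segment). ``stroke_px`` must be odd.
    """
    if stroke_px < 1 or stroke_px % 2 == 0:
        raise ValueError("stroke_px must be a positive odd integer")
    h, w = shape
    mask = np.zeros((h, w), bool)
    for idx, bp in enumerate(paths):
        pts = np.rint(bp.points).astype(int)
        if (pts[:, 0] < 0).any() or (pts[:, 0] >= h).any() or \
           (pts[:, 1] < 0).any() or (pts[:, 1] >= w).any():
            raise ValueError(f"boundary {idx}: point outside image of shape {shape}")
        if len(pts) == 1:
            mask[pts[0, 0], pts[0, 1]] = True
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
    if stroke_px > 1:
        mask = dilation(mask, footprint_rectangle((stroke_px, stroke_px)))
    return mask.astype(np.uint8)


def _wavy_rows(rng, base_row: float, width: int, amplitude: float) -> np.ndarray:
    """Smooth random undulation around ``base_row``, one row per column."""
    if amplitude == 0:
        return np.full(width, float(base_row))
    steps = rng.normal(0.0, 1.0, size=width)
    walk = gaussian_filter1d(np.cumsum(steps), sigma=max(4.0, width / 16.0))
    walk -= walk.mean()
    peak = np.abs(walk).max()
    if peak > 0:
        walk *= amplitude / peak
    return base_row + walk


def _draw_boundary_rows(cfg: SynthConfig, rng) -> np.ndarray:
    """Per-column rows of each boundary, shape (n_boundaries, W), non-crossing."""
    n, h = cfg.n_boundaries, cfg.height_px
    if n == 0:
        return np.zeros((0, cfg.width_px))
    margin = cfg.fiber_band_halfwidth_px + np.ceil(cfg.boundary_waviness_px) + 1
    for _attempt in range(50):
        widths = rng.normal(
            cfg.mean_ring_width_px, cfg.ring_width_cv * cfg.mean_ring_width_px, size=n + 1
        )
        widths = np.clip(widths, 0.25 * cfg.mean_ring_width_px, None)
        # scale ring spans so n boundaries sit inside the image with margins
        base = margin + np.cumsum(widths[:n]) * (h - 2 * margin) / widths.sum()
        rows = np.stack(
            [_wavy_rows(rng, b, cfg.width_px, cfg.boundary_waviness_px) for b in base]
        )
        rows = np.clip(rows, margin, h - 1 - margin)
        gaps = np.diff(rows, axis=0)
        if n < 2 or gaps.min() > 2 * cfg.fiber_band_halfwidth_px + 2:
            return rows
    raise RuntimeError("could not draw non-crossing boundaries; relax waviness")


def _place_vessels(cfg: SynthConfig, rng, rows: np.ndarray):
    """Sample vessel centers/radii per ring, avoiding the fiber bands."""
    h, w = cfg.height_px, cfg.width_px
    n_rings = cfg.n_boundaries + 1
    rmin, rmax = cfg.vessel_radius_range_px
    centers, radii, ring_idx = [], [], []
    for ring in range(n_rings):
        count = rng.poisson(cfg.vessels_per_ring_mean)
        placed = 0
        for _ in range(count * 20):
            if placed >= count:
                break
            col = rng.uniform(0, w - 1)
            t = rng.uniform(0, 1)  # position within the ring, 0=start (top)
            # semi-ring-porous: expected radius shrinks linearly across the ring
            r_mean = rmax + (rmin - rmax) * t
            radius = float(np.clip(r_mean * rng.lognormal(0.0, 0.15), rmin, rmax))
            top = rows[ring - 1, int(round(col))] if ring > 0 else 0.0
            bot = rows[ring, int(round(col))] if ring < cfg.n_boundaries else float(h - 1)
            pad = cfg.fiber_band_halfwidth_px + radius + 1
            lo, hi = top + pad, bot - pad
            if hi <= lo:
                continue
            row = lo + t * (hi - lo)
            if not (radius < row < h - 1 - radius and radius < col < w - 1 - radius):
                continue
            centers.append((row, col))
            radii.append(radius)
            ring_idx.append(ring)
            placed += 1
    return centers, radii, ring_idx


def generate_sample(cfg: SynthConfig) -> AnnotatedSample:
    """Generate one annotated synthetic microsection.

    Deterministic in ``cfg`` (including ``cfg.seed``): identical configs give
    bit-identical images and annotations.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height_px, cfg.width_px
    rows = _draw_boundary_rows(cfg, rng)

    img = np.empty((h, w, 3), float)
    img[:] = _GROUND
    # mild vertical texture so the ground tissue is not flat
    texture = gaussian_filter1d(rng.normal(0, 1, size=h), 8)
    img += texture[:, None, None] * 4.0

    rr_grid = np.arange(h)[:, None]
    for k in range(cfg.n_boundaries):
        dist = np.abs(rr_grid - rows[k][None, :])
        band = np.clip(1.0 - dist / (cfg.fiber_band_halfwidth_px + 1.5), 0.0, 1.0)
        img += band[:, :, None] * (_BAND - _GROUND)[None, None, :]

    centers, radii, ring_idx = _place_vessels(cfg, rng, rows)
    vessels = []
    res2 = cfg.resolution_um_per_px ** 2
    for i, ((r, c), rad) in enumerate(zip(centers, radii)):
        ax_r = rad * rng.uniform(0.8, 1.0)
        ax_c = rad
        rr, cc = draw_ellipse(r, c, ax_r, ax_c, shape=(h, w))
        img[rr, cc] = _LUMEN + rng.normal(0, 2, size=3)
        vessels.append(
            VesselRecord((r, c), float(np.pi * ax_r * ax_c * res2), f"v{i}")
        )

    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    cols = np.arange(w, dtype=float)
    boundaries = [
        BoundaryPath(np.column_stack([rows[k], cols]), source="synthetic")
        for k in range(cfg.n_boundaries)
    ]
    mask = rasterize_boundaries(boundaries, (h, w), stroke_px=1)
    image = MicrosectionImage(pixels, cfg.resolution_um_per_px, f"synth-{cfg.seed}")
    return AnnotatedSample(
        image=image,
        boundaries=boundaries,
        vessels=vessels,
        vessel_ring_index=np.asarray(ring_idx, int),
        mask=mask,
    )


def write_sample(sample: AnnotatedSample, cfg: SynthConfig, out_dir) -> None:
    """Write image (TIFF), boundary/vessel CSVs and the config YAML sidecar."""
    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = sample.image.sample_id
    rio.write_microsection(sample.image, out / f"{sid}.tif")
    rio.write_boundaries(sample.boundaries, out / f"{sid}_boundaries.csv")
    rio.write_vessels(
        sample.vessels, out / f"{sid}_vessels.csv", ring_index=sample.vessel_ring_index
    )
    d = asdict(cfg)
    d["vessel_radius_range_px"] = list(cfg.vessel_radius_range_px)
    (out / f"{sid}_config.yaml").write_text(yaml.safe_dump(d))
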