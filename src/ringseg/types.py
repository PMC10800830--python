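"""Core domain types for microsection ring-boundary analysis.

Coordinate convention: 0-based ``(row, col)`` with row 0 at the image top.
Wood cores are much taller than wide (the growth axis is the row axis), so
ring boundaries run roughly along columns and each boundary is represented
as a function of column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_RESOLUTION_UM_PER_PX = 1.63

BOUNDARY_SOURCES = ("manual", "model", "synthetic")


@dataclass
class MicrosectionImage:
    """An RGB microsection image with its physical pixel resolution.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    resolution_um_per_px
        Physical side length of one pixel in micrometres (default 1.63).
    sample_id
        Free-text identifier of the core / section.
    """

    pixels: np.ndarray
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected an (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """``(H, W)`` of the pixel grid."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class BoundaryPath:
    """One ring boundary as an ordered pixel path, a function of column.

    ``points`` is an ``(n, 2)`` float array of ``(row, col)`` with strictly
    increasing column. Rows may be fractional (e.g. per-column mean rows of a
    skeleton). ``source`` records provenance: ``manual``, ``model`` or
    ``synthetic``.
    """

    points: np.ndarray
    source: str = "manual"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be a non-empty (n, 2) array of (row, col)")
        if pts.shape[0] > 1 and not np.all(np.diff(pts[:, 1]) > 0):
            raise ValueError("boundary path columns must be strictly increasing")
        if self.source not in BOUNDARY_SOURCES:
            raise ValueError(f"source must be one of {BOUNDARY_SOURCES}")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def row_at(self, col) -> np.ndarray | float:
        """Interpolated row at ``col``.

        Linear interpolation between path points; outside the covered column
        span the boundary is extended horizontally from its nearest endpoint.
        """
        rows = np.interp(col, self.points[:, 1], self.points[:, 0])
        return rows

    def mean_position(self) -> tuple[float, float]:
        """Arithmetic mean ``(row, col)`` of the path's points."""
        m = self.points.mean(axis=0)
        return float(m[0]), float(m[1])


@dataclass
class VesselRecord:
    """A xylem vessel reduced to its lumen center point.

    The ring a vessel center falls in is the quantity that matters for
    quantitative wood anatomy; ``lumen_area_um2`` is carried through when
    available.
    """

    center: tuple[float, float]
    lumen_area_um2: float | None = None
    vessel_id: str = ""

    def __post_init__(self) -> None:
        r, c = self.center
        self.center = (float(r), float(c))
        if self.lumen_area_um2 is not None:
            self.lumen_area_um2 = float(self.lumen_area_um2)
            if self.lumen_area_um2 < 0:
                raise ValueError(f"vessel {self.vessel_id!r}: negative lumen area")


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and return ``arr`` as a 2-D {0,1} uint8 mask."""
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    return a.astype(np.uint8)


def as_probability_map(arr: np.ndarray) -> np.ndarray:
    """Validate and return ``arr`` as a 2-D float map with values in [0, 1]."""
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"probability map must be 2-D, got shape {a.shape}")
    if a.size and (a.min() < 0 or a.max() > 1):
        raise ValueError("probability values must lie in [0, 1]")
    return a


@dataclass
class AnnotatedSample:
    """A microsection image together with full ground-truth annotations."""

    image: MicrosectionImage
    boundaries: list[BoundaryPath] = field(default_factory=list)
    vessels: list[VesselRecord] = field(default_factory=list)
    vessel_ring_index: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    mask: np.ndarray = field(default_factory=lambda: np.zeros((1, 1), np.uint8))
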