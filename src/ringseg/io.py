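"""Readers and writers for images, boundary annotations and vessel tables.

Images are baseline TIFF or PNG; annotations are RFC-4180 CSV with a
mandatory header row; run manifests and image sidecars are YAML. All readers
reject malformed rows instead of silently coercing them, and every
write/read pair round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    DEFAULT_RESOLUTION_UM_PER_PX,
    BoundaryPath,
    MicrosectionImage,
    VesselRecord,
)

BOUNDARY_COLUMNS = ["boundary_id", "point_index", "row", "col"]
VESSEL_COLUMNS = ["vessel_id", "row", "col"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def read_microsection(
    path, resolution_um_per_px: float | None = None
) -> MicrosectionImage:
    """Read an 8/16-bit RGB TIFF or PNG as a :class:`MicrosectionImage`.

    Resolution precedence: explicit argument, then a ``<file>.<ext>.yaml``
    sidecar with a ``resolution_um_per_px`` key, then the 1.63 µm/px default.
    16-bit inputs are rescaled affinely to 8-bit (65535 -> 255).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; need uint8/uint16")

    res = resolution_um_per_px
    if res is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            res = meta.get("resolution_um_per_px")
    if res is None:
        res = DEFAULT_RESOLUTION_UM_PER_PX
    return MicrosectionImage(arr, float(res), sample_id=path.stem)


def write_microsection(image: MicrosectionImage, path) -> None:
    """Write the image as TIFF or PNG plus a YAML resolution sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)
    _sidecar_path(path).write_text(
        yaml.safe_dump({"resolution_um_per_px": image.resolution_um_per_px,
                        "sample_id": image.sample_id})
    )


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(out[c], errors="coerce")
        if vals.isna().any() and not out[c].isna().any():
            bad = out.loc[vals.isna(), c].iloc[0]
            raise ValueError(f"{path}: non-numeric value {bad!r} in column {c!r}")
        out[c] = vals
    return out


def read_boundaries(path, source: str = "manual") -> list[BoundaryPath]:
    """Read boundary polylines from CSV (boundary_id, point_index, row, col).

    Points are sorted by ``point_index`` within each boundary; boundaries are
    returned in order of first appearance.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, BOUNDARY_COLUMNS, path)
    df = _numeric(df, ["point_index", "row", "col"], path)
    if df.duplicated(subset=["boundary_id", "point_index"]).any():
        dup = df[df.duplicated(subset=["boundary_id", "point_index"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate (boundary_id, point_index) = "
            f"({dup['boundary_id']!r}, {int(dup['point_index'])})"
        )
    paths = []
    for _, grp in df.groupby("boundary_id", sort=False):
        grp = grp.sort_values("point_index")
        paths.append(BoundaryPath(grp[["row", "col"]].to_numpy(float), source=source))
    return paths


def write_boundaries(paths: list[BoundaryPath], path) -> None:
    rows = []
    for b, bp in enumerate(paths):
        for i, (r, c) in enumerate(bp.points):
            rows.append({"boundary_id": f"b{b}", "point_index": i, "row": r, "col": c})
    pd.DataFrame(rows, columns=BOUNDARY_COLUMNS).to_csv(path, index=False)


def read_vessels(path) -> list[VesselRecord]:
    """Read vessel centers from CSV (vessel_id, row, col[, lumen_area_um2[, ring_index]])."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, VESSEL_COLUMNS, path)
    numeric_cols = ["row", "col"]
    if "lumen_area_um2" in df.columns:
        numeric_cols.append("lumen_area_um2")
    df = _numeric(df, numeric_cols, path)
    records = []
    for _, r in df.iterrows():
        area = None
        if "lumen_area_um2" in df.columns and not pd.isna(r["lumen_area_um2"]):
            area = float(r["lumen_area_um2"])
        records.append(
            VesselRecord((float(r["row"]), float(r["col"])), area, str(r["vessel_id"]))
        )
    return records


def write_vessels(
    vessels: list[VesselRecord], path, ring_index: np.ndarray | None = None
) -> None:
    rows = []
    for i, v in enumerate(vessels):
        row = {
            "vessel_id": v.vessel_id or f"v{i}",
            "row": v.center[0],
            "col": v.center[1],
        }
        if ring_index is not None:
            row["ring_index"] = int(ring_index[i])
        if v.lumen_area_um2 is not None:
            row["lumen_area_um2"] = v.lumen_area_um2
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vessel_ring_index(path) -> np.ndarray:
    """Ring-index column of a vessel CSV, if present."""
    df = pd.read_csv(path)
    if "ring_index" not in df.columns:
        raise ValueError(f"{path}: no ring_index column")
    return df["ring_index"].to_numpy(int)


def read_expert_labels(path) -> dict[str, int]:
    """Read trinomial expert labels (ring_id, label) with label in {0, 1, 2}.

    0 = manual delineation judged better, 1 = no difference, 2 = model
    delineation judged better.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["ring_id", "label"], path)
    labels = {}
    for _, r in df.iterrows():
        lab = int(r["label"])
        if lab not in (0, 1, 2):
            raise ValueError(f"{path}: label must be 0, 1 or 2, got {lab}")
        labels[str(r["ring_id"])] = lab
    return labels
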