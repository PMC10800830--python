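"""Four-criterion evaluation of ring-boundary delineations for QWA.

Compares a manual and a model delineation of the same microsection by
(1) pixel-level coincidence of the rasterized boundaries, (2) the distance
between the mean positions of matched boundaries (px and µm), (3) the
number of vessels whose ring assignment differs between the two
delineations, and (4) summaries of expert trinomial judgements
(0 = manual better, 1 = no difference, 2 = model better) with counts,
percentages and standard errors.

Percentages in summaries are truncated (not rounded) at two decimals, the
convention used in the reference result tables; raw floats are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import BoundaryPath, VesselRecord

LABEL_NAMES = {0: "manual", 1: "similar", 2: "model"}


def truncate_decimals(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals (41.8999 -> 41.89)."""
    scale = 10.0**ndigits
    return math.trunc(x * scale) / scale


def pixel_agreement(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    """(precision, recall, F1, IoU) of mask ``b`` against reference ``a``.

    Two empty masks agree perfectly (all metrics 1). Two parallel 1-px lines
    one row apart share no pixels and score 0 — the motivation for the
    position- and vessel-based criteria below.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    tp = float((a & b).sum())
    na, nb = float(a.sum()), float(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0, 1.0, 1.0
    precision = tp / nb if nb else (1.0 if na == 0 else 0.0)
    recall = tp / na if na else (1.0 if nb == 0 else 0.0)
    f1 = 2 * tp / (na + nb)
    union = na + nb - tp
    iou = tp / union if union else 1.0
    return precision, recall, f1, iou


def boundary_mean_position(path: BoundaryPath) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the path's points."""
    return path.mean_position()


def center_distance(
    manual: BoundaryPath, predicted: BoundaryPath, mode: str = "euclidean"
) -> float:
    """Distance in px between the two boundaries' mean positions.

    ``mode='euclidean'`` uses the full 2-D distance; ``mode='row'`` the
    absolute difference of mean rows (growth-axis projection).
    """
    mr, mc = manual.mean_position()
    pr, pc = predicted.mean_position()
    if mode == "row":
        return abs(mr - pr)
    if mode != "euclidean":
        raise ValueError("mode must be 'euclidean' or 'row'")
    return math.hypot(mr - pr, mc - pc)


def px_to_um(d_px: float, resolution_um_per_px: float = 1.63) -> float:
    """Convert a pixel distance to micrometres."""
    return d_px * resolution_um_per_px


@dataclass
class BoundaryMatch:
    """A manual/predicted boundary pairing (or an unmatched singleton)."""

    manual: BoundaryPath | None = None
    predicted: BoundaryPath | None = None
    center_distance_px: float | None = None
    vessel_mismatch: int | None = None

    def __post_init__(self) -> None:
        if self.manual is None and self.predicted is None:
            raise ValueError("a match must reference at least one boundary")

    @property
    def matched(self) -> bool:
        return self.manual is not None and self.predicted is not None

    @property
    def predicted_only(self) -> bool:
        return self.manual is None

    @property
    def manual_only(self) -> bool:
        return self.predicted is None


def default_gate_px(manual: list[BoundaryPath]) -> float:
    """Half the median manual ring width; infinite with < 2 boundaries."""
    if len(manual) < 2:
        return math.inf
    rows = sorted(bp.mean_position()[0] for bp in manual)
    return 0.5 * float(np.median(np.diff(rows)))


def match_boundaries(
    manual: list[BoundaryPath],
    predicted: list[BoundaryPath],
    gate_px: float | None = None,
) -> list[BoundaryMatch]:
    """One-to-one matching minimizing total mean-position distance.

    Pairs farther apart than ``gate_px`` are forbidden; leftover manual
    boundaries become manual-only records (missed rings) and leftover
    predictions predicted-only records (extra rings).
    """
    if gate_px is None:
        gate_px = default_gate_px(manual)
    matches: list[BoundaryMatch] = []
    if manual and predicted:
        cost = np.array(
            [[center_distance(m, p) for p in predicted] for m in manual]
        )
        big = 1e9
        feasible = cost <= gate_px
        rows, cols = linear_sum_assignment(np.where(feasible, cost, big))
        used_m, used_p = set(), set()
        for i, j in zip(rows, cols):
            if feasible[i, j]:
                matches.append(
                    BoundaryMatch(manual[i], predicted[j], center_distance_px=cost[i, j])
                )
                used_m.add(i)
                used_p.add(j)
    else:
        used_m, used_p = set(), set()
    for i, m in enumerate(manual):
        if i not in used_m:
            matches.append(BoundaryMatch(manual=m))
    for j, p in enumerate(predicted):
        if j not in used_p:
            matches.append(BoundaryMatch(predicted=p))
    return matches


def _check_non_crossing(boundaries: list[BoundaryPath], n_cols: int) -> None:
    if len(boundaries) < 2:
        return
    cols = np.arange(n_cols)
    rows = np.stack([bp.row_at(cols) for bp in boundaries])
    if (np.diff(rows, axis=0) < 0).any():
        raise ValueError("boundaries cross: not a valid ordered delineation")


def assign_vessels(
    boundaries: list[BoundaryPath],
    vessels: list[VesselRecord],
    image_width: int | None = None,
) -> np.ndarray:
    """Ring index of each vessel given sorted, non-crossing boundaries.

    A vessel's ring index is the number of boundaries whose interpolated row
    at the vessel's column lies strictly above (less than) the vessel's row;
    boundaries are extended horizontally beyond their column span. Indices
    run from 0 (above the first boundary) to ``len(boundaries)``.
    """
    if image_width is not None:
        _check_non_crossing(boundaries, image_width)
    idx = np.zeros(len(vessels), dtype=int)
    for i, v in enumerate(vessels):
        r, c = v.center
        idx[i] = sum(1 for bp in boundaries if float(bp.row_at(c)) < r)
    return idx


def vessel_mismatch(match: BoundaryMatch, vessels: list[VesselRecord]) -> int:
    """Vessels whose side of this boundary differs between delineations.

    Counts vessel centers lying between the manual and the predicted version
    of the same ring boundary; symmetric in the two delineations.
    """
    if not match.matched:
        raise ValueError("vessel mismatch requires a matched boundary pair")
    count = 0
    for v in vessels:
        r, c = v.center
        side_m = float(match.manual.row_at(c)) < r
        side_p = float(match.predicted.row_at(c)) < r
        count += side_m != side_p
    return count


def evaluate_delineations(
    manual: list[BoundaryPath],
    predicted: list[BoundaryPath],
    vessels: list[VesselRecord],
    gate_px: float | None = None,
) -> list[BoundaryMatch]:
    """Match boundaries and fill in distances and vessel mismatches."""
    matches = match_boundaries(manual, predicted, gate_px)
    for m in matches:
        if m.matched:
            m.vessel_mismatch = vessel_mismatch(m, vessels)
    return matches


@dataclass
class EvalRecord:
    """A matched boundary pair with an optional expert trinomial label."""

    match: BoundaryMatch
    expert_label: int | None = None  # 0 manual / 1 similar / 2 model

    def __post_init__(self) -> None:
        if self.expert_label is not None and self.expert_label not in (0, 1, 2):
            raise ValueError("expert label must be 0, 1 or 2")


def _mean_se(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, se


@dataclass
class AgreementSummary:
    """Per-label counts/percentages and metric means with standard errors."""

    counts: dict[str, int]
    percentages: dict[str, float]  # of total_rings, truncated at 2 decimals
    center_distance_mean_se: dict[str, tuple[float, float]]
    vessel_mismatch_mean_se: dict[str, tuple[float, float]]
    equal_or_better_pct: float
    total_rings: int
    n_manual_only: int = 0
    n_predicted_only: int = 0
    raw_percentages: dict[str, float] = field(default_factory=dict)


def summarize_agreement(
    records: list[EvalRecord], total_rings: int
) -> AgreementSummary:
    """Aggregate labelled records into the per-label agreement table.

    Percentages are ``count / total_rings * 100`` truncated at two decimals;
    the equal-or-better figure pools the ``similar`` and ``model`` labels.
    Standard errors are sample sd (n-1 denominator) / sqrt(n).
    """
    if any(r.expert_label is None for r in records):
        raise ValueError("all records must carry an expert label")
    if total_rings < len(records):
        raise ValueError("total_rings smaller than the number of records")
    counts = {name: 0 for name in LABEL_NAMES.values()}
    dists: dict[str, list[float]] = {name: [] for name in LABEL_NAMES.values()}
    mism: dict[str, list[float]] = {name: [] for name in LABEL_NAMES.values()}
    for r in records:
        name = LABEL_NAMES[r.expert_label]
        counts[name] += 1
        if r.match.center_distance_px is not None:
            dists[name].append(r.match.center_distance_px)
        if r.match.vessel_mismatch is not None:
            mism[name].append(r.match.vessel_mismatch)
    raw = {k: v / total_rings * 100.0 for k, v in counts.items()}
    return AgreementSummary(
        counts=counts,
        percentages={k: truncate_decimals(v) for k, v in raw.items()},
        center_distance_mean_se={k: _mean_se(v) for k, v in dists.items()},
        vessel_mismatch_mean_se={k: _mean_se(v) for k, v in mism.items()},
        equal_or_better_pct=truncate_decimals(
            (counts["similar"] + counts["model"]) / total_rings * 100.0
        ),
        total_rings=total_rings,
        raw_percentages=raw,
    )


def summary_from_counts(
    n_manual: int, n_similar: int, n_model: int, total_rings: int
) -> AgreementSummary:
    """Agreement summary from bare label counts (no per-ring metrics)."""
    records = (
        [EvalRecord(BoundaryMatch(manual=_DUMMY, predicted=_DUMMY), 0)] * n_manual
        + [EvalRecord(BoundaryMatch(manual=_DUMMY, predicted=_DUMMY), 1)] * n_similar
        + [EvalRecord(BoundaryMatch(manual=_DUMMY, predicted=_DUMMY), 2)] * n_model
    )
    return summarize_agreement(records, total_rings)


_DUMMY = BoundaryPath(np.array([[0.0, 0.0]]), source="manual")
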