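"""Skeleton extraction, Discrete Skeleton Evolution pruning, path extraction.

The thresholded prediction is thinned to a 1-px-wide, topology-preserving
skeleton. Spurious side branches are pruned by Discrete Skeleton Evolution:
each removable end-branch is weighted by the area of the source mask that
only its maximal inscribed disks reconstruct, and the least informative
branch is removed repeatedly while its weight stays under an area threshold
(default 100 px). Surviving components are reduced to their longest
geodesic pixel path and projected to one mean row per column, yielding ring
boundary polylines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import distance_transform_edt, label
from skimage.draw import disk as draw_disk
from skimage.morphology import skeletonize as _skimage_skeletonize

from .types import BoundaryPath

_NEIGH_KERNEL = np.ones((3, 3), int)
_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Branch:
    """A maximal skeleton chain between graph nodes (ordered pixel list).

    ``exclusive`` are the pixels deleted if the branch is pruned: the chain
    minus any junction pixels shared with the remaining skeleton.
    """

    pixels: list[tuple[int, int]]
    end_nodes: list[tuple[int, int]]  # attached node pixels (0, 1 or 2)
    is_end_branch: bool
    exclusive: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class SkeletonGraph:
    """A skeleton decomposed into endpoints, junctions and branches."""

    skeleton: np.ndarray  # bool (H, W)
    source_mask: np.ndarray  # uint8 {0,1} (H, W)
    endpoints: set = field(default_factory=set)
    junctions: set = field(default_factory=set)
    branches: list[Branch] = field(default_factory=list)
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def pixels(self) -> set:
        return set(map(tuple, np.argwhere(self.skeleton)))

    def n_components(self) -> int:
        return label(self.skeleton, structure=_NEIGH_KERNEL)[1]


def _pixel_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    coords = np.argwhere(skel)
    for r, c in coords:
        g.add_node((int(r), int(c)))
    h, w = skel.shape
    for r, c in coords:
        for dr, dc in _EIGHT:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                g.add_edge((int(r), int(c)), (int(rr), int(cc)))
    return g


def _decompose(skel: np.ndarray, source_mask: np.ndarray) -> SkeletonGraph:
    g = _pixel_graph(skel)
    endpoints = {p for p in g.nodes if g.degree[p] == 1}
    junctions = {p for p in g.nodes if g.degree[p] >= 3}
    nodes = endpoints | junctions
    isolated = {p for p in g.nodes if g.degree[p] == 0}

    branches: list[Branch] = []
    chain_sub = g.subgraph([p for p in g.nodes if p not in nodes and p not in isolated])
    for comp in nx.connected_components(chain_sub):
        comp = set(comp)
        # order the chain: start from a pixel with <=1 neighbour inside the chain
        ends = [p for p in comp if len(set(chain_sub.adj[p]) & comp) <= 1]
        start = min(ends) if ends else min(comp)  # cycle: arbitrary start
        order = [start]
        seen = {start}
        cur = start
        while True:
            nxt = [q for q in chain_sub.adj[cur] if q in comp and q not in seen]
            if not nxt:
                break
            cur = min(nxt)
            seen.add(cur)
            order.append(cur)
        attached = []
        for end_pixel in (order[0], order[-1]):
            for q in g.adj[end_pixel]:
                if q in nodes and q not in attached:
                    attached.append(q)
        pixels = list(order)
        exclusive = list(order)
        for node in attached:
            if node in endpoints:
                exclusive.append(node)
            pixels.append(node)
        # a chain with no attached node is a pure cycle: never removable
        is_end = any(n in endpoints for n in attached)
        branches.append(Branch(pixels, attached, is_end, exclusive))
    # direct node-to-node links with no interior chain (e.g. 2-px spurs)
    for u, v in g.edges:
        if u in nodes and v in nodes:
            exclusive = [p for p in (u, v) if p in endpoints]
            is_end = bool(exclusive)
            branches.append(Branch([u, v], [u, v], is_end, exclusive))
    for p in isolated:
        branches.append(Branch([p], [], True, [p]))
    return SkeletonGraph(skel, source_mask, endpoints, junctions, branches, g)


def skeletonize_mask(mask: np.ndarray) -> SkeletonGraph:
    """Thin a binary mask to a 1-px skeleton and decompose it into branches."""
    mask = np.asarray(mask)
    skel = _skimage_skeletonize(mask.astype(bool))
    return _decompose(skel, mask.astype(np.uint8))


def _disk_pixels(edt: np.ndarray, p: tuple[int, int]):
    """Pixels of the maximal inscribed disk centred on skeleton pixel ``p``."""
    radius = float(edt[p])
    return draw_disk(p, max(radius, 1.0), shape=edt.shape)


def _coverage(edt: np.ndarray, pixels) -> np.ndarray:
    cover = np.zeros(edt.shape, dtype=np.int32)
    for p in pixels:
        rr, cc = _disk_pixels(edt, p)
        cover[rr, cc] += 1
    return cover


def branch_reconstruction_weight(graph: SkeletonGraph, branch: Branch) -> float:
    """Reconstruction area lost if ``branch`` were removed.

    Counts source-mask foreground pixels covered by the maximal disks of the
    branch's exclusive pixels but by no disk of the remaining skeleton.
    """
    if branch not in graph.branches:
        raise ValueError("branch does not belong to this skeleton graph")
    edt = distance_transform_edt(graph.source_mask)
    total = _coverage(edt, graph.pixels)
    own = _coverage(edt, branch.exclusive)
    lost = (own > 0) & (own == total) & (graph.source_mask > 0)
    return float(lost.sum())


@dataclass
class PruneConfig:
    min_branch_area_px: float = 100.0

    def __post_init__(self) -> None:
        if self.min_branch_area_px <= 0:
            raise ValueError("min_branch_area_px must be positive")


def dse_prune(graph: SkeletonGraph, cfg: PruneConfig = PruneConfig()) -> SkeletonGraph:
    """Discrete Skeleton Evolution pruning.

    Repeatedly removes the end-branch with the smallest reconstruction
    weight while that weight is below ``min_branch_area_px``, re-deriving
    node classification and weights after every removal. Pure cycles are
    left untouched. Monotone (output skeleton is a subset of the input) and
    idempotent.
    """
    skel = graph.skeleton.copy()
    src = graph.source_mask
    edt = distance_transform_edt(src)
    current = _decompose(skel, src)
    while True:
        candidates = [b for b in current.branches if b.is_end_branch and b.exclusive]
        if not candidates:
            break
        total = _coverage(edt, current.pixels)
        fg = src > 0
        best = None
        for b in candidates:
            own = _coverage(edt, b.exclusive)
            weight = float(((own > 0) & (own == total) & fg).sum())
            key = (weight, len(b), min(b.pixels))
            if best is None or key < best[0]:
                best = (key, b)
        (weight, _, _), branch = best
        if weight >= cfg.min_branch_area_px:
            break
        for r, c in branch.exclusive:
            skel[r, c] = False
        current = _decompose(skel, src)
    return current


def extract_boundary_paths(
    graph: SkeletonGraph, min_path_len_px: int = 50
) -> list[BoundaryPath]:
    """Longest geodesic path per component, projected to one row per column.

    Components whose longest path is shorter than ``min_path_len_px`` pixels
    are discarded; surviving paths are returned sorted by mean row with
    ``source='model'``.
    """
    g = graph.graph if graph.graph.number_of_nodes() else _pixel_graph(graph.skeleton)
    paths = []
    for comp in nx.connected_components(g):
        comp = list(comp)
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        # double sweep: farthest pixel from an arbitrary start, then farthest again
        lengths = nx.single_source_shortest_path_length(sub, comp[0])
        far = max(lengths, key=lambda p: (lengths[p], p))
        lengths2, trails = nx.single_source_dijkstra(sub, far, weight=None)
        far2 = max(lengths2, key=lambda p: (lengths2[p], p))
        pixel_path = trails[far2]
        if len(pixel_path) < min_path_len_px:
            continue
        arr = np.asarray(pixel_path, dtype=float)
        cols, inverse = np.unique(arr[:, 1], return_inverse=True)
        mean_rows = np.bincount(inverse, weights=arr[:, 0]) / np.bincount(inverse)
        paths.append(
            BoundaryPath(np.column_stack([mean_rows, cols]), source="model")
        )
    paths.sort(key=lambda bp: bp.mean_position()[0])
    return paths


def mask_to_boundaries(
    mask: np.ndarray,
    prune_cfg: PruneConfig = PruneConfig(),
    min_path_len_px: int = 50,
) -> list[BoundaryPath]:
    """Full post-processing chain: skeletonize, DSE-prune, extract paths."""
    return extract_boundary_paths(
        dse_prune(skeletonize_mask(mask), prune_cfg), min_path_len_px
    )
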