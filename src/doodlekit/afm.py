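"""AFM height-map analysis: flattening, segmentation, trunk/branch tracing.

High-speed contact-mode AFM images of surface-deposited DNA are processed in
four stages:

1. line-by-line flattening — a 3rd-order polynomial is fitted to each scan
   row and subtracted; a second masked pass refits on background pixels only
   so tall molecules do not bias the background estimate;
2. segmentation — pixels above a height threshold (nm) are grouped into
   8-connected components, discarding specks below ``min_pixels``;
3. skeleton tracing — each component is reduced to a one-pixel-wide
   skeleton, turned into a pixel graph (step weight 1 for rook moves, sqrt 2
   for diagonal), short spurs pruned, and decomposed into the *trunk* (the
   maximum-length endpoint-to-endpoint path) plus *branches* (longest paths
   from their junction on the trunk to an endpoint, recursively);
4. physical conversion — path lengths in pixels become nm via the pixel
   size (default 0.48 nm/px) and nucleotides via 0.34 nm per nucleotide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import tifffile
from scipy.ndimage import label as cc_label
from skimage.morphology import skeletonize

NM_PER_NT = 0.34  # rise per nucleotide along the strand axis
DEFAULT_PIXEL_NM = 0.48

__all__ = [
    "NM_PER_NT",
    "DEFAULT_PIXEL_NM",
    "HeightMap",
    "MoleculeTrace",
    "flatten_rows_poly3",
    "segment_molecules",
    "trace_trunk_branches",
    "trace_lengths_nt",
    "branch_count_distribution",
    "analyze_height_map",
]


@dataclass
class HeightMap:
    heights: np.ndarray  # 2-D, nm
    pixel_nm: float = DEFAULT_PIXEL_NM

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be 2-D")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")

    @classmethod
    def from_file(cls, path: str | Path, pixel_nm: float = DEFAULT_PIXEL_NM) -> "HeightMap":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            return cls(tifffile.imread(path).astype(float), pixel_nm)
        return cls(np.loadtxt(path), pixel_nm)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, self.heights.astype(np.float32))
        else:
            np.savetxt(path, self.heights)


@dataclass
class MoleculeTrace:
    trunk: list[tuple[int, int]]  # ordered (row, col) pixel path
    branches: list[list[tuple[int, int]]] = field(default_factory=list)
    attachments: list[tuple[int, int]] = field(default_factory=list)  # junction per branch
    trunk_length_px: float = 0.0  # step-weighted path length in pixels
    branch_lengths_px: list[float] = field(default_factory=list)
    trunk_length_nm: Optional[float] = None
    branch_lengths_nm: list[float] = field(default_factory=list)
    trunk_length_nt: Optional[int] = None
    branch_lengths_nt: list[int] = field(default_factory=list)
    had_cycle: bool = False

    @property
    def n_branches(self) -> int:
        return len(self.branches)


def flatten_rows_poly3(image: HeightMap, masked_second_pass: bool = True) -> HeightMap:
    """Subtract a least-squares cubic from every scan row.

    With ``masked_second_pass`` (default), a second fit uses only pixels
    whose first-pass residual is below median + 3 robust sigma, so ridges do
    not drag the background estimate upward.
    """
    h = image.heights
    if h.shape[1] < 4:
        raise ValueError("rows must have at least 4 pixels for a cubic fit")
    x = np.arange(h.shape[1], dtype=float)
    vander = np.polynomial.polynomial.polyvander(x, 3)

    def fit_rows(mask: np.ndarray | None) -> np.ndarray:
        out = np.empty_like(h)
        for i, row in enumerate(h):
            if mask is not None and (use := ~mask[i]).sum() >= 8:
                coef, *_ = np.linalg.lstsq(vander[use], row[use], rcond=None)
            else:
                # L1 (IRLS) fit: resists a contiguous ridge plateau crossing
                # the row, which an L2 cubic would partially absorb
                coef, *_ = np.linalg.lstsq(vander, row, rcond=None)
                for _ in range(8):
                    r = row - vander @ coef
                    w = 1.0 / np.sqrt(np.maximum(np.abs(r), 1e-6))
                    cw, *_ = np.linalg.lstsq(vander * w[:, None], row * w, rcond=None)
                    if np.max(np.abs(cw - coef)) < 1e-12:
                        break
                    coef = cw
            out[i] = row - vander @ coef
        return out

    flat = fit_rows(None)
    if masked_second_pass:
        # global foreground from the first pass; dilation lets clean
        # neighbouring rows reveal strand pixels in rows the ridge crosses
        med = np.median(flat)
        sigma = 1.4826 * np.median(np.abs(flat - med))
        # guard for noiseless images, where the MAD collapses to rounding error
        sigma = max(sigma, 1e-6 * max(1.0, float(np.max(np.abs(flat)))))
        fg = flat > med + 5 * sigma
        if fg.any():
            from skimage.morphology import dilation, disk

            fg = dilation(fg, disk(3))
            flat = fit_rows(fg)
    return HeightMap(flat, image.pixel_nm)


def segment_molecules(
    image: HeightMap, threshold_nm: float, min_pixels: int = 20, closing_radius: int = 1
) -> list[np.ndarray]:
    """Boolean masks of 8-connected components above ``threshold_nm``.

    A morphological closing of ``closing_radius`` bridges one-pixel dropouts
    along a strand (imperfect flattening can locally pull a ridge under the
    threshold) without merging separated molecules. Components smaller than
    ``min_pixels`` are discarded as noise. Masks are returned largest first.
    """
    binary = image.heights > threshold_nm
    if closing_radius > 0:
        from skimage.morphology import closing, disk

        binary = closing(binary, disk(closing_radius))
    labeled, n = cc_label(binary, structure=np.ones((3, 3), dtype=int))
    masks = []
    for k in range(1, n + 1):
        mask = labeled == k
        if mask.sum() >= min_pixels:
            masks.append(mask)
    masks.sort(key=lambda m: -int(m.sum()))
    return masks


_NEIGHBOR_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def _skeleton_graph(mask: np.ndarray) -> nx.Graph:
    skel = skeletonize(mask)
    pixels = list(zip(*np.nonzero(skel)))
    pixel_set = set(pixels)
    G = nx.Graph()
    G.add_nodes_from(pixels)
    for (r, c) in pixels:
        for dr, dc in _NEIGHBOR_OFFSETS:
            nb = (r + dr, c + dc)
            if nb in pixel_set and not G.has_edge((r, c), nb):
                G.add_edge((r, c), nb, weight=math.sqrt(2.0) if dr and dc else 1.0)
    # drop diagonal edges that shortcut two rook edges: they create spurious
    # triangles at junctions and corners (true loops in the shape remain)
    redundant = []
    for u, v, w in G.edges(data="weight"):
        if w > 1.0:
            (r0, c0), (r1, c1) = u, v
            for mid in ((r0, c1), (r1, c0)):
                if mid in pixel_set and G.has_edge(u, mid) and G.has_edge(mid, v):
                    redundant.append((u, v))
                    break
    G.remove_edges_from(redundant)
    return G


def _break_cycles(G: nx.Graph) -> bool:
    """Remove one edge per cycle, at the highest-degree node in the cycle."""
    had = False
    while True:
        try:
            cycle = nx.find_cycle(G)
        except nx.NetworkXNoCycle:
            return had
        had = True
        node = max({u for e in cycle for u in e[:2]}, key=lambda u: (G.degree(u), u))
        for u, v in cycle:
            if node in (u, v):
                G.remove_edge(u, v)
                break


def _farthest(G: nx.Graph, source) -> tuple[object, float, list]:
    dist, paths = nx.single_source_dijkstra(G, source, weight="weight")
    far = max(dist, key=lambda n: (dist[n], n))
    return far, dist[far], paths[far]


def _longest_path(T: nx.Graph, nodes=None) -> tuple[list, float]:
    """Double-sweep longest path in a (sub)tree with positive weights."""
    sub = T.subgraph(nodes) if nodes is not None else T
    start = next(iter(sub.nodes))
    a, _, _ = _farthest(sub, start)
    b, length, path = _farthest(sub, a)
    return path, length


def _path_length(G: nx.Graph, path: list) -> float:
    return sum(G[u][v]["weight"] for u, v in zip(path, path[1:]))


def _prune_spurs(G: nx.Graph, spur_min_pixels: int) -> None:
    """Iteratively remove endpoint twigs shorter than ``spur_min_pixels`` pixels."""
    changed = True
    while changed:
        changed = False
        endpoints = [n for n in G.nodes if G.degree(n) == 1]
        for ep in endpoints:
            if ep not in G:
                continue
            # walk from the endpoint to the first junction
            twig = [ep]
            prev, cur = None, ep
            while G.degree(cur) <= 2:
                nbrs = [n for n in G.neighbors(cur) if n != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                twig.append(cur)
            if G.degree(cur) >= 3 and len(twig) - 1 < spur_min_pixels:
                G.remove_nodes_from(twig[:-1])
                changed = True


def _extend_into_mask(path: list, mask: np.ndarray, max_steps: int = 6) -> list:
    """Extend a path's free end along its direction while still on the mask.

    The skeleton of a strand of finite width ends about half a width short of
    the physical molecule end (the rounded cap is eroded); walking the last
    segment's direction out to the mask boundary recovers that length. On a
    one-pixel-wide mask there is nothing to recover and the path is returned
    unchanged.
    """
    if len(path) < 2:
        return path
    tail = np.asarray(path[-min(6, len(path)) :], dtype=float)
    direction = tail[-1] - tail[0]
    norm = np.hypot(*direction)
    if norm == 0:
        return path
    direction = direction / norm
    end = np.asarray(path[-1], dtype=float)
    seen = set(path)
    out = list(path)
    for t in range(1, max_steps + 1):
        cand = tuple(np.round(end + t * direction).astype(int))
        if not (0 <= cand[0] < mask.shape[0] and 0 <= cand[1] < mask.shape[1]):
            break
        if not mask[cand] or cand in seen:
            break
        out.append(cand)
        seen.add(cand)
    return out


def trace_trunk_branches(mask: np.ndarray, spur_min_pixels: int = 5) -> MoleculeTrace:
    """Decompose one molecule mask into a trunk and its branches.

    The trunk is the maximum step-weighted endpoint-to-endpoint path through
    the skeleton; every remaining sub-tree hanging off the trunk contributes
    a branch, measured from its junction on the trunk to its farthest
    endpoint (recursively, so branches of branches are counted too). Spurs
    shorter than ``spur_min_pixels`` are pruned first.
    """
    if not np.any(mask):
        raise ValueError("empty mask")
    G = _skeleton_graph(mask)
    had_cycle = _break_cycles(G)
    # work on the largest connected piece (skeletonization preserves connectivity,
    # but cycle-breaking cannot disconnect a graph)
    if G.number_of_nodes() == 0:
        raise ValueError("skeleton is empty")
    if G.number_of_nodes() == 1:
        only = next(iter(G.nodes))
        return MoleculeTrace(trunk=[only], had_cycle=had_cycle)
    _prune_spurs(G, spur_min_pixels)
    trunk_path, trunk_len = _longest_path(G)
    trunk_set = set(trunk_path)

    branches: list[list[tuple[int, int]]] = []
    attachments: list[tuple[int, int]] = []
    lengths: list[float] = []

    def harvest(graph: nx.Graph, backbone: set) -> None:
        """Collect branches attached to ``backbone``, longest-first, recursively."""
        H = graph.copy()
        # remove backbone edges, keep backbone nodes as potential attachment points
        H.remove_edges_from(
            [(u, v) for u, v in graph.edges if u in backbone and v in backbone]
        )
        H.remove_nodes_from([n for n in list(H.nodes) if H.degree(n) == 0 and n in backbone])
        for comp in list(nx.connected_components(H)):
            anchors = comp & backbone
            if not anchors:
                continue  # disconnected debris; skeleton of one mask should not produce this
            sub = H.subgraph(comp)
            anchor = min(anchors)
            far, dist, path = _farthest(sub, anchor)
            if len(path) - 1 < spur_min_pixels:
                continue
            branches.append(path)
            attachments.append(anchor)
            lengths.append(dist)
            # branches hanging off this branch
            harvest(sub, set(path))

    harvest(G, trunk_set)

    def chain_length(path: list) -> float:
        pts = np.asarray(path, dtype=float)
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T))) if len(pts) > 1 else 0.0

    # free ends stop half a strand-width short of the molecule end; extend
    trunk_path = _extend_into_mask(trunk_path, mask)
    trunk_path = list(reversed(_extend_into_mask(list(reversed(trunk_path)), mask)))
    branches = [_extend_into_mask(b, mask) for b in branches]
    return MoleculeTrace(
        trunk=trunk_path,
        branches=branches,
        attachments=attachments,
        trunk_length_px=chain_length(trunk_path),
        branch_lengths_px=[chain_length(b) for b in branches],
        had_cycle=had_cycle,
    )


def smoothed_path_length_px(path: list[tuple[int, int]], window: int = 7) -> float:
    """Path length after moving-average smoothing of the pixel coordinates.

    Raw chain-code summation (1 / sqrt(2) steps) overestimates the length of
    a digitized straight line by up to ~8% at shallow angles (the staircase
    effect); summing Euclidean steps along a lightly smoothed version of the
    path removes most of that bias while following genuine curvature.
    Endpoints use shrinking centered windows so the path is not shortened.
    """
    if len(path) < 2:
        return 0.0
    pts = np.asarray(path, dtype=float)
    half = window // 2
    sm = np.empty_like(pts)
    for i in range(len(pts)):
        w = min(half, i, len(pts) - 1 - i)
        sm[i] = pts[i - w : i + w + 1].mean(axis=0)
    return float(np.sum(np.hypot(*np.diff(sm, axis=0).T)))


def trace_lengths_nt(
    trace: MoleculeTrace, pixel_nm: float = DEFAULT_PIXEL_NM, smooth_paths: bool = True
) -> MoleculeTrace:
    """Fill in physical (nm) and nucleotide lengths: nt = round(nm / 0.34).

    By default the physical lengths come from smoothed-path summation (see
    :func:`smoothed_path_length_px`); ``smooth_paths=False`` converts the raw
    chain-code step lengths instead.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be > 0")
    if smooth_paths:
        trunk_px = smoothed_path_length_px(trace.trunk)
        branch_px = [smoothed_path_length_px(b) for b in trace.branches]
    else:
        trunk_px = trace.trunk_length_px
        branch_px = trace.branch_lengths_px
    trace.trunk_length_nm = trunk_px * pixel_nm
    trace.branch_lengths_nm = [l * pixel_nm for l in branch_px]
    trace.trunk_length_nt = int(round(trace.trunk_length_nm / NM_PER_NT))
    trace.branch_lengths_nt = [int(round(l / NM_PER_NT)) for l in trace.branch_lengths_nm]
    return trace


def branch_count_distribution(traces: list[MoleculeTrace]) -> tuple[dict[int, int], float]:
    """Histogram over branch counts and the fraction of branched molecules."""
    if not traces:
        raise ValueError("no traces provided")
    counts: dict[int, int] = {}
    for t in traces:
        counts[t.n_branches] = counts.get(t.n_branches, 0) + 1
    branched = sum(v for k, v in counts.items() if k >= 1) / len(traces)
    return dict(sorted(counts.items())), branched


def analyze_height_map(
    image: HeightMap,
    threshold_nm: float,
    min_pixels: int = 20,
    spur_min_pixels: int = 5,
    flatten: bool = True,
) -> list[MoleculeTrace]:
    """Full pipeline: flatten -> segment -> trace -> convert to nm/nt."""
    flat = flatten_rows_poly3(image) if flatten else image
    traces = []
    for mask in segment_molecules(flat, threshold_nm, min_pixels=min_pixels):
        trace = trace_trunk_branches(mask, spur_min_pixels=spur_min_pixels)
        traces.append(trace_lengths_nt(trace, image.pixel_nm))
    return traces
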