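"""Structural metrics of myelinated fibers from binarized 2-D images.

Images are thinned to a one-pixel skeleton; total fiber length follows the
chain-code convention (1 per orthogonal step, sqrt(2) per diagonal step,
times the pixel size), branch points are 8-connected clusters of skeleton
pixels with three or more neighbors, and the skeleton is abstracted to a
junction/endpoint graph whose node-degree distribution describes the
connectivity of the fiber network.

Diagonal adjacencies that shortcut an orthogonal corner (the two pixels
share an orthogonal common neighbor) are pruned, the standard correction
that keeps chain-code lengths unbiased at corners.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = ["binarize", "skeleton_metrics", "node_degree_density", "SkeletonGraph"]

_SQRT2 = float(np.sqrt(2.0))
_ORTHO = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, -1), (-1, 1), (1, -1), (1, 1))


def binarize(img: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Threshold a grayscale fiber image to foreground=True.

    Boolean input passes through unchanged; a constant image has no
    foreground/background separation and is rejected.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype == bool:
        return img
    if np.ptp(img) == 0:
        raise ValueError("constant image cannot be thresholded")
    if method != "otsu":
        raise ValueError(f"unknown binarization method {method!r}")
    return img > threshold_otsu(img)


@dataclass
class SkeletonGraph:
    """Junction/endpoint graph of a skeleton.

    Nodes carry ``kind`` ("junction", "endpoint" or "cycle") and ``coord``
    (row, col); edges carry ``length_um``.
    """

    graph: nx.MultiGraph
    total_length_um: float
    n_branch_points: int
    pixel_size_um: float

    @property
    def degrees(self) -> dict:
        return dict(self.graph.degree())


def _corrected_adjacency(skel: np.ndarray):
    """Pixel adjacency with corner-shortcut diagonals removed.

    Returns (coords, index map array, list of (i, j, weight) with i < j in
    flat pixel order).
    """
    rr, cc = np.nonzero(skel)
    idx = -np.ones(skel.shape, dtype=np.int64)
    idx[rr, cc] = np.arange(rr.size)
    h, w = skel.shape

    def at(r, c):
        return 0 <= r < h and 0 <= c < w and skel[r, c]

    edges = []
    for k in range(rr.size):
        r, c = int(rr[k]), int(cc[k])
        for dr, dc in _ORTHO:
            if at(r + dr, c + dc) and idx[r + dr, c + dc] > k:
                edges.append((k, int(idx[r + dr, c + dc]), 1.0))
        for dr, dc in _DIAG:
            if at(r + dr, c + dc) and idx[r + dr, c + dc] > k:
                # prune if an orthogonal pixel bridges the corner
                if at(r, c + dc) or at(r + dr, c):
                    continue
                edges.append((k, int(idx[r + dr, c + dc]), _SQRT2))
    return np.column_stack([rr, cc]), idx, edges


def skeleton_metrics(binary: np.ndarray, pixel_size_um: float = 1.0
                     ) -> tuple[float, int, SkeletonGraph]:
    """Skeletonize and measure a binary fiber image.

    Returns (total length in µm, branch-point count, SkeletonGraph).
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise ValueError("empty foreground")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    skel = skeletonize(binary)
    if not skel.any():  # single-pixel objects can vanish; keep maxima
        skel = binary.copy()
    coords, idx, edges = _corrected_adjacency(skel)
    total_length = sum(w for _, _, w in edges) * pixel_size_um

    n_pix = coords.shape[0]
    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(n_pix)]
    for i, j, w in edges:
        neighbors[i].append((j, w))
        neighbors[j].append((i, w))
    degree = np.array([len(nb) for nb in neighbors])

    # junction clusters: 8-connected components of branch pixels
    branch_mask = np.zeros_like(skel)
    branch_pix = np.flatnonzero(degree >= 3)
    branch_mask[coords[branch_pix, 0], coords[branch_pix, 1]] = True
    labels, n_junctions = ndimage.label(branch_mask, structure=np.ones((3, 3)))

    g = nx.MultiGraph()
    node_of_pixel = np.full(n_pix, -1, dtype=np.int64)
    for jid in range(1, n_junctions + 1):
        member_rc = np.argwhere(labels == jid)
        g.add_node(f"J{jid}", kind="junction",
                   coord=tuple(member_rc.mean(axis=0)))
        for r, c in member_rc:
            node_of_pixel[idx[r, c]] = jid  # positive => junction jid
    endpoints = np.flatnonzero(degree == 1)
    for n_e, k in enumerate(endpoints):
        g.add_node(f"E{n_e + 1}", kind="endpoint",
                   coord=(int(coords[k, 0]), int(coords[k, 1])))
        node_of_pixel[k] = -(n_e + 2)  # <= -2 => endpoint n_e+1

    def node_name(k: int) -> str:
        v = node_of_pixel[k]
        return f"J{v}" if v > 0 else f"E{-v - 1}"

    # trace paths between node pixels through degree-2 pixels
    visited = set()
    node_pixels = np.flatnonzero(node_of_pixel != -1)
    for start in node_pixels:
        for nxt, w0 in neighbors[start]:
            key = (min(start, nxt), max(start, nxt))
            if key in visited:
                continue
            if node_of_pixel[nxt] != -1 and node_of_pixel[nxt] == node_of_pixel[start]:
                visited.add(key)  # intra-junction edge, not a branch
                continue
            length = w0
            visited.add(key)
            prev, cur = start, nxt
            while node_of_pixel[cur] == -1:
                nbs = [(j, w) for j, w in neighbors[cur] if j != prev]
                if not nbs:
                    break  # dangling path end (shouldn't happen after class.)
                (cur2, w) = nbs[0]
                visited.add((min(cur, cur2), max(cur, cur2)))
                length += w
                prev, cur = cur, cur2
            if node_of_pixel[cur] != -1:
                g.add_edge(node_name(start), node_name(cur),
                           length_um=length * pixel_size_um)

    # isolated cycles: remaining degree-2 pixels with no node on them
    remaining = set()
    for i, j, w in edges:
        if (min(i, j), max(i, j)) not in visited:
            remaining.add((i, j, w))
    cyc = 0
    seen_px = set()
    for i, j, w in sorted(remaining):
        if i in seen_px:
            continue
        cyc += 1
        name = f"C{cyc}"
        g.add_node(name, kind="cycle",
                   coord=(int(coords[i, 0]), int(coords[i, 1])))
        length = 0.0
        prev, cur = None, i
        while True:
            seen_px.add(cur)
            nbs = [(q, wq) for q, wq in neighbors[cur] if q != prev]
            if not nbs:
                break
            q, wq = nbs[0]
            length += wq
            prev, cur = cur, q
            if cur == i:
                break
        g.add_edge(name, name, length_um=length * pixel_size_um)

    if g.number_of_nodes() == 0 and n_pix == 1:
        g.add_node("E1", kind="endpoint",
                   coord=(int(coords[0, 0]), int(coords[0, 1])))

    sg = SkeletonGraph(graph=g, total_length_um=total_length,
                       n_branch_points=int(n_junctions),
                       pixel_size_um=pixel_size_um)
    return total_length, int(n_junctions), sg


def node_degree_density(graph: SkeletonGraph | nx.Graph) -> dict[int, float]:
    """Fraction of graph nodes at each degree; values sum to 1."""
    g = graph.graph if isinstance(graph, SkeletonGraph) else graph
    degs = [d for _, d in g.degree()]
    if not degs:
        raise ValueError("graph has no nodes")
    hist: dict[int, float] = {}
    for d in degs:
        hist[d] = hist.get(d, 0) + 1
    return {d: c / len(degs) for d, c in sorted(hist.items())}
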