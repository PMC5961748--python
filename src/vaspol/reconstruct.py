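"""Binary lumen mask -> radius-annotated vascular graph.

The pipeline is: skeletonize the mask to a one-pixel-wide centerline,
trace the skeleton into a spatial graph (branch points and endpoints as
nodes, ordered pixel paths as edges), estimate per-edge radii from the
Euclidean distance transform, prune short terminal spurs, and run the
degree-4 coplanarity diagnostic.

Coordinate convention: pixel coordinates are 0-based with x = column and
y = row (origin top-left).  All physical quantities are converted to
micrometres via ``pixel_size`` at graph-construction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "BinaryMask",
    "VesselNode",
    "VesselEdge",
    "VesselNetwork",
    "CaliberHistogram",
    "skeletonize_mask",
    "extract_graph",
    "estimate_radii",
    "prune_network",
    "diagnose_overlaps",
    "caliber_histogram",
    "build_network",
]


@dataclass(frozen=True)
class BinaryMask:
    """A single-plane binary lumen mask with physical pixel size.

    Parameters
    ----------
    pixels : ndarray of bool, shape (rows, cols)
        Foreground (nonzero) marks the vessel lumen.
    pixel_size : float
        Micrometres per pixel; must be positive.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2D, got {px.ndim}D")
        object.__setattr__(self, "pixels", px.astype(bool))
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass
class VesselNode:
    id: int
    x: float  # px (column)
    y: float  # px (row)

    def position_um(self, pixel_size: float) -> tuple[float, float]:
        return self.x * pixel_size, self.y * pixel_size


@dataclass
class VesselEdge:
    """An edge between two nodes carrying an ordered centerline path.

    ``path`` is an (n, 2) float array of (x, y) pixel coordinates ordered
    from node ``u`` to node ``v``.  ``length_um`` is the polyline length
    of the path times the pixel size; ``radius_um`` is filled by
    :func:`estimate_radii` (NaN before that).
    """

    id: int
    u: int
    v: int
    path: np.ndarray
    length_um: float
    radius_um: float = float("nan")

    @property
    def is_self_loop(self) -> bool:
        return self.u == self.v


@dataclass
class VesselNetwork:
    """Spatial vessel graph: nodes with pixel positions, edges with paths."""

    nodes: dict[int, VesselNode]
    edges: dict[int, VesselEdge]
    pixel_size: float
    _adj: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rebuild_adjacency()

    def _rebuild_adjacency(self) -> None:
        self._adj = {nid: [] for nid in self.nodes}
        for eid, e in self.edges.items():
            self._adj[e.u].append(eid)
            if e.v != e.u:
                self._adj[e.v].append(eid)
            else:  # self-loop contributes 2 to degree
                self._adj[e.u].append(eid)

    def degree(self, node_id: int) -> int:
        return len(self._adj[node_id])

    def incident_edges(self, node_id: int) -> list[int]:
        return list(self._adj[node_id])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_length_um(self) -> float:
        return float(sum(e.length_um for e in self.edges.values()))

    def connected_components(self) -> list[set[int]]:
        """Node-id sets of connected components (isolated nodes included)."""
        seen: set[int] = set()
        comps: list[set[int]] = []
        for start in self.nodes:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                n = stack.pop()
                for eid in self._adj[n]:
                    e = self.edges[eid]
                    for other in (e.u, e.v):
                        if other not in comp:
                            comp.add(other)
                            stack.append(other)
            seen |= comp
            comps.append(comp)
        return comps

    def copy(self) -> "VesselNetwork":
        return VesselNetwork(
            nodes={nid: replace(n) for nid, n in self.nodes.items()},
            edges={eid: replace(e, path=e.path.copy()) for eid, e in self.edges.items()},
            pixel_size=self.pixel_size,
        )


@dataclass(frozen=True)
class CaliberHistogram:
    """Histogram of per-edge diameters (2r, um)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    length_weighted: bool


# ---------------------------------------------------------------------------
# skeletonization


def skeletonize_mask(mask: BinaryMask) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide, topology-preserving skeleton.

    Returns a boolean array of the same shape as ``mask.pixels``.  The
    skeleton is 8-connected, lies inside the foreground, and has the same
    number of connected components as the mask.
    """
    if mask.n_foreground == 0:
        raise ValueError("no foreground: mask is empty")
    skel = _sk_skeletonize(mask.pixels)
    # Zhang thinning can drop isolated single pixels; restore them so
    # topology (component count) is preserved exactly.
    lbl, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    if n:
        kept = np.unique(lbl[skel])
        for comp in range(1, n + 1):
            if comp not in kept:
                ys, xs = np.nonzero(lbl == comp)
                # deposit a single representative pixel (component is tiny)
                skel[ys[len(ys) // 2], xs[len(xs) // 2]] = True
    return skel


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant", cval=0)


def extract_graph(skeleton: np.ndarray, pixel_size: float) -> VesselNetwork:
    """Trace a skeleton into a :class:`VesselNetwork`.

    Node pixels are skeleton pixels with a number of 8-neighbors different
    from two; 8-connected clusters of node pixels collapse into a single
    node.  Edges are ordered pixel paths between node clusters; diagonal
    steps contribute sqrt(2) * pixel_size to the length.  A cyclic
    component with no node pixel becomes a single self-loop edge anchored
    at an arbitrary loop pixel (with a warning).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        raise ValueError("no foreground: skeleton is empty")

    ncount = _neighbor_count(skel)
    node_mask = skel & (ncount != 2)

    # pure loops: components made entirely of degree-2 pixels
    s8 = np.ones((3, 3), dtype=int)
    lbl, ncomp = ndimage.label(skel, structure=s8)
    loop_anchor: list[tuple[int, int]] = []
    if ncomp:
        has_node = np.zeros(ncomp + 1, dtype=bool)
        has_node[np.unique(lbl[node_mask])] = True
        for comp in range(1, ncomp + 1):
            if not has_node[comp]:
                ys, xs = np.nonzero(lbl == comp)
                loop_anchor.append((int(ys[0]), int(xs[0])))
        if loop_anchor:
            warnings.warn(
                f"{len(loop_anchor)} cyclic component(s) without branch points; "
                "represented as self-loop edges",
                stacklevel=2,
            )
            for (r, c) in loop_anchor:
                node_mask[r, c] = True

    # cluster node pixels (8-connected) into nodes
    nlbl, n_nodes = ndimage.label(node_mask, structure=s8)
    nodes: dict[int, VesselNode] = {}
    cluster_pixels: dict[int, list[tuple[int, int]]] = {i: [] for i in range(1, n_nodes + 1)}
    for r, c in zip(*np.nonzero(node_mask)):
        cluster_pixels[nlbl[r, c]].append((int(r), int(c)))
    for cid, pix in cluster_pixels.items():
        arr = np.array(pix, dtype=float)
        cy, cx = arr.mean(axis=0)
        nodes[cid - 1] = VesselNode(id=cid - 1, x=float(cx), y=float(cy))

    rows, cols = skel.shape

    def nbrs(r: int, c: int):
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and skel[rr, cc]:
                yield rr, cc

    edges: dict[int, VesselEdge] = {}
    eid = 0
    # visited flags for non-node (corridor) pixels
    visited = np.zeros_like(skel, dtype=bool)
    # track used (node_pixel -> first corridor pixel) departures to avoid
    # tracing the same edge twice from both ends
    used_departures: set[tuple[int, int, int, int]] = set()

    def add_edge(u: int, v: int, path_rc: list[tuple[int, int]]) -> None:
        nonlocal eid
        arr = np.array([(c, r) for r, c in path_rc], dtype=float)  # (x, y)
        steps = np.diff(arr, axis=0)
        length = float(np.sqrt((steps**2).sum(axis=1)).sum()) * pixel_size
        edges[eid] = VesselEdge(id=eid, u=u, v=v, path=arr, length_um=length)
        eid += 1

    node_pixel_list = [(r, c) for r, c in zip(*np.nonzero(node_mask))]
    for (r0, c0) in node_pixel_list:
        u = int(nlbl[r0, c0]) - 1
        for r1, c1 in nbrs(r0, c0):
            if node_mask[r1, c1]:
                # adjacent node pixel in a *different* cluster: direct edge
                v = int(nlbl[r1, c1]) - 1
                if v != u:
                    key = (min((r0, c0), (r1, c1)) + max((r0, c0), (r1, c1)))
                    if key in used_departures:
                        continue
                    used_departures.add(key)
                    add_edge(u, v, [(r0, c0), (r1, c1)])
                continue
            if visited[r1, c1]:
                continue
            # trace corridor
            path = [(r0, c0), (r1, c1)]
            visited[r1, c1] = True
            prev, cur = (r0, c0), (r1, c1)
            while True:
                other_cluster = None
                corridor_next = None
                same_cluster = None
                for rr, cc in nbrs(*cur):
                    if (rr, cc) == prev:
                        continue
                    if node_mask[rr, cc]:
                        if int(nlbl[rr, cc]) - 1 != u:
                            other_cluster = (rr, cc)
                        else:
                            same_cluster = (rr, cc)
                    elif not visited[rr, cc]:
                        corridor_next = (rr, cc)
                # prefer leaving toward another node cluster or continuing
                # along the corridor; closing back onto the origin cluster is
                # accepted only for genuine loops (longer than a diagonal
                # staircase artifact)
                if other_cluster is not None:
                    path.append(other_cluster)
                    v = int(nlbl[other_cluster[0], other_cluster[1]]) - 1
                    add_edge(u, v, path)
                    break
                if corridor_next is not None:
                    path.append(corridor_next)
                    visited[corridor_next[0], corridor_next[1]] = True
                    prev, cur = cur, corridor_next
                    continue
                if same_cluster is not None and len(path) >= 4:
                    path.append(same_cluster)
                    add_edge(u, u, path)
                    break
                if same_cluster is not None:
                    break  # staircase artifact next to the cluster; drop
                # dead end inside corridor (rare on a clean skeleton):
                # terminate path at current pixel as a fresh endpoint node
                v_node = max(nodes) + 1 if nodes else 0
                nodes[v_node] = VesselNode(id=v_node, x=float(cur[1]), y=float(cur[0]))
                add_edge(u, v_node, path)
                break

    net = VesselNetwork(nodes=nodes, edges=edges, pixel_size=pixel_size)
    _merge_degree2_chains(net)
    return net


def _merge_degree2_chains(net: VesselNetwork) -> None:
    """Merge chains through degree-2 nodes in place (radius length-averaged)."""
    changed = True
    while changed:
        changed = False
        for nid in list(net.nodes):
            if nid not in net.nodes:
                continue
            inc = net.incident_edges(nid)
            if len(inc) != 2:
                continue
            e1_id, e2_id = inc
            if e1_id == e2_id:  # self-loop anchored here
                continue
            e1, e2 = net.edges[e1_id], net.edges[e2_id]
            # orient e1 to end at nid, e2 to start at nid
            p1 = e1.path if e1.v == nid else e1.path[::-1]
            u_new = e1.u if e1.v == nid else e1.v
            p2 = e2.path if e2.u == nid else e2.path[::-1]
            v_new = e2.v if e2.u == nid else e2.u
            if u_new == nid or v_new == nid:
                continue  # would create a weird lollipop; leave as-is
            path = np.vstack([p1, p2[1:]])
            length = e1.length_um + e2.length_um
            if np.isnan(e1.radius_um) or np.isnan(e2.radius_um):
                radius = float("nan")
            else:
                radius = (e1.radius_um * e1.length_um + e2.radius_um * e2.length_um) / length
            new_id = max(net.edges) + 1
            net.edges[new_id] = VesselEdge(
                id=new_id, u=u_new, v=v_new, path=path, length_um=length, radius_um=radius
            )
            del net.edges[e1_id], net.edges[e2_id], net.nodes[nid]
            net._rebuild_adjacency()
            changed = True


# ---------------------------------------------------------------------------
# radii


def estimate_radii(mask: BinaryMask, net: VesselNetwork) -> VesselNetwork:
    """Fill per-edge radii from the Euclidean distance transform.

    Radius = median over the edge path of (EDT - 0.5 px) * pixel_size,
    clamped to >= 0.5 * pixel_size.  The median (not the mean) resists
    inflation near junctions.  The mask is padded by one background pixel
    so the image border counts as vessel wall.
    """
    padded = np.pad(mask.pixels, 1, constant_values=False)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    for e in net.edges.values():
        if len(e.path) == 0:
            raise ValueError(f"edge {e.id} has an empty path")
        xs = np.clip(np.round(e.path[:, 0]).astype(int), 0, mask.pixels.shape[1] - 1)
        ys = np.clip(np.round(e.path[:, 1]).astype(int), 0, mask.pixels.shape[0] - 1)
        vals = edt[ys, xs]
        r_px = float(np.median(vals)) - 0.5
        e.radius_um = max(r_px, 0.5) * mask.pixel_size
    return net


# ---------------------------------------------------------------------------
# pruning


def prune_network(net: VesselNetwork, min_spur_length_factor: float = 2.0) -> VesselNetwork:
    """Remove terminal spurs shorter than ``factor * local radius``.

    A terminal edge (one endpoint of degree 1) is removed when its length
    is below ``min_spur_length_factor`` times the local vessel radius —
    the largest radius among the edges meeting it at its junction (a thin
    skeletonization spur on a wide vessel must be judged against the wide
    vessel, not against itself).  Isolated segments (both endpoints of
    degree 1) are never deleted.  Degree-2 chains left behind are
    re-merged; the operation iterates to a fixed point and is therefore
    idempotent.
    """
    out = net.copy()
    changed = True
    while changed:
        changed = False
        for eid in list(out.edges):
            e = out.edges.get(eid)
            if e is None or e.is_self_loop:
                continue
            du, dv = out.degree(e.u), out.degree(e.v)
            if min(du, dv) != 1:
                continue
            if du == 1 and dv == 1:
                continue  # isolated segment: keep
            junction = e.v if du == 1 else e.u
            local = [
                out.edges[k].radius_um
                for k in out.incident_edges(junction)
                if not np.isnan(out.edges[k].radius_um)
            ]
            radius = max(local) if local else 0.0
            if e.length_um < min_spur_length_factor * radius:
                if out.n_edges == 1:
                    raise ValueError("network degenerate after pruning")
                del out.edges[eid]
                for nid in (e.u, e.v):
                    out._rebuild_adjacency()
                    if out.degree(nid) == 0:
                        del out.nodes[nid]
                out._rebuild_adjacency()
                changed = True
        if changed:
            _merge_degree2_chains(out)
    if out.n_edges == 0:
        raise ValueError("network degenerate after pruning")
    return out


# ---------------------------------------------------------------------------
# diagnostics & histograms


def diagnose_overlaps(net: VesselNetwork) -> list[int]:
    """Node ids with degree >= 4 (possible non-coplanar vessel crossings).

    An empty list means the coplanarity check passes.
    """
    return sorted(nid for nid in net.nodes if net.degree(nid) >= 4)


def caliber_histogram(
    net: VesselNetwork,
    bins: int | np.ndarray = 16,
    length_weighted: bool = True,
) -> CaliberHistogram:
    """Histogram of per-edge diameters (2r, um), length-weighted by default."""
    if net.n_edges == 0:
        raise ValueError("empty network")
    diam = np.array([2.0 * e.radius_um for e in net.edges.values()])
    if np.isnan(diam).any():
        raise ValueError("radii not estimated")
    w = (
        np.array([e.length_um for e in net.edges.values()])
        if length_weighted
        else np.ones_like(diam)
    )
    counts, edges = np.histogram(diam, bins=bins, weights=w)
    return CaliberHistogram(bin_edges=edges, counts=counts, length_weighted=length_weighted)


# ---------------------------------------------------------------------------
# convenience


def build_network(
    mask: BinaryMask, min_spur_factor: float = 2.0, prune: bool = True
) -> VesselNetwork:
    """Full reconstruction: skeletonize, trace, estimate radii, prune."""
    skel = skeletonize_mask(mask)
    net = extract_graph(skel, mask.pixel_size)
    estimate_radii(mask, net)
    if prune:
        net = prune_network(net, min_spur_factor)
        estimate_radii(mask, net)
    return net
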