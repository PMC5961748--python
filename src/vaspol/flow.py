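"""1D Poiseuille network hemodynamics on a vessel graph.

Node pressures are obtained from Kirchhoff balance with per-edge
conductance g = pi r^4 / (8 mu_eff L) under pressure (Dirichlet)
boundary conditions.  Shear-thinning rheology is handled with an outer
fixed-point loop updating the per-edge effective viscosity from the wall
shear rate of the previous iterate.

This is a deliberate reduced-order stand-in for a resolved 3D solver: it
preserves the boundary-condition design (pressure BCs at network inlets
and outlets, V-A-V style) and the output quantities (pressure, flow,
velocity, shear rate, oriented wall-shear-stress vectors).

Units: radii and lengths enter in micrometres and are converted to SI
internally; pressures are Pa, flows m^3/s, viscosities Pa*s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .reconstruct import VesselNetwork

__all__ = [
    "RheologyModel",
    "BoundaryCondition",
    "FlowSolution",
    "WssSample",
    "effective_viscosity",
    "solve_flow",
    "wss_vector_field",
    "wss_histogram",
    "identify_unperfused",
]

UM = 1e-6  # metres per micrometre


@dataclass(frozen=True)
class RheologyModel:
    """Blood rheology: Newtonian or Carreau-Yasuda shear-thinning.

    For Carreau-Yasuda the effective viscosity is
    ``mu_inf + (mu0 - mu_inf) * (1 + (lam * g)**a) ** ((n - 1) / a)``
    with shear rate ``g``; it decreases monotonically from ``mu0`` at
    zero shear to ``mu_inf`` at infinite shear (requires n <= 1).
    """

    kind: str = "newtonian"
    mu: float = 3.5e-3
    mu0: float = 1.6e-2
    mu_inf: float = 3.5e-3
    lam: float = 8.2
    a: float = 0.64
    n: float = 0.2128

    def __post_init__(self) -> None:
        if self.kind not in ("newtonian", "carreau_yasuda"):
            raise ValueError(f"unknown rheology kind {self.kind!r}")
        if self.kind == "newtonian":
            if not self.mu > 0:
                raise ValueError("viscosity must be > 0")
        else:
            if not (self.mu0 > 0 and self.mu_inf > 0):
                raise ValueError("viscosities must be > 0")
            if self.mu0 < self.mu_inf:
                raise ValueError("mu0 must be >= mu_inf")
            if self.n > 1:
                raise ValueError("n must be <= 1 for shear thinning")

    @property
    def zero_shear_viscosity(self) -> float:
        return self.mu if self.kind == "newtonian" else self.mu0


def effective_viscosity(shear_rate, rheology: RheologyModel):
    """Effective viscosity (Pa*s) at the given shear rate(s) (1/s)."""
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be >= 0")
    if rheology.kind == "newtonian":
        out = np.full_like(g, rheology.mu)
    else:
        lg = rheology.lam * g
        out = rheology.mu_inf + (rheology.mu0 - rheology.mu_inf) * (
            1.0 + lg**rheology.a
        ) ** ((rheology.n - 1.0) / rheology.a)
    return float(out) if np.isscalar(shear_rate) else out


@dataclass(frozen=True)
class BoundaryCondition:
    node: int
    pressure: float  # Pa
    role: str = "inlet"

    def __post_init__(self) -> None:
        if self.role not in ("inlet", "outlet"):
            raise ValueError(f"role must be inlet or outlet, got {self.role!r}")


@dataclass
class FlowSolution:
    """Pressures, flows and derived wall quantities on a vessel graph.

    ``flow`` is signed relative to each edge's stored path orientation
    (positive = first node toward second node).  ``pressure`` is NaN on
    unperfused components.
    """

    pressure: dict[int, float]  # node id -> Pa
    flow: dict[int, float]  # edge id -> m^3/s, signed
    velocity: dict[int, float]  # edge id -> m/s, signed
    shear_rate: dict[int, float]  # edge id -> 1/s
    wss: dict[int, float]  # edge id -> Pa
    viscosity: dict[int, float]  # edge id -> Pa*s
    unperfused_edges: list[int] = field(default_factory=list)
    iterations: int = 0
    residual: float = 0.0


def _components_with_bcs(net: VesselNetwork, bcs: list[BoundaryCondition]):
    bc_nodes = {bc.node for bc in bcs}
    comps = net.connected_components()
    out = []
    for comp in comps:
        out.append((comp, sorted(bc_nodes & comp)))
    return out


def solve_flow(
    net: VesselNetwork,
    bcs: list[BoundaryCondition],
    rheology: RheologyModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    relaxation: float = 0.5,
) -> FlowSolution:
    """Solve the Poiseuille network under pressure boundary conditions.

    Raises on invalid BCs; components carrying no boundary node are left
    unperfused (zero flow, NaN pressure) with a warning.  The outer
    fixed-point loop over effective viscosity converges when the maximum
    relative change in edge flow drops below ``tol``.
    """
    if rheology is None:
        rheology = RheologyModel()
    for bc in bcs:
        if bc.node not in net.nodes:
            raise ValueError(f"boundary node {bc.node} not in network")
        if net.degree(bc.node) != 1:
            raise ValueError(f"boundary node {bc.node} must have degree 1")
    for e in net.edges.values():
        if not (e.radius_um > 0 and e.length_um > 0):
            raise ValueError(f"edge {e.id} has non-positive radius or length")

    bc_pressure = {bc.node: bc.pressure for bc in bcs}
    eids = sorted(net.edges)
    e_index = {eid: i for i, eid in enumerate(eids)}
    r = np.array([net.edges[eid].radius_um * UM for eid in eids])
    L = np.array([net.edges[eid].length_um * UM for eid in eids])

    # classify components
    perfused_nodes: set[int] = set()
    unperfused_edges: list[int] = []
    for comp, comp_bcs in _components_with_bcs(net, bcs):
        if len(comp_bcs) == 0:
            edge_ids = {
                eid
                for n in comp
                for eid in net.incident_edges(n)
            }
            if edge_ids:
                warnings.warn(
                    f"component with {len(comp)} nodes has no boundary condition; "
                    "left unperfused",
                    stacklevel=2,
                )
            unperfused_edges.extend(edge_ids)
        else:
            roles = {bc.role for bc in bcs if bc.node in comp}
            if not {"inlet", "outlet"} <= roles and len(comp_bcs) < 2:
                warnings.warn(
                    "component has a single boundary node; flow will be zero there",
                    stacklevel=2,
                )
            perfused_nodes |= comp
    unperfused_edges = sorted(set(unperfused_edges))

    solve_nodes = sorted(perfused_nodes)
    n_idx = {nid: i for i, nid in enumerate(solve_nodes)}
    free = [nid for nid in solve_nodes if nid not in bc_pressure]
    free_idx = {nid: i for i, nid in enumerate(free)}

    # edges participating in the solve (perfused, non-self-loop)
    active = [
        eid
        for eid in eids
        if net.edges[eid].u in perfused_nodes and not net.edges[eid].is_self_loop
    ]

    mu_eff = np.full(len(eids), rheology.zero_shear_viscosity)
    Q = np.zeros(len(eids))
    P = {nid: float("nan") for nid in net.nodes}
    for nid, p in bc_pressure.items():
        P[nid] = p

    converged = rheology.kind == "newtonian" and max_iter >= 1
    residual = np.inf
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        g = math.pi * r**4 / (8.0 * mu_eff * L)  # conductance, m^3/(s*Pa)

        # assemble Laplacian over free nodes
        rows, cols, vals = [], [], []
        b = np.zeros(len(free))
        for eid in active:
            e = net.edges[eid]
            ge = g[e_index[eid]]
            for a_node, b_node in ((e.u, e.v), (e.v, e.u)):
                if a_node in bc_pressure:
                    continue
                ia = free_idx[a_node]
                rows.append(ia)
                cols.append(ia)
                vals.append(ge)
                if b_node in bc_pressure:
                    b[ia] += ge * bc_pressure[b_node]
                else:
                    rows.append(ia)
                    cols.append(free_idx[b_node])
                    vals.append(-ge)
        if free:
            A = sp.csr_matrix((vals, (rows, cols)), shape=(len(free), len(free)))
            x = spla.spsolve(A.tocsc(), b)
            for nid, xi in zip(free, np.atleast_1d(x)):
                P[nid] = float(xi)

        Q_new = np.zeros(len(eids))
        for eid in active:
            e = net.edges[eid]
            Q_new[e_index[eid]] = g[e_index[eid]] * (P[e.u] - P[e.v])

        scale = np.abs(Q_new).max()
        if scale == 0.0:
            residual = 0.0
            Q = Q_new
            converged = True
            break
        denom = np.maximum(np.abs(Q_new), 1e-12 * scale)
        residual = float(np.abs(Q_new - Q).max() / scale) if it > 1 else np.inf
        rel = float((np.abs(Q_new - Q) / denom).max()) if it > 1 else np.inf
        Q = Q_new
        if rheology.kind == "newtonian":
            converged = True
            break
        if rel < tol:
            converged = True
            break
        gamma = 4.0 * np.abs(Q) / (math.pi * r**3)
        mu_new = effective_viscosity(gamma, rheology)
        mu_new[gamma == 0.0] = rheology.zero_shear_viscosity
        mu_eff = (1.0 - relaxation) * mu_eff + relaxation * mu_new

    if not converged:
        raise RuntimeError(
            f"viscosity fixed point did not converge in {max_iter} iterations "
            f"(last max relative flow change {residual:.3e})"
        )

    gamma = 4.0 * np.abs(Q) / (math.pi * r**3)
    tau = mu_eff * gamma
    vel = Q / (math.pi * r**2)
    flow, velocity, shear, wss, visc = {}, {}, {}, {}, {}
    for eid in eids:
        i = e_index[eid]
        if eid in unperfused_edges or net.edges[eid].is_self_loop:
            flow[eid] = velocity[eid] = shear[eid] = wss[eid] = 0.0
            visc[eid] = rheology.zero_shear_viscosity
        else:
            flow[eid] = float(Q[i])
            velocity[eid] = float(vel[i])
            shear[eid] = float(gamma[i])
            wss[eid] = float(tau[i])
            visc[eid] = float(mu_eff[i])
    return FlowSolution(
        pressure=P,
        flow=flow,
        velocity=velocity,
        shear_rate=shear,
        wss=wss,
        viscosity=visc,
        unperfused_edges=unperfused_edges,
        iterations=iterations,
        residual=0.0 if math.isinf(residual) else float(residual),
    )


@dataclass(frozen=True)
class WssSample:
    """One oriented WSS sample on a centerline: position (um), unit-tangent
    direction times magnitude (Pa), parent edge and arclength (um)."""

    edge: int
    x: float
    y: float
    tx: float
    ty: float
    tau: float
    arclength_um: float


def _polyline_resample(path_um: np.ndarray, arcs: np.ndarray):
    """Points and unit tangents at the given arclengths along a polyline."""
    seg = np.diff(path_um, axis=0)
    seglen = np.sqrt((seg**2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    pts = np.empty((len(arcs), 2))
    tans = np.empty((len(arcs), 2))
    if total == 0 or len(seg) == 0:
        pts[:] = path_um[0]
        tans[:] = (1.0, 0.0)
        return pts, tans
    idx = np.clip(np.searchsorted(cum, arcs, side="right") - 1, 0, len(seg) - 1)
    frac = (arcs - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    pts = path_um[idx] + seg[idx] * frac[:, None]
    with np.errstate(invalid="ignore"):
        tans = seg[idx] / seglen[idx][:, None]
    tans[~np.isfinite(tans)] = 0.0
    return pts, tans


def wss_vector_field(
    net: VesselNetwork,
    sol: FlowSolution,
    sample_spacing: float = 2.0,
) -> list[WssSample]:
    """Oriented WSS vectors sampled every ``sample_spacing`` um.

    Each edge contributes ``ceil(L / spacing)`` samples at equally spaced
    arclengths; the vector is the unit path tangent, flipped by the sign
    of the edge flow, scaled by the WSS magnitude.  Zero-flow edges yield
    zero vectors.
    """
    samples: list[WssSample] = []
    for eid in sorted(net.edges):
        e = net.edges[eid]
        n = max(1, math.ceil(e.length_um / sample_spacing))
        arcs = (np.arange(n) + 0.5) * e.length_um / n
        path_um = e.path * net.pixel_size
        pts, tans = _polyline_resample(path_um, arcs)
        q = sol.flow.get(eid, 0.0)
        tau = sol.wss.get(eid, 0.0)
        sgn = float(np.sign(q))
        for k in range(n):
            tx, ty = tans[k] * sgn * tau if sgn != 0.0 else (0.0, 0.0)
            samples.append(
                WssSample(
                    edge=eid,
                    x=float(pts[k, 0]),
                    y=float(pts[k, 1]),
                    tx=float(tx),
                    ty=float(ty),
                    tau=tau if sgn != 0.0 else 0.0,
                    arclength_um=float(arcs[k]),
                )
            )
    return samples


def wss_histogram(
    net: VesselNetwork,
    sol: FlowSolution,
    bins: int | np.ndarray = 16,
):
    """Length-weighted histogram of per-edge WSS magnitude, plus summary.

    Returns ``(bin_edges, counts, summary)`` where summary holds the
    min/median/max of tau for comparison against physiological ranges
    (arterioles roughly 6-14 Pa, capillaries ~1.2 Pa, venules 0.3-1 Pa).
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    eids = sorted(net.edges)
    tau = np.array([sol.wss[eid] for eid in eids])
    w = np.array([net.edges[eid].length_um for eid in eids])
    counts, edges = np.histogram(tau, bins=bins, weights=w)
    order = np.argsort(tau)
    csum = np.cumsum(w[order])
    med = float(tau[order][np.searchsorted(csum, csum[-1] / 2.0)])
    summary = {"min": float(tau.min()), "median": med, "max": float(tau.max())}
    return edges, counts, summary


def identify_unperfused(net: VesselNetwork, bcs: list[BoundaryCondition]) -> list[int]:
    """Edges that cannot carry steady flow under the given BCs.

    Includes every edge of a component holding fewer than two boundary
    nodes, and dead-end branches reached by iteratively stripping
    degree-1 non-boundary nodes (those terminate at a closed end).
    """
    bc_nodes = {bc.node for bc in bcs}
    dead: set[int] = set()
    for comp, comp_bcs in _components_with_bcs(net, bcs):
        if len(comp_bcs) < 2:
            for n in comp:
                dead.update(net.incident_edges(n))

    # iteratively strip dead-end branches
    alive_edges = {eid for eid in net.edges if eid not in dead}
    degree: dict[int, int] = {nid: 0 for nid in net.nodes}
    for eid in alive_edges:
        e = net.edges[eid]
        degree[e.u] += 1
        degree[e.v] += 1 if e.v != e.u else 1
    changed = True
    while changed:
        changed = False
        for eid in list(alive_edges):
            e = net.edges[eid]
            if e.is_self_loop:
                continue
            for nid in (e.u, e.v):
                if degree[nid] == 1 and nid not in bc_nodes:
                    alive_edges.discard(eid)
                    dead.add(eid)
                    degree[e.u] -= 1
                    degree[e.v] -= 1
                    changed = True
                    break
    # self-loops can never carry net flow
    dead.update(eid for eid, e in net.edges.items() if e.is_self_loop)
    return sorted(dead)
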