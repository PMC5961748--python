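"""File formats: masks, networks (GraphML + CSV), solutions, configs.

Networks round-trip through GraphML with node attributes x, y (px) and
edge attributes radius_um, length_um and the centerline path encoded as
a semicolon-separated point list.  Flat CSV node/edge tables are written
alongside for spreadsheet use.  Run configuration is TOML.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import imageio.v3 as iio
import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .flow import BoundaryCondition, FlowSolution, RheologyModel, WssSample
from .reconstruct import BinaryMask, VesselEdge, VesselNetwork, VesselNode

__all__ = [
    "read_mask",
    "write_mask",
    "write_network",
    "read_network",
    "write_solution",
    "write_wss_samples",
    "load_config",
    "rheology_from_config",
    "bcs_from_config",
]


def read_mask(path: str | Path, pixel_size: float) -> BinaryMask:
    """Read a single-channel TIFF or PNG; nonzero pixels are lumen."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # collapse RGB(A) to any-channel-nonzero
        img = img[..., :3].any(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {img.shape}")
    return BinaryMask(pixels=img != 0, pixel_size=pixel_size)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    path = Path(path)
    arr = mask.pixels.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def _encode_path(path: np.ndarray) -> str:
    return ";".join(f"{x:.3f},{y:.3f}" for x, y in path)


def _decode_path(s: str) -> np.ndarray:
    pts = [tuple(map(float, p.split(","))) for p in s.split(";") if p]
    return np.array(pts, dtype=float)


def write_network(net: VesselNetwork, prefix: str | Path) -> None:
    """Write ``<prefix>.graphml`` plus ``<prefix>_nodes.csv`` and
    ``<prefix>_edges.csv``."""
    prefix = Path(prefix)
    g = nx.MultiGraph(pixel_size=net.pixel_size)
    for nid, node in net.nodes.items():
        g.add_node(nid, x=node.x, y=node.y)
    for eid, e in net.edges.items():
        g.add_edge(
            e.u,
            e.v,
            key=eid,
            edge_id=eid,
            radius_um=e.radius_um,
            length_um=e.length_um,
            path=_encode_path(e.path),
        )
    nx.write_graphml(g, prefix.with_suffix(".graphml"))

    pd.DataFrame(
        {
            "node_id": list(net.nodes),
            "x_px": [n.x for n in net.nodes.values()],
            "y_px": [n.y for n in net.nodes.values()],
            "x_um": [n.x * net.pixel_size for n in net.nodes.values()],
            "y_um": [n.y * net.pixel_size for n in net.nodes.values()],
            "degree": [net.degree(nid) for nid in net.nodes],
        }
    ).to_csv(f"{prefix}_nodes.csv", index=False)
    pd.DataFrame(
        {
            "edge_id": list(net.edges),
            "node_u": [e.u for e in net.edges.values()],
            "node_v": [e.v for e in net.edges.values()],
            "radius_um": [e.radius_um for e in net.edges.values()],
            "length_um": [e.length_um for e in net.edges.values()],
        }
    ).to_csv(f"{prefix}_edges.csv", index=False)


def read_network(path: str | Path) -> VesselNetwork:
    """Read a network from a ``.graphml`` file written by write_network."""
    g = nx.read_graphml(path, force_multigraph=True)
    pixel_size = float(g.graph.get("pixel_size", 1.0))
    nodes = {
        int(nid): VesselNode(id=int(nid), x=float(d["x"]), y=float(d["y"]))
        for nid, d in g.nodes(data=True)
    }
    edges = {}
    for u, v, _key, d in g.edges(keys=True, data=True):
        eid = int(d["edge_id"])
        u, v = int(u), int(v)
        path = _decode_path(d["path"])
        # GraphML edges are unordered; restore the orientation implied by
        # the stored path (the flow sign convention depends on it)
        if u != v and len(path):
            du = np.hypot(path[0, 0] - nodes[u].x, path[0, 1] - nodes[u].y)
            dv = np.hypot(path[0, 0] - nodes[v].x, path[0, 1] - nodes[v].y)
            if dv < du:
                u, v = v, u
        edges[eid] = VesselEdge(
            id=eid,
            u=u,
            v=v,
            path=path,
            length_um=float(d["length_um"]),
            radius_um=float(d["radius_um"]),
        )
    return VesselNetwork(nodes=nodes, edges=edges, pixel_size=pixel_size)


def write_solution(net: VesselNetwork, sol: FlowSolution, prefix: str | Path) -> None:
    """Write per-node pressures and per-edge hemodynamics as CSV."""
    pd.DataFrame(
        {
            "node_id": list(net.nodes),
            "pressure_pa": [sol.pressure[nid] for nid in net.nodes],
        }
    ).to_csv(f"{prefix}_pressures.csv", index=False)
    eids = sorted(net.edges)
    pd.DataFrame(
        {
            "edge_id": eids,
            "flow_m3s": [sol.flow[e] for e in eids],
            "velocity_ms": [sol.velocity[e] for e in eids],
            "shear_rate_1s": [sol.shear_rate[e] for e in eids],
            "wss_pa": [sol.wss[e] for e in eids],
            "viscosity_pas": [sol.viscosity[e] for e in eids],
            "unperfused": [e in sol.unperfused_edges for e in eids],
        }
    ).to_csv(f"{prefix}_edges_flow.csv", index=False)


def write_wss_samples(samples: list[WssSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "edge_id": [s.edge for s in samples],
            "x_um": [s.x for s in samples],
            "y_um": [s.y for s in samples],
            "tx_pa": [s.tx for s in samples],
            "ty_pa": [s.ty for s in samples],
            "tau_pa": [s.tau for s in samples],
            "arclength_um": [s.arclength_um for s in samples],
        }
    ).to_csv(path, index=False)


def read_wss_samples(path: str | Path) -> list[WssSample]:
    df = pd.read_csv(path)
    return [
        WssSample(
            edge=int(r.edge_id),
            x=float(r.x_um),
            y=float(r.y_um),
            tx=float(r.tx_pa),
            ty=float(r.ty_pa),
            tau=float(r.tau_pa),
            arclength_um=float(r.arclength_um),
        )
        for r in df.itertuples(index=False)
    ]


DEFAULT_CONFIG = {
    "pixel_size_um": 1.0,
    "min_spur_factor": 2.0,
    "rheology": {
        # Carreau-Yasuda parameters are literature whole-blood values
        # shipped as editable defaults, not measurements from any single
        # retina data set.
        "kind": "carreau_yasuda",
        "mu0": 1.6e-2,
        "mu_inf": 3.5e-3,
        "lam": 8.2,
        "a": 0.64,
        "n": 0.2128,
        "mu": 3.5e-3,
    },
    "solver": {"tol": 1e-6, "max_iter": 100, "relaxation": 0.5},
    "analysis": {
        "tolerance_deg": 45.0,
        "threshold_frac": 0.60,
        "n_bins": 8,
        "polar_bins": 24,
        "max_distance_um": 25.0,
        "sample_spacing_um": 2.0,
        "seed": 0,
    },
    "boundary_conditions": [],
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None) -> dict:
    """TOML run config merged over the defaults."""
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    return _deep_update(DEFAULT_CONFIG, user)


def rheology_from_config(cfg: dict) -> RheologyModel:
    r = cfg.get("rheology", {})
    kind = r.get("kind", "carreau_yasuda")
    if kind == "newtonian":
        return RheologyModel(kind="newtonian", mu=float(r.get("mu", 3.5e-3)))
    return RheologyModel(
        kind="carreau_yasuda",
        mu0=float(r.get("mu0", 1.6e-2)),
        mu_inf=float(r.get("mu_inf", 3.5e-3)),
        lam=float(r.get("lam", 8.2)),
        a=float(r.get("a", 0.64)),
        n=float(r.get("n", 0.2128)),
    )


def bcs_from_config(cfg: dict) -> list[BoundaryCondition]:
    return [
        BoundaryCondition(
            node=int(b["node"]), pressure=float(b["pressure"]), role=b.get("role", "inlet")
        )
        for b in cfg.get("boundary_conditions", [])
    ]


def read_region_polygons(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Region polygons from a CSV with columns label, x, y (um),
    vertices in order, one polygon per label."""
    df = pd.read_csv(path)
    for col in ("label", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in regions file")
    out = []
    for label, grp in df.groupby("label", sort=False):
        out.append((str(label), grp[["x", "y"]].to_numpy(dtype=float)))
    return out
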