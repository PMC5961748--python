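"""Synthetic inputs: tube/crossing/plexus masks and cell populations.

Everything the pipeline consumes can be generated here, so tests and
demos never need external data.  Masks are ideal (no noise, no PSF) by
design.  The plexus fixture follows the vein-artery-vein layout: a wide
central artery feeding a staggered capillary lattice drained by two
lateral veins, with all junctions three-way by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import BoundaryCondition, FlowSolution, wss_vector_field
from .polarity import CellRecord
from .reconstruct import BinaryMask, VesselNetwork

__all__ = [
    "PlexusSpec",
    "PolarityGroundTruth",
    "make_tube_mask",
    "make_crossing_mask",
    "make_vav_plexus",
    "locate_vav_boundary_nodes",
    "sample_cells",
    "sample_pairs_linear_response",
    "cells_to_frame",
]


def _blank(shape: tuple[int, int]) -> np.ndarray:
    return np.zeros(shape, dtype=bool)


def make_tube_mask(
    width_px: int,
    length_px: int,
    orientation: str = "horizontal",
    pixel_size: float = 1.0,
    margin: int | None = None,
) -> BinaryMask:
    """A straight tube of exact odd width, with a background margin.

    ``orientation`` is 'horizontal', 'vertical' or 'diagonal' (45 deg,
    width within +/- 1 px measured perpendicular to the axis).
    """
    if width_px < 3 or width_px % 2 == 0:
        raise ValueError("width must be odd and >= 3 (centerline ambiguity otherwise)")
    m = margin if margin is not None else max(4, width_px)
    if orientation == "horizontal":
        img = _blank((width_px + 2 * m, length_px + 2 * m))
        img[m : m + width_px, m : m + length_px] = True
    elif orientation == "vertical":
        img = _blank((length_px + 2 * m, width_px + 2 * m))
        img[m : m + length_px, m : m + width_px] = True
    elif orientation == "diagonal":
        # band |y - x - c| <= k has perpendicular width (2k + 1) / sqrt(2)
        k = max(1, round((width_px * math.sqrt(2.0) - 1.0) / 2.0))
        ext = int(math.ceil(length_px / math.sqrt(2.0))) + 2 * k
        size = ext + 2 * m
        img = _blank((size, size))
        yy, xx = np.mgrid[0:size, 0:size]
        c = 0
        along = (xx + yy - size) / 2.0
        half_len = length_px / (2.0 * math.sqrt(2.0))
        img[(np.abs(yy - xx - c) <= k) & (np.abs(along) <= half_len)] = True
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return BinaryMask(pixels=img, pixel_size=pixel_size)


_CROSSING_PRESETS = {
    "small": (5, 61),
    "medium": (9, 121),
    "large": (15, 201),
}


def make_crossing_mask(preset: str = "medium", pixel_size: float = 1.0) -> BinaryMask:
    """Two perpendicular tubes crossing at the center.

    Mimics two vessels passing at different depths that appear connected
    in a z-projection; guaranteed to trigger the degree-4 overlap
    diagnostic.
    """
    if preset not in _CROSSING_PRESETS:
        raise ValueError(f"preset must be one of {sorted(_CROSSING_PRESETS)}")
    w, ln = _CROSSING_PRESETS[preset]
    m = max(4, w)
    size = ln + 2 * m
    img = _blank((size, size))
    c = size // 2
    h = w // 2
    img[c - h : c + h + 1, m : m + ln] = True
    img[m : m + ln, c - h : c + h + 1] = True
    return BinaryMask(pixels=img, pixel_size=pixel_size)


@dataclass(frozen=True)
class PlexusSpec:
    """Geometry of the synthetic vein-artery-vein plexus (pixels)."""

    width: int = 420
    height: int = 580
    pixel_size: float = 1.0
    artery_x: int = 210
    vein_x: tuple[int, int] = (30, 390)
    artery_width: int = 9
    vein_width: int = 9
    capillary_width: int = 5
    row_spacing: int = 36
    top_margin: int = 14
    n_rows: int = 14  # capillary rows per side

    def __post_init__(self) -> None:
        for w in (self.artery_width, self.vein_width, self.capillary_width):
            if w < 3 or w % 2 == 0:
                raise ValueError("vessel widths must be odd and >= 3")
        if self.artery_width <= self.capillary_width:
            raise ValueError("artery must be wider than capillaries")
        if self.row_spacing < 3 * self.artery_width:
            raise ValueError("row spacing too small for vessel width")


def _stamp_h(img: np.ndarray, y: int, x0: int, x1: int, w: int) -> None:
    h = w // 2
    img[y - h : y + h + 1, min(x0, x1) : max(x0, x1) + 1] = True


def _stamp_v(img: np.ndarray, x: int, y0: int, y1: int, w: int) -> None:
    h = w // 2
    img[min(y0, y1) : max(y0, y1) + 1, x - h : x + h + 1] = True


def make_vav_plexus(
    spec: PlexusSpec | None = None,
    pressure_in: float = 100.0,
    pressure_out: float = 0.0,
) -> tuple[BinaryMask, dict]:
    """Vein-artery-vein plexus mask plus suggested boundary conditions.

    Returns ``(mask, bc_spec)`` where ``bc_spec`` maps terminal locations
    (x, y in px) to pressures/roles; resolve them to node ids on the
    reconstructed graph with :func:`locate_vav_boundary_nodes`.

    Left- and right-half capillary rows attach to the artery at staggered
    heights, and inter-row connectors alternate x positions, so every
    junction is three-way.
    """
    sp = spec or PlexusSpec()
    img = _blank((sp.height, sp.width))
    xa = sp.artery_x
    xl, xr = sp.vein_x
    y0 = sp.top_margin
    s = sp.row_spacing

    left_rows = [y0 + s * (m + 1) for m in range(sp.n_rows)]
    right_rows = [y0 + s * (m + 1) + s // 2 for m in range(sp.n_rows)]
    y_bot = max(left_rows[-1], right_rows[-1])
    if y_bot + sp.capillary_width >= sp.height:
        raise ValueError("plexus rows exceed image height; enlarge the image")

    # trunks
    _stamp_v(img, xa, y0, y_bot, sp.artery_width)
    _stamp_v(img, xl, y0, left_rows[-1], sp.vein_width)
    _stamp_v(img, xr, y0, right_rows[-1], sp.vein_width)

    # capillary rows
    for y in left_rows:
        _stamp_h(img, y, xl, xa, sp.capillary_width)
    for y in right_rows:
        _stamp_h(img, y, xa, xr, sp.capillary_width)

    # staggered connectors between consecutive rows (three-way junctions:
    # consecutive gaps never reuse an x position)
    def connector_xs(x_lo: int, x_hi: int, gap_index: int) -> list[int]:
        span = x_hi - x_lo
        if gap_index % 2 == 0:
            return [x_lo + span // 3, x_lo + 2 * span // 3]
        return [x_lo + span // 2]

    for rows, x_lo, x_hi in (
        (left_rows, xl, xa),
        (right_rows, xa, xr),
    ):
        inset = 2 * sp.capillary_width
        for m in range(len(rows) - 1):
            for xc in connector_xs(x_lo + inset, x_hi - inset, m):
                _stamp_v(img, xc, rows[m], rows[m + 1], sp.capillary_width)

    mask = BinaryMask(pixels=img, pixel_size=sp.pixel_size)
    bc_spec = {
        "inlet": {"x": xa, "y": y0, "pressure": pressure_in},
        "outlet_left": {"x": xl, "y": y0, "pressure": pressure_out},
        "outlet_right": {"x": xr, "y": y0, "pressure": pressure_out},
    }
    return mask, bc_spec


def locate_vav_boundary_nodes(
    net: VesselNetwork, bc_spec: dict, max_px: float = 30.0
) -> list[BoundaryCondition]:
    """Resolve the plexus BC spec to degree-1 nodes of the built graph."""
    terminals = [nid for nid in net.nodes if net.degree(nid) == 1]
    if not terminals:
        raise ValueError("network has no terminal nodes for boundary conditions")
    bcs = []
    used: set[int] = set()
    for name, d in bc_spec.items():
        best, best_d = None, np.inf
        for nid in terminals:
            if nid in used:
                continue
            node = net.nodes[nid]
            dist = math.hypot(node.x - d["x"], node.y - d["y"])
            if dist < best_d:
                best, best_d = nid, dist
        if best is None or best_d > max_px:
            raise ValueError(f"no terminal node near {name} at ({d['x']}, {d['y']})")
        used.add(best)
        role = "inlet" if name.startswith("inlet") else "outlet"
        bcs.append(BoundaryCondition(node=best, pressure=d["pressure"], role=role))
    return bcs


# ---------------------------------------------------------------------------
# synthetic cells


@dataclass(frozen=True)
class PolarityGroundTruth:
    """True relative angles and response parameters behind a cell sample."""

    theta_deg: np.ndarray
    tau: np.ndarray
    kappa: np.ndarray
    kappa_max: float
    tau_half: float
    p_mag_um: float
    seed: int


def sample_cells(
    network: VesselNetwork,
    solution: FlowSolution,
    n: int,
    kappa_max: float = 4.0,
    tau_half: float = 1.0,
    p_mag_um: float = 5.0,
    seed: int = 0,
    sample_spacing: float = 2.0,
) -> tuple[list[CellRecord], PolarityGroundTruth]:
    """Place cells on perfused centerlines with flow-coupled polarity.

    Each cell's relative angle is drawn from a von Mises distribution
    with mean 180 deg (against flow) and concentration
    ``kappa = kappa_max * tau / (tau_half + tau)`` — a saturating
    response, so low- and high-WSS regimes are both exercised.  The
    Golgi point is the nucleus plus ``p_mag_um`` times the local flow
    direction rotated by the drawn angle.  Deterministic under ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    samples = [s for s in wss_vector_field(network, solution, sample_spacing) if s.tau > 0]
    if not samples:
        raise ValueError("no perfused centerline samples to place cells on")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(samples), size=n)
    tau = np.array([samples[i].tau for i in picks])
    kappa = kappa_max * tau / (tau_half + tau)
    theta = np.array([
        rng.vonmises(math.pi, k) if k > 0 else rng.uniform(-math.pi, math.pi)
        for k in kappa
    ])
    cells = []
    for j, (i, th) in enumerate(zip(picks, theta)):
        s = samples[i]
        t = np.array([s.tx, s.ty])
        t_hat = t / np.hypot(*t)
        ct, st = math.cos(th), math.sin(th)
        direction = np.array([ct * t_hat[0] - st * t_hat[1], st * t_hat[0] + ct * t_hat[1]])
        nucleus = (s.x, s.y)
        golgi = (s.x + p_mag_um * direction[0], s.y + p_mag_um * direction[1])
        cells.append(CellRecord(cell_id=j, nucleus=nucleus, golgi=golgi))
    truth = PolarityGroundTruth(
        theta_deg=np.degrees(theta),
        tau=tau,
        kappa=kappa,
        kappa_max=kappa_max,
        tau_half=tau_half,
        p_mag_um=p_mag_um,
        seed=seed,
    )
    return cells, truth


def sample_pairs_linear_response(
    n: int,
    seed: int = 0,
    base: float = 0.2,
    gain: float = 0.2,
    tau_max: float = 3.0,
    tolerance_deg: float = 45.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(tau, theta) pairs with P(against | tau) = base + gain * tau.

    tau is uniform on [0, tau_max]; against-flow cells get an angle
    uniform in the 180 +/- tolerance window, others uniform outside it.
    With the defaults the against-flow fraction crosses 0.60 at
    tau = 2.0 Pa.
    """
    rng = np.random.default_rng(seed)
    tau = rng.uniform(0.0, tau_max, size=n)
    p_against = np.clip(base + gain * tau, 0.0, 1.0)
    hit = rng.random(n) < p_against
    lo = 180.0 - tolerance_deg
    theta = np.empty(n)
    n_hit = int(hit.sum())
    mag = rng.uniform(lo, 180.0, size=n_hit)
    sign = np.where(rng.random(n_hit) < 0.5, -1.0, 1.0)
    theta[hit] = mag * sign
    theta[~hit] = rng.uniform(-lo, lo, size=n - n_hit)
    return tau, theta


def cells_to_frame(cells: list[CellRecord], pixel_size: float = 1.0) -> pd.DataFrame:
    """Cell records as the pixel-coordinate CSV table the pipeline reads."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "nucleus_x": [c.nucleus[0] / pixel_size for c in cells],
            "nucleus_y": [c.nucleus[1] / pixel_size for c in cells],
            "golgi_x": [c.golgi[0] / pixel_size for c in cells],
            "golgi_y": [c.golgi[1] / pixel_size for c in cells],
        }
    )
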