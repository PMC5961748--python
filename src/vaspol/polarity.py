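"""Cell polarity vectors and their pairing with local flow.

A cell's polarity vector p runs from the nucleus center to the Golgi
center.  Each cell is matched to the nearest wall-shear-stress sample on
a perfused centerline, giving a signed relative angle theta (degrees,
measured from the WSS vector t to p, counterclockwise positive in image
coordinates) and the scalar product s = p . t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .flow import FlowSolution, WssSample, wss_vector_field
from .reconstruct import VesselNetwork

__all__ = [
    "CellRecord",
    "CellFlowPair",
    "load_cell_points",
    "map_cell_to_flow",
    "map_cells_to_flow",
    "relative_angle",
    "assign_regions",
    "pairs_to_frame",
]


@dataclass
class CellRecord:
    """One endothelial cell: nucleus and Golgi points in micrometres."""

    cell_id: int
    nucleus: tuple[float, float]  # um
    golgi: tuple[float, float]  # um
    region: str = "unassigned"

    @property
    def polarity(self) -> np.ndarray:
        """p = golgi - nucleus (um)."""
        return np.array(
            [self.golgi[0] - self.nucleus[0], self.golgi[1] - self.nucleus[1]]
        )

    @property
    def polarity_magnitude(self) -> float:
        return float(np.hypot(*self.polarity))

    @property
    def degenerate(self) -> bool:
        """Nucleus and Golgi coincide; excluded from angle analyses."""
        return self.polarity_magnitude == 0.0


@dataclass
class CellFlowPair:
    """A cell joined to its local WSS vector.

    ``theta_deg`` is the signed angle from t to p in (-180, 180];
    ``s`` = p . t (Pa*um).  Unmatched pairs carry ``matched=False`` and
    NaN kinematics.
    """

    cell_id: int
    matched: bool
    edge: int = -1
    arclength_um: float = float("nan")
    t: tuple[float, float] = (float("nan"), float("nan"))
    t_mag: float = float("nan")
    theta_deg: float = float("nan")
    s: float = float("nan")
    distance_um: float = float("nan")
    region: str = "unassigned"
    p: tuple[float, float] = (float("nan"), float("nan"))
    p_mag: float = float("nan")


REQUIRED_COLUMNS = ("cell_id", "nucleus_x", "nucleus_y", "golgi_x", "golgi_y")


def load_cell_points(table: pd.DataFrame | str, pixel_size: float = 1.0) -> list[CellRecord]:
    """Read nucleus/Golgi point pairs (pixel coordinates) into cell records.

    ``table`` may be a DataFrame or a CSV path with columns
    cell_id, nucleus_x, nucleus_y, golgi_x, golgi_y.  Coordinates are
    converted to micrometres with ``pixel_size``.  Cells with coincident
    nucleus and Golgi are kept but flagged degenerate (and warned about).
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    df = pd.read_csv(table) if isinstance(table, str) else table
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in cell table")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell_id values: {dups}")
    cells = []
    n_degenerate = 0
    for row in df.itertuples(index=False):
        rec = CellRecord(
            cell_id=int(row.cell_id),
            nucleus=(float(row.nucleus_x) * pixel_size, float(row.nucleus_y) * pixel_size),
            golgi=(float(row.golgi_x) * pixel_size, float(row.golgi_y) * pixel_size),
        )
        if rec.degenerate:
            n_degenerate += 1
        cells.append(rec)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} cell(s) have coincident nucleus and Golgi; "
            "flagged and excluded from angle analyses",
            stacklevel=2,
        )
    return cells


def relative_angle(p, t) -> float:
    """Signed angle (degrees) from t to p, counterclockwise positive.

    Result lies in (-180, 180]; exactly antiparallel vectors give +180.
    """
    px, py = float(p[0]), float(p[1])
    tx, ty = float(t[0]), float(t[1])
    if px == 0.0 and py == 0.0:
        raise ValueError("zero-length polarity vector")
    if tx == 0.0 and ty == 0.0:
        raise ValueError("zero-length flow vector")
    cross = tx * py - ty * px
    dot = tx * px + ty * py
    ang = math.degrees(math.atan2(cross, dot))
    return 180.0 if ang == -180.0 else ang


def map_cell_to_flow(
    cell: CellRecord,
    samples: list[WssSample],
    tree: cKDTree | None = None,
    max_distance: float = 25.0,
) -> CellFlowPair:
    """Match one cell to the nearest perfused centerline WSS sample.

    Samples with zero magnitude (unperfused) are not candidates.  Cells
    farther than ``max_distance`` (um) from any candidate, or degenerate
    cells, come back unmatched rather than raising.  Ties in distance are
    broken by the lower edge id, then lower arclength.
    """
    cand = [s for s in samples if s.tau > 0.0]
    if cell.degenerate or not cand:
        return CellFlowPair(cell_id=cell.cell_id, matched=False, region=cell.region)
    pts = np.array([(s.x, s.y) for s in cand])
    if tree is None:
        tree = cKDTree(pts)
    d, idx = tree.query(cell.nucleus, k=min(8, len(cand)))
    d = np.atleast_1d(d)
    idx = np.atleast_1d(idx)
    best = None
    best_key = None
    for dist, i in zip(d, idx):
        if not np.isfinite(dist):
            continue
        s = cand[int(i)]
        key = (round(float(dist), 9), s.edge, s.arclength_um)
        if best_key is None or key < best_key:
            best, best_key = s, key
    if best is None or best_key[0] > max_distance:
        return CellFlowPair(cell_id=cell.cell_id, matched=False, region=cell.region)
    p = cell.polarity
    t = np.array([best.tx, best.ty])
    theta = relative_angle(p, t)
    return CellFlowPair(
        cell_id=cell.cell_id,
        matched=True,
        edge=best.edge,
        arclength_um=best.arclength_um,
        t=(best.tx, best.ty),
        t_mag=best.tau,
        theta_deg=theta,
        s=float(p @ t),
        distance_um=float(best_key[0]),
        region=cell.region,
        p=(float(p[0]), float(p[1])),
        p_mag=cell.polarity_magnitude,
    )


def map_cells_to_flow(
    cells: list[CellRecord],
    network: VesselNetwork,
    solution: FlowSolution,
    max_distance: float = 25.0,
    sample_spacing: float = 2.0,
    samples: list[WssSample] | None = None,
) -> list[CellFlowPair]:
    """Vector-match all cells against the solution's WSS sample field."""
    if samples is None:
        samples = wss_vector_field(network, solution, sample_spacing)
    cand = [s for s in samples if s.tau > 0.0]
    tree = cKDTree(np.array([(s.x, s.y) for s in cand])) if cand else None
    return [
        map_cell_to_flow(c, samples, tree=None if tree is None else tree,
                         max_distance=max_distance)
        for c in cells
    ]


def assign_regions(
    cells: list[CellRecord],
    polygons: list[tuple[str, np.ndarray]],
) -> list[CellRecord]:
    """Label each cell by the polygon containing its nucleus (in place).

    ``polygons`` is a list of (label, (n, 2) vertex array in um).  The
    boundary counts as inside; when polygons overlap, the first label in
    input order wins (with a warning).  Cells in no polygon are labeled
    "unassigned".  Self-intersecting polygons raise.
    """
    shapes = []
    for label, verts in polygons:
        poly = Polygon(np.asarray(verts, dtype=float))
        if not poly.is_valid:
            raise ValueError(f"polygon {label!r} is self-intersecting or invalid")
        shapes.append((label, poly))
    warned = False
    for cell in cells:
        pt = Point(cell.nucleus)
        hits = [label for label, poly in shapes if poly.covers(pt)]
        if len(hits) > 1 and not warned:
            warnings.warn(
                f"overlapping region polygons ({hits}); first label wins",
                stacklevel=2,
            )
            warned = True
        cell.region = hits[0] if hits else "unassigned"
    return cells


def pairs_to_frame(pairs: list[CellFlowPair]) -> pd.DataFrame:
    """Flatten pairs into the cells-with-flow table used downstream."""
    return pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in pairs],
            "matched": [p.matched for p in pairs],
            "region": [p.region for p in pairs],
            "edge": [p.edge for p in pairs],
            "px": [p.p[0] for p in pairs],
            "py": [p.p[1] for p in pairs],
            "p_mag_um": [p.p_mag for p in pairs],
            "tx": [p.t[0] for p in pairs],
            "ty": [p.t[1] for p in pairs],
            "t_mag_pa": [p.t_mag for p in pairs],
            "theta_deg": [p.theta_deg for p in pairs],
            "s": [p.s for p in pairs],
            "distance_um": [p.distance_um for p in pairs],
        }
    )
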