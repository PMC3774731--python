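"""Polygonal cell-sheet data structures and hexagonal lattice construction.

The epithelium is represented as a planar tiling: an array of vertex
positions, a boolean ``fixed`` flag per vertex (sheet-boundary vertices are
immobile), and a list of cells, each an ordered counter-clockwise ring of
vertex ids carrying a (row, col) lattice index and a ``margin`` flag for the
non-contractile anterior/posterior border cells.

Coordinate convention: x is the antero-posterior (AP) axis (columns), y is
the latero-ventral (LV) axis (rows).  By default hexagons are oriented
with two edges perpendicular to the AP axis, so each cell contributes two
steep ("vertical"-class) edges and four shallow ("transverse"-class)
edges, and all cells of one row sit at the same y level; the 90-degree
rotated lattice is available as ``orientation="ap_edges"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Cell",
    "EdgeRecord",
    "Sheet",
    "Topology",
    "build_hex_sheet",
    "build_hex_rosette",
    "polygon_area",
    "polygon_centroid",
    "polygon_second_moments",
    "edge_orientation_class",
    "validate_topology",
    "HEX_AREA_FACTOR",
]

#: area of a regular hexagon of unit side length
HEX_AREA_FACTOR = 3.0 * np.sqrt(3.0) / 2.0


@dataclass
class Cell:
    """A single cell face: CCW vertex ring plus lattice metadata."""

    id: int
    ring: list[int]
    row: int
    col: int
    margin: bool = False


@dataclass(frozen=True)
class EdgeRecord:
    """An undirected cell boundary between two vertices."""

    id: int
    a: int
    b: int
    cells: tuple[int, ...]  # 1 (boundary) or 2 (interior) incident cell ids


@dataclass
class Topology:
    """Flattened index arrays derived from the cell rings.

    Rebuilt whenever the topology changes (T1 transitions); used for
    vectorized area/energy/force assembly.
    """

    ring_cell: np.ndarray  # cell index for each ring entry
    ring_v: np.ndarray  # vertex id of the entry
    ring_next: np.ndarray  # vertex id following in the CCW ring
    ring_prev: np.ndarray  # vertex id preceding in the CCW ring
    ring_pad: np.ndarray  # (n_cells, max_ring) vertex ids, padded by repetition
    edges: list[EdgeRecord]
    edge_a: np.ndarray
    edge_b: np.ndarray
    edge_margin: np.ndarray  # True if >=1 incident cell is a margin cell
    edge_interior: np.ndarray  # True if the edge has two incident cells


class Sheet:
    """Planar polygonal mesh of an epithelial sheet."""

    def __init__(
        self,
        positions: np.ndarray,
        fixed: np.ndarray,
        cells: list[Cell],
        n_rows: int,
        n_cols: int,
        edge_length: float = 1.0,
        orientation: str = "lv_edges",
    ):
        self.positions = np.asarray(positions, dtype=float)
        self.fixed = np.asarray(fixed, dtype=bool)
        self.cells = cells
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.edge_length = float(edge_length)
        self.orientation = orientation
        self._topology: Topology | None = None

    # ------------------------------------------------------------------
    # Derived structure
    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def row_pitch(self) -> float:
        """Center-to-center spacing of adjacent cell rows (length units)."""
        if self.orientation == "lv_edges":
            return 1.5 * self.edge_length
        return np.sqrt(3.0) * self.edge_length

    @property
    def midline_row(self) -> int:
        """0-based index of the central (ventral midline) cell row Z."""
        return (self.n_rows - 1) // 2

    def invalidate_topology(self) -> None:
        self._topology = None

    def topology(self) -> Topology:
        if self._topology is None:
            self._topology = self._build_topology()
        return self._topology

    def _build_topology(self) -> Topology:
        ring_cell, ring_v, ring_next, ring_prev = [], [], [], []
        edge_map: dict[tuple[int, int], list[int]] = {}
        for ci, cell in enumerate(self.cells):
            ring = cell.ring
            n = len(ring)
            for k in range(n):
                v = ring[k]
                ring_cell.append(ci)
                ring_v.append(v)
                ring_next.append(ring[(k + 1) % n])
                ring_prev.append(ring[(k - 1) % n])
                key = (v, ring[(k + 1) % n])
                key = key if key[0] < key[1] else (key[1], key[0])
                edge_map.setdefault(key, []).append(ci)
        edges = [
            EdgeRecord(i, a, b, tuple(cs))
            for i, ((a, b), cs) in enumerate(sorted(edge_map.items()))
        ]
        max_ring = max(len(c.ring) for c in self.cells)
        ring_pad = np.empty((len(self.cells), max_ring), dtype=np.intp)
        for ci, cell in enumerate(self.cells):
            n = len(cell.ring)
            ring_pad[ci, :n] = cell.ring
            ring_pad[ci, n:] = cell.ring[-1]  # repeat last vertex as padding
        edge_a = np.array([e.a for e in edges], dtype=np.intp)
        edge_b = np.array([e.b for e in edges], dtype=np.intp)
        edge_margin = np.array(
            [any(self.cells[c].margin for c in e.cells) for e in edges], dtype=bool
        )
        edge_interior = np.array([len(e.cells) == 2 for e in edges], dtype=bool)
        return Topology(
            ring_cell=np.array(ring_cell, dtype=np.intp),
            ring_v=np.array(ring_v, dtype=np.intp),
            ring_next=np.array(ring_next, dtype=np.intp),
            ring_prev=np.array(ring_prev, dtype=np.intp),
            ring_pad=ring_pad,
            edges=edges,
            edge_a=edge_a,
            edge_b=edge_b,
            edge_margin=edge_margin,
            edge_interior=edge_interior,
        )

    @property
    def edges(self) -> list[EdgeRecord]:
        return self.topology().edges

    # ------------------------------------------------------------------
    # Geometry
    # ------------------------------------------------------------------
    def cell_areas(self) -> np.ndarray:
        """Shoelace area of every cell (vectorized)."""
        top = self.topology()
        x, y = self.positions[:, 0], self.positions[:, 1]
        cross = x[top.ring_v] * y[top.ring_next] - x[top.ring_next] * y[top.ring_v]
        return 0.5 * np.bincount(top.ring_cell, weights=cross, minlength=self.n_cells)

    def cell_centroids(self) -> np.ndarray:
        top = self.topology()
        x, y = self.positions[:, 0], self.positions[:, 1]
        xv, yv = x[top.ring_v], y[top.ring_v]
        xn, yn = x[top.ring_next], y[top.ring_next]
        cross = xv * yn - xn * yv
        a = 0.5 * np.bincount(top.ring_cell, weights=cross, minlength=self.n_cells)
        cx = np.bincount(top.ring_cell, weights=(xv + xn) * cross, minlength=self.n_cells)
        cy = np.bincount(top.ring_cell, weights=(yv + yn) * cross, minlength=self.n_cells)
        return np.column_stack([cx, cy]) / (6.0 * a)[:, None]

    def cell_eccentricities(self) -> np.ndarray:
        """AP/LV extent ratio of the per-cell second-moment ellipse."""
        top = self.topology()
        x, y = self.positions[:, 0], self.positions[:, 1]
        xv, yv = x[top.ring_v], y[top.ring_v]
        xn, yn = x[top.ring_next], y[top.ring_next]
        cross = xv * yn - xn * yv
        a = 0.5 * np.bincount(top.ring_cell, weights=cross, minlength=self.n_cells)
        cx = np.bincount(top.ring_cell, weights=(xv + xn) * cross, minlength=self.n_cells) / (6 * a)
        cy = np.bincount(top.ring_cell, weights=(yv + yn) * cross, minlength=self.n_cells) / (6 * a)
        ixx = np.bincount(
            top.ring_cell, weights=(xv * xv + xv * xn + xn * xn) * cross, minlength=self.n_cells
        ) / 12.0
        iyy = np.bincount(
            top.ring_cell, weights=(yv * yv + yv * yn + yn * yn) * cross, minlength=self.n_cells
        ) / 12.0
        cov_xx = ixx / a - cx**2
        cov_yy = iyy / a - cy**2
        return np.sqrt(np.maximum(cov_xx, 0.0) / np.maximum(cov_yy, 1e-300))

    def row_of_cells(self) -> np.ndarray:
        return np.array([c.row for c in self.cells], dtype=int)

    def col_of_cells(self) -> np.ndarray:
        return np.array([c.col for c in self.cells], dtype=int)

    def margin_mask(self) -> np.ndarray:
        return np.array([c.margin for c in self.cells], dtype=bool)

    # ------------------------------------------------------------------
    # Copy / serialization
    # ------------------------------------------------------------------
    def copy(self) -> "Sheet":
        return Sheet(
            self.positions.copy(),
            self.fixed.copy(),
            [Cell(c.id, list(c.ring), c.row, c.col, c.margin) for c in self.cells],
            self.n_rows,
            self.n_cols,
            self.edge_length,
            self.orientation,
        )

    def to_dict(self) -> dict:
        """JSON-serializable description (documented mesh schema)."""
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "edge_length": self.edge_length,
            "orientation": self.orientation,
            "vertices": [
                {"id": i, "position": [float(p[0]), float(p[1])], "fixed": bool(f)}
                for i, (p, f) in enumerate(zip(self.positions, self.fixed))
            ],
            "cells": [
                {
                    "id": c.id,
                    "ring": list(map(int, c.ring)),
                    "row": c.row,
                    "col": c.col,
                    "margin": c.margin,
                }
                for c in self.cells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sheet":
        verts = sorted(d["vertices"], key=lambda v: v["id"])
        positions = np.array([v["position"] for v in verts], dtype=float)
        fixed = np.array([v["fixed"] for v in verts], dtype=bool)
        cells = [
            Cell(c["id"], list(c["ring"]), c["row"], c["col"], bool(c["margin"]))
            for c in d["cells"]
        ]
        return cls(
            positions,
            fixed,
            cells,
            d["n_rows"],
            d["n_cols"],
            d["edge_length"],
            d.get("orientation", "lv_edges"),
        )


# ----------------------------------------------------------------------
# Polygon primitives
# ----------------------------------------------------------------------
def polygon_area(ring: np.ndarray) -> float:
    """Shoelace area of a simple CCW polygon given as an (n, 2) array."""
    ring = np.asarray(ring, dtype=float)
    if ring.shape[0] < 3:
        raise ValueError("degenerate polygon: fewer than 3 vertices")
    x, y = ring[:, 0], ring[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_centroid(ring: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple polygon."""
    ring = np.asarray(ring, dtype=float)
    if ring.shape[0] < 3:
        raise ValueError("degenerate polygon: fewer than 3 vertices")
    x, y = ring[:, 0], ring[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-300:
        raise ValueError("degenerate polygon: zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_second_moments(ring: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and central second-moment (covariance) matrix.

    The covariance is the second area moment about the centroid divided by
    the area, i.e. the covariance of the uniform density on the polygon.
    The ring is shifted to its vertex mean before the moment integrals so
    the result is translation-invariant to machine precision.
    """
    ring = np.asarray(ring, dtype=float)
    if ring.shape[0] < 3:
        raise ValueError("degenerate polygon: fewer than 3 vertices")
    shift = ring.mean(axis=0)
    ring = ring - shift
    x, y = ring[:, 0], ring[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-300:
        raise ValueError("degenerate polygon: zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    ixx = np.sum((x * x + x * xn + xn * xn) * cross) / 12.0
    iyy = np.sum((y * y + y * yn + yn * yn) * cross) / 12.0
    ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    cov = np.array(
        [
            [ixx / a - cx * cx, ixy / a - cx * cy],
            [ixy / a - cx * cy, iyy / a - cy * cy],
        ]
    )
    return float(a), np.array([cx, cy]) + shift, cov


def edge_orientation_class(p_a: np.ndarray, p_b: np.ndarray) -> str:
    """Classify an edge as ``"transverse"`` or ``"vertical"``.

    Transverse boundaries make an acute angle of at most 45 degrees with
    the AP (x) axis; vertical boundaries more than 45 degrees.  Edges at
    exactly 45 degrees are classed transverse (deterministic tie-break).
    The class is a function of current geometry only.
    """
    d = np.asarray(p_b, dtype=float) - np.asarray(p_a, dtype=float)
    if np.hypot(d[0], d[1]) == 0.0:
        raise ValueError("zero-length edge has no orientation")
    return "transverse" if abs(d[1]) <= abs(d[0]) else "vertical"


# ----------------------------------------------------------------------
# Construction
# ----------------------------------------------------------------------
def _hex_corner_keys(i: int, j: int, orientation: str) -> list[tuple[int, int]]:
    """Integer lattice keys of the 6 corners of cell (row i, col j), CCW.

    Keys are exact integers (in half-width/half-height units), so shared
    corners of adjacent hexagons deduplicate without floating-point
    tolerance.

    ``orientation="lv_edges"`` (default lattice): each hexagon has two
    edges perpendicular to the AP (x) axis; cells of one row share a
    common y, rows are brick-offset along x.  Key units are
    (sqrt(3)/2 s, s/2).
    ``orientation="ap_edges"``: each hexagon has two edges perpendicular
    to the LV (y) axis; columns are brick-offset along y.  Key units are
    (s/2, sqrt(3)/2 s).
    """
    if orientation == "ap_edges":
        cxk = 3 * j  # center x = 1.5 s j
        cyk = 2 * i + (j % 2)  # center y = sqrt(3) s (i + (j%2)/2)
        return [
            (cxk + 2, cyk),
            (cxk + 1, cyk + 1),
            (cxk - 1, cyk + 1),
            (cxk - 2, cyk),
            (cxk - 1, cyk - 1),
            (cxk + 1, cyk - 1),
        ]
    if orientation == "lv_edges":
        cxk = 2 * j + (i % 2)  # center x = sqrt(3) s (j + (i%2)/2)
        cyk = 3 * i  # center y = 1.5 s i
        return [
            (cxk + 1, cyk + 1),
            (cxk, cyk + 2),
            (cxk - 1, cyk + 1),
            (cxk - 1, cyk - 1),
            (cxk, cyk - 2),
            (cxk + 1, cyk - 1),
        ]
    raise ValueError(f"unknown hexagon orientation {orientation!r}")


def build_hex_sheet(
    n_rows: int,
    n_cols: int,
    edge_length: float = 1.0,
    *,
    margin_mode: str = "columns",
    margin_width: int = 2,
    fix_boundary: bool = True,
    orientation: str = "lv_edges",
) -> Sheet:
    """Build a brick-offset packed sheet of regular hexagons.

    Parameters
    ----------
    n_rows, n_cols
        Lattice size; rows run along the LV (y) axis, columns along the
        AP (x) axis.  The standard ventral-epithelium sheet is 15 x 24.
    edge_length
        Hexagon side length s; every cell starts at the regular-hexagon
        area (3 sqrt(3)/2) s^2.
    margin_mode
        ``"columns"`` flags ``margin_width`` cell columns at the anterior
        and posterior (left/right) borders as non-contractile margin;
        ``"border"`` flags the full perimeter ring of cells (used by the
        square/rectangular geometry variants); ``"none"`` flags nothing.
    fix_boundary
        Flag perimeter vertices as fixed (the default); disable only for
        isolated-cell relaxation experiments.
    orientation
        ``"lv_edges"`` (default): each hexagon has two edges perpendicular
        to the AP axis and cells of a row share one y level; rows are
        brick-offset along x.  ``"ap_edges"``: the 90-degree-rotated
        lattice with two AP-parallel edges per cell.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError(f"sheet dimensions must be positive, got {n_rows}x{n_cols}")
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    s = float(edge_length)
    if orientation == "lv_edges":
        ux, uy = np.sqrt(3.0) / 2.0 * s, s / 2.0
    else:
        ux, uy = s / 2.0, np.sqrt(3.0) / 2.0 * s

    key_to_id: dict[tuple[int, int], int] = {}
    positions: list[tuple[float, float]] = []
    cells: list[Cell] = []
    for i in range(n_rows):
        for j in range(n_cols):
            ring = []
            for xk, yk in _hex_corner_keys(i, j, orientation):
                vid = key_to_id.get((xk, yk))
                if vid is None:
                    vid = len(positions)
                    key_to_id[(xk, yk)] = vid
                    positions.append((xk * ux, yk * uy))
                ring.append(vid)
            if margin_mode == "columns":
                margin = j < margin_width or j >= n_cols - margin_width
            elif margin_mode == "border":
                margin = (
                    i < margin_width
                    or i >= n_rows - margin_width
                    or j < margin_width
                    or j >= n_cols - margin_width
                )
            elif margin_mode == "none":
                margin = False
            else:
                raise ValueError(f"unknown margin_mode {margin_mode!r}")
            cells.append(Cell(len(cells), ring, i, j, margin))

    sheet = Sheet(
        np.array(positions, dtype=float),
        np.zeros(len(positions), dtype=bool),
        cells,
        n_rows,
        n_cols,
        s,
        orientation,
    )
    if fix_boundary:
        top = sheet.topology()
        for e in top.edges:
            if len(e.cells) == 1:
                sheet.fixed[e.a] = True
                sheet.fixed[e.b] = True
    return sheet


def build_hex_rosette(
    edge_length: float = 1.0, *, fix_boundary: bool = True, orientation: str = "lv_edges"
) -> Sheet:
    """Build the reduced 7-cell model: one central hexagon and its 6
    neighbours, outer boundary fixed.

    The central cell is cell 0 (row 0, col 0); neighbours carry row/col
    offsets identifying their position but no margin flag.
    """
    s = float(edge_length)
    if orientation == "lv_edges":
        ux, uy = np.sqrt(3.0) / 2.0 * s, s / 2.0
        centers = [(0, 0), (2, 0), (-2, 0), (1, 3), (-1, 3), (1, -3), (-1, -3)]
        corner_offsets = [(1, 1), (0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1)]
    else:
        ux, uy = s / 2.0, np.sqrt(3.0) / 2.0 * s
        centers = [(0, 0), (3, 1), (3, -1), (0, 2), (0, -2), (-3, 1), (-3, -1)]
        corner_offsets = [(2, 0), (1, 1), (-1, 1), (-2, 0), (-1, -1), (1, -1)]
    key_to_id: dict[tuple[int, int], int] = {}
    positions: list[tuple[float, float]] = []
    cells: list[Cell] = []
    for ci, (cxk, cyk) in enumerate(centers):
        ring = []
        for dx, dy in corner_offsets:
            k = (cxk + dx, cyk + dy)
            vid = key_to_id.get(k)
            if vid is None:
                vid = len(positions)
                key_to_id[k] = vid
                positions.append((k[0] * ux, k[1] * uy))
            ring.append(vid)
        cells.append(Cell(ci, ring, 0, ci, False))
    sheet = Sheet(
        np.array(positions, dtype=float),
        np.zeros(len(positions), dtype=bool),
        cells,
        1,
        7,
        s,
        orientation,
    )
    if fix_boundary:
        for e in sheet.topology().edges:
            if len(e.cells) == 1:
                sheet.fixed[e.a] = True
                sheet.fixed[e.b] = True
    return sheet


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------
def validate_topology(sheet: Sheet) -> list[str]:
    """Check all Sheet invariants; returns a list of violation messages.

    Checks: ring size and uniqueness, positive signed area, polygon
    simplicity, edge/cell incidence consistency, the planar Euler relation
    V - E + F = 1 (outer face excluded), and finiteness of positions.
    """
    violations: list[str] = []
    if not np.all(np.isfinite(sheet.positions)):
        violations.append("non-finite vertex positions")
        return violations

    from shapely.geometry import Polygon

    for cell in sheet.cells:
        if len(cell.ring) < 3:
            violations.append(f"cell {cell.id}: ring has fewer than 3 vertices")
            continue
        if len(set(cell.ring)) != len(cell.ring):
            violations.append(f"cell {cell.id}: repeated vertex in ring")
            continue
        pts = sheet.positions[cell.ring]
        area = polygon_area(pts)
        if area <= 0:
            violations.append(f"cell {cell.id}: non-positive signed area {area:.3g}")
        if not Polygon(pts).is_valid:
            violations.append(f"cell {cell.id}: self-intersecting ring")

    top = sheet.topology()
    for e in top.edges:
        if len(e.cells) not in (1, 2):
            violations.append(
                f"edge ({e.a},{e.b}): incident to {len(e.cells)} cells"
            )
    v_used = {v for c in sheet.cells for v in c.ring}
    V = len(v_used)
    E = len(top.edges)
    F = sheet.n_cells
    if V - E + F != 1:
        violations.append(f"Euler relation violated: V-E+F = {V}-{E}+{F} = {V - E + F}")
    return violations
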