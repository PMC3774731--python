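"""Potential energy of the cell sheet and analytic per-vertex forces.

The energy is the standard apical vertex-model form with an area-based
contractile term,

    E = sum_cells K/2 (A_i - A0)^2          (area elasticity)
      + sum_edges Lambda_e l_e              (line tension)
      + sum_cells Gamma_i/2 A_i^2           (contractility, preferred area 0),

with the line tension chosen per edge from its current orientation class
(transverse vs vertical) or set to the margin tension when the edge belongs
to a non-contractile margin cell.  Vertices move down the energy gradient
against friction, so the force on vertex v is -dE/dx_v, assembled
analytically from shoelace area derivatives and unit edge tangents.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh import HEX_AREA_FACTOR, Sheet

__all__ = ["MechanicalParams", "edge_tensions", "total_energy", "vertex_forces"]


@dataclass
class MechanicalParams:
    """Mechanical constants of the sheet.

    ``A0 = None`` means "the initial regular-hexagon area of the sheet",
    resolved against the sheet's edge length when forces or energies are
    evaluated.  ``edge_k``/``edge_l0`` enable an optional quadratic
    edge-elasticity term k/2 (l - l0)^2 per edge; it is off (k = 0) by
    default since the model is parameterized by pure tension.
    """

    K: float = 2.5
    A0: float | None = None
    lambda_transverse: float = 0.2
    lambda_vertical: float = 0.075
    lambda_margin: float = 6.0
    edge_k: float = 0.0
    edge_l0: float | None = None

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.A0 is not None and self.A0 <= 0:
            raise ValueError("A0 must be positive")
        for name in ("lambda_transverse", "lambda_vertical", "lambda_margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def resolved_A0(self, sheet: Sheet) -> float:
        if self.A0 is not None:
            return self.A0
        return HEX_AREA_FACTOR * sheet.edge_length**2

    def resolved_l0(self, sheet: Sheet) -> float:
        return self.edge_l0 if self.edge_l0 is not None else sheet.edge_length

    def with_tensions(self, lambda_t: float, lambda_v: float) -> "MechanicalParams":
        return replace(self, lambda_transverse=lambda_t, lambda_vertical=lambda_v)


def _check_gamma(sheet: Sheet, gamma: np.ndarray) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (sheet.n_cells,):
        raise ValueError(
            f"contractility must be defined for every cell: expected shape "
            f"({sheet.n_cells},), got {gamma.shape}"
        )
    if np.any(gamma < 0):
        raise ValueError("contractility must be non-negative for every cell")
    return gamma


def _edge_geometry(sheet: Sheet):
    top = sheet.topology()
    d = sheet.positions[top.edge_b] - sheet.positions[top.edge_a]
    length = np.hypot(d[:, 0], d[:, 1])
    if np.any(length == 0.0):
        idx = int(np.argmin(length))
        e = top.edges[idx]
        raise ValueError(f"zero-length edge between vertices {e.a} and {e.b}")
    return top, d, length


def edge_tensions(sheet: Sheet, params: MechanicalParams) -> np.ndarray:
    """Per-edge line tension from the current orientation class.

    Edges at most 45 degrees from the AP axis are transverse (|dy| <= |dx|,
    45-degree ties transverse); edges of margin cells always use the margin
    tension regardless of orientation.
    """
    top, d, length = _edge_geometry(sheet)
    transverse = np.abs(d[:, 1]) <= np.abs(d[:, 0])
    lam = np.where(transverse, params.lambda_transverse, params.lambda_vertical)
    lam = np.where(top.edge_margin, params.lambda_margin, lam)
    return lam


def total_energy(
    sheet: Sheet,
    params: MechanicalParams,
    gamma: np.ndarray,
    lam: np.ndarray | None = None,
) -> float:
    """Total potential energy E1 + E2 + E3.

    ``lam`` optionally freezes the per-edge tensions (e.g. to compare the
    energy before and after one step on the same tension branch, since the
    orientation class of a rotating edge can switch discontinuously).
    """
    gamma = _check_gamma(sheet, gamma)
    A0 = params.resolved_A0(sheet)
    areas = sheet.cell_areas()
    e1 = 0.5 * params.K * np.sum((areas - A0) ** 2)
    e3 = 0.5 * np.sum(gamma * areas**2)
    _, _, length = _edge_geometry(sheet)
    if lam is None:
        lam = edge_tensions(sheet, params)
    e2 = float(np.sum(lam * length))
    if params.edge_k > 0:
        e2 += 0.5 * params.edge_k * float(np.sum((length - params.resolved_l0(sheet)) ** 2))
    return float(e1 + e2 + e3)


def vertex_forces(sheet: Sheet, params: MechanicalParams, gamma: np.ndarray) -> np.ndarray:
    """Analytic -dE/dx_v for every vertex as an (n_vertices, 2) array.

    Forces on fixed vertices are reported (they are part of the gradient)
    but the integrator never applies them.
    """
    gamma = _check_gamma(sheet, gamma)
    A0 = params.resolved_A0(sheet)
    top, d, length = _edge_geometry(sheet)
    x, y = sheet.positions[:, 0], sheet.positions[:, 1]
    nv = sheet.n_vertices

    # area terms: dE/dA_i = K (A_i - A0) + Gamma_i A_i, shoelace derivative
    # dA/dx_v = (y_next - y_prev)/2, dA/dy_v = (x_prev - x_next)/2
    areas = sheet.cell_areas()
    coef = params.K * (areas - A0) + gamma * areas
    c_entry = coef[top.ring_cell]
    fx = np.bincount(
        top.ring_v, weights=-c_entry * 0.5 * (y[top.ring_next] - y[top.ring_prev]), minlength=nv
    )
    fy = np.bincount(
        top.ring_v, weights=-c_entry * 0.5 * (x[top.ring_prev] - x[top.ring_next]), minlength=nv
    )

    # tension terms: dl/dx_a = (x_a - x_b)/l, so f_a = -lambda (a - b)/l
    lam = edge_tensions(sheet, params)
    if params.edge_k > 0:
        lam = lam + params.edge_k * (length - params.resolved_l0(sheet))
    t = (lam / length)[:, None] * d  # lambda * unit tangent a->b
    fx += np.bincount(top.edge_a, weights=t[:, 0], minlength=nv)
    fy += np.bincount(top.edge_a, weights=t[:, 1], minlength=nv)
    fx += np.bincount(top.edge_b, weights=-t[:, 0], minlength=nv)
    fy += np.bincount(top.edge_b, weights=-t[:, 1], minlength=nv)

    forces = np.column_stack([fx, fy])
    if not np.all(np.isfinite(forces)):
        bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
        raise FloatingPointError(f"non-finite force on vertex {bad}")
    return forces
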