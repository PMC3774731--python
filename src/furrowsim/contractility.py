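"""Spatial and temporal contractility programs Gamma_i(t).

Contractility is the per-cell coefficient of the area-dependent contractile
energy term.  Every program composes a spatial weight in [0, 1] (a cutoff
band or a Gaussian gradient peaked at the ventral midline row Z) with a
shared temporal scalar (constant, a capped linear ramp, or the ramp plus an
independent Wiener path per cell).  Margin cells are always non-contractile.

Variants
--------
cutoff
    Gamma = gamma_cutoff inside the n_central_rows band, 0 outside;
    constant in time.
gradient_static
    Gamma = gamma_mid * exp(-(i - Z)^2 / (2 sigma^2)); constant in time.
cutoff_timed / gradient_timed
    The spatial profile multiplied by the capped ramp
    min(gamma_init + alpha_rate * t, gamma_max).
gradient_stochastic
    Per-cell scalar clamp(gamma_init + alpha_rate * t
    + sigma_wiener * W_i(t), 0, gamma_max) times the gradient weight,
    with W_i an independent standard Wiener path per cell.
gradient_alternative
    Like gradient_stochastic, but the Gaussian weight is recomputed every
    step from the cell centroid's current distance to the (fixed) midline
    y-coordinate instead of the static row index.
twi
    gradient_stochastic attenuated by a per-cell factor U(i, j) drawn once
    uniformly from [0, twi_umax], modelling the fragmentary apical myosin
    accumulation of twist mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import Sheet

__all__ = [
    "VARIANTS",
    "ContractilityProgram",
    "NoiseState",
    "sample_noise",
    "spatial_profile",
    "temporal_ramp",
    "gamma_field",
    "contractility_at",
    "alternative_gradient_weight",
]

VARIANTS = (
    "cutoff",
    "gradient_static",
    "cutoff_timed",
    "gradient_timed",
    "gradient_stochastic",
    "gradient_alternative",
    "twi",
)

#: variants whose per-cell Gamma includes a Wiener path
STOCHASTIC_VARIANTS = ("gradient_stochastic", "gradient_alternative", "twi")


@dataclass
class ContractilityProgram:
    variant: str = "gradient_stochastic"
    gamma_cutoff: float = 10.0
    gamma_mid: float = 15.0
    sigma_width: float = 2.0
    gamma_init: float = 0.0
    alpha_rate: float = 0.15
    gamma_max: float = 25.0
    sigma_wiener: float = 0.3
    n_central_rows: int = 5
    twi_umax: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown contractility variant {self.variant!r}")
        for name in (
            "gamma_cutoff",
            "gamma_mid",
            "gamma_init",
            "alpha_rate",
            "gamma_max",
            "sigma_wiener",
            "twi_umax",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma_width <= 0:
            raise ValueError("sigma_width must be positive")
        if self.n_central_rows < 1 or self.n_central_rows % 2 == 0:
            raise ValueError("n_central_rows must be a positive odd integer")


@dataclass
class NoiseState:
    """All randomness of a run: per-cell Wiener paths and twi attenuation.

    ``wiener[c, k]`` is W_c(k * dt) with W_c(0) = 0; increments over one
    step are independent N(0, dt) draws.  Each cell's stream is seeded from
    (master_seed, row, col) so that changing the sheet size does not
    reshuffle the paths of unrelated cells.  The state is sufficient to
    replicate a simulation bit-exactly.
    """

    master_seed: int
    dt: float
    increments: np.ndarray  # (n_cells, n_steps)
    attenuation: np.ndarray  # (n_cells,) twi factors U(i, j)
    wiener: np.ndarray = field(init=False)  # (n_cells, n_steps + 1)

    def __post_init__(self) -> None:
        n_cells, n_steps = self.increments.shape
        self.wiener = np.zeros((n_cells, n_steps + 1))
        np.cumsum(self.increments, axis=1, out=self.wiener[:, 1:])

    @property
    def n_steps(self) -> int:
        return self.increments.shape[1]


def sample_noise(
    master_seed: int,
    sheet: Sheet,
    n_steps: int,
    dt: float,
    *,
    twi_umax: float = 0.5,
) -> NoiseState:
    """Draw every cell's Wiener increments and twi attenuation factor.

    Deterministic in (master_seed, row, col), so a given cell's path is
    reproducible regardless of sheet size or cell ordering.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    n_cells = sheet.n_cells
    increments = np.empty((n_cells, n_steps))
    attenuation = np.empty(n_cells)
    sqrt_dt = np.sqrt(dt)
    for c, cell in enumerate(sheet.cells):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(master_seed), cell.row, cell.col])
        )
        increments[c] = rng.normal(0.0, sqrt_dt, n_steps)
        # separate stream so U(i, j) does not depend on the path length
        rng_u = np.random.default_rng(
            np.random.SeedSequence([int(master_seed), cell.row, cell.col, 1])
        )
        attenuation[c] = rng_u.uniform(0.0, twi_umax)
    return NoiseState(int(master_seed), float(dt), increments, attenuation)


def spatial_profile(program: ContractilityProgram, sheet: Sheet) -> np.ndarray:
    """Dimensionless per-cell weight in [0, 1]; 0 in margin cells.

    Cutoff variants: 1 inside the central band of n_central_rows rows.
    Gradient variants: exp(-(i - Z)^2 / (2 sigma^2)) in the row index i.
    """
    rows = sheet.row_of_cells()
    z = sheet.midline_row
    if program.variant in ("cutoff", "cutoff_timed"):
        half = (program.n_central_rows - 1) // 2
        w = (np.abs(rows - z) <= half).astype(float)
    else:
        w = np.exp(-((rows - z) ** 2) / (2.0 * program.sigma_width**2))
    w[sheet.margin_mask()] = 0.0
    return w


def temporal_ramp(program: ContractilityProgram, t: float) -> float:
    """Capped linear ramp min(gamma_init + alpha_rate * t, gamma_max)."""
    if t < 0:
        raise ValueError("model time must be non-negative")
    return float(min(program.gamma_init + program.alpha_rate * t, program.gamma_max))


def alternative_gradient_weight(
    program: ContractilityProgram,
    centroid_y: np.ndarray | float,
    y_mid: float,
    row_pitch: float,
) -> np.ndarray | float:
    """Gaussian weight in the current centroid distance to the midline.

    ``row_pitch`` converts sigma (given in cell-row units) to length
    units; use ``sheet.row_pitch`` (the centre-to-centre row spacing of
    the lattice).  The weight is recomputed every step, so a cell grows
    more contractile the closer it approaches the midline.
    """
    d = (np.asarray(centroid_y, dtype=float) - y_mid) / row_pitch
    return np.exp(-(d**2) / (2.0 * program.sigma_width**2))


def gamma_field(
    program: ContractilityProgram,
    sheet: Sheet,
    noise: NoiseState | None,
    step: int,
    dt: float,
    *,
    y_mid: float | None = None,
) -> np.ndarray:
    """Per-cell contractility at time t = step * dt (vectorized dispatch).

    The shared scalar process is clamped to [0, gamma_max] before spatial
    weighting (the cap is defined at the midline); clamping at zero keeps
    early negative noise excursions from turning contractility expansile.
    """
    t = step * dt
    if t < 0:
        raise ValueError("model time must be non-negative")
    variant = program.variant

    if variant == "gradient_alternative":
        if y_mid is None:
            raise ValueError("gradient_alternative requires y_mid")
        w = alternative_gradient_weight(
            program,
            sheet.cell_centroids()[:, 1],
            y_mid,
            sheet.row_pitch,
        )
        w = np.asarray(w, dtype=float)
        w[sheet.margin_mask()] = 0.0
    else:
        w = spatial_profile(program, sheet)

    if variant == "cutoff":
        gamma = program.gamma_cutoff * w
    elif variant == "gradient_static":
        gamma = program.gamma_mid * w
    elif variant in ("cutoff_timed", "gradient_timed"):
        gamma = temporal_ramp(program, t) * w
    elif variant in STOCHASTIC_VARIANTS:
        if noise is None:
            raise ValueError(f"variant {variant!r} requires a NoiseState")
        if abs(noise.dt - dt) > 1e-12:
            raise ValueError("NoiseState dt does not match integration dt")
        scalar = (
            program.gamma_init
            + program.alpha_rate * t
            + program.sigma_wiener * noise.wiener[:, step]
        )
        np.clip(scalar, 0.0, program.gamma_max, out=scalar)
        gamma = scalar * w
        if variant == "twi":
            gamma = gamma * noise.attenuation
    else:  # pragma: no cover - guarded by ContractilityProgram
        raise ValueError(f"unknown contractility variant {variant!r}")
    return gamma


def contractility_at(
    program: ContractilityProgram,
    noise: NoiseState | None,
    sheet: Sheet,
    cell_index: int,
    step: int,
    dt: float,
    *,
    y_mid: float | None = None,
) -> float:
    """Scalar Gamma_i(t) of one cell (thin wrapper over gamma_field)."""
    return float(gamma_field(program, sheet, noise, step, dt, y_mid=y_mid)[cell_index])
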