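# Model and methods

`furrowsim` simulates the first phase of *Drosophila* gastrulation — the
formation of a band of apically constricted cells along the ventral
midline — as a two-dimensional vertex model of the apical epithelial
surface. This note records the model, its parameters, the numerical
choices, and the limits of what the synthetic experiments can show.

## Energy function

The ventral epithelium is a tiling of polygonal cells whose vertices carry
the degrees of freedom. The potential energy is

```
E = Σ_cells K/2 (A_i − A0)²        area elasticity
  + Σ_edges Λ_e · l_e              line tension
  + Σ_cells Γ_i/2 · A_i²           contractility
```

* **Area elasticity** penalizes deviation of the apical area `A_i` from
  the preferred area `A0` (the initial regular-hexagon area). `K` and `A0`
  are identical for all cells.
* **Line tension** acts along cell–cell boundaries and is anisotropic:
  edges within 45° of the antero-posterior (AP) axis are *transverse*
  (`Λ_t = 0.2`), steeper edges are *vertical* (`Λ_v = 0.075`), reflecting
  the higher AP-directed tension measured in the embryo. Edges at exactly
  45° count as transverse (a deterministic tie-break); the class is
  re-evaluated from the current geometry every step because edges rotate
  during constriction. Every edge of a margin cell uses `Λ = 6.0`
  regardless of orientation.
* **Contractility** is an area-based term (preferred area zero) because
  apical actomyosin contracts across the whole apical surface rather than
  in a circumferential ring. `Γ_i(t̃)` is the externally prescribed
  per-cell contractility program.

The ½ prefactors on the quadratic terms follow the common vertex-model
convention; with them, an isolated tension-free cell balances at
`A* = K·A0/(K+Γ)`, which the test suite verifies against direct
relaxation to 0.1 %. An optional quadratic edge-elasticity term
(`edge_k`, default 0) exists behind a config flag; the model as published
is pure tension.

## Lattice

The standard sheet is 15 rows × 24 columns of regular hexagons
(`edge_length = 1`), the outer perimeter vertices fixed for all time. Two
cell columns at the anterior and posterior borders (one in the
square-sheet variants) are a non-contractile, high-tension *margin* that
delimits the furrow and suppresses border artefacts. Rows are indexed
along the latero-ventral (LV) y axis; the midline row `Z` is row 8 of 15
(index 7).

Hexagon orientation is not dictated by the biology, but it is not neutral
either. The default lattice (`orientation="lv_edges"`) places two edges of
every cell perpendicular to the AP axis, so that all cells of one row lie
at the same y and each cell has four shallow (transverse-class) and two
steep (vertical-class) edges. With the 90°-rotated alternative
(`orientation="ap_edges"`, also available) the tension-symmetry contrasts
invert: the high-tension AP-parallel edge pair collapses in the squeezed
furrow and neighbour exchanges churn in exactly the runs where they should
be rare. The default orientation reproduces the intended contrasts —
asymmetric tension: eccentric cells and rare T1 transitions; symmetric
tension: near-isotropic cells and frequent T1 transitions — and is
therefore the package default.

## Contractility programs

All programs compose a spatial weight in [0, 1] with a temporal scalar;
margin cells are always zero.

| variant | definition |
|---|---|
| `cutoff` | weight 1 in the five central rows, 0 outside; `Γ = 10`, constant |
| `gradient_static` | `Γ_mid·exp(−(i−Z)²/2σ²)`, `Γ_mid = 15`, `σ = 2.0` rows |
| `cutoff_timed` / `gradient_timed` | spatial weight × `min(Γ_init + α·t̃, Γ_max)`, `Γ_init = 0`, `α = 0.15`, `Γ_max = 25` |
| `gradient_stochastic` | weight × `clamp(α·t̃ + σ_W·W_i(t̃), 0, Γ_max)`, `σ_W = 0.3`, `W_i` an independent standard Wiener path per cell |
| `gradient_alternative` | as stochastic, but the Gaussian weight uses the cell centroid's *current* distance to the midline y (fixed at start), so cells grow more contractile as they approach the midline |
| `twi` | stochastic value × `U(i,j)`, `U ~ Uniform(0, 0.5)` drawn once per cell — the twist-mutant's fragmentary apical myosin accumulation |

Composition choices that the one-line formulas leave open:

* The ramp cap `Γ_max` applies to the shared scalar process *before*
  spatial weighting, i.e. it is defined at the midline; off-midline cells
  saturate at `weight × Γ_max`.
* Clamping at zero happens *after* the noise is added, so an early
  negative excursion of the Wiener path cannot make a cell expansile.
* Per-cell noise streams are seeded from `(master_seed, row, col)` so a
  cell keeps its path regardless of sheet size or enumeration order, and
  `U(i,j)` comes from a separate stream so it is independent of the path
  length.
* Gradient width presets: `σ = 1.25` (narrow), `3.00` (wide), `4.25`
  (widened twist variant). The reduced-overall-contractility preset
  (`low_contractility`) halves the ramp slope and cap (α = 0.075,
  Γ_max = 12.5); the published parameter set for that variant is only
  partially legible, so these values are this package's interpretation
  and are exposed as ordinary config parameters.

## Dynamics

Vertices follow overdamped gradient flow: friction balances the potential
force, integrated with an explicit Euler scheme,

```
x_v(t̃+dt) = x_v(t̃) + (dt/η) · (−∂E/∂x_v),    dt = 0.05.
```

The friction coefficient η sets the mechanical response time relative to
the contractility ramp; it is not a published constant. The default
`η = 10` was calibrated so that a cell's area visibly lags its
contractility on the seconds scale after time normalization (the
rate-correlation analysis below) while runs stay numerically stable; at
`η = 1` the response is effectively instantaneous on that scale, and
beyond `η ≈ 40` the crowded furrow accumulates extreme shear. With
`η = 10`, standard runs reach furrow completion in ≈ 1900–2300 steps
(t̃ ≈ 100).

Termination: a run stops after `max_steps` or when the *furrow width* —
the mean area of the non-margin cells in the five central rows — falls
below `0.35·A0` (the threshold fraction is configurable; completion-based
presets use it, static-contractility presets use a fixed horizon because
their force balance can sit arbitrarily close to any threshold).

### T1 transitions

When an interior edge becomes shorter than `eps = 0.1` its two vertices
swap neighbours: the edge collapses and re-opens perpendicular through its
midpoint at length `1.5·eps = 0.15`, the two cells that shared it lose
adjacency and the two flanking cells gain it. Swaps are unconditional at
the trigger, as in the published model. Edges touching fixed vertices are
exempt; a vertex pair that just swapped is immune for 10 steps to avoid
flip-flopping; V − E + F and the vertex/edge/cell counts are conserved and
the mesh is re-validated after every event.

Finite steps and finite re-opening lengths can, in rare crowded
configurations, produce geometric degeneracies that the continuous model
never reaches. Four deterministic guards keep the tiling valid without
altering quasi-static behaviour:

1. **Displacement cap** (0.02 length units/step): bounds the force spike
   right after a re-opening so one step cannot carry a vertex across a
   neighbouring boundary.
2. **Tangle revert**: a swap whose re-opened edge would make any touching
   ring non-simple is undone and simply re-tried later.
3. **Minimum edge separation** (0.05 = eps/2): a compressed pair that
   cannot productively swap persists as a near-fourfold vertex instead of
   inverting through zero length.
4. **Unfold guard**: if extreme shear sweeps a vertex across a
   non-adjacent edge of a cell, that cell's vertices are rolled back to
   their pre-step positions for that step (counted in the archive;
   typically zero per run).

### Determinism and replay

A run is a pure function of (config, master seed). The archive stores the
full config, every per-cell Wiener increment, per-cell traces (area, Γ,
eccentricity, centroid, every step), mesh snapshots (every 10 steps), the
T1 event log and the energy series; replaying an archive reproduces every
array bit-exactly. Replay accepts declarative overrides — force `Γ` to a
value in a listed cell set over a step window — which implements the
neighbour-knockout experiments.

## Analysis metrics

* **Eccentricity**: ratio of the AP extent to the LV extent of the
  ellipse with the polygon's area-weighted second central moments.
  Axis-aligned extents (projections of the moment ellipse) are used, not
  principal-axis lengths, because the measure is defined relative to the
  body axes. 1 = isotropic, > 1 = AP-elongated.
* **Rates**: centred local-linear smoothing (Savitzky-Golay, polynomial
  order 1, default 5 samples — a centred moving average in the interior,
  exact at the ends for linear trends) followed by a centred-difference
  derivative; one-sided at the ends.
* **Rate-lag analysis**: per cell, the contractility rate is shifted
  forward by candidate offsets and Pearson-correlated with the
  constriction rate (−dA/dt) on the overlapping support; correlations are
  averaged over cells per offset and the maximizing offset reported. Run
  time is first normalized so completion = 600 s (the 10-minute span of
  furrow formation) and traces are resampled on a 1-s grid. The measured
  best offset is positive in every standard run: the cell responds to its
  contractility, not vice versa. Its magnitude (≈ 2 s at the defaults)
  reflects both the mechanical response time (∝ η) and the smoothing
  kernel; it grows only weakly with η in the stable range.
* **Stagnation periods**: maximal intervals in which the smoothed area
  rate stays within ±`tol` for at least `min_duration`, excluding the
  pre-onset plateau (before the smoothed area first drops 5 % below its
  initial value) and any interval that runs to the end of the series — a
  stagnation is a *temporary* plateau after which reduction resumes, not
  the final approach to force balance. The thresholds are not published;
  the defaults are `tol = 2 % of A0 per 10 normalized seconds`
  (0.002·A0/s) and `min_duration = 30 s`, both configurable and reported
  in output metadata.
* **Unit normalization**: model time maps run span → 600 s; model area
  maps the initial hexagon → the mean apical area at the end of
  cellularization (default 40 µm², configurable).

## What the experiments show — and what they cannot

The synthetic experiments reproduce, at the level of qualitative contrasts
and invariants: the constricted ventral band with a gradual (gradient) vs
discontinuous (cutoff) mediolateral profile; anisotropic constriction and
its dependence on tension asymmetry, sheet geometry and the gradient; the
emergence of stagnation periods from stochastic contractility and their
disappearance without noise or without neighbour contractility; and the
twist-mutant's irregular, weakly eccentric constriction pattern under
random per-cell attenuation.

The model is a flat 2D apical surface: it cannot address invagination,
apico-basal shortening, or any 3D mechanics. Contractility is prescribed,
not mechanochemically coupled; there is no strain feedback, no Fog
diffusion, no cell division or extrusion (T2). Boundary vertices are
pinned, so global tissue flows are suppressed and within-row trace
equality of the deterministic variant holds only away from the margins.
Passing tests therefore validate the implementation of this model, not the
embryo: real recordings have segmentation noise, unequal cell sizes and
drift that the generator does not emulate.

## Problem sizes used in the test suite

Full-size (15×24) runs to furrow completion are used wherever a claim
concerns the standard model (≈ 2000 steps, seconds per run); the
finite-difference force oracle uses a 3×4 sheet; property tests for the
mesh and the integrator use 3×3 to 6×8 sheets; the reduced model is the
exact 7-cell rosette.
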