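"""Time integration, T1 neighbour exchanges, termination and replay.

Vertices obey overdamped dynamics: friction balances the potential force,
so each free vertex moves by (dt / eta) * (-dE/dx) per explicit Euler step.
Sheet-boundary vertices stay fixed.  After every step, interior edges
shorter than the critical threshold eps undergo a T1 transition: the edge
collapses and re-opens perpendicular through its midpoint, the two cells
that shared it lose adjacency and the two flanking cells gain it.

A run records everything needed to replicate it bit-exactly — the full
configuration, the master seed, every per-cell Wiener increment, periodic
mesh snapshots, per-cell traces and a T1 event log — in a
:class:`RunArchive`.  :func:`replay` re-runs an archive with optional
declarative overrides (e.g. forcing contractility to zero in a chosen cell
set from a given step), the in-silico analogue of a targeted perturbation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .config import RunConfig
from .contractility import NoiseState, gamma_field, sample_noise
from .mechanics import MechanicalParams, edge_tensions, total_energy, vertex_forces
from .mesh import Sheet, validate_topology

__all__ = [
    "T1Event",
    "Modification",
    "RunArchive",
    "euler_step",
    "apply_t1_transitions",
    "furrow_width",
    "run_simulation",
    "replay",
    "save_archive",
    "load_archive",
]


@dataclass(frozen=True)
class T1Event:
    step: int
    vertex_a: int
    vertex_b: int
    cells_separated: tuple[int, int]  # lost the shared edge
    cells_joined: tuple[int, int]  # gained adjacency


@dataclass(frozen=True)
class Modification:
    """Declarative override applied during a replay.

    Forces Gamma = ``gamma`` for the listed (row, col) cells from
    ``from_step`` (inclusive) to ``to_step`` (exclusive; None = run end).
    """

    cells: tuple[tuple[int, int], ...]
    gamma: float = 0.0
    from_step: int = 0
    to_step: int | None = None


@dataclass
class RunArchive:
    """Self-contained record of one simulation run."""

    config: RunConfig
    noise: NoiseState
    sheet_initial: Sheet
    sheet_final: Sheet = None  # type: ignore[assignment]
    snapshots: list[tuple[int, np.ndarray, list[list[int]]]] = field(default_factory=list)
    traces: dict[str, np.ndarray] = field(default_factory=dict)
    t1_events: list[T1Event] = field(default_factory=list)
    energy: np.ndarray = field(default_factory=lambda: np.empty(0))
    descent_violations: int = 0
    fold_rollbacks: int = 0
    final_step: int = 0
    completed: bool = False
    y_mid: float = 0.0

    @property
    def n_steps(self) -> int:
        return self.final_step

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.final_step + 1) * self.config.integration.dt

    def traces_dataframe(self):
        """Per-cell time series as a tidy pandas DataFrame."""
        import pandas as pd

        cells = self.sheet_initial.cells
        n_steps, n_cells = self.traces["area"].shape
        dt = self.config.integration.dt
        step = np.repeat(np.arange(n_steps), n_cells)
        cell_idx = np.tile(np.arange(n_cells), n_steps)
        return pd.DataFrame(
            {
                "cell_id": cell_idx,
                "row": np.tile([c.row for c in cells], n_steps),
                "col": np.tile([c.col for c in cells], n_steps),
                "step": step,
                "t": step * dt,
                "area": self.traces["area"].ravel(),
                "gamma": self.traces["gamma"].ravel(),
                "eccentricity": self.traces["eccentricity"].ravel(),
                "centroid_x": self.traces["centroid_x"].ravel(),
                "centroid_y": self.traces["centroid_y"].ravel(),
            }
        )


# ----------------------------------------------------------------------
# Elementary steps
# ----------------------------------------------------------------------
def euler_step(
    sheet: Sheet,
    mech: MechanicalParams,
    gamma: np.ndarray,
    dt: float,
    friction_eta: float = 1.0,
    forces: np.ndarray | None = None,
    max_displacement: float | None = None,
) -> np.ndarray:
    """Advance free vertices by (dt / eta) * force, in place.

    Returns the forces used.  Fixed vertices never move.  If
    ``max_displacement`` is given, each vertex's step is capped at that
    length (direction preserved): quasi-static motion is unaffected, but
    the transient spike after a T1 re-opening cannot carry a vertex across
    a cell boundary in a single step.
    """
    if forces is None:
        forces = vertex_forces(sheet, mech, gamma)
    free = ~sheet.fixed
    disp = (dt / friction_eta) * forces[free]
    if max_displacement is not None:
        norms = np.hypot(disp[:, 0], disp[:, 1])
        over = norms > max_displacement
        if np.any(over):
            disp[over] *= (max_displacement / norms[over])[:, None]
    sheet.positions[free] += disp
    return forces


def simple_cells_mask(sheet: Sheet) -> np.ndarray:
    """Vectorized simplicity check: True for cells whose ring is a valid
    (non-self-intersecting) polygon."""
    import shapely

    top = sheet.topology()
    coords = sheet.positions[top.ring_pad]
    return shapely.is_valid(shapely.polygons(coords))


def unfold_guard(sheet: Sheet, pos_before: np.ndarray, max_rounds: int = 5) -> int:
    """Roll back this step's motion for any cell whose ring became
    non-simple (a vertex swept across a non-adjacent edge under extreme
    shear).  Restoring a vertex can in turn invalidate a neighbour, so the
    rollback set grows until every ring is simple again; the pre-step
    state is always a valid fixed point.  Returns the number of cells
    rolled back (0 almost always).
    """
    rolled = 0
    for _ in range(max_rounds):
        ok = simple_cells_mask(sheet)
        if ok.all():
            return rolled
        for ci in np.flatnonzero(~ok):
            vids = sheet.cells[ci].ring
            sheet.positions[vids] = pos_before[vids]
            rolled += 1
    # last resort: restore everything moved this step
    sheet.positions[:] = pos_before
    return rolled


def enforce_min_edge_length(sheet: Sheet, l_min: float) -> int:
    """Push the endpoints of too-short interior edges apart to ``l_min``.

    Symmetric about the midpoint along the current edge direction (only
    the free endpoint moves if the other is fixed).  Returns the number of
    edges adjusted.  This regularizes near-fourfold vertices: pairs whose
    T1 exchange is unproductive hover at the floor instead of collapsing
    through zero length.
    """
    top = sheet.topology()
    d = sheet.positions[top.edge_b] - sheet.positions[top.edge_a]
    lengths = np.hypot(d[:, 0], d[:, 1])
    short = np.flatnonzero((lengths < l_min) & top.edge_interior)
    n = 0
    for ei in short:
        a, b = int(top.edge_a[ei]), int(top.edge_b[ei])
        pa, pb = sheet.positions[a], sheet.positions[b]
        dv = pb - pa
        length = np.hypot(*dv)
        if length >= l_min:
            continue  # already adjusted via a shared vertex
        u = dv / length if length > 1e-12 else np.array([1.0, 0.0])
        deficit = l_min - length
        if sheet.fixed[a] and sheet.fixed[b]:
            continue
        if sheet.fixed[a]:
            sheet.positions[b] = pb + deficit * u
        elif sheet.fixed[b]:
            sheet.positions[a] = pa - deficit * u
        else:
            sheet.positions[a] = pa - 0.5 * deficit * u
            sheet.positions[b] = pb + 0.5 * deficit * u
        n += 1
    return n


def furrow_width(sheet: Sheet) -> float:
    """Mean area of non-margin cells in the five centralmost rows."""
    if sheet.n_rows < 5:
        raise ValueError("furrow width requires at least 5 cell rows")
    rows = sheet.row_of_cells()
    z = sheet.midline_row
    sel = (np.abs(rows - z) <= 2) & ~sheet.margin_mask()
    return float(sheet.cell_areas()[sel].mean())


# ----------------------------------------------------------------------
# T1 transitions
# ----------------------------------------------------------------------
def _cells_at_vertex(sheet: Sheet, v: int) -> list[int]:
    return [ci for ci, c in enumerate(sheet.cells) if v in c.ring]


def apply_t1_transitions(
    sheet: Sheet,
    eps_t1: float,
    t1_separation: float,
    step: int = 0,
    cooldown: dict[tuple[int, int], int] | None = None,
    t1_cooldown: int = 10,
) -> list[T1Event]:
    """Swap neighbours across every interior edge shorter than eps.

    The collapsed edge re-opens perpendicular through its midpoint at
    length ``t1_separation``.  Edges touching fixed vertices or the outer
    boundary are skipped, as are edges whose endpoints swapped within the
    cooldown window (to prevent flip-flopping) and configurations whose
    swap would be degenerate (a flanking cell shared by both endpoints, a
    triangle that would lose its third vertex, or a re-opening that would
    tangle a neighbouring ring -- such attempts are reverted and simply
    retried once the local geometry has changed).
    """
    top = sheet.topology()
    pos = sheet.positions
    d = pos[top.edge_b] - pos[top.edge_a]
    lengths = np.hypot(d[:, 0], d[:, 1])
    short = np.flatnonzero((lengths < eps_t1) & top.edge_interior)
    if short.size == 0:
        return []

    events: list[T1Event] = []
    for ei in short:
        e = top.edges[ei]
        a, b = e.a, e.b
        if sheet.fixed[a] or sheet.fixed[b]:
            continue
        key = (a, b) if a < b else (b, a)
        if cooldown is not None and step - cooldown.get(key, -(10**9)) < t1_cooldown:
            continue
        # re-measure: an earlier swap in this pass may have moved a or b
        if np.hypot(*(sheet.positions[b] - sheet.positions[a])) >= eps_t1:
            continue
        ev = _try_t1(sheet, a, b, t1_separation, step)
        if cooldown is not None:
            # stamp even reverted attempts so a stuck pair is re-examined
            # only once per cooldown window
            cooldown[key] = step
        if ev is not None:
            events.append(ev)
    if events:
        sheet.invalidate_topology()
    return events


def _try_t1(sheet: Sheet, a: int, b: int, separation: float, step: int) -> T1Event | None:
    cells_a = _cells_at_vertex(sheet, a)
    cells_b = _cells_at_vertex(sheet, b)
    shared = [c for c in cells_a if c in cells_b]
    if len(shared) != 2:
        return None  # boundary edge
    c1 = c2 = None
    for c in shared:
        ring = sheet.cells[c].ring
        ia = ring.index(a)
        if ring[(ia + 1) % len(ring)] == b:
            c1 = c  # traverses a -> b
        else:
            c2 = c  # traverses b -> a
    if c1 is None or c2 is None:
        return None
    ca = [c for c in cells_a if c not in shared]
    cb = [c for c in cells_b if c not in shared]
    if len(ca) != 1 or len(cb) != 1 or ca[0] == cb[0]:
        return None  # vertex on boundary or degenerate rosette
    ca, cb = ca[0], cb[0]
    ring1, ring2 = sheet.cells[c1].ring, sheet.cells[c2].ring
    if len(ring1) < 4 or len(ring2) < 4:
        return None  # would create a 2-gon

    # geometry: new edge perpendicular to the old, b toward c1's side
    pa, pb = sheet.positions[a].copy(), sheet.positions[b].copy()
    ring1_old, ring2_old = list(ring1), list(ring2)
    mid = 0.5 * (pa + pb)
    u = (pb - pa) / np.hypot(*(pb - pa))
    n = np.array([-u[1], u[0]])  # left of a->b == interior side of c1
    sheet.positions[b] = mid + 0.5 * separation * n
    sheet.positions[a] = mid - 0.5 * separation * n

    # topology: c1 keeps b, c2 keeps a, ca and cb gain the new edge a-b
    ring1.remove(a)
    ring2.remove(b)
    ring_ca = sheet.cells[ca].ring
    ia = ring_ca.index(a)
    nxt = ring_ca[(ia + 1) % len(ring_ca)]
    # insert b on the side of the edge of ca shared with c1
    if nxt in sheet.cells[c1].ring or nxt == b:
        ring_ca.insert(ia + 1, b)
    else:
        ring_ca.insert(ia, b)
    ring_cb = sheet.cells[cb].ring
    ib = ring_cb.index(b)
    nxt = ring_cb[(ib + 1) % len(ring_cb)]
    if nxt in sheet.cells[c2].ring or nxt == a:
        ring_cb.insert(ib + 1, a)
    else:
        ring_cb.insert(ib, a)
    sheet.invalidate_topology()

    def revert() -> None:
        sheet.cells[c1].ring[:] = ring1_old
        sheet.cells[c2].ring[:] = ring2_old
        sheet.cells[ca].ring.remove(b)
        sheet.cells[cb].ring.remove(a)
        sheet.positions[a] = pa
        sheet.positions[b] = pb
        sheet.invalidate_topology()

    # the re-opened edge must not tangle any ring touching either vertex
    # (in a crowded region the perpendicular placement can poke a vertex
    # through a neighbouring boundary)
    from shapely.geometry import Polygon

    from .mesh import polygon_area

    for ci in set(cells_a) | set(cells_b) | {ca, cb}:
        ring_pts = sheet.positions[sheet.cells[ci].ring]
        if polygon_area(ring_pts) <= 0 or not Polygon(ring_pts).is_valid:
            revert()
            return None
    return T1Event(step, a, b, (c1, c2), (ca, cb))


# ----------------------------------------------------------------------
# Main loop
# ----------------------------------------------------------------------
def run_simulation(
    config: RunConfig,
    noise: NoiseState | None = None,
    gamma_fn: Callable[[Sheet, int, float], np.ndarray] | None = None,
    modifications: Sequence[Modification] = (),
) -> RunArchive:
    """Run the model defined by ``config`` and archive everything.

    The loop per step: evaluate Gamma(t), record traces, assemble forces,
    Euler-update free vertices, apply T1 transitions, snapshot.  The run
    stops at ``max_steps`` or as soon as the furrow width falls below the
    completion threshold.  ``gamma_fn(sheet, step, t) -> per-cell Gamma``
    replaces the contractility program entirely (used by the reduced
    scheduled experiments); ``modifications`` force Gamma in chosen cells
    (used by replay).  The result is a pure function of (config, noise).
    """
    ip = config.integration
    mech = config.mechanics
    program = config.contractility
    sheet = config.sheet.build()
    n_cells = sheet.n_cells

    if noise is None:
        noise = sample_noise(
            config.master_seed, sheet, ip.max_steps, ip.dt, twi_umax=program.twi_umax
        )
    if noise.n_steps < ip.max_steps:
        raise ValueError("noise state too short for max_steps")

    # ventral midline y, fixed at start (alternative gradient model)
    rows = sheet.row_of_cells()
    y_mid = float(sheet.cell_centroids()[rows == sheet.midline_row, 1].mean())

    # resolve modification cell indices once
    mod_index: list[tuple[np.ndarray, Modification]] = []
    rc_to_idx = {(c.row, c.col): i for i, c in enumerate(sheet.cells)}
    for mod in modifications:
        idx = []
        for rc in mod.cells:
            key = (int(rc[0]), int(rc[1]))
            if key not in rc_to_idx:
                raise ValueError(f"modification references unknown cell {key}")
            idx.append(rc_to_idx[key])
        mod_index.append((np.array(idx, dtype=int), mod))

    A0 = mech.resolved_A0(sheet)
    threshold = (
        ip.furrow_threshold_frac * A0 if ip.furrow_threshold_frac is not None else None
    )

    n_max = ip.max_steps
    tr_area = np.empty((n_max + 1, n_cells))
    tr_gamma = np.empty((n_max + 1, n_cells))
    tr_ecc = np.empty((n_max + 1, n_cells))
    tr_cx = np.empty((n_max + 1, n_cells))
    tr_cy = np.empty((n_max + 1, n_cells))
    energy = np.empty(n_max + 1)

    archive = RunArchive(
        config=config, noise=noise, sheet_initial=sheet.copy(), y_mid=y_mid
    )
    cooldown: dict[tuple[int, int], int] = {}
    descent_violations = 0

    def eval_gamma(step: int) -> np.ndarray:
        t = step * ip.dt
        if gamma_fn is not None:
            g = np.asarray(gamma_fn(sheet, step, t), dtype=float)
        else:
            g = gamma_field(program, sheet, noise, step, ip.dt, y_mid=y_mid)
        for idx, mod in mod_index:
            to = mod.to_step if mod.to_step is not None else n_max + 1
            if mod.from_step <= step < to:
                g[idx] = mod.gamma
        return g

    def record(step: int, gamma: np.ndarray) -> None:
        tr_area[step] = sheet.cell_areas()
        tr_gamma[step] = gamma
        tr_ecc[step] = sheet.cell_eccentricities()
        cent = sheet.cell_centroids()
        tr_cx[step] = cent[:, 0]
        tr_cy[step] = cent[:, 1]

    step = 0
    completed = False
    gamma = eval_gamma(0)
    record(0, gamma)
    energy[0] = total_energy(sheet, mech, gamma)
    archive.snapshots.append((0, sheet.positions.copy(), [list(c.ring) for c in sheet.cells]))

    fold_rollbacks = 0
    for step in range(1, n_max + 1):
        # gamma currently holds Gamma(t_{step-1}) on the current geometry
        lam = edge_tensions(sheet, mech)
        e_pre = total_energy(sheet, mech, gamma, lam=lam)
        pos_before = sheet.positions.copy()
        euler_step(
            sheet, mech, gamma, ip.dt, ip.friction_eta,
            max_displacement=ip.max_step_displacement,
        )
        e_post = total_energy(sheet, mech, gamma, lam=lam)
        if e_post > e_pre + 1e-10:
            descent_violations += 1
        if ip.min_edge_length is not None:
            enforce_min_edge_length(sheet, ip.min_edge_length)
        fold_rollbacks += unfold_guard(sheet, pos_before)
        events = apply_t1_transitions(
            sheet, ip.eps_t1, ip.t1_separation, step, cooldown, ip.t1_cooldown
        )
        if events:
            archive.t1_events.extend(events)
            bad = validate_topology(sheet)
            if bad:
                archive.final_step = step
                archive.sheet_final = sheet.copy()
                raise RuntimeError(
                    f"topology violation after T1 at step {step}: {bad[:3]}"
                )

        gamma = eval_gamma(step)
        record(step, gamma)
        energy[step] = total_energy(sheet, mech, gamma)
        if step % ip.snapshot_every == 0:
            archive.snapshots.append(
                (step, sheet.positions.copy(), [list(c.ring) for c in sheet.cells])
            )
        if threshold is not None and sheet.n_rows >= 5 and furrow_width(sheet) < threshold:
            completed = True
            break

    if archive.snapshots[-1][0] != step:
        archive.snapshots.append(
            (step, sheet.positions.copy(), [list(c.ring) for c in sheet.cells])
        )
    archive.traces = {
        "area": tr_area[: step + 1].copy(),
        "gamma": tr_gamma[: step + 1].copy(),
        "eccentricity": tr_ecc[: step + 1].copy(),
        "centroid_x": tr_cx[: step + 1].copy(),
        "centroid_y": tr_cy[: step + 1].copy(),
    }
    archive.energy = energy[: step + 1].copy()
    archive.descent_violations = descent_violations
    archive.fold_rollbacks = fold_rollbacks
    archive.final_step = step
    archive.completed = completed
    archive.sheet_final = sheet.copy()
    return archive


def replay(archive: RunArchive, modifications: Sequence[Modification] = ()) -> RunArchive:
    """Re-run an archived simulation with its stored noise paths.

    With no modifications the result is bit-identical to the original;
    with modifications, the identical noise is replayed while Gamma is
    overridden in the listed cells.
    """
    return run_simulation(archive.config, noise=archive.noise, modifications=modifications)


# ----------------------------------------------------------------------
# Disk format: JSON manifest + HDF5 arrays + CSV traces
# ----------------------------------------------------------------------
def save_archive(archive: RunArchive, out_dir: str | Path) -> Path:
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": archive.config.to_dict(),
        "master_seed": archive.noise.master_seed,
        "final_step": archive.final_step,
        "completed": archive.completed,
        "descent_violations": archive.descent_violations,
        "y_mid": archive.y_mid,
        "t1_events": [dataclasses.asdict(e) for e in archive.t1_events],
        "mesh_initial": archive.sheet_initial.to_dict(),
        "mesh_final": archive.sheet_final.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    with h5py.File(out / "arrays.h5", "w") as f:
        f.create_dataset("noise/increments", data=archive.noise.increments)
        f.create_dataset("noise/attenuation", data=archive.noise.attenuation)
        f.attrs["noise_dt"] = archive.noise.dt
        for name, arr in archive.traces.items():
            f.create_dataset(f"traces/{name}", data=arr)
        f.create_dataset("energy", data=archive.energy)
        snap = f.create_group("snapshots")
        for k, (step, pos, rings) in enumerate(archive.snapshots):
            g = snap.create_group(str(k))
            g.attrs["step"] = step
            g.create_dataset("positions", data=pos)
            flat = np.array([v for r in rings for v in r], dtype=np.int64)
            sizes = np.array([len(r) for r in rings], dtype=np.int64)
            g.create_dataset("ring_flat", data=flat)
            g.create_dataset("ring_sizes", data=sizes)
    archive.traces_dataframe().to_csv(out / "traces.csv", index=False)
    with open(out / "t1_events.csv", "w") as fh:
        fh.write("step,vertex_a,vertex_b,cell_sep_1,cell_sep_2,cell_join_1,cell_join_2\n")
        for e in archive.t1_events:
            fh.write(
                f"{e.step},{e.vertex_a},{e.vertex_b},{e.cells_separated[0]},"
                f"{e.cells_separated[1]},{e.cells_joined[0]},{e.cells_joined[1]}\n"
            )
    return out


def load_archive(path: str | Path) -> RunArchive:
    import h5py

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    config = RunConfig.from_dict(manifest["config"])
    with h5py.File(path / "arrays.h5", "r") as f:
        noise = NoiseState(
            manifest["master_seed"],
            float(f.attrs["noise_dt"]),
            f["noise/increments"][...],
            f["noise/attenuation"][...],
        )
        traces = {name: f[f"traces/{name}"][...] for name in f["traces"]}
        energy = f["energy"][...]
        snapshots = []
        for k in sorted(f["snapshots"], key=int):
            g = f["snapshots"][k]
            sizes = g["ring_sizes"][...]
            flat = g["ring_flat"][...]
            rings, off = [], 0
            for n in sizes:
                rings.append([int(v) for v in flat[off : off + n]])
                off += n
            snapshots.append((int(g.attrs["step"]), g["positions"][...], rings))
    archive = RunArchive(
        config=config,
        noise=noise,
        sheet_initial=Sheet.from_dict(manifest["mesh_initial"]),
        sheet_final=Sheet.from_dict(manifest["mesh_final"]),
        snapshots=snapshots,
        traces=traces,
        t1_events=[
            T1Event(
                e["step"],
                e["vertex_a"],
                e["vertex_b"],
                tuple(e["cells_separated"]),
                tuple(e["cells_joined"]),
            )
            for e in manifest["t1_events"]
        ],
        energy=energy,
        descent_violations=manifest["descent_violations"],
        final_step=manifest["final_step"],
        completed=manifest["completed"],
        y_mid=manifest["y_mid"],
    )
    return archive
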