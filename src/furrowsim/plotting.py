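"""Deterministic frame rendering of archived runs.

One image per mesh snapshot, cells colour-mapped by apical area or by
contractility, mirroring the movie panels of the simulation output.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection

from .dynamics import RunArchive
from .mesh import HEX_AREA_FACTOR

__all__ = ["render_frames"]


def render_frames(
    archive: RunArchive,
    out_dir: str | Path,
    color_by: str = "area",
    fmt: str = "svg",
    cmap: str = "RdYlGn",
) -> list[Path]:
    """Render every snapshot of an archive to ``out_dir``.

    ``color_by`` is ``"area"`` (red = constricted, green = dilated) or
    ``"gamma"`` (white = non-contractile, dark red = maximal).  SVG output
    is byte-deterministic for identical archives.
    """
    if not archive.snapshots:
        raise ValueError("archive contains no snapshots")
    if color_by not in ("area", "gamma"):
        raise ValueError("color_by must be 'area' or 'gamma'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    a0 = HEX_AREA_FACTOR * archive.sheet_initial.edge_length**2
    gmax = archive.config.contractility.gamma_max
    paths = []
    plt.rcParams["svg.hashsalt"] = "furrowsim"
    for k, (step, pos, rings) in enumerate(archive.snapshots):
        polys = [pos[r] for r in rings]
        if color_by == "area":
            areas = np.array(
                [0.5 * abs(np.sum(p[:, 0] * np.roll(p[:, 1], -1) - np.roll(p[:, 0], -1) * p[:, 1])) for p in polys]
            )
            values = areas / a0
            norm = plt.Normalize(0.0, 2.0)
            used_cmap = plt.get_cmap(cmap + "_r" if not cmap.endswith("_r") else cmap)
        else:
            idx = min(step, archive.traces["gamma"].shape[0] - 1)
            values = archive.traces["gamma"][idx] / max(gmax, 1e-12)
            norm = plt.Normalize(0.0, 1.0)
            used_cmap = plt.get_cmap("Reds")
        fig, ax = plt.subplots(figsize=(6, 4))
        coll = PolyCollection(
            polys, array=values, cmap=used_cmap, norm=norm, edgecolor="black", linewidth=0.4
        )
        ax.add_collection(coll)
        ax.autoscale_view()
        ax.set_aspect("equal")
        ax.set_xlabel("AP axis (model units)")
        ax.set_ylabel("LV axis (model units)")
        ax.set_title(f"step {step}")
        p = out / f"frame_{k:04d}.{fmt}"
        fig.savefig(p, metadata={"Date": None} if fmt == "svg" else None)
        plt.close(fig)
        paths.append(p)
    return paths
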