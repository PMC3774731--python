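"""Run configuration: schema, defaults, validation and YAML round-trip.

A :class:`RunConfig` bundles everything a simulation needs — sheet
geometry, mechanical constants, the contractility program, integration
parameters, unit normalization and the master seed — and round-trips
losslessly through ``to_dict``/``from_dict`` and YAML files.  Unknown keys
are rejected so that a typo in a config file fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contractility import ContractilityProgram
from .mechanics import MechanicalParams

__all__ = [
    "SheetSpec",
    "IntegrationParams",
    "NormalizationRule",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass
class SheetSpec:
    n_rows: int = 15
    n_cols: int = 24
    edge_length: float = 1.0
    margin_mode: str = "columns"  # "columns" | "border" | "none"
    margin_width: int = 2
    fix_boundary: bool = True
    orientation: str = "lv_edges"  # hexagon orientation, see mesh module

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("sheet dimensions must be positive")
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        if self.margin_mode not in ("columns", "border", "none"):
            raise ValueError(f"unknown margin_mode {self.margin_mode!r}")
        if self.orientation not in ("lv_edges", "ap_edges"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def build(self):
        from .mesh import build_hex_sheet

        return build_hex_sheet(
            self.n_rows,
            self.n_cols,
            self.edge_length,
            margin_mode=self.margin_mode,
            margin_width=self.margin_width,
            fix_boundary=self.fix_boundary,
            orientation=self.orientation,
        )


@dataclass
class IntegrationParams:
    """Euler integration, T1 handling and termination.

    ``furrow_threshold_frac`` stops the run once the furrow width (mean
    area of the five central rows) falls below this fraction of A0; set to
    ``None`` to run for exactly ``max_steps`` steps.
    """

    dt: float = 0.05
    friction_eta: float = 10.0
    eps_t1: float = 0.1
    t1_separation: float = 0.15
    max_steps: int = 6000
    furrow_threshold_frac: float | None = 0.35
    snapshot_every: int = 10
    t1_cooldown: int = 10
    #: per-step displacement cap (model length units); bounds the large
    #: transient forces right after a T1 re-opening so a single Euler step
    #: cannot carry a vertex across a neighbouring cell boundary.
    max_step_displacement: float = 0.02
    #: hard-core separation for interior vertex pairs.  An edge under
    #: compression whose exchange is mechanically unproductive persists as
    #: a near-fourfold vertex; this floor (together with the displacement
    #: cap, 2 * cap < floor) keeps the pair from inverting through zero
    #: length and tangling the adjacent rings.
    min_edge_length: float = 0.05

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction_eta <= 0:
            raise ValueError("friction_eta must be positive")
        if self.eps_t1 <= 0:
            raise ValueError("eps_t1 must be positive")
        if self.t1_separation <= self.eps_t1:
            raise ValueError("t1_separation must exceed eps_t1")
        if self.max_steps < 0:
            raise ValueError("max_steps must be non-negative")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1")
        if self.max_step_displacement is not None and self.min_edge_length is not None:
            if 2 * self.max_step_displacement >= self.min_edge_length:
                raise ValueError(
                    "min_edge_length must exceed twice max_step_displacement "
                    "(otherwise a minimal edge can invert within one step)"
                )


@dataclass
class NormalizationRule:
    """Mapping from model units to real-world units.

    The run duration (onset to furrow completion) maps to
    ``total_seconds`` (10 minutes of live imaging), and the initial
    regular-hexagon area maps to ``initial_cell_area_um2``, the mean apical
    area of ventral cells at the end of cellularization.
    """

    total_seconds: float = 600.0
    initial_cell_area_um2: float = 40.0

    def __post_init__(self) -> None:
        if self.total_seconds <= 0 or self.initial_cell_area_um2 <= 0:
            raise ValueError("normalization factors must be positive")


@dataclass
class RunConfig:
    sheet: SheetSpec = field(default_factory=SheetSpec)
    mechanics: MechanicalParams = field(default_factory=MechanicalParams)
    contractility: ContractilityProgram = field(default_factory=ContractilityProgram)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    normalization: NormalizationRule = field(default_factory=NormalizationRule)
    master_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {
            "sheet": SheetSpec,
            "mechanics": MechanicalParams,
            "contractility": ContractilityProgram,
            "integration": IntegrationParams,
            "normalization": NormalizationRule,
        }
        kwargs: dict = {}
        for name, klass in sections.items():
            sub = d.pop(name, {})
            if not isinstance(sub, dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(
                    f"unknown keys in config section {name!r}: {sorted(unknown)}"
                )
            kwargs[name] = klass(**sub)
        kwargs["master_seed"] = int(d.pop("master_seed", 0))
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    The file may name a preset (``preset: gradient_stochastic``) and
    override any of its sections, or spell out sections directly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    preset = raw.pop("preset", None)
    if preset is not None:
        from .experiments import preset_config

        base = preset_config(preset, seed=int(raw.pop("master_seed", 0)))
        merged = base.to_dict()
        for key, sub in raw.items():
            if key not in merged:
                raise ValueError(f"unknown top-level config key {key!r}")
            if isinstance(sub, dict):
                merged[key].update(sub)
            else:
                merged[key] = sub
        return RunConfig.from_dict(merged)
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
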