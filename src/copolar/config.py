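"""Run configuration: YAML serialization, validation, defaults.

A run config is a flat, human-editable YAML document describing one
simulation batch: layout, parameter profile, junction couplings, stimulus
schedule, seeds and outputs.  Loading validates against a strict schema
(unknown keys are errors) and fills defaults explicitly, so the resolved
config written next to a run's outputs fully reproduces it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .domain import CellParams, ConfigurationError, PeriodicDomain
from .junctions import (ActinRegulation, MOTIF_NAMES, RateRegulation,
                        StimulusSpec, build_junction_map, crosstalk_actin,
                        motif_regulations, pushpull_actin)
from .model import GroupConfig

__all__ = ["RunConfig", "load_config", "save_config", "resolve_group_config"]


@dataclass
class RunConfig:
    """Serializable description of a simulation batch."""

    layout: str = "doublet"
    f_cc: float = 0.25
    n_realizations: int = 100
    base_seed: int = 0
    t_end: Optional[float] = None
    out_stride: int = 100
    snapshot_stride: Optional[int] = None
    neutralize: bool = False
    veto_prob: float = 0.7
    params: dict = field(default_factory=dict)          # CellParams overrides
    cell_params: list = field(default_factory=list)     # per-cell override dicts
    motif: Optional[str] = None                         # named GTPase motif
    motif_gamma: float = 1000.0
    motif_conc_dependent: bool = False
    actin_coupling: Optional[str] = None                # 'pushpull' | 'crosstalk'
    actin_e: float = 1.0
    actin_e_like: float = 0.0
    rate_regulation: list = field(default_factory=list)     # free-form entries
    actin_regulation: list = field(default_factory=list)
    stimuli: list = field(default_factory=list)
    output_dir: str = "results"

    def validate(self) -> "RunConfig":
        from .junctions import LAYOUT_CELLS
        if self.layout not in LAYOUT_CELLS:
            raise ConfigurationError(f"layout: unknown layout {self.layout!r}")
        if not (0.0 < self.f_cc < 1.0) and self.layout != "single":
            raise ConfigurationError("f_cc: must be in (0, 1)")
        if self.n_realizations <= 0:
            raise ConfigurationError("n_realizations: must be positive")
        if self.motif is not None and self.motif not in MOTIF_NAMES:
            raise ConfigurationError(
                f"motif: unknown motif {self.motif!r}; options {MOTIF_NAMES}")
        if self.actin_coupling not in (None, "pushpull", "crosstalk"):
            raise ConfigurationError(
                f"actin_coupling: unknown coupling {self.actin_coupling!r}")
        # raises on bad values / unknown keys
        self.resolve_params()
        for st in self.stimuli:
            _stimulus_from_dict(st)
        return self

    def resolve_params(self) -> CellParams:
        try:
            return CellParams(**self.params)
        except TypeError as exc:
            raise ConfigurationError(f"params: {exc}") from exc

    def resolve_cell_params(self, n_cells: int):
        base = self.resolve_params()
        if not self.cell_params:
            return base
        if len(self.cell_params) != n_cells:
            raise ConfigurationError(
                f"cell_params: {len(self.cell_params)} entries for "
                f"{n_cells} cells")
        return [base.replace(**d) for d in self.cell_params]


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown key(s) {sorted(unknown)}")
    return RunConfig(**raw).validate()


def save_config(config: RunConfig, path) -> None:
    """Write the fully resolved config (defaults included) as YAML."""
    Path(path).write_text(
        yaml.safe_dump(asdict(config), sort_keys=False))


def _stimulus_from_dict(d: dict) -> StimulusSpec:
    try:
        return StimulusSpec(**d)
    except TypeError as exc:
        raise ConfigurationError(f"stimuli: {exc}") from exc


def resolve_group_config(cfg: RunConfig) -> GroupConfig:
    """Expand a RunConfig into the GroupConfig driving simulate_group."""
    cfg.validate()
    jmap = build_junction_map(cfg.layout, cfg.f_cc if cfg.layout != "single" else 0.25)
    params = cfg.resolve_cell_params(jmap.n_cells)
    regs = [RateRegulation(**d) for d in cfg.rate_regulation]
    if cfg.motif:
        regs += motif_regulations(cfg.motif, jmap, cfg.motif_gamma,
                                  cfg.motif_conc_dependent)
    aregs = [ActinRegulation(**d) for d in cfg.actin_regulation]
    if cfg.actin_coupling == "pushpull":
        aregs += pushpull_actin(jmap, cfg.actin_e)
    elif cfg.actin_coupling == "crosstalk":
        aregs += crosstalk_actin(jmap, cfg.actin_e, cfg.actin_e_like)
    stimuli = [_stimulus_from_dict(d) for d in cfg.stimuli]
    return GroupConfig(
        layout=cfg.layout, params=params, f_cc=cfg.f_cc,
        rate_regulation=tuple(regs), actin_regulation=tuple(aregs),
        stimuli=tuple(stimuli), neutralize=cfg.neutralize,
        veto_prob=cfg.veto_prob, t_end=cfg.t_end)
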