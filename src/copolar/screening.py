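"""Coupling-grid enumeration and outcome-probability screens.

A screen runs many stochastic realizations for each candidate junction
coupling, classifies the final arrangement of every realization and
aggregates outcome probabilities (fractions of realizations).  A coupling
is scored 'successful' when the co-alignment probability reaches 70%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .domain import CellParams, ConfigurationError, PeriodicDomain
from .junctions import (ActinRegulation, RateRegulation, StimulusSpec,
                        build_junction_map)
from .metrics import (CO_ALIGNMENT, COLLISION, MISALIGNMENT, NON_POLARIZED,
                      OutcomeLabel, classify_doublet_full,
                      classify_quadruplet, classify_supracellular,
                      time_to_polarize)
from .model import GroupConfig, Trajectory, simulate_group

__all__ = [
    "CouplingConfig", "ScreenConfig", "ScreenResult",
    "enumerate_biochemical_grid", "enumerate_structural_grid",
    "run_screen", "summarize", "SUCCESS_THRESHOLD",
]

SUCCESS_THRESHOLD = 0.70
PRIMARY_LABELS = (CO_ALIGNMENT, COLLISION, MISALIGNMENT, NON_POLARIZED)

_SLOT_NAMES = ("konRac", "konRho", "koffRac", "koffRho")
_SLOT_SPEC = {
    "konRac": ("rac", "on"), "konRho": ("rho", "on"),
    "koffRac": ("rac", "off"), "koffRho": ("rho", "off"),
}


@dataclass(frozen=True)
class CouplingConfig:
    """One point of a coupling grid."""

    name: str
    rate_regulation: tuple = ()
    actin_regulation: tuple = ()
    meta: tuple = ()  # hashable key/value pairs describing the grid point

    @property
    def meta_dict(self) -> dict:
        return dict(self.meta)


def enumerate_biochemical_grid(gammas: Sequence[float] = (1, 10, 100, 1000),
                               conc_dependent: bool = False,
                               collapse_symmetric: bool = False):
    """All per-cell single-rate amplifications of a doublet.

    Each cell independently either leaves its rates unchanged or amplifies
    exactly one of {kon, koff} x {Rac, Rho} at the junction by a factor
    from ``gammas``.  With the default four-value gamma set this yields
    13 x 13 = 169 combinations, or 91 after collapsing mirror-symmetric
    duplicates under cell exchange.
    """
    gset = [g for g in gammas if g > 1]
    per_cell = [("none", 1.0)] + [(s, g) for s in _SLOT_NAMES for g in gset]
    configs = []
    seen = set()
    for (s1, g1), (s2, g2) in itertools.product(per_cell, per_cell):
        key = frozenset((((s1, g1), 0), ((s2, g2), 1)))
        mirror = frozenset((((s2, g2), 0), ((s1, g1), 1)))
        if collapse_symmetric and mirror in seen:
            continue
        seen.add(key)
        regs = []
        for cell, (slot, g) in enumerate(((s1, g1), (s2, g2))):
            if slot == "none":
                continue
            species, rate = _SLOT_SPEC[slot]
            src = species if conc_dependent else None
            regs.append(RateRegulation(cell, species, rate, g,
                                       conc_dependent, src))
        name = f"{s1}x{g1:g}(c1)+{s2}x{g2:g}(c2)"
        configs.append(CouplingConfig(
            name, tuple(regs), (),
            meta=(("cell1", f"{s1}x{g1:g}"), ("cell2", f"{s2}x{g2:g}"),
                  ("conc_dependent", conc_dependent))))
    return configs


def enumerate_structural_grid(e_magnitude: float = 1.0):
    """All F-actin growth-rate couplings of a doublet: 162 configurations.

    Two families of 3^4 each: constant terms (eps_A, eps_B per cell, each
    in {-e, 0, +e}) and concentration-dependent coefficients
    (eps_AA, eps_AB, eps_BA, eps_BB applied symmetrically in both cells,
    each in {-e, 0, +e}).
    """
    if e_magnitude <= 0:
        raise ConfigurationError("e_magnitude must be positive")
    levels = (-e_magnitude, 0.0, e_magnitude)
    configs = []
    for ea1, eb1, ea2, eb2 in itertools.product(levels, repeat=4):
        regs = (ActinRegulation(0, eps_a=ea1, eps_b=eb1),
                ActinRegulation(1, eps_a=ea2, eps_b=eb2))
        name = f"const[eA1={ea1:g},eB1={eb1:g},eA2={ea2:g},eB2={eb2:g}]"
        configs.append(CouplingConfig(
            name, (), regs,
            meta=(("family", "constant"), ("eps_a1", ea1), ("eps_b1", eb1),
                  ("eps_a2", ea2), ("eps_b2", eb2))))
    for eaa, eab, eba, ebb in itertools.product(levels, repeat=4):
        regs = (ActinRegulation(0, eps_aa=eaa, eps_ab=eab, eps_ba=eba, eps_bb=ebb),
                ActinRegulation(1, eps_aa=eaa, eps_ab=eab, eps_ba=eba, eps_bb=ebb))
        name = f"dep[eAA={eaa:g},eAB={eab:g},eBA={eba:g},eBB={ebb:g}]"
        configs.append(CouplingConfig(
            name, (), regs,
            meta=(("family", "dependent"), ("eps_aa", eaa), ("eps_ab", eab),
                  ("eps_ba", eba), ("eps_bb", ebb))))
    assert len(configs) == 162
    return configs


@dataclass
class ScreenConfig:
    """Grid of couplings plus shared run conditions."""

    couplings: Sequence[CouplingConfig]
    layout: str = "doublet"
    n_realizations: int = 100
    base_seed: int = 0
    params: CellParams = field(default_factory=CellParams)
    cell_params: Optional[Sequence[CellParams]] = None  # per-cell overrides
    domain: PeriodicDomain = field(default_factory=PeriodicDomain)
    f_cc: float = 0.25
    stimuli: Sequence[StimulusSpec] = ()
    neutralize: bool = False
    t_end: Optional[float] = None
    success_threshold: float = SUCCESS_THRESHOLD
    record_time_to_polarize: bool = False


@dataclass
class ScreenResult:
    """Per-coupling outcome probabilities and per-realization labels."""

    config: ScreenConfig
    labels: dict          # name -> list[OutcomeLabel or str]
    seeds: dict           # name -> list[int]
    t_polarize: dict      # name -> list[float or None] (group settle time)

    def counts(self, name: str) -> dict:
        out = {lab: 0 for lab in PRIMARY_LABELS}
        out["supracellular"] = 0
        extra = {}
        for lab in self.labels[name]:
            primary = lab.primary if isinstance(lab, OutcomeLabel) else lab
            if primary in out:
                out[primary] += 1
            else:
                extra[primary] = extra.get(primary, 0) + 1
            if isinstance(lab, OutcomeLabel) and lab.supracellular:
                out["supracellular"] += 1
        out.update(extra)
        return out

    def probability(self, name: str, outcome: str) -> float:
        n = len(self.labels[name])
        if n == 0:
            return float("nan")
        return self.counts(name).get(outcome, 0) / n

    def success(self, name: str) -> bool:
        return self.probability(name, CO_ALIGNMENT) >= self.config.success_threshold

    @property
    def names(self):
        return list(self.labels)


def _default_runner(screen: ScreenConfig, coupling: CouplingConfig, seed):
    """Simulate one realization of one coupling and classify it."""
    jmap = build_junction_map(screen.layout, screen.f_cc, screen.domain)
    params = (list(screen.cell_params) if screen.cell_params is not None
              else screen.params)
    cfg = GroupConfig(
        layout=screen.layout, params=params, domain=screen.domain,
        f_cc=screen.f_cc, rate_regulation=coupling.rate_regulation,
        actin_regulation=coupling.actin_regulation, stimuli=screen.stimuli,
        neutralize=screen.neutralize, t_end=screen.t_end)
    stride = 1 if screen.record_time_to_polarize else 25
    traj = simulate_group(cfg, seed, out_stride=stride)
    axes = traj.final_axes()
    if jmap.n_cells == 2:
        label = classify_doublet_full(axes[0], axes[1], jmap)
    elif jmap.n_cells == 4:
        label = OutcomeLabel(classify_quadruplet(axes, jmap))
    else:
        label = OutcomeLabel(CO_ALIGNMENT if np.isfinite(axes[0]) else NON_POLARIZED)
    tp = None
    if screen.record_time_to_polarize:
        dt_out = traj.times[1] - traj.times[0]
        per_cell = [time_to_polarize(traj.axes_deg[:, c], dt_out)
                    for c in range(traj.n_cells)]
        tp = None if any(t is None for t in per_cell) else max(per_cell)
    return label, tp


def run_screen(screen: ScreenConfig,
               runner: Optional[Callable] = None,
               prior: Optional[ScreenResult] = None,
               progress: bool = False) -> ScreenResult:
    """Run every coupling of the grid for ``n_realizations`` seeds each.

    Realization ``r`` uses the substream ``(base_seed, r)`` for every
    coupling (common random numbers), so a neutral coupling (gamma = 1,
    eps = 0) reproduces the uncoupled outcome distribution exactly.
    Pairs already present in ``prior`` are skipped (resume support).
    Deterministic given ``base_seed``; aggregation is order-independent.
    """
    runner = runner or _default_runner
    labels: dict = {}
    seeds: dict = {}
    tps: dict = {}
    root = np.random.SeedSequence(int(screen.base_seed))
    for coupling in screen.couplings:
        name = coupling.name
        done = {}
        if prior is not None and name in prior.labels:
            done = dict(zip(prior.seeds[name], zip(
                prior.labels[name],
                prior.t_polarize.get(name, [None] * len(prior.labels[name])))))
        labels[name] = []
        seeds[name] = []
        tps[name] = []
        for r in range(screen.n_realizations):
            if r in done:
                lab, tp = done[r]
            else:
                seed = np.random.SeedSequence(entropy=root.entropy,
                                              spawn_key=(r,))
                out = runner(screen, coupling, seed)
                lab, tp = out if isinstance(out, tuple) else (out, None)
            labels[name].append(lab)
            seeds[name].append(r)
            tps[name].append(tp)
        if progress:
            res = ScreenResult(screen, {name: labels[name]},
                               {name: seeds[name]}, {name: tps[name]})
            print(f"{name}: co-alignment "
                  f"{res.probability(name, CO_ALIGNMENT):.2f}")
    return ScreenResult(screen, labels, seeds, tps)


def summarize(result: ScreenResult) -> pd.DataFrame:
    """Long-form probability table with Wilson 95% confidence intervals."""
    rows = []
    for name in result.names:
        counts = result.counts(name)
        n = len(result.labels[name])
        outcomes = list(PRIMARY_LABELS) + ["supracellular"]
        for outcome in outcomes:
            k = counts.get(outcome, 0)
            if n > 0:
                lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            else:
                lo = hi = float("nan")
            rows.append({"configuration": name, "outcome": outcome,
                         "probability": k / n if n else float("nan"),
                         "n": n, "ci_low": lo, "ci_high": hi,
                         "success": result.success(name)})
    return pd.DataFrame(rows)


def outcome_matrix(result: ScreenResult, outcome: str = CO_ALIGNMENT) -> pd.DataFrame:
    """Grid-style probability matrix keyed by per-cell modifications.

    Available for screens whose couplings carry 'cell1'/'cell2' metadata
    (the biochemical grid).
    """
    rows = []
    for name in result.names:
        meta = None
        for c in result.config.couplings:
            if c.name == name:
                meta = c.meta_dict
                break
        if not meta or "cell1" not in meta:
            continue
        rows.append({"cell1": meta["cell1"], "cell2": meta["cell2"],
                     "probability": result.probability(name, outcome)})
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).pivot(index="cell1", columns="cell2",
                                    values="probability")
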