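"""State representation and time stepping of the polarity model.

A cell couples a stochastic particle description of membrane-bound Rac and
Rho GTPases to two continuum actin density fields (branched A, bundled B)
on the periodic membrane domain.  ``simulate_group`` advances one, two or
four coupled cells and records the per-cell polarity-axis angle over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import kernels
from .domain import CellParams, ConfigurationError, PeriodicDomain
from .junctions import (ActinRegulation, JunctionMap, RateRegulation,
                        StimulusSpec, build_junction_map, growth_arrays,
                        regulation_arrays, stimulus_rate_profile)

__all__ = [
    "GtpaseState", "ActinFields", "CellState", "EffectiveRates",
    "GroupConfig", "Trajectory", "NumericalFailure",
    "init_state", "local_count", "effective_kon", "gtpase_step",
    "actin_step", "homogeneous_steady_states", "simulate_group",
]

_SP = {"rac": 0, "rho": 1}


class NumericalFailure(RuntimeError):
    """Non-finite value in the continuum fields during stepping."""

    def __init__(self, step, cell, time=None):
        self.step = step
        self.cell = cell
        self.time = time
        super().__init__(
            f"non-finite actin field in cell {cell} at step {step}"
            + (f" (t = {time:.3f} s)" if time is not None else ""))


@dataclass
class GtpaseState:
    """Positions of membrane-bound molecules plus inactive pool, per species.

    Conservation of mass holds by construction:
    ``bound_count + inactive_count == N`` for each species.  In the
    spatial-pool variant the inactive molecules also carry positions
    (``rac_pool``/``rho_pool``); in the well-mixed variant these are None
    and only the inactive count matters.
    """

    rac: np.ndarray
    rho: np.ndarray
    n_rac: int
    n_rho: int
    rac_pool: Optional[np.ndarray] = None
    rho_pool: Optional[np.ndarray] = None

    def pool(self, species: str) -> Optional[np.ndarray]:
        return self.rac_pool if _SP[species] == 0 else self.rho_pool

    def positions(self, species: str) -> np.ndarray:
        return self.rac if _SP[species] == 0 else self.rho

    def set_positions(self, species: str, pos: np.ndarray) -> None:
        pos = np.asarray(pos, float)
        if species == "rac":
            if len(pos) > self.n_rac:
                raise ConfigurationError("more bound Rac than total")
            self.rac = pos
        else:
            if len(pos) > self.n_rho:
                raise ConfigurationError("more bound Rho than total")
            self.rho = pos

    def total(self, species: str) -> int:
        return self.n_rac if _SP[species] == 0 else self.n_rho

    def bound_count(self, species: str) -> int:
        return len(self.positions(species))

    def inactive_count(self, species: str) -> int:
        return self.total(species) - self.bound_count(species)


@dataclass
class ActinFields:
    """Branched (a) and bundled (b) density fields on the grid."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, float)
        self.b = np.asarray(self.b, float)
        if self.a.shape != self.b.shape:
            raise ConfigurationError("A and B must share the grid")
        if np.any(self.a < 0) or np.any(self.b < 0):
            raise ConfigurationError("actin densities must be nonnegative")


@dataclass
class CellState:
    domain: PeriodicDomain
    params: CellParams
    gtpase: GtpaseState
    actin: ActinFields

    def copy(self) -> "CellState":
        g = GtpaseState(self.gtpase.rac.copy(), self.gtpase.rho.copy(),
                        self.gtpase.n_rac, self.gtpase.n_rho,
                        None if self.gtpase.rac_pool is None else self.gtpase.rac_pool.copy(),
                        None if self.gtpase.rho_pool is None else self.gtpase.rho_pool.copy())
        return CellState(self.domain, self.params, g,
                         ActinFields(self.actin.a.copy(), self.actin.b.copy()))


def init_state(params: CellParams, domain: Optional[PeriodicDomain] = None,
               rng: Union[int, np.random.Generator, None] = 0) -> CellState:
    """Random initial condition of one cell.

    10% of each species is bound at independent uniform positions on the
    membrane; the rest is inactive.  Actin fields start at the homogeneous
    unit baseline plus a small uniform perturbation, so symmetry breaking
    is endogenous.  Reproducible given the seed.
    """
    domain = domain or PeriodicDomain()
    params.check_pde_stability(domain)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = domain.perimeter
    nb_rac = int(params.init_bound_fraction * params.n_rac + 0.5)
    nb_rho = int(params.init_bound_fraction * params.n_rho + 0.5)
    rac = rng.random(nb_rac) * L
    rac_pool = rng.random(params.n_rac - nb_rac) * L if params.spatial_pool else None
    rho = rng.random(nb_rho) * L
    rho_pool = rng.random(params.n_rho - nb_rho) * L if params.spatial_pool else None
    gt = GtpaseState(rac, rho, params.n_rac, params.n_rho, rac_pool, rho_pool)
    eta = params.init_actin_noise
    a = 1.0 + eta * rng.uniform(-1.0, 1.0, domain.n_grid)
    b = 1.0 + eta * rng.uniform(-1.0, 1.0, domain.n_grid)
    return CellState(domain, params, gt, ActinFields(a, b))


def local_count(state: Union[CellState, GtpaseState], species: str, s: float,
                radius: float, domain: Optional[PeriodicDomain] = None) -> int:
    """Number of bound molecules within the periodic arc (s - r, s + r)."""
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    if isinstance(state, CellState):
        domain = state.domain
        gt = state.gtpase
    else:
        gt = state
        if domain is None:
            raise ConfigurationError("domain required with a bare GtpaseState")
    pos = gt.positions(species)
    if len(pos) == 0:
        return 0
    return int(np.count_nonzero(domain.circular_distance(pos, s) < radius))


def effective_kon(base_kon, actin_local_density, beta_rev, junction_factor=1.0):
    """Actin- and junction-modified association rate.

    ``junction_factor * base_kon * (1 + beta_rev * density)``; Rac reads the
    branched density A, Rho the bundled density B.  Monotone in the density.
    """
    return junction_factor * base_kon * (1.0 + beta_rev * np.asarray(actin_local_density))


@dataclass
class EffectiveRates:
    """Per-site absolute rates driving one GTPase step of one cell."""

    kon_rac: np.ndarray
    kon_rho: np.ndarray
    koff_rac: np.ndarray
    koff_rho: np.ndarray

    def kon(self, species: str) -> np.ndarray:
        return self.kon_rac if _SP[species] == 0 else self.kon_rho

    def koff(self, species: str) -> np.ndarray:
        return self.koff_rac if _SP[species] == 0 else self.koff_rho


def _windowed(state: CellState, species: str) -> np.ndarray:
    d = state.domain
    p = state.params
    hw = int(p.inhibition_radius / d.ds + 0.5)
    out = np.zeros(d.n_grid)
    pos = state.gtpase.positions(species)
    kernels.windowed_counts(pos, len(pos), d.n_grid, d.ds, hw, out)
    return out


def gtpase_step(state: CellState, rates: EffectiveRates,
                rng: np.random.Generator, dt: Optional[float] = None,
                veto_prob: float = 0.7) -> CellState:
    """One fixed-dt stochastic step of both GTPase species.

    For each species: bound molecules unbind with probability
    ``1 - exp(-k_off_local dt)``; inactive molecules bind with probability
    ``1 - exp(-mean(k_on) dt)`` at a site drawn proportionally to the local
    rate; bound molecules recruit an inactive molecule within the
    inhibition radius with probability ``1 - exp(-k_fb dt)``.  Events whose
    target site has any opposite-species molecule within the inhibition
    window are vetoed.  Mass is conserved; pool exhaustion silently skips
    events.
    """
    out = state.copy()
    d, p = state.domain, state.params
    dt = p.dt if dt is None else dt
    cnt = {sp: _windowed(state, sp) for sp in ("rac", "rho")}
    for sp, opp in (("rac", "rho"), ("rho", "rac")):
        n_tot = out.gtpase.total(sp)
        buf = np.empty(n_tot)
        pos = out.gtpase.positions(sp)
        buf[:len(pos)] = pos
        if p.spatial_pool:
            pool = out.gtpase.pool(sp)
            if pool is None or len(pool) != n_tot - len(pos):
                raise ConfigurationError(
                    "spatial_pool state requires inactive positions")
            buf[len(pos):] = pool
        konv = np.ascontiguousarray(rates.kon(sp), dtype=float)
        koffv = np.ascontiguousarray(rates.koff(sp), dtype=float)
        nb = kernels.species_update(
            rng, buf, len(pos), n_tot, konv, float(konv.sum()),
            koffv, cnt[opp], p.k_fb, p.inhibition_radius, d.ds, d.n_grid,
            d.perimeter, dt, veto_prob, p.spatial_pool, p.d_gtpase)
        out.gtpase.set_positions(sp, buf[:nb].copy())
        if p.spatial_pool:
            if sp == "rac":
                out.gtpase.rac_pool = buf[nb:].copy()
            else:
                out.gtpase.rho_pool = buf[nb:].copy()
    return out


def actin_step(fields: ActinFields, rac_counts, rho_counts, growth_mods,
               params: CellParams, domain: PeriodicDomain,
               dt: Optional[float] = None) -> ActinFields:
    """One explicit Euler step of the coupled actin reaction-diffusion pair.

    ``growth_mods`` is a pair of per-site additive terms (eps_A, eps_B),
    zero outside junction regions.  Negative overshoot is clamped at zero.
    With eps = 0 this is exactly the unmodified two-network system.
    """
    dt = params.dt if dt is None else dt
    params.check_pde_stability(domain)
    eps_a, eps_b = growth_mods
    a_new = np.empty(domain.n_grid)
    b_new = np.empty(domain.n_grid)
    bad = kernels.actin_pair_step(
        np.asarray(fields.a, float), np.asarray(fields.b, float),
        np.asarray(rac_counts, float), np.asarray(rho_counts, float),
        np.asarray(eps_a, float), np.asarray(eps_b, float),
        params.alpha, params.m0, params.d_actin, dt, domain.ds, a_new, b_new)
    if bad:
        raise NumericalFailure(step=0, cell=0)
    return ActinFields(a_new, b_new)


def homogeneous_steady_states(params: CellParams, n_rac: float, n_rho: float,
                              eps_a: float = 0.0, eps_b: float = 0.0):
    """Closed-form homogeneous fixed points of the 2x2 reaction system.

    With uniform local counts the reaction part reads
    ``A' = A (g_a - A - m0 B)``, ``B' = B (g_b - B - m0 A)`` with
    ``g_a = 1 + alpha n_Rac + eps_A`` and ``g_b = 1 + alpha n_Rho + eps_B``.
    Returns the nonnegative roots among (0,0), (g_a, 0), (0, g_b) and the
    coexistence solution of the linear system.
    """
    ga = 1.0 + params.alpha * n_rac + eps_a
    gb = 1.0 + params.alpha * n_rho + eps_b
    roots = [(0.0, 0.0)]
    if ga > 0:
        roots.append((ga, 0.0))
    if gb > 0:
        roots.append((0.0, gb))
    m0 = params.m0
    det = 1.0 - m0 * m0
    if abs(det) > 1e-12:
        a = (ga - m0 * gb) / det
        b = (gb - m0 * ga) / det
        if a > 0 and b > 0:
            roots.append((a, b))
    return roots


# ---------------------------------------------------------------------------
# group simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupConfig:
    """Full specification of one group simulation."""

    layout: str = "doublet"
    params: Union[CellParams, Sequence[CellParams]] = field(default_factory=CellParams)
    domain: PeriodicDomain = field(default_factory=PeriodicDomain)
    f_cc: float = 0.25
    rate_regulation: Sequence[RateRegulation] = ()
    actin_regulation: Sequence[ActinRegulation] = ()
    stimuli: Sequence[StimulusSpec] = ()
    neutralize: bool = False
    veto_prob: float = 0.7
    t_end: Optional[float] = None

    def cell_params(self, n_cells: int):
        if isinstance(self.params, CellParams):
            return [self.params] * n_cells
        plist = list(self.params)
        if len(plist) != n_cells:
            raise ConfigurationError(
                f"{len(plist)} parameter sets for {n_cells} cells")
        return plist


@dataclass
class Trajectory:
    """Recorded output of one group realization."""

    times: np.ndarray                 # (n_out,)
    axes_deg: np.ndarray              # (n_out, n_cells); NaN = undefined
    jmap: JunctionMap
    final_states: list
    seed: object
    invariants_ok: bool = True
    snapshots: Optional[dict] = None  # times, a, b, rac, rho arrays

    @property
    def n_cells(self) -> int:
        return self.axes_deg.shape[1]

    def final_axes(self) -> np.ndarray:
        return self.axes_deg[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, cell, axis_angle_deg, polarized) table."""
        n_out, n_cells = self.axes_deg.shape
        return pd.DataFrame({
            "time": np.repeat(self.times, n_cells),
            "cell": np.tile(np.arange(n_cells), n_out),
            "axis_angle_deg": self.axes_deg.ravel(),
            "polarized": np.isfinite(self.axes_deg).ravel(),
        })


def cell_seed_sequence(seed, key: int) -> np.random.SeedSequence:
    """Deterministic per-cell substream of a root seed."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(entropy=seed.entropy,
                                      spawn_key=seed.spawn_key + (key,))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))


def simulate_group(config: GroupConfig, seed, out_stride: int = 1,
                   snapshot_stride: Optional[int] = None,
                   cell_seed_keys: Optional[Sequence[int]] = None,
                   check_invariants: bool = False) -> Trajectory:
    """Run one realization of a coupled cell group.

    All junction terms read the neighbor's previous-step state (explicit
    coupling).  Each cell consumes its own random substream derived from
    ``(seed, cell_seed_keys[i])`` (defaults to the cell index), so an
    uncoupled group is bitwise identical to independent single-cell runs
    with matched keys.
    """
    jmap = build_junction_map(config.layout, config.f_cc, config.domain)
    n_cells = jmap.n_cells
    plist = config.cell_params(n_cells)
    domain = config.domain
    dt = plist[0].dt
    if any(p.dt != dt for p in plist):
        raise ConfigurationError("all cells must share the time step")
    for p in plist:
        p.check_pde_stability(domain)
    t_end = config.t_end if config.t_end is not None else plist[0].t_end
    n_steps = int(round(t_end / dt))
    n_grid = domain.n_grid

    keys = list(cell_seed_keys) if cell_seed_keys is not None else list(range(n_cells))
    if len(keys) != n_cells:
        raise ConfigurationError("one seed key per cell required")
    rngs = tuple(np.random.default_rng(cell_seed_sequence(seed, k)) for k in keys)

    # initial condition (drawn from the same per-cell streams as stepping)
    states = [init_state(plist[c], domain, rngs[c]) for c in range(n_cells)]
    nmax = max(max(p.n_rac, p.n_rho) for p in plist)
    pos = np.zeros((n_cells, 2, nmax))
    nb = np.zeros((n_cells, 2), np.int64)
    A = np.zeros((n_cells, n_grid))
    B = np.zeros((n_cells, n_grid))
    spatial = plist[0].spatial_pool
    if any(p.spatial_pool != spatial for p in plist):
        raise ConfigurationError("all cells must share the pool variant")
    for c, st in enumerate(states):
        for k, sp in enumerate(("rac", "rho")):
            q = st.gtpase.positions(sp)
            nb[c, k] = len(q)
            pos[c, k, :len(q)] = q
            if spatial:
                pool = st.gtpase.pool(sp)
                pos[c, k, len(q):len(q) + len(pool)] = pool
        A[c] = st.actin.a
        B[c] = st.actin.b

    P = np.array([[p.k_on, p.k_off, p.k_fb, p.d_actin, p.alpha, p.m0,
                   p.beta_rev, p.inhibition_radius, p.c_crit, p.d_gtpase,
                   p.eps_cap] for p in plist])
    NN = np.array([[p.n_rac, p.n_rho] for p in plist], np.int64)
    CF, CG, CS = regulation_arrays(config.rate_regulation, jmap, plist)
    EC, ED = growth_arrays(config.actin_regulation, jmap, plist)
    MC, MI = jmap.mirror_arrays()

    stims = list(config.stimuli)
    n_stim = len(stims)
    st0 = np.zeros(n_stim)
    st1 = np.zeros(n_stim)
    scell = np.zeros(n_stim, np.int64)
    sprof = np.zeros((n_stim, 2, n_grid))
    for k, sp in enumerate(stims):
        if sp.cell >= n_cells:
            raise ConfigurationError(f"stimulus targets cell {sp.cell} "
                                     f"outside the {config.layout} layout")
        st0[k] = sp.t_on
        st1[k] = min(sp.t_off, t_end + dt)
        scell[k] = sp.cell
        base = plist[sp.cell].k_on
        sprof[k, 0], sprof[k, 1] = stimulus_rate_profile(sp, domain, base)

    out_steps = np.arange(0, n_steps + 1, max(1, out_stride), dtype=np.int64)
    if out_steps[-1] != n_steps:
        out_steps = np.append(out_steps, n_steps)
    if snapshot_stride:
        snap_steps = np.arange(0, n_steps + 1, snapshot_stride, dtype=np.int64)
        if snap_steps[-1] != n_steps:
            snap_steps = np.append(snap_steps, n_steps)
    else:
        snap_steps = np.zeros(0, np.int64)

    (status, fail_step, fail_cell, axes, snapA, snapB, snapRac, snapRho,
     inv_ok) = kernels.run_group(
        n_steps, dt, domain.ds, n_grid, P, NN, CF, CG, CS, MC, MI, EC, ED,
        st0, st1, scell, sprof, config.neutralize, config.veto_prob,
        spatial, rngs, pos, nb, A, B, out_steps, snap_steps, check_invariants)
    if status == kernels.STATUS_NONFINITE:
        raise NumericalFailure(fail_step, fail_cell, fail_step * dt)

    finals = []
    for c in range(n_cells):
        gt = GtpaseState(pos[c, 0, :nb[c, 0]].copy(), pos[c, 1, :nb[c, 1]].copy(),
                         plist[c].n_rac, plist[c].n_rho,
                         pos[c, 0, nb[c, 0]:plist[c].n_rac].copy() if spatial else None,
                         pos[c, 1, nb[c, 1]:plist[c].n_rho].copy() if spatial else None)
        finals.append(CellState(domain, plist[c], gt, ActinFields(A[c].copy(), B[c].copy())))

    snaps = None
    if snapshot_stride:
        snaps = {"times": snap_steps * dt, "a": snapA, "b": snapB,
                 "rac": snapRac, "rho": snapRho}
    return Trajectory(out_steps * dt, axes, jmap, finals, seed,
                      bool(inv_ok), snaps)
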