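"""Intercellular junction geometry and coupling specifications.

A group layout (doublet, 4-cell chain, 4-cell square) defines, for every
adjacent pair of cells, a junction arc ``s_cc`` covering a fixed fraction
``f_cc`` (default 25%) of each cell's perimeter, together with a mirror
correspondence pairing juxtaposed membrane points of the two cells.

All intercellular couplings act only on these arcs:

* ``RateRegulation`` -- a GTPase binding or unbinding rate multiplied by an
  amplification factor ``gamma >= 1``, optionally proportional to the
  number of source-species molecules near the mirrored point in the
  neighbor cell;
* ``ActinRegulation`` -- additive growth-rate terms ``eps_A, eps_B`` for
  the actin networks, constant or proportional to the neighbor's actin
  densities at the mirrored point;
* ``StimulusSpec`` -- an external directional bias that replaces the
  actin-dependent binding rates of the exposed cell by fixed complementary
  spatial profiles for Rac and Rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .domain import CellParams, ConfigurationError, PeriodicDomain
from .kernels import SLOT_KOFF_RAC, SLOT_KOFF_RHO, SLOT_KON_RAC, SLOT_KON_RHO

__all__ = [
    "Junction", "JunctionMap", "build_junction_map",
    "RateRegulation", "ActinRegulation", "StimulusSpec",
    "regulation_arrays", "growth_arrays", "junction_rate_fields",
    "junction_growth_fields", "stimulus_rate_profile",
    "neutralize_if_depleted", "apply_cell_variability",
    "motif_regulations", "pushpull_actin", "crosstalk_actin",
    "LAYOUT_CELLS", "MOTIF_NAMES",
]

LAYOUT_CELLS = {"single": 1, "doublet": 2, "chain4": 4, "square4": 4}

_SPECIES = {"rac": 0, "rho": 1}
_RATE = {"on": 0, "off": 1}


@dataclass(frozen=True)
class Junction:
    """One junction between two cells.

    ``sites_a[k]`` and ``sites_b[k]`` are mirror-paired grid sites; the
    pairing reverses orientation so that juxtaposed membrane points align.
    """

    cell_a: int
    cell_b: int
    center_a_deg: float
    center_b_deg: float
    sites_a: np.ndarray
    sites_b: np.ndarray


@dataclass(frozen=True)
class JunctionMap:
    layout: str
    f_cc: float
    n_cells: int
    domain: PeriodicDomain
    junctions: tuple
    cell_centers: np.ndarray  # (n_cells, 2), in units of cell diameter

    def junction_directions(self, cell: int) -> list:
        """Facing angles (deg) of all junction arcs of ``cell``."""
        out = []
        for j in self.junctions:
            if j.cell_a == cell:
                out.append(j.center_a_deg)
            if j.cell_b == cell:
                out.append(j.center_b_deg)
        return out

    def junctions_of(self, cell: int, partner: Optional[int] = None) -> list:
        out = []
        for j in self.junctions:
            if cell in (j.cell_a, j.cell_b):
                other = j.cell_b if j.cell_a == cell else j.cell_a
                if partner is None or other == partner:
                    out.append(j)
        return out

    def mirror_arrays(self):
        """Per-site mirror cell and mirror site index (-1 off junction)."""
        n = self.domain.n_grid
        mc = np.full((self.n_cells, n), -1, np.int32)
        mi = np.full((self.n_cells, n), -1, np.int32)
        for j in self.junctions:
            mc[j.cell_a, j.sites_a] = j.cell_b
            mi[j.cell_a, j.sites_a] = j.sites_b
            mc[j.cell_b, j.sites_b] = j.cell_a
            mi[j.cell_b, j.sites_b] = j.sites_a
        return mc, mi

    def mirror(self, cell: int, site: int):
        """Mirror image of one membrane site, or None off the junction."""
        mc, mi = self.mirror_arrays()
        if mc[cell, site] < 0:
            return None
        return int(mc[cell, site]), int(mi[cell, site])


def _arc_sites(domain: PeriodicDomain, center_deg: float, n_sites: int) -> np.ndarray:
    """Grid sites of an arc of ``n_sites`` sites centered on ``center_deg``.

    The arc is aligned so its midpoint matches the center angle as closely
    as the grid allows; with an even site count on a grid where the center
    falls on a site boundary the alignment is exact.
    """
    n = domain.n_grid
    start = int(round(center_deg / 360.0 * n - n_sites / 2.0))
    return np.mod(np.arange(start, start + n_sites), n).astype(np.int64)


def _make_junction(domain, cell_a, cell_b, center_a, center_b, f_cc) -> Junction:
    n_sites = int(round(f_cc * domain.n_grid))
    sa = _arc_sites(domain, center_a, n_sites)
    sb = _arc_sites(domain, center_b, n_sites)[::-1].copy()  # reversed pairing
    return Junction(cell_a, cell_b, center_a % 360.0, center_b % 360.0, sa, sb)


def build_junction_map(layout: str, f_cc: float = 0.25,
                       domain: Optional[PeriodicDomain] = None) -> JunctionMap:
    """Construct the junction geometry of a group layout.

    Layouts (cell positions in units of one cell diameter):

    * ``doublet`` -- cell 0 left, cell 1 right; one junction with facing
      angles 0 deg (cell 0) and 180 deg (cell 1).
    * ``chain4`` -- four cells in a single file along the horizontal;
      three junctions; interior cells carry two disjoint arcs.
    * ``square4`` -- cells 0..3 at top-left, top-right, bottom-right,
      bottom-left corners; four lateral junctions between edge-adjacent
      cells and no diagonal contact.
    """
    domain = domain or PeriodicDomain()
    if layout not in LAYOUT_CELLS:
        raise ConfigurationError(f"unknown layout {layout!r}")
    if layout != "single" and not (0.0 < f_cc < 1.0):
        raise ConfigurationError("f_cc must be in (0, 1)")
    if layout == "single":
        centers = np.zeros((1, 2))
        junctions = ()
    elif layout == "doublet":
        centers = np.array([[-0.5, 0.0], [0.5, 0.0]])
        junctions = (_make_junction(domain, 0, 1, 0.0, 180.0, f_cc),)
    elif layout == "chain4":
        centers = np.array([[-1.5, 0.0], [-0.5, 0.0], [0.5, 0.0], [1.5, 0.0]])
        junctions = tuple(
            _make_junction(domain, i, i + 1, 0.0, 180.0, f_cc) for i in range(3)
        )
    else:  # square4, cycle order TL -> TR -> BR -> BL is clockwise
        centers = np.array([[-0.5, 0.5], [0.5, 0.5], [0.5, -0.5], [-0.5, -0.5]])
        junctions = (
            _make_junction(domain, 0, 1, 0.0, 180.0, f_cc),
            _make_junction(domain, 1, 2, 270.0, 90.0, f_cc),
            _make_junction(domain, 2, 3, 180.0, 0.0, f_cc),
            _make_junction(domain, 3, 0, 90.0, 270.0, f_cc),
        )
    return JunctionMap(layout, f_cc, LAYOUT_CELLS[layout], domain,
                       junctions, centers)


# ---------------------------------------------------------------------------
# coupling specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateRegulation:
    """Amplification of one GTPase kinetic rate on a junction arc.

    ``gamma`` multiplies the binding (``rate='on'``) or unbinding
    (``rate='off'``) rate of ``species`` in ``cell``, on the arc facing
    ``partner`` (all junction arcs of the cell when ``partner`` is None).
    With ``conc_dependent`` the factor is ``max(1, gamma * n)`` where ``n``
    is the neighbor's count of ``source_species`` near the mirrored point.
    """

    cell: int
    species: str
    rate: str
    gamma: float
    conc_dependent: bool = False
    source_species: Optional[str] = None
    partner: Optional[int] = None

    def __post_init__(self):
        if self.gamma < 1.0:
            raise ConfigurationError("amplification factor gamma must be >= 1")
        if self.species not in _SPECIES or self.rate not in _RATE:
            raise ConfigurationError(
                f"bad species/rate {self.species!r}/{self.rate!r}")
        if self.conc_dependent and self.source_species is None:
            raise ConfigurationError(
                "conc_dependent regulation requires a source_species")

    @property
    def slot(self) -> int:
        return (SLOT_KON_RAC, SLOT_KON_RHO)[_SPECIES[self.species]] \
            if self.rate == "on" else \
            (SLOT_KOFF_RAC, SLOT_KOFF_RHO)[_SPECIES[self.species]]


@dataclass(frozen=True)
class ActinRegulation:
    """Growth-rate modification of the actin networks on a junction arc.

    ``eps_a``/``eps_b`` are constant additive terms; ``eps_aa`` .. ``eps_bb``
    multiply the neighbor's branched/bundled density at the mirrored point
    (eps_A = eps_aa * A' + eps_ab * B', eps_B = eps_ba * A' + eps_bb * B').
    """

    cell: int
    partner: Optional[int] = None
    eps_a: float = 0.0
    eps_b: float = 0.0
    eps_aa: float = 0.0
    eps_ab: float = 0.0
    eps_ba: float = 0.0
    eps_bb: float = 0.0


@dataclass(frozen=True)
class StimulusSpec:
    """External directional bias applied to one cell.

    While active (``t_on <= t < t_off``) the exposed cell's Rac binding
    rate follows a raised-cosine bump of total amplitude
    ``base * (1 + amplitude)`` peaked at ``center_deg`` with the given
    half-width; the Rho rate is the spatial complement so the pointwise sum
    is constant.  Junction amplification still composes multiplicatively.
    """

    cell: int
    center_deg: float
    amplitude: float = 4.0
    half_width_deg: float = 90.0
    t_on: float = 0.0
    t_off: float = math.inf

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigurationError("stimulus amplitude must be >= 0")
        if not (0 < self.half_width_deg <= 180):
            raise ConfigurationError("half_width_deg must be in (0, 180]")


def stimulus_rate_profile(spec: StimulusSpec, domain: PeriodicDomain,
                          base_kon: float, t: Optional[float] = None):
    """Per-site Rac and Rho binding-rate profiles of an external stimulus.

    Returns uniform baseline profiles when ``t`` is given and outside the
    active window.  The pointwise sum ``k_Rac + k_Rho`` is constant.
    """
    theta = domain.theta_deg(domain.site_centers)
    if t is not None and not (spec.t_on <= t < spec.t_off):
        ones = np.ones_like(theta)
        return base_kon * ones, base_kon * ones
    delta = np.abs((theta - spec.center_deg + 180.0) % 360.0 - 180.0)
    bump = np.where(delta <= spec.half_width_deg,
                    0.5 * (1.0 + np.cos(np.pi * delta / spec.half_width_deg)),
                    0.0)
    k_rac = base_kon * (1.0 + spec.amplitude * bump)
    k_rho = base_kon * (1.0 + spec.amplitude * (1.0 - bump))
    return k_rac, k_rho


# ---------------------------------------------------------------------------
# kernel array builders and evaluated fields
# ---------------------------------------------------------------------------

def regulation_arrays(regs: Sequence[RateRegulation], jmap: JunctionMap,
                      params: Sequence[CellParams]):
    """Build (CF, CG, CS) rate-factor arrays for the stepping kernel.

    CF holds constant multiplicative factors (whole-domain variability
    factors composed with junction gammas); CG/CS describe
    concentration-dependent entries.
    """
    n, nc = jmap.domain.n_grid, jmap.n_cells
    cf = np.ones((nc, 4, n))
    cg = np.zeros((nc, 4, n))
    cs = np.full((nc, 4, n), -1, np.int8)
    for c, p in enumerate(params):
        cf[c, SLOT_KON_RAC] *= p.kon_rac_factor
        cf[c, SLOT_KON_RHO] *= p.kon_rho_factor
    for r in regs:
        if r.cell >= nc:
            raise ConfigurationError(f"regulation targets cell {r.cell} "
                                     f"outside the {jmap.layout} layout")
        juncs = jmap.junctions_of(r.cell, r.partner)
        if not juncs:
            raise ConfigurationError(
                f"cell {r.cell} has no junction with partner {r.partner}")
        for j in juncs:
            sites = j.sites_a if j.cell_a == r.cell else j.sites_b
            if r.conc_dependent:
                cg[r.cell, r.slot, sites] = r.gamma
                cs[r.cell, r.slot, sites] = _SPECIES[r.source_species]
            else:
                cf[r.cell, r.slot, sites] *= r.gamma
    return cf, cg, cs


def growth_arrays(regs: Sequence[ActinRegulation], jmap: JunctionMap,
                  params: Sequence[CellParams]):
    """Build (EC, ED) growth-modification arrays for the stepping kernel."""
    n, nc = jmap.domain.n_grid, jmap.n_cells
    ec = np.zeros((nc, 2, n))
    ed = np.zeros((nc, 4, n))
    for c, p in enumerate(params):
        ec[c, 0] += p.eps_a0
        ec[c, 1] += p.eps_b0
    for r in regs:
        if r.cell >= nc:
            raise ConfigurationError(f"regulation targets cell {r.cell} "
                                     f"outside the {jmap.layout} layout")
        for j in jmap.junctions_of(r.cell, r.partner):
            sites = j.sites_a if j.cell_a == r.cell else j.sites_b
            ec[r.cell, 0, sites] += r.eps_a
            ec[r.cell, 1, sites] += r.eps_b
            ed[r.cell, 0, sites] += r.eps_aa
            ed[r.cell, 1, sites] += r.eps_ab
            ed[r.cell, 2, sites] += r.eps_ba
            ed[r.cell, 3, sites] += r.eps_bb
    return ec, ed


def junction_rate_fields(regs: Sequence[RateRegulation], jmap: JunctionMap,
                         params: Sequence[CellParams],
                         neighbor_counts=None) -> np.ndarray:
    """Evaluated per-site multiplicative rate factors, shape (n_cells, 4, n).

    ``neighbor_counts[cell]`` must provide the previous-step windowed
    (Rac, Rho) count arrays of each cell when concentration-dependent
    entries are present.  Constant entries contribute gamma on the junction
    arc and 1 elsewhere; dependent entries contribute
    ``max(1, gamma * n_source(mirror point))``.
    """
    cf, cg, cs = regulation_arrays(regs, jmap, params)
    mc, mi = jmap.mirror_arrays()
    out = cf.copy()
    if np.any(cs >= 0):
        if neighbor_counts is None:
            raise ConfigurationError(
                "conc_dependent regulation requires neighbor counts")
        for c in range(jmap.n_cells):
            for slot in range(4):
                sel = np.nonzero(cs[c, slot] >= 0)[0]
                for g in sel:
                    n_src = neighbor_counts[mc[c, g]][cs[c, slot, g]][mi[c, g]]
                    out[c, slot, g] *= max(1.0, cg[c, slot, g] * n_src)
    return out


def junction_growth_fields(regs: Sequence[ActinRegulation], jmap: JunctionMap,
                           params: Sequence[CellParams],
                           neighbor_fields=None):
    """Evaluated (eps_A, eps_B) fields, each of shape (n_cells, n_grid).

    ``neighbor_fields[cell] = (A, B)`` previous-step densities, required
    when concentration-dependent coefficients are present.
    """
    ec, ed = growth_arrays(regs, jmap, params)
    mc, mi = jmap.mirror_arrays()
    eps_a = ec[:, 0].copy()
    eps_b = ec[:, 1].copy()
    if np.any(ed != 0.0):
        if neighbor_fields is None:
            raise ConfigurationError(
                "conc_dependent growth regulation requires neighbor fields")
        for c in range(jmap.n_cells):
            sel = np.nonzero(mc[c] >= 0)[0]
            for g in sel:
                a_nb, b_nb = neighbor_fields[mc[c, g]]
                eps_a[c, g] += ed[c, 0, g] * a_nb[mi[c, g]] + ed[c, 1, g] * b_nb[mi[c, g]]
                eps_b[c, g] += ed[c, 2, g] * a_nb[mi[c, g]] + ed[c, 3, g] * b_nb[mi[c, g]]
    return eps_a, eps_b


def apply_cell_variability(params: CellParams, overrides: dict) -> CellParams:
    """Whole-domain baseline modifications for one cell.

    Supported keys: multiplicative ``kon_rac_factor``/``kon_rho_factor``
    (e.g. 10 for a tenfold baseline binding rate) and additive
    ``eps_a0``/``eps_b0`` growth offsets.  Junction regulation composes
    multiplicatively on top of these factors.
    """
    allowed = {"kon_rac_factor", "kon_rho_factor", "eps_a0", "eps_b0"}
    bad = set(overrides) - allowed
    if bad:
        raise ConfigurationError(f"unknown variability keys: {sorted(bad)}")
    for k in ("kon_rac_factor", "kon_rho_factor"):
        if overrides.get(k, 1.0) < 0:
            raise ConfigurationError(f"{k} must be nonnegative")
    return params.replace(**overrides)


def neutralize_if_depleted(state, rng, fraction: float = 0.10):
    """Rebind ``fraction`` of any fully unbound species at random positions.

    Mirrors the in-kernel neutralization used in signal-switch experiments;
    operates on a CellState in place and returns it.
    """
    L = state.domain.perimeter
    for sp in ("rac", "rho"):
        if state.gtpase.bound_count(sp) == 0:
            n_tot = state.gtpase.total(sp)
            k = int(fraction * n_tot + 0.5)
            new = rng.random(k) * L
            state.gtpase.set_positions(sp, new)
    return state


# ---------------------------------------------------------------------------
# named interaction motifs
# ---------------------------------------------------------------------------

MOTIF_NAMES = (
    "asym_bind_complementary",
    "asym_unbind_complementary",
    "asym_bind_unbind_rac",
    "asym_bind_unbind_rho",
    "sym_bind_rac", "sym_bind_rho", "sym_unbind_rac", "sym_unbind_rho",
)

_MOTIF_TABLE = {
    # (species_a, rate_a, species_b, rate_b)
    "asym_bind_complementary": ("rac", "on", "rho", "on"),
    "asym_unbind_complementary": ("rac", "off", "rho", "off"),
    "asym_bind_unbind_rac": ("rac", "on", "rac", "off"),
    "asym_bind_unbind_rho": ("rho", "on", "rho", "off"),
    "sym_bind_rac": ("rac", "on", "rac", "on"),
    "sym_bind_rho": ("rho", "on", "rho", "on"),
    "sym_unbind_rac": ("rac", "off", "rac", "off"),
    "sym_unbind_rho": ("rho", "off", "rho", "off"),
}


def motif_regulations(name: str, jmap: JunctionMap, gamma: float = 1000.0,
                      conc_dependent: bool = False):
    """Apply a named Rho-GTPase interaction motif at every junction.

    The first cell of each junction takes the 'cell 1' role of the motif,
    so the motif orientation follows the layout's junction order (left to
    right in chains, around the cycle in the square).  For
    concentration-dependent motifs, each entry's source is the species
    engaged on the partner side of the junction.
    """
    if name not in _MOTIF_TABLE:
        raise ConfigurationError(f"unknown motif {name!r}")
    sp_a, rt_a, sp_b, rt_b = _MOTIF_TABLE[name]
    regs = []
    for j in jmap.junctions:
        regs.append(RateRegulation(
            j.cell_a, sp_a, rt_a, gamma, conc_dependent,
            sp_b if conc_dependent else None, partner=j.cell_b))
        regs.append(RateRegulation(
            j.cell_b, sp_b, rt_b, gamma, conc_dependent,
            sp_a if conc_dependent else None, partner=j.cell_a))
    return regs


def pushpull_actin(jmap: JunctionMap, e: float = 1.0):
    """Reciprocal excitation of complementary networks (push-n-pull).

    Bundled growth is up-regulated at the junction in the first cell of
    each junction and branched growth in the second cell.
    """
    regs = []
    for j in jmap.junctions:
        regs.append(ActinRegulation(j.cell_a, partner=j.cell_b, eps_b=e))
        regs.append(ActinRegulation(j.cell_b, partner=j.cell_a, eps_a=e))
    return regs


def crosstalk_actin(jmap: JunctionMap, e: float = 1.0, e_like: float = 0.0):
    """Concentration-dependent mutual excitation-inhibition crosstalk.

    Reciprocal excitatory cross terms (eps_AB = eps_BA = e > 0) with
    like-network coefficients ``e_like`` (<= 0), symmetric in both cells of
    every junction.
    """
    regs = []
    for j in jmap.junctions:
        for cell, partner in ((j.cell_a, j.cell_b), (j.cell_b, j.cell_a)):
            regs.append(ActinRegulation(
                cell, partner=partner,
                eps_aa=e_like, eps_ab=e, eps_ba=e, eps_bb=e_like))
    return regs
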