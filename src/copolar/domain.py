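"""Geometry and per-cell parameters.

The membrane of each model cell is a static circle, represented as a 1D
periodic arclength domain of length ``perimeter``.  Positions are measured
by arclength ``s`` in ``[0, perimeter)``; the angle ``theta(s) = 2*pi*s/L``
is counted counterclockwise from the positive horizontal axis, so
``theta(0) = 0`` points to the right of the cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PeriodicDomain", "CellParams", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class PeriodicDomain:
    """Periodic 1D membrane domain.

    Parameters
    ----------
    perimeter : float
        Total arclength of the membrane (a.u.).
    n_grid : int
        Number of grid sites for the continuum (actin) fields.  Site ``g``
        covers the arc ``[g*ds, (g+1)*ds)`` and its center sits at
        ``(g + 0.5) * ds``.
    """

    perimeter: float = 10.0
    n_grid: int = 96

    def __post_init__(self) -> None:
        if self.n_grid < 16:
            raise ConfigurationError(f"n_grid must be >= 16, got {self.n_grid}")
        if not self.perimeter > 0:
            raise ConfigurationError("perimeter must be positive")

    @property
    def ds(self) -> float:
        return self.perimeter / self.n_grid

    @property
    def site_centers(self) -> np.ndarray:
        return (np.arange(self.n_grid) + 0.5) * self.ds

    def wrap(self, s):
        """Map arclength(s) into [0, perimeter)."""
        return np.mod(s, self.perimeter)

    def site_of(self, s):
        """Grid site index containing arclength position ``s``."""
        return np.mod(np.floor(np.asarray(s) / self.ds).astype(np.int64), self.n_grid)

    def theta_deg(self, s):
        """Angle (degrees, CCW from horizontal) of arclength position ``s``."""
        return np.mod(np.asarray(s) / self.perimeter * 360.0, 360.0)

    def s_of_theta_deg(self, theta):
        """Arclength position of an angle given in degrees."""
        return np.mod(np.asarray(theta), 360.0) / 360.0 * self.perimeter

    def circular_distance(self, s1, s2):
        """Shortest arclength distance between two membrane points."""
        d = np.abs(np.mod(np.asarray(s1) - np.asarray(s2), self.perimeter))
        return np.minimum(d, self.perimeter - d)


# Default profile: calibrated so that (a) a single cell spontaneously
# polarizes in well over 90 of 100 seeds by T_end, (b) axes of uncoupled
# cells are isotropic, which fixes the uncoupled-doublet co-alignment
# probability near the geometric 25%, and (c) a junction arc cleared of one
# species by strong unbinding amplification reliably attracts the
# complementary species (see docs/methods.md on the annealing regime).
@dataclass(frozen=True)
class CellParams:
    """Kinetic and network parameters of one cell.

    Rates are per second; lengths are in the arclength units of the domain.

    Attributes
    ----------
    k_on, k_off, k_fb : float
        GTPase membrane association, dissociation and feedback-recruitment
        rates.  ``k_on`` is the total association propensity of one inactive
        molecule when the local weight field is 1 everywhere.
    d_actin : float
        Diffusion coefficient of both actin density fields.
    d_gtpase : float
        Cytosolic diffusion coefficient of the inactive pool.  Used by the
        default explicitly spatial pool (``spatial_pool=True``); ignored in
        the well-mixed (fast-diffusion limit) variant.
    alpha : float
        Strength of the GTPase -> actin growth coupling (per molecule in
        the local neighborhood).
    m0 : float
        Competition strength between the branched and bundled networks.
    beta_rev : float
        Reverse coupling: the local association weight of Rac (Rho) is
        ``1 + beta_rev * A`` (``1 + beta_rev * B``).
    n_rac, n_rho : int
        Total molecule numbers per species (bound + inactive).
    c_crit : float
        Density threshold defining a polarized network region.
    inhibition_radius : float
        Arclength half-width of the neighborhood used for mutual
        inhibition, feedback recruitment placement and local counts.
    dt, t_end : float
        Hybrid time step and simulated duration (seconds).
    kon_rac_factor, kon_rho_factor : float
        Whole-domain baseline multipliers of the association rates, used
        for the cell-to-cell variability experiments.
    eps_a0, eps_b0 : float
        Whole-domain additive growth-rate offsets for the branched and
        bundled networks (variability experiments).
    init_bound_fraction : float
        Fraction of each species placed on the membrane at t = 0.
    init_actin_noise : float
        Relative amplitude of the uniform perturbation around the
        homogeneous unit actin baseline at t = 0.
    spatial_pool : bool
        If True (default), inactive molecules carry positions and diffuse
        along a thin cytosolic shell with coefficient ``d_gtpase``, binding
        at the local rate; if False the pool is well mixed.
    eps_cap : float
        Saturation bound on the magnitude of the junction growth-rate
        modifications; concentration-dependent reciprocal excitation is
        linearly unstable without a ceiling on the growth rates.
    """

    k_on: float = 4.8
    k_off: float = 4.0
    k_fb: float = 0.2
    d_actin: float = 0.1
    d_gtpase: float = 10.0
    alpha: float = 0.15
    m0: float = 2.0
    beta_rev: float = 1.5
    n_rac: int = 100
    n_rho: int = 100
    c_crit: float = 3.0
    inhibition_radius: float = 0.8
    dt: float = 0.02
    t_end: float = 100.0
    kon_rac_factor: float = 1.0
    kon_rho_factor: float = 1.0
    eps_a0: float = 0.0
    eps_b0: float = 0.0
    init_bound_fraction: float = 0.10
    init_actin_noise: float = 0.01
    spatial_pool: bool = True
    eps_cap: float = 5.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_fb", "d_actin", "d_gtpase", "alpha",
                     "m0", "beta_rev", "c_crit", "kon_rac_factor",
                     "kon_rho_factor"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.n_rac <= 0 or self.n_rho <= 0:
            raise ConfigurationError("molecule counts must be positive")
        if not (0 < self.init_bound_fraction <= 1):
            raise ConfigurationError("init_bound_fraction must be in (0, 1]")
        if self.dt <= 0 or self.t_end <= 0:
            raise ConfigurationError("dt and t_end must be positive")
        if self.inhibition_radius <= 0:
            raise ConfigurationError("inhibition_radius must be positive")
        # Baseline per-event probabilities must stay well below 1 for the
        # fixed-step Bernoulli sampler; junction-amplified rates are allowed
        # to saturate (an amplified event then fires within one step).
        if self.dt * max(self.k_on, self.k_off, self.k_fb) >= 1.0:
            raise ConfigurationError("dt too large for the baseline event rates")

    def check_pde_stability(self, domain: PeriodicDomain) -> None:
        ds = domain.ds
        if self.d_actin > 0 and self.dt > ds * ds / (4.0 * self.d_actin):
            raise ConfigurationError(
                f"dt={self.dt} violates the diffusion stability bound "
                f"ds^2/(4 D) = {ds * ds / (4.0 * self.d_actin):.4g}"
            )

    def replace(self, **kwargs) -> "CellParams":
        return dataclasses.replace(self, **kwargs)


def params_default() -> CellParams:
    """The shipped calibration profile (see docs/methods.md)."""
    return CellParams()
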