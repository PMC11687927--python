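"""Polarity-axis extraction and arrangement classification.

The front-rear axis of a cell points from the cell center to the circular
midpoint of the largest contiguous arc where the branched network A
exceeds the threshold ``c_crit``; the cell counts as polarized only if the
bundled network B also exceeds the threshold somewhere.  Doublet
arrangements are classified into four mutually exclusive primary labels
(co-alignment, collision, misalignment, non-polarized) plus a
supracellular (leader-follower) overlay; square quadruplets additionally
admit paired and circular (CW/CCW) alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import kernels
from .domain import PeriodicDomain
from .junctions import JunctionMap

__all__ = [
    "PolarityAxis", "OutcomeLabel",
    "CO_ALIGNMENT", "COLLISION", "MISALIGNMENT", "NON_POLARIZED",
    "CIRCULAR_CW", "CIRCULAR_CCW", "PAIRED",
    "compute_axis", "classify_doublet", "classify_supracellular",
    "classify_doublet_full", "classify_quadruplet", "time_to_polarize",
    "circular_difference",
]

CO_ALIGNMENT = "co-alignment"
COLLISION = "collision"
MISALIGNMENT = "misalignment"
NON_POLARIZED = "non-polarized"
CIRCULAR_CW = "circular-CW"
CIRCULAR_CCW = "circular-CCW"
PAIRED = "paired"

# Cone conventions: an "opening" is the total sector width, so the test is
# |angle - center| < width / 2.
COALIGN_DIFF_DEG = 45.0     # pairwise axis difference for co-alignment
COLLISION_CONE_DEG = 36.0   # total cone about the junction direction
SUPRA_CONE_DEG = 45.0       # total cone for the leader/follower tests


@dataclass(frozen=True)
class PolarityAxis:
    """Front direction of one cell; undefined when the cell is unpolarized."""

    defined: bool
    angle_deg: float = float("nan")

    def __post_init__(self):
        if self.defined:
            object.__setattr__(self, "angle_deg", self.angle_deg % 360.0)

    @classmethod
    def from_angle(cls, angle) -> "PolarityAxis":
        angle = float(angle) if angle is not None else float("nan")
        return cls(bool(np.isfinite(angle)), angle)


@dataclass(frozen=True)
class OutcomeLabel:
    primary: str
    supracellular: bool = False


def _angle(ax: Union[PolarityAxis, float, None]) -> float:
    if isinstance(ax, PolarityAxis):
        return ax.angle_deg if ax.defined else float("nan")
    return float(ax) if ax is not None else float("nan")


def circular_difference(a: float, b: float) -> float:
    """Unsigned circular difference of two angles in degrees, in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def _in_cone(angle: float, center: float, total_width: float) -> bool:
    return circular_difference(angle, center) < total_width / 2.0


def compute_axis(fields, c_crit: float,
                 domain: Optional[PeriodicDomain] = None) -> PolarityAxis:
    """Polarity axis from the actin fields of one cell.

    Accepts an ``ActinFields`` or a plain ``(A, B)`` pair of grid arrays.
    Undefined when either network never exceeds ``c_crit`` (or A is
    supra-threshold everywhere, leaving no localized front).
    """
    if hasattr(fields, "a"):
        a, b = fields.a, fields.b
    else:
        a, b = fields
    ang = kernels.axis_from_fields(np.asarray(a, float), np.asarray(b, float),
                                   float(c_crit))
    return PolarityAxis.from_angle(ang)


def _doublet_dirs(jmap: Optional[JunctionMap]):
    if jmap is None:
        return 0.0, 180.0
    j = jmap.junctions[0]
    return j.center_a_deg, j.center_b_deg


def classify_doublet(axis1, axis2, jmap: Optional[JunctionMap] = None) -> str:
    """Primary arrangement label of a cell pair.

    Collision requires both axes inside the 36-degree cone about their
    junction directions (both fronts toward the junction); co-alignment
    requires a circular axis difference below 45 degrees; misalignment is
    the polarized remainder.  Collision is checked first (the cones make
    the two geometrically exclusive).
    """
    a1, a2 = _angle(axis1), _angle(axis2)
    if not (np.isfinite(a1) and np.isfinite(a2)):
        return NON_POLARIZED
    d1, d2 = _doublet_dirs(jmap)
    if _in_cone(a1, d1, COLLISION_CONE_DEG) and _in_cone(a2, d2, COLLISION_CONE_DEG):
        return COLLISION
    if circular_difference(a1, a2) < COALIGN_DIFF_DEG:
        return CO_ALIGNMENT
    return MISALIGNMENT


def classify_supracellular(axis1, axis2,
                           jmap: Optional[JunctionMap] = None) -> bool:
    """Leader-follower overlay flag for a cell pair.

    True when for either role assignment the leader's axis points away
    from its junction (outside the 45-degree contact cone) while the
    follower's axis points toward the leader's center within a 45-degree
    opening.  For the doublet the follower-to-leader direction is the
    follower's junction direction.
    """
    a1, a2 = _angle(axis1), _angle(axis2)
    if not (np.isfinite(a1) and np.isfinite(a2)):
        return False
    d1, d2 = _doublet_dirs(jmap)
    for leader_axis, leader_dir, follower_axis, follower_dir in (
            (a1, d1, a2, d2), (a2, d2, a1, d1)):
        if (not _in_cone(leader_axis, leader_dir, SUPRA_CONE_DEG)
                and _in_cone(follower_axis, follower_dir, SUPRA_CONE_DEG)):
            return True
    return False


def classify_doublet_full(axis1, axis2,
                          jmap: Optional[JunctionMap] = None) -> OutcomeLabel:
    return OutcomeLabel(classify_doublet(axis1, axis2, jmap),
                        classify_supracellular(axis1, axis2, jmap))


_SQUARE_CYCLE = (0, 1, 2, 3)  # clockwise order of the square layout


def _tangential_dirs(jmap: JunctionMap, clockwise: bool):
    centers = jmap.cell_centers
    cyc = _SQUARE_CYCLE if clockwise else _SQUARE_CYCLE[::-1]
    dirs = np.empty(4)
    for k, c in enumerate(cyc):
        nxt = cyc[(k + 1) % 4]
        v = centers[nxt] - centers[c]
        dirs[c] = math.degrees(math.atan2(v[1], v[0])) % 360.0
    return dirs


def classify_quadruplet(axes: Sequence, jmap: JunctionMap) -> str:
    """Arrangement label of a 4-cell group.

    Square layout: non-polarized if any axis is undefined; co-alignment if
    all pairwise differences are below 45 degrees; circular-CW/CCW if every
    axis lies within 45 degrees of the tangential direction of a common
    rotation sense; paired if some split into two disjoint pairs is
    internally co-aligned with pair means at least 45 degrees apart;
    misalignment otherwise.  Chain layout: co-alignment / non-polarized /
    misalignment by the same pairwise rule.
    """
    if len(axes) != 4:
        raise ValueError(f"expected 4 axes, got {len(axes)}")
    ang = np.array([_angle(a) for a in axes])
    if not np.all(np.isfinite(ang)):
        return NON_POLARIZED
    pair_diff = np.array([[circular_difference(x, y) for y in ang] for x in ang])
    if np.all(pair_diff < COALIGN_DIFF_DEG):
        return CO_ALIGNMENT
    if jmap.layout == "chain4":
        return MISALIGNMENT
    for clockwise, label in ((True, CIRCULAR_CW), (False, CIRCULAR_CCW)):
        tang = _tangential_dirs(jmap, clockwise)
        if all(circular_difference(ang[c], tang[c]) < COALIGN_DIFF_DEG
               for c in range(4)):
            return label
    for (i, j), (k, l) in (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))):
        if (pair_diff[i, j] < COALIGN_DIFF_DEG
                and pair_diff[k, l] < COALIGN_DIFF_DEG):
            m1 = _circular_mean(ang[i], ang[j])
            m2 = _circular_mean(ang[k], ang[l])
            if circular_difference(m1, m2) >= COALIGN_DIFF_DEG:
                return PAIRED
    return MISALIGNMENT


def _circular_mean(a: float, b: float) -> float:
    x = math.cos(math.radians(a)) + math.cos(math.radians(b))
    y = math.sin(math.radians(a)) + math.sin(math.radians(b))
    return math.degrees(math.atan2(y, x)) % 360.0


def time_to_polarize(axis_series, dt_out: float,
                     window: int = 100,
                     max_step_deg: float = 15.0) -> Optional[float]:
    """Earliest time at which the polarity axis settles.

    Returns the first time ``t*`` such that the axis is defined throughout
    ``[t*, t* + window]`` output steps and every consecutive angular change
    is below ``max_step_deg`` (pi/12 radians by default); None if the
    criterion is never met within the series.
    """
    ang = np.array([_angle(a) for a in axis_series], float)
    n = len(ang)
    if n < window + 1:
        return None
    diffs = np.array([circular_difference(ang[i], ang[i + 1])
                      if np.isfinite(ang[i]) and np.isfinite(ang[i + 1])
                      else np.inf
                      for i in range(n - 1)])
    good = diffs < max_step_deg
    run_start = None
    run_len = 0
    for i in range(len(good)):
        if good[i]:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= window:
                return run_start * dt_out
        else:
            run_len = 0
    return None
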