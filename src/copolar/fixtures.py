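"""Synthetic axis-angle tracks for classifier-only tests.

Each scenario constructs per-cell axis time series that satisfy a named
arrangement label by construction (jitter is kept inside the decision
margins), so the classifiers can be unit-tested without running the
simulator.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .domain import ConfigurationError
from .junctions import build_junction_map
from .metrics import _tangential_dirs

__all__ = ["generate_axis_fixtures", "SCENARIOS"]

SCENARIOS = ("coalign", "collide", "misalign", "supracellular",
             "paired4", "circular4_cw", "circular4_ccw", "nonpolar")

_LAYOUT = {
    "coalign": "doublet", "collide": "doublet", "misalign": "doublet",
    "supracellular": "doublet", "nonpolar": "doublet",
    "paired4": "square4", "circular4_cw": "square4", "circular4_ccw": "square4",
}


def _base_angles(scenario: str, rng: np.random.Generator) -> np.ndarray:
    if scenario == "coalign":
        # common direction, pairwise difference < 45 by construction
        mean = rng.uniform(0.0, 360.0)
        return np.array([mean, mean + rng.uniform(-15.0, 15.0)])
    if scenario == "collide":
        # both fronts toward the junction, inside the 36-degree cone
        return np.array([rng.uniform(-10.0, 10.0),
                         180.0 + rng.uniform(-10.0, 10.0)])
    if scenario == "misalign":
        # perpendicular and opposed: fails both the difference and cone tests
        a = rng.uniform(60.0, 120.0)
        return np.array([a, a + 180.0])
    if scenario == "supracellular":
        # leader (cell 1) away from its junction at 180, follower (cell 0)
        # toward the leader (near 0): also co-aligned
        lead = rng.uniform(-12.0, 12.0)
        return np.array([rng.uniform(-12.0, 12.0), 360.0 + lead])
    if scenario == "paired4":
        a = rng.uniform(0.0, 360.0)
        j = rng.uniform(-10.0, 10.0, 4)
        return np.array([a + j[0], a + j[1], a + 120.0 + j[2], a + 120.0 + j[3]])
    if scenario in ("circular4_cw", "circular4_ccw"):
        jmap = build_junction_map("square4")
        tang = _tangential_dirs(jmap, clockwise=scenario.endswith("_cw"))
        return tang + rng.uniform(-15.0, 15.0, 4)
    if scenario == "nonpolar":
        return np.array([np.nan, rng.uniform(0.0, 360.0)])
    raise ConfigurationError(f"unknown scenario {scenario!r}")


def generate_axis_fixtures(scenario: str, n: int = 10, seed: int = 0,
                           n_steps: int = 120, jitter_deg: float = 5.0,
                           dt_out: float = 0.5,
                           path: Optional[str] = None) -> pd.DataFrame:
    """Synthetic axis tracks guaranteed to classify as ``scenario``.

    Returns a tidy frame (track, time, cell, angle_deg, defined); when
    ``path`` is given it is also written as CSV.  The final-time angles of
    each track satisfy the scenario's label under the classifier
    definitions; earlier samples add small jitter so the tracks also
    exercise the settling-time machinery.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; options {SCENARIOS}")
    rng = np.random.default_rng(seed)
    rows = []
    layout = _LAYOUT[scenario]
    n_cells = 2 if layout == "doublet" else 4
    for track in range(n):
        base = np.mod(_base_angles(scenario, rng), 360.0)
        for step in range(n_steps):
            t = step * dt_out
            # jitter shrinks to zero at the end so the final state is exact
            fade = max(0.0, 1.0 - step / (n_steps * 0.75))
            for c in range(n_cells):
                ang = base[c]
                if np.isfinite(ang):
                    ang = (ang + fade * rng.uniform(-jitter_deg, jitter_deg)) % 360.0
                rows.append({"track": track, "time": t, "cell": c,
                             "angle_deg": ang,
                             "defined": bool(np.isfinite(ang))})
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
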