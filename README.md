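# copolar

A hybrid stochastic / reaction–diffusion simulator of collective
front–rear polarization in small cell groups, for quantitative cell
biologists studying how neighboring cells coordinate their polarity axes
before collective migration.

Each model cell is a 1D periodic membrane carrying two antagonistic Rho
GTPases — Rac (front) and Rho (rear) — as stochastic particles that bind,
unbind and recruit with mutual inhibition, coupled to two competing
F-actin density fields: branched protrusive `A(s,t)` and bundled
contractile `B(s,t)`,

    ∂A/∂t = A (1 + α·n_Rac + ε_A) − A² − m₀AB + DΔA
    ∂B/∂t = B (1 + α·n_Rho + ε_B) − B² − m₀AB + DΔB

with the reverse coupling `k_on ∝ (1 + β·A)` (Rac) and `(1 + β·B)` (Rho).
The bidirectional feedback makes single cells break symmetry
spontaneously; a cell's front is the midpoint of the arc where `A`
exceeds a threshold `C_crit`.

Cells in doublets, 4-cell chains, or 4-cell squares interact only on
junction arcs covering 25% of each perimeter, through:

* amplification `γ ≥ 1` of GTPase binding/unbinding rates (optionally
  proportional to the neighbor's local molecule count),
* additive actin growth modifications `ε` (constant or proportional to
  the neighbor's densities at the juxtaposed membrane point),
* external stimuli that replace a cell's binding rates by fixed
  complementary spatial profiles, with mid-run switching and
  neutralization.

Final arrangements are classified (co-alignment / collision /
misalignment / non-polarized, a supracellular leader–follower overlay,
and paired / circular rotation for squares), and screening utilities
enumerate coupling grids and tabulate outcome probabilities with Wilson
confidence intervals.  The headline result reproduced by the default
calibration: only *asymmetric* junction regulation — complementary
GTPase kinetics across the junction, or reciprocal excitation of
complementary actin networks — drives doublet co-alignment above 70%,
while every symmetric coupling fails.

## Worked example

```python
from copolar import (GroupConfig, build_junction_map, classify_doublet_full,
                     motif_regulations, simulate_group, time_to_polarize)

jmap = build_junction_map("doublet")
coupling = motif_regulations("asym_bind_complementary", jmap, gamma=1000.0)

counts = {}
for seed in range(20):
    traj = simulate_group(GroupConfig(layout="doublet",
                                      rate_regulation=coupling), seed)
    a0, a1 = traj.final_axes()
    label = classify_doublet_full(a0, a1, traj.jmap)
    counts[label.primary] = counts.get(label.primary, 0) + 1
```

prints, for the first seeds,

```
seed 0: axes = (  15.0,    1.9) deg -> co-alignment + supracellular, cell 0 settles at t = 3.5 s
seed 1: axes = ( 356.2,  350.6) deg -> co-alignment + supracellular, cell 0 settles at t = 4.4 s
outcome probabilities over 20 realizations:
  co-alignment   1.00
median settling time of cell 0: 3.3 s
```

With Rac binding amplified 1000× at the junction in the left cell and Rho
binding in the right cell, the left cell's front is pulled onto the
junction and the right cell's rear onto its junction, so both axes point
along the +x direction (angles near 0°/360°): the doublet co-aligns in
essentially every realization, against ~25% for an uncoupled pair.  Axis
angles are quantized to the 96-site membrane grid (1.875° steps), which
is why distinct realizations can report identical angles.

The same machinery runs from the shell:

```bash
copolar batch --config screen.yaml --out results/batch
copolar screen --config screen.yaml --grid structural --out results/screen
copolar fixtures --scenario circular4_cw --out tracks.csv
```

## Layout

- `src/copolar/domain.py` — membrane geometry, parameter profile
- `src/copolar/kernels.py` — numba stepping core
- `src/copolar/model.py` — cell state, stepping operations, group runs
- `src/copolar/junctions.py` — junction maps, couplings, stimuli, motifs
- `src/copolar/metrics.py` — axis extraction and arrangement classifiers
- `src/copolar/screening.py` — coupling grids and probability screens
- `src/copolar/config.py`, `io.py`, `fixtures.py`, `cli.py` — run configs,
  serialization, synthetic classifier fixtures, command line
- `docs/methods.md` — model description, parameter choices, limitations
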