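# Model and methods

`copolar` simulates spontaneous and stimulus-driven front–rear
polarization of one, two, or four cells coupled through intercellular
junctions, and screens junction couplings by the probability of collective
arrangements of the polarity axes.

## The single-cell polarity circuit

Each cell is a static circle; its membrane (plus a thin cytosolic shell)
is a 1D periodic arclength domain of length `L` discretized into `n_grid`
sites.  Two coupled circuits evolve on it:

**Biochemical circuit (stochastic particles).**  Each of the two
antagonistic Rho-family GTPases — Rac (front marker) and Rho (rear
marker) — is a population of `N` molecules that cycle between a
membrane-bound active state and an inactive cytosolic state:

* *binding*: an inactive molecule binds at the local rate
  `k_on (1 + β·A)` for Rac, `k_on (1 + β·B)` for Rho — the reverse
  coupling that makes the association affinity track the respective
  actin network;
* *unbinding*: a bound molecule dissociates at rate `k_off`;
* *feedback recruitment*: each bound molecule recruits an inactive
  same-species molecule to a position within the inhibition radius `r`
  at rate `k_fb`;
* *mutual inhibition*: a binding or recruitment event whose target site
  has at least one opposite-species molecule within `r` is vetoed with
  probability `veto_prob`.

Events are sampled with fixed-step Bernoulli draws
(`p = 1 − exp(−rate·dt)`) synchronized with the PDE step; per-step
probabilities of the baseline rates stay below ~0.1.  Mass is conserved
exactly: `bound + inactive = N` at every step by construction.

**Structural circuit (reaction–diffusion fields).**  Densities of the
branched protrusive network `A(s,t)` and the contractile bundled network
`B(s,t)` obey

    ∂A/∂t = A (1 + α n_Rac + ε_A) − A² − m₀ A B + D ΔA
    ∂B/∂t = B (1 + α n_Rho + ε_B) − B² − m₀ A B + D ΔB

with `n_Rac`, `n_Rho` the local bound counts within `r`, competition
strength `m₀ > 1` (locally exclusive networks), and junction growth
modifications `ε`.  The scheme is explicit Euler with second-order central
differences on the periodic grid (`dt ≤ ds²/4D` enforced); negative
overshoot is clamped at zero.

**Inactive pool.**  By default the inactive molecules are explicitly
spatial: they diffuse along the cytosolic shell with coefficient
`d_gtpase` and bind at the local rate at their own position, so molecules
expelled from a membrane region re-enter near it.  This locality is what
lets a junction arc cleared of one species (by strong unbinding
amplification) recruit the complementary species and anchor the axis —
the mechanism behind the unbinding-based couplings.  A well-mixed pool
(`spatial_pool=False`) is available as the fast-cytosolic-diffusion limit.

**Soft mutual inhibition (`veto_prob = 0.7` by default).**  With a hard
veto (probability 1), opposite-species territories freeze wherever they
first nucleate: interfaces between the Rac/A and Rho/B domains are
absorbing stalemates, cleared junction arcs never attract the
complementary species, and the per-cell axis distribution under junction
couplings stays ~40–60° wide.  A leaky veto keeps segregation (the
β-feedback and network competition maintain exclusive territories) but
makes interfaces mobile, so over the 100 s horizon the arc pair anneals
onto the configuration favored by the junction: the measured probability
of the axis falling within 45° of a cleared junction rises from ~0.6
(hard) to ~1.0 (soft).  The hard veto remains available
(`GroupConfig(veto_prob=1.0)`).

## Parameter profile

No reference parameter table ships with the package; the defaults are a
calibration profile fixed once against three behaviors of the circuit:
(a) a single cell spontaneously polarizes in ≥ 90/100 seeds by `t_end`,
(b) the axis of an uncoupled cell is isotropic, which pins uncoupled
doublet co-alignment near the geometric 25%, and (c) strong asymmetric
junction regulation of the GTPases orients cells reliably (the screen's
qualitative shape).

| parameter | default | meaning |
|---|---|---|
| `perimeter` | 10 a.u. | membrane length |
| `n_grid` | 96 | grid sites; a 25% junction arc is an even 24 sites and centers exactly on its facing angle |
| `n_rac`, `n_rho` | 100 | molecules per species |
| `k_on` | 4.8 s⁻¹ | association propensity per inactive molecule at unit weight |
| `k_off` | 4.0 s⁻¹ | dissociation rate |
| `k_fb` | 0.2 s⁻¹ | feedback recruitment rate |
| `β` (`beta_rev`) | 1.5 | actin → binding-affinity coupling |
| `α` | 0.15 | GTPase → actin growth coupling (per molecule) |
| `m₀` | 2.0 | network competition strength |
| `D` (`d_actin`) | 0.1 a.u.²/s | actin diffusion |
| `d_gtpase` | 10 a.u.²/s | cytosolic pool diffusion |
| `r` (`inhibition_radius`) | 0.8 a.u. | inhibition / recruitment neighborhood |
| `C_crit` | 3.0 | polarization threshold density |
| `dt`, `t_end` | 0.02 s, 100 s | hybrid step and horizon |
| `veto_prob` | 0.7 | softness of mutual inhibition |
| `eps_cap` | 5.0 | saturation of junction growth modifications |

The turnover rates are fast (bound lifetime 0.25 s) relative to the 100 s
horizon; this is deliberate — axis annealing toward the junction-favored
state is driven by molecular turnover, and slower kinetics leave the axis
distribution frozen near its nucleation position.

## Junctions and couplings

A layout (`doublet`, `chain4`, `square4`) places cells on a line or a
square; every adjacent pair shares a junction arc covering `f_cc = 25%` of
each cell's perimeter, centered on the facing direction, with a
mirror map pairing juxtaposed membrane points (orientation-reversing, an
involution).  All couplings act only on these arcs:

* **GTPase rate amplification** — `k_on` or `k_off` of one species
  multiplied by `γ ≥ 1`; concentration-dependent variants use
  `max(1, γ·n)` with `n` the neighbor's count of the source species near
  the mirrored point.  The `max(1, ·)` form keeps `γ ≥ 1` while making
  up-regulation vanish when the source concentration is zero.
* **Actin growth modification** — additive `ε_A`, `ε_B`, constant or
  proportional to the neighbor's densities at the mirrored point
  (`ε_A = ε_AA A' + ε_AB B'`, etc.).  Reciprocal cross-excitation
  (`ε_AB, ε_BA > 0`) is a positive feedback loop across cells with unit
  gain and no intrinsic ceiling; modifications are therefore saturated at
  `±eps_cap` (a physiological bound on growth-rate modulation and a
  numerical safeguard — without it 4-cell squares can diverge).
* **External stimulus** — in the exposed cell the actin-dependent binding
  rates are replaced by fixed complementary spatial profiles: a
  raised-cosine bump (half-width 90°, amplitude 4) peaked at the stimulus
  angle for Rac, its complement for Rho, with a constant pointwise sum.
  Amplitude 4 is the smallest tested value at which a stimulated cell
  polarizes toward the stimulus in essentially every seed.
* **Neutralization** (signal-switch experiments) — when a species fully
  unbinds, 10% of it is rebound at uniform random positions, mirroring
  the initialization rule.
* **Cell variability** — whole-domain baseline factors (e.g. 10× Rac
  binding) or growth offsets per cell; junction factors compose
  multiplicatively on top.

Named motifs apply a pattern at every junction with the junction's
orientation (first cell takes the "cell 1" role): the four asymmetric
GTPase motifs (`asym_bind_complementary`, `asym_unbind_complementary`,
`asym_bind_unbind_rac`, `asym_bind_unbind_rho`), their symmetric
controls, the constant push-n-pull actin coupling, and the
concentration-dependent reciprocal crosstalk.

## Classification

The front–rear axis points from the cell center to the circular midpoint
of the largest contiguous arc where `A > C_crit`; the cell is polarized
only if `B` also exceeds `C_crit` somewhere.  Ties between equally long
arcs break by larger integrated density, then smaller start index.

Doublets: **collision** if both axes lie inside the 36°-total cone about
their junction directions; else **co-alignment** if the circular axis
difference is below 45°; else **misalignment**; **non-polarized** if
either axis is undefined.  The **supracellular** overlay holds when, for
either role assignment, the leader's axis is outside the 45°-total cone
about its junction while the follower's axis is inside the 45°-total cone
toward the leader.  All "openings" are read as total sector widths
(cone = ±half the stated width).

Squares add **circular-CW/CCW** (every axis within 45° of the tangential
direction of a common rotation sense) and **paired** (two disjoint
internally co-aligned pairs whose mean directions differ by ≥ 45°);
precedence is non-polarized → co-alignment → circular → paired →
misalignment.  Chains use the pairwise rule (co-alignment iff all four
axes within 45° of each other).

Classification happens at `t_end`; the settling time of the axis is the
first moment from which 100 consecutive output steps each change the axis
by less than π/12.

In the signal-switch experiment, "polarized toward the signal" means the
final axis lies within the stimulus half-width (±90°) of the new signal
direction — deliberately wider than the 45° pairwise co-alignment
criterion, which is applied on top for the co-alignment-toward-signal
statistic.

## Screening

A screen runs `n_realizations` independent realizations per coupling
configuration (default 100), classifies each final state, and reports
outcome probabilities with Wilson 95% intervals; a coupling is
"successful" at ≥ 70% co-alignment.  Realization `r` always uses the
random substream `(base_seed, r)`, for every configuration, so a neutral
configuration (`γ = 1`, `ε = 0`) reproduces the uncoupled distribution
exactly and screens are resumable and order-independent.  The biochemical
grid enumerates per-cell single-rate amplifications over
`γ ∈ {1, 10, 100, 1000}` (169 combinations, 91 after collapsing mirror
duplicates); the structural grid enumerates `3⁴` constant plus `3⁴`
concentration-dependent growth couplings at magnitude `|ε| = 1` — exactly
162 configurations.

## Randomness and reproducibility

Every realization takes one root seed; each cell consumes an independent
substream spawned from `(root, cell index)`.  Junction terms read the
neighbor's previous-step state, so cells can be updated in any order and
an uncoupled group is *bitwise* identical to independent single-cell runs
with matched substreams (this is asserted in the test suite).

## Problem sizes

Standard experiment sizes used by `scripts/acceptance.py`: 100
realizations for doublet experiments; 50 for quadruplets except the
square crosstalk distribution (100); 30 per configuration for the
81-configuration stimulated structural sweep, where only the maximum over
the sweep is reported.

## What the simulations do and do not show

The generator *is* the study system: all claims are about this model, not
about data from real cells.  The model has a static geometry — no shape
change, membrane mechanics, actin flow, or cell motion — a single pair of
antagonistic GTPases, linear couplings, and junctions of fixed size and
position.  Passing screens therefore demonstrate which junction-coupling
topologies can coordinate polarity in the model's physics; they do not
calibrate rates against any measured cell type, and absolute times (e.g.
settling times) are only meaningful relative to each other.

## Known limitations

* The collision and supracellular statistics are sensitive to the exact
  cone conventions; alternative readings of the sector widths change the
  printed probabilities.
* The mutual-inhibition softness and the stimulus amplitude are
  calibration choices, not measured quantities; qualitative screen
  results are robust across moderate changes, exact percentages are not.
* With the concentration-dependent reciprocal crosstalk the growth
  saturation `eps_cap` bounds a structurally divergent feedback loop;
  conclusions for that family depend on the ceiling being finite, not on
  its exact value.
* The signal-switch repolarization statistics sit on the co-alignment
  cone boundary (the mean axis pair differs by ≈ 45°), so they have wider
  run-to-run variability than the other screens.
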