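"""Numba-compiled core of the hybrid stochastic / reaction-diffusion stepper.

One time step of duration ``dt`` advances, for every cell in the group:

1. membrane-bound GTPase particles (Rac, Rho) with fixed-step Bernoulli
   event sampling (unbind, bind, feedback recruitment, mutual inhibition
   veto), and
2. the branched (A) and bundled (B) actin density fields with an explicit
   Euler step of the competing logistic reaction-diffusion system on the
   periodic grid.

All intercellular terms (junction-amplified rates, growth modifications,
concentration-dependent factors) read the *previous-step* state of the
neighbor cell: fields and local counts for every cell are assembled in a
first phase before any cell is advanced, so the scheme is an explicit
coupling and cells can be updated in any order.  Each cell draws random
numbers from its own generator, which makes an uncoupled group bitwise
identical to independent single-cell runs with matched per-cell seeds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Rate-regulation slots.
SLOT_KON_RAC = 0
SLOT_KON_RHO = 1
SLOT_KOFF_RAC = 2
SLOT_KOFF_RHO = 3

# Status codes returned by run_group.
STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def windowed_counts(pos, nb, n_grid, ds, hw, out):
    """Per-site counts of bound molecules within ``hw`` grid sites.

    ``out[g]`` counts molecules whose containing site lies within
    ``g - hw .. g + hw`` (circular), i.e. the grid-resolution version of a
    count within an arclength radius ``(hw + 0.5) * ds`` of the site center.
    """
    raw = np.zeros(n_grid, np.float64)
    for i in range(nb):
        g = int(pos[i] / ds) % n_grid
        raw[g] += 1.0
    for g in range(n_grid):
        acc = 0.0
        for k in range(-hw, hw + 1):
            acc += raw[(g + k) % n_grid]
        out[g] = acc
    return out


@njit(cache=True)
def bin_counts(pos, nb, n_grid, ds, out):
    """Raw per-site occupancy (no window)."""
    for g in range(n_grid):
        out[g] = 0.0
    for i in range(nb):
        g = int(pos[i] / ds) % n_grid
        out[g] += 1.0
    return out


@njit(cache=True)
def axis_from_fields(A, B, c_crit):
    """Polarity-axis angle (degrees CCW from horizontal) or NaN.

    The axis points from the cell center to the circular midpoint of the
    largest contiguous supra-threshold arc of the branched field A.  It is
    undefined (NaN) when A never exceeds ``c_crit``, when B never exceeds
    ``c_crit``, or when A is supra-threshold on the whole circle (no
    localized front).  Ties between equally long arcs are broken by larger
    integrated density, then by smaller start index.
    """
    n = A.shape[0]
    bmax = B[0]
    for g in range(1, n):
        if B[g] > bmax:
            bmax = B[g]
    if bmax <= c_crit:
        return np.nan
    n_above = 0
    for g in range(n):
        if A[g] > c_crit:
            n_above += 1
    if n_above == 0 or n_above == n:
        return np.nan
    best_len = -1
    best_mass = -1.0
    best_start = -1
    for g in range(n):
        prev = (g - 1) % n
        if A[g] > c_crit and not (A[prev] > c_crit):
            run_len = 0
            mass = 0.0
            i = g
            while A[i % n] > c_crit and run_len < n:
                mass += A[i % n]
                run_len += 1
                i += 1
            if run_len > best_len or (run_len == best_len and mass > best_mass):
                best_len = run_len
                best_mass = mass
                best_start = g
    mid = (best_start + best_len / 2.0) % n
    return mid / n * 360.0


@njit(cache=True)
def actin_pair_step(A, B, cnt_rac, cnt_rho, eps_a, eps_b,
                    alpha, m0, d_actin, dt, ds, Anew, Bnew):
    """One explicit Euler step of the coupled actin equations.

    dA/dt = A (1 + alpha n_Rac + eps_A) - A^2 - m0 A B + D lap A
    dB/dt = B (1 + alpha n_Rho + eps_B) - B^2 - m0 A B + D lap B

    Negative overshoot is clamped at zero.  Returns 0 on success, 1 if a
    non-finite value appeared.
    """
    n = A.shape[0]
    inv_ds2 = 1.0 / (ds * ds)
    ok = True
    for g in range(n):
        gm = (g - 1) % n
        gp = (g + 1) % n
        lap_a = (A[gm] - 2.0 * A[g] + A[gp]) * inv_ds2
        lap_b = (B[gm] - 2.0 * B[g] + B[gp]) * inv_ds2
        da = (A[g] * (1.0 + alpha * cnt_rac[g] + eps_a[g])
              - A[g] * A[g] - m0 * A[g] * B[g] + d_actin * lap_a)
        db = (B[g] * (1.0 + alpha * cnt_rho[g] + eps_b[g])
              - B[g] * B[g] - m0 * A[g] * B[g] + d_actin * lap_b)
        av = A[g] + dt * da
        bv = B[g] + dt * db
        if not (np.isfinite(av) and np.isfinite(bv)):
            ok = False
            av = 0.0
            bv = 0.0
        Anew[g] = av if av > 0.0 else 0.0
        Bnew[g] = bv if bv > 0.0 else 0.0
    return 0 if ok else 1


@njit(cache=True)
def species_update(rng, pos, nb, n_total, konv, kon_tot, koffv, cntw_opp,
                   k_fb, r_inh, ds, n_grid, L, dt, veto_prob,
                   spatial_pool, d_pool):
    """Advance one GTPase species of one cell by one step.

    ``pos`` stores all ``n_total`` molecule positions: bound molecules in
    ``pos[:nb]``, inactive ones in ``pos[nb:]`` (order not meaningful).
    Event order: unbinding, binding from the inactive pool, feedback
    recruitment.  Binding/recruitment targeting a site with at least one
    opposite-species molecule within the inhibition window is vetoed with
    probability ``veto_prob`` (1 = hard veto).  Returns the new bound count.

    With ``spatial_pool`` the inactive molecules diffuse in a thin
    cytosolic shell along the membrane (coefficient ``d_pool``), bind at
    the local per-site rate at their own position, and recruitment draws
    only from the pool within the inhibition radius of the recruiter.
    Otherwise the pool is well mixed: every inactive molecule binds at the
    spatial mean rate and the landing site is drawn proportionally to the
    local rate.
    """
    # --- unbinding (bound molecule joins the pool where it unbinds) ------
    i = 0
    while i < nb:
        g = int(pos[i] / ds) % n_grid
        p = 1.0 - np.exp(-koffv[g] * dt)
        if rng.random() < p:
            nb -= 1
            tmp = pos[i]
            pos[i] = pos[nb]
            pos[nb] = tmp
        else:
            i += 1
    # --- cytosolic diffusion of the inactive pool ------------------------
    if spatial_pool:
        sig = np.sqrt(2.0 * d_pool * dt)
        for i in range(nb, n_total):
            pos[i] = (pos[i] + sig * rng.normal()) % L
    # --- binding ---------------------------------------------------------
    if spatial_pool:
        i = nb
        for i in range(nb, n_total):
            g = int(pos[i] / ds) % n_grid
            p = 1.0 - np.exp(-konv[g] * dt)
            if rng.random() < p:
                if cntw_opp[g] >= 1.0:
                    if veto_prob >= 1.0 or rng.random() < veto_prob:
                        continue
                tmp = pos[i]
                pos[i] = pos[nb]
                pos[nb] = tmp
                nb += 1
    else:
        n_inact = n_total - nb
        mean_rate = kon_tot / n_grid
        pb = 1.0 - np.exp(-mean_rate * dt)
        for _ in range(n_inact):
            if rng.random() < pb:
                u = rng.random() * kon_tot
                g = 0
                acc = konv[0]
                while acc < u and g < n_grid - 1:
                    g += 1
                    acc += konv[g]
                if cntw_opp[g] >= 1.0:
                    if veto_prob >= 1.0 or rng.random() < veto_prob:
                        continue
                pos[nb] = (g + rng.random()) * ds
                nb += 1
    # --- feedback recruitment -------------------------------------------
    n_rec = nb
    pf = 1.0 - np.exp(-k_fb * dt)
    for i in range(n_rec):
        if rng.random() < pf:
            if nb >= n_total:
                continue  # inactive pool exhausted: event silently skipped
            target = (pos[i] + rng.uniform(-r_inh, r_inh)) % L
            g = int(target / ds) % n_grid
            if cntw_opp[g] >= 1.0:
                if veto_prob >= 1.0 or rng.random() < veto_prob:
                    continue
            if spatial_pool:
                # nearest pool molecule within the inhibition radius
                pick = -1
                best = r_inh
                for j in range(nb, n_total):
                    d = abs(pos[j] - pos[i])
                    if d > L - d:
                        d = L - d
                    if d <= best:
                        best = d
                        pick = j
                if pick < 0:
                    continue  # no local supply: event skipped
                pos[pick] = pos[nb]
                pos[nb] = target
                nb += 1
            else:
                pos[nb] = target
                nb += 1
    return nb


@njit(cache=True)
def rebind_fraction(rng, pos, nb, n_total, fraction, L):
    """Place ``round(fraction * n_total)`` molecules uniformly at random."""
    k = int(fraction * n_total + 0.5)
    if k > n_total - nb:
        k = n_total - nb
    for _ in range(k):
        pos[nb] = rng.random() * L
        nb += 1
    return nb


@njit(cache=True)
def run_group(n_steps, dt, ds, n_grid,
              P, NN,
              CF, CG, CS, MC, MI,
              EC, ED,
              st0, st1, scell, sprof,
              neutralize, veto_prob, spatial_pool,
              rngs,
              pos, nb, A, B,
              out_steps, snap_steps, check):
    """Advance a group of coupled cells for ``n_steps`` steps.

    Parameters (array layouts)
    --------------------------
    P : float64[n_cells, 11]
        Per-cell scalars: k_on, k_off, k_fb, D, alpha, m0, beta_rev,
        inhibition_radius, c_crit, d_pool, eps_cap.  ``eps_cap`` saturates
        the magnitude of the concentration-dependent growth modifications
        (the reciprocal cross-excitation loop is linearly unstable without
        a physiological ceiling on the growth rates).
    NN : int64[n_cells, 2]
        Total molecules per species.
    CF : float64[n_cells, 4, n_grid]
        Constant multiplicative rate factors per slot (kon Rac, kon Rho,
        koff Rac, koff Rho); includes whole-domain variability factors.
    CG, CS : conc-dependent amplification gamma per slot (0 = none) and
        source species code (0 Rac, 1 Rho, -1 none); source cell is the
        mirror cell.
    MC, MI : int32[n_cells, n_grid]
        Junction mirror map: paired cell and paired site (-1 off junction).
    EC : float64[n_cells, 2, n_grid]
        Constant growth-rate modifications (eps_A, eps_B), incl. any
        whole-domain offsets.
    ED : float64[n_cells, 4, n_grid]
        Concentration-dependent growth coefficients (AA, AB, BA, BB),
        evaluated on the mirror cell's previous-step fields.
    st0, st1, scell, sprof : stimulus intervals [t0, t1), exposed cell and
        absolute binding-rate profiles (Rac, Rho) that *replace* the
        actin-dependent association rates in the exposed cell.
    pos, nb, A, B : in/out state (modified in place).
    out_steps : int64[:]
        Step indices (0 = initial state) at which axis angles are recorded.
    snap_steps : int64[:]
        Step indices at which full field snapshots are stored.

    Returns
    -------
    status, fail_step, fail_cell, axes_deg, snapA, snapB, snapRac, snapRho,
    invariants_ok
    """
    n_cells = A.shape[0]
    n_out = out_steps.shape[0]
    n_snap = snap_steps.shape[0]
    axes = np.full((n_out, n_cells), np.nan)
    snapA = np.zeros((n_snap, n_cells, n_grid))
    snapB = np.zeros((n_snap, n_cells, n_grid))
    snapRac = np.zeros((n_snap, n_cells, n_grid))
    snapRho = np.zeros((n_snap, n_cells, n_grid))
    inv_ok = True

    L = ds * n_grid
    cntw = np.zeros((n_cells, 2, n_grid))
    konF = np.zeros((n_cells, 2, n_grid))
    koffF = np.zeros((n_cells, 2, n_grid))
    kon_tot = np.zeros((n_cells, 2))
    epsA = np.zeros((n_cells, n_grid))
    epsB = np.zeros((n_cells, n_grid))
    Atmp = np.zeros(n_grid)
    Btmp = np.zeros(n_grid)

    i_out = 0
    i_snap = 0
    # record initial state if requested
    while i_out < n_out and out_steps[i_out] == 0:
        for c in range(n_cells):
            axes[i_out, c] = axis_from_fields(A[c], B[c], P[c, 8])
        i_out += 1
    while i_snap < n_snap and snap_steps[i_snap] == 0:
        for c in range(n_cells):
            for g in range(n_grid):
                snapA[i_snap, c, g] = A[c, g]
                snapB[i_snap, c, g] = B[c, g]
            bin_counts(pos[c, 0], nb[c, 0], n_grid, ds, snapRac[i_snap, c])
            bin_counts(pos[c, 1], nb[c, 1], n_grid, ds, snapRho[i_snap, c])
        i_snap += 1

    for step in range(1, n_steps + 1):
        t_prev = (step - 1) * dt
        # ---------------- phase 1: fields from previous-step state -------
        for c in range(n_cells):
            hw = int(P[c, 7] / ds + 0.5)
            windowed_counts(pos[c, 0], nb[c, 0], n_grid, ds, hw, cntw[c, 0])
            windowed_counts(pos[c, 1], nb[c, 1], n_grid, ds, hw, cntw[c, 1])
        for c in range(n_cells):
            k_on = P[c, 0]
            k_off = P[c, 1]
            beta = P[c, 6]
            # active stimulus interval for this cell, if any
            s_idx = -1
            for k in range(st0.shape[0]):
                if scell[k] == c and st0[k] <= t_prev < st1[k]:
                    s_idx = k
                    break
            for sp in range(2):
                tot = 0.0
                for g in range(n_grid):
                    # concentration-dependent junction factor, kon slot
                    cd_on = 1.0
                    slot = sp
                    if CS[c, slot, g] >= 0:
                        src = CS[c, slot, g]
                        f = CG[c, slot, g] * cntw[MC[c, g], src, MI[c, g]]
                        cd_on = f if f > 1.0 else 1.0
                    cd_off = 1.0
                    slot = 2 + sp
                    if CS[c, slot, g] >= 0:
                        src = CS[c, slot, g]
                        f = CG[c, slot, g] * cntw[MC[c, g], src, MI[c, g]]
                        cd_off = f if f > 1.0 else 1.0
                    if s_idx >= 0:
                        base = sprof[s_idx, sp, g]
                    else:
                        dens = A[c, g] if sp == 0 else B[c, g]
                        base = k_on * (1.0 + beta * dens)
                    kv = base * CF[c, sp, g] * cd_on
                    konF[c, sp, g] = kv
                    tot += kv
                    koffF[c, sp, g] = k_off * CF[c, 2 + sp, g] * cd_off
                kon_tot[c, sp] = tot
            # growth-rate modification fields (saturated at +-eps_cap)
            cap = P[c, 10]
            for g in range(n_grid):
                ea = EC[c, 0, g]
                eb = EC[c, 1, g]
                mc = MC[c, g]
                if mc >= 0:
                    mi = MI[c, g]
                    a_nb = A[mc, mi]
                    b_nb = B[mc, mi]
                    ea += ED[c, 0, g] * a_nb + ED[c, 1, g] * b_nb
                    eb += ED[c, 2, g] * a_nb + ED[c, 3, g] * b_nb
                if ea > cap:
                    ea = cap
                elif ea < -cap:
                    ea = -cap
                if eb > cap:
                    eb = cap
                elif eb < -cap:
                    eb = -cap
                epsA[c, g] = ea
                epsB[c, g] = eb
        # ---------------- phase 2: advance each cell ----------------------
        for c in range(n_cells):
            rng = rngs[c]
            r_inh = P[c, 7]
            for sp in range(2):
                nb[c, sp] = species_update(
                    rng, pos[c, sp], nb[c, sp], NN[c, sp],
                    konF[c, sp], kon_tot[c, sp], koffF[c, sp],
                    cntw[c, 1 - sp], P[c, 2], r_inh, ds, n_grid, L, dt,
                    veto_prob, spatial_pool, P[c, 9])
                if neutralize and nb[c, sp] == 0:
                    nb[c, sp] = rebind_fraction(
                        rng, pos[c, sp], 0, NN[c, sp], 0.10, L)
            bad = actin_pair_step(
                A[c], B[c], cntw[c, 0], cntw[c, 1], epsA[c], epsB[c],
                P[c, 4], P[c, 5], P[c, 3], dt, ds, Atmp, Btmp)
            if bad != 0:
                return (STATUS_NONFINITE, step, c, axes,
                        snapA, snapB, snapRac, snapRho, inv_ok)
            for g in range(n_grid):
                A[c, g] = Atmp[g]
                B[c, g] = Btmp[g]
            if check:
                for sp in range(2):
                    if nb[c, sp] < 0 or nb[c, sp] > NN[c, sp]:
                        inv_ok = False
                    for i in range(nb[c, sp]):
                        if not (0.0 <= pos[c, sp, i] < L):
                            inv_ok = False
                for g in range(n_grid):
                    if not (A[c, g] >= 0.0 and B[c, g] >= 0.0):
                        inv_ok = False
        # ---------------- recording --------------------------------------
        while i_out < n_out and out_steps[i_out] == step:
            for c in range(n_cells):
                axes[i_out, c] = axis_from_fields(A[c], B[c], P[c, 8])
            i_out += 1
        while i_snap < n_snap and snap_steps[i_snap] == step:
            for c in range(n_cells):
                for g in range(n_grid):
                    snapA[i_snap, c, g] = A[c, g]
                    snapB[i_snap, c, g] = B[c, g]
                bin_counts(pos[c, 0], nb[c, 0], n_grid, ds, snapRac[i_snap, c])
                bin_counts(pos[c, 1], nb[c, 1], n_grid, ds, snapRho[i_snap, c])
            i_snap += 1
    return (STATUS_OK, -1, -1, axes, snapA, snapB, snapRac, snapRho, inv_ok)
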