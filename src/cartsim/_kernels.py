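"""Fused numba kernels for the simulation inner loop.

One mechanics substep (pair forces via a linked-cell list, CAR T-cell
decisions, explicit position update) and the per-agent substrate
exchange are compiled with numba; the decision logic mirrors the
readable reference implementations in :mod:`cartsim.mechanics` and
:mod:`cartsim.immune`, which the test suite cross-checks against these
kernels. All stochastic decisions inside the kernels draw from numba's
global RNG, seeded once per run from the master seed, so runs are
bitwise reproducible and single-threaded by design.

Status codes: 0 live, 1 apoptotic corpse, 2 necrotic corpse,
3 removed-from-simulation (exhausted T-cell awaiting compaction).
Corpses still interact mechanically; status-3 agents do not.

Counter slots: 0 face clamps, 1 over-large steps (> one radius),
2 kills, 3 exhaustions, 4 coincident-centre events.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "seed_kernel_rng",
    "mech_substep",
    "exchange_substep",
    "diffusion_block",
    "build_cell_list",
]


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


def build_cell_list(pos: np.ndarray, box: np.ndarray, mech_dx: float):
    """Linked-cell list on the mechanics grid (numpy counting sort).

    Returns (cell_start, sorted_idx, shape): agents in flat cell c are
    ``sorted_idx[cell_start[c]:cell_start[c+1]]``.
    """
    shape = np.maximum((box / mech_dx).astype(np.int64), 1)
    if pos.shape[0] == 0:
        ncell = int(shape[0] * shape[1] * shape[2])
        return (
            np.zeros(ncell + 1, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            shape,
        )
    idx = np.clip((pos / mech_dx).astype(np.int64), 0, shape - 1)
    flat = (idx[:, 0] * shape[1] + idx[:, 1]) * shape[2] + idx[:, 2]
    order = np.argsort(flat, kind="stable").astype(np.int64)
    ncell = int(shape[0] * shape[1] * shape[2])
    cell_start = np.searchsorted(flat[order], np.arange(ncell + 1)).astype(np.int64)
    return cell_start, order, shape


@njit(cache=True)
def mech_substep(
    pos,
    vel,
    radius,
    kind,
    status,
    o,
    sqrt_crep,
    c_adh,
    adh_reach,
    d_dir,
    d_r,
    attach,
    attach_clock,
    age,
    lifespan,
    kills,
    n_attackers,
    kills_by_type,
    box,
    dt,
    cell_start,
    sorted_idx,
    mshape,
    mech_dx,
    v_mot,
    bias,
    t_per,
    r_kill,
    t_attach_max,
    r_adh,
    r_la,
    o_min,
    multi_mode,
    uniform_sphere,
    conc_if,
    grid_dx,
    counters,
):
    n = pos.shape[0]
    mx, my, mz = mshape[0], mshape[1], mshape[2]

    # --- pairwise interaction velocities -------------------------------
    # each pair evaluated once (b > a), accumulated antisymmetrically
    for a in range(n):
        vel[a, 0] = 0.0
        vel[a, 1] = 0.0
        vel[a, 2] = 0.0
    for a in range(n):
        if status[a] >= 3:
            continue
        ax = pos[a, 0]
        ay = pos[a, 1]
        az = pos[a, 2]
        ia = int(ax / mech_dx)
        ja = int(ay / mech_dx)
        ka = int(az / mech_dx)
        if ia >= mx:
            ia = mx - 1
        if ja >= my:
            ja = my - 1
        if ka >= mz:
            ka = mz - 1
        for ci in range(ia - 1, ia + 2):
            if ci < 0 or ci >= mx:
                continue
            for cj in range(ja - 1, ja + 2):
                if cj < 0 or cj >= my:
                    continue
                for ck in range(ka - 1, ka + 2):
                    if ck < 0 or ck >= mz:
                        continue
                    flat = (ci * my + cj) * mz + ck
                    for s in range(cell_start[flat], cell_start[flat + 1]):
                        b = sorted_idx[s]
                        if b <= a or status[b] >= 3:
                            continue
                        dx = ax - pos[b, 0]
                        dy = ay - pos[b, 1]
                        dz = az - pos[b, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        rc = radius[a] + radius[b]
                        rm = adh_reach * rc
                        if d2 >= rm * rm:
                            continue
                        d = np.sqrt(d2)
                        if d < 1e-9:
                            # coincident centres: repulsive kick along a
                            # random axis from the seeded kernel RNG
                            ux = np.random.normal()
                            uy = np.random.normal()
                            uz = np.random.normal()
                            un = np.sqrt(ux * ux + uy * uy + uz * uz)
                            if un < 1e-12:
                                ux, uy, uz, un = 1.0, 0.0, 0.0, 1.0
                            f = sqrt_crep[a] * sqrt_crep[b]
                            vel[a, 0] += f * ux / un
                            vel[a, 1] += f * uy / un
                            vel[a, 2] += f * uz / un
                            vel[b, 0] -= f * ux / un
                            vel[b, 1] -= f * uy / un
                            vel[b, 2] -= f * uz / un
                            counters[4] += 1
                            continue
                        f = -c_adh * (1.0 - d / rm) ** 2
                        if d < rc:
                            f += sqrt_crep[a] * sqrt_crep[b] * (1.0 - d / rc) ** 2
                        inv = f / d
                        fx = inv * dx
                        fy = inv * dy
                        fz = inv * dz
                        vel[a, 0] += fx
                        vel[a, 1] += fy
                        vel[a, 2] += fz
                        vel[b, 0] -= fx
                        vel[b, 1] -= fy
                        vel[b, 2] -= fz

    # --- CAR T-cell decisions ------------------------------------------
    nx, ny, nz = conc_if.shape
    for a in range(n):
        if kind[a] != 1 or status[a] != 0:
            continue
        age[a] += dt
        if age[a] > lifespan[a]:
            status[a] = 3  # exhausted: removed from the simulation
            t = attach[a]
            if t >= 0:
                n_attackers[t] -= 1
                attach[a] = -1
            counters[3] += 1
            continue
        t = attach[a]
        if t >= 0:
            if status[t] != 0:  # target already dead: detach, no kill
                attach[a] = -1
                attach_clock[a] = 0.0
                n_attackers[t] -= 1
                continue
            attach_clock[a] += dt
            if multi_mode:
                imm = 1.0
            elif o[t] < o_min:
                imm = 0.0
            else:
                imm = o[t]
            p = r_kill * dt * imm
            if p > 1.0:
                p = 1.0
            if p > 0.0 and np.random.random() < p:
                status[t] = 1  # target enters apoptosis
                kills[a] += 1
                counters[2] += 1
                tt = int(o[t] / 0.5)
                if tt > 3:
                    tt = 3
                kills_by_type[3 - tt] += 1
                attach[a] = -1
                attach_clock[a] = 0.0
                n_attackers[t] -= 1
            elif attach_clock[a] > t_attach_max:
                attach[a] = -1  # timed out without inducing apoptosis
                attach_clock[a] = 0.0
                n_attackers[t] -= 1
            continue  # attached this step: motility off

        # unattached: persistence-timed redraw of the random direction
        if np.random.random() < dt / t_per:
            if uniform_sphere:
                ux = np.random.normal()
                uy = np.random.normal()
                uz = np.random.normal()
                un = np.sqrt(ux * ux + uy * uy + uz * uz)
                if un < 1e-12:
                    ux, uy, uz, un = 1.0, 0.0, 0.0, 1.0
                d_r[a, 0] = ux / un
                d_r[a, 1] = uy / un
                d_r[a, 2] = uz / un
            else:
                theta = np.random.random() * np.pi
                phi = np.random.random() * 2.0 * np.pi
                d_r[a, 0] = np.sin(phi) * np.cos(theta)
                d_r[a, 1] = np.sin(phi) * np.sin(theta)
                d_r[a, 2] = np.cos(phi)

        # immunostimulatory gradient direction (keep previous d if zero)
        gi = int(pos[a, 0] / grid_dx)
        gj = int(pos[a, 1] / grid_dx)
        gk = int(pos[a, 2] / grid_dx)
        if gi >= nx:
            gi = nx - 1
        if gj >= ny:
            gj = ny - 1
        if gk >= nz:
            gk = nz - 1
        ilo = gi - 1 if gi > 0 else gi
        ihi = gi + 1 if gi < nx - 1 else gi
        jlo = gj - 1 if gj > 0 else gj
        jhi = gj + 1 if gj < ny - 1 else gj
        klo = gk - 1 if gk > 0 else gk
        khi = gk + 1 if gk < nz - 1 else gk
        gx = 0.0 if ihi == ilo else (conc_if[ihi, gj, gk] - conc_if[ilo, gj, gk]) / ((ihi - ilo) * grid_dx)
        gy = 0.0 if jhi == jlo else (conc_if[gi, jhi, gk] - conc_if[gi, jlo, gk]) / ((jhi - jlo) * grid_dx)
        gz = 0.0 if khi == klo else (conc_if[gi, gj, khi] - conc_if[gi, gj, klo]) / ((khi - klo) * grid_dx)
        gn = np.sqrt(gx * gx + gy * gy + gz * gz)
        if gn > 1e-12:
            d_dir[a, 0] = gx / gn
            d_dir[a, 1] = gy / gn
            d_dir[a, 2] = gz / gn

        # adhesion attempt: nearest recognisable live cancer cell in R_LA
        best = -1
        bestd = 1e30
        ia = int(pos[a, 0] / mech_dx)
        ja = int(pos[a, 1] / mech_dx)
        ka = int(pos[a, 2] / mech_dx)
        if ia >= mx:
            ia = mx - 1
        if ja >= my:
            ja = my - 1
        if ka >= mz:
            ka = mz - 1
        for ci in range(ia - 1, ia + 2):
            if ci < 0 or ci >= mx:
                continue
            for cj in range(ja - 1, ja + 2):
                if cj < 0 or cj >= my:
                    continue
                for ck in range(ka - 1, ka + 2):
                    if ck < 0 or ck >= mz:
                        continue
                    flat = (ci * my + cj) * mz + ck
                    for s in range(cell_start[flat], cell_start[flat + 1]):
                        b = sorted_idx[s]
                        if kind[b] != 0 or status[b] != 0:
                            continue
                        if (not multi_mode) and o[b] < o_min:
                            continue
                        dx = pos[a, 0] - pos[b, 0]
                        dy = pos[a, 1] - pos[b, 1]
                        dz = pos[a, 2] - pos[b, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 <= r_la * r_la and (
                            d2 < bestd or (d2 == bestd and b < best)
                        ):
                            best = b
                            bestd = d2
        if best >= 0 and np.random.random() < r_adh * dt:
            attach[a] = best
            attach_clock[a] = 0.0
            n_attackers[best] += 1
            # motility switches off on adhesion; no migration this step
        else:
            bx = bias * d_dir[a, 0] + (1.0 - bias) * d_r[a, 0]
            by = bias * d_dir[a, 1] + (1.0 - bias) * d_r[a, 1]
            bz = bias * d_dir[a, 2] + (1.0 - bias) * d_r[a, 2]
            bn = np.sqrt(bx * bx + by * by + bz * bz)
            if bn < 1e-12:
                vel[a, 0] += v_mot * d_r[a, 0]
                vel[a, 1] += v_mot * d_r[a, 1]
                vel[a, 2] += v_mot * d_r[a, 2]
            else:
                vel[a, 0] += v_mot * bx / bn
                vel[a, 1] += v_mot * by / bn
                vel[a, 2] += v_mot * bz / bn

    # --- forward-Euler position update with face clamping --------------
    nclamp = 0
    nbig = 0
    for a in range(n):
        if status[a] >= 3:
            continue
        sx = vel[a, 0] * dt
        sy = vel[a, 1] * dt
        sz = vel[a, 2] * dt
        if sx * sx + sy * sy + sz * sz > radius[a] * radius[a]:
            nbig += 1
        clamped = False
        for ax3 in range(3):
            p = pos[a, ax3] + vel[a, ax3] * dt
            if p < 0.0:
                p = 0.0
                clamped = True
            elif p > box[ax3]:
                p = box[ax3]
                clamped = True
            pos[a, ax3] = p
        if clamped:
            nclamp += 1
    counters[0] += nclamp
    counters[1] += nbig


@njit(cache=True)
def _thomas_coeffs(n, alpha):
    """Forward-elimination coefficients for (I − α·Lap_1D), zero flux."""
    cp = np.empty(n)
    inv = np.empty(n)
    b0 = 1.0 + alpha
    cp[0] = -alpha / b0
    inv[0] = 1.0 / b0
    for i in range(1, n):
        bi = (1.0 + alpha) if i == n - 1 else (1.0 + 2.0 * alpha)
        denom = bi + alpha * cp[i - 1]
        cp[i] = -alpha / denom
        inv[i] = 1.0 / denom
    return cp, inv


@njit(cache=True)
def _thomas_sweep(c, axis, alpha):
    """In-place implicit 1-D diffusion sweep along ``axis`` (zero flux).

    The recurrences run across whole planes of lines at once so the
    innermost loops stay contiguous (SIMD-friendly).
    """
    nx, ny, nz = c.shape
    if axis == 0:
        n = nx
    elif axis == 1:
        n = ny
    else:
        n = nz
    if n == 1 or alpha == 0.0:
        return
    cp, inv = _thomas_coeffs(n, alpha)
    if axis == 0:
        f = c.reshape(nx, ny * nz)
        m = ny * nz
        for q in range(m):
            f[0, q] *= inv[0]
        for i in range(1, n):
            for q in range(m):
                f[i, q] = (f[i, q] + alpha * f[i - 1, q]) * inv[i]
        for i in range(n - 2, -1, -1):
            for q in range(m):
                f[i, q] -= cp[i] * f[i + 1, q]
    elif axis == 1:
        for i in range(nx):
            b = c[i]
            for k in range(nz):
                b[0, k] *= inv[0]
            for j in range(1, n):
                for k in range(nz):
                    b[j, k] = (b[j, k] + alpha * b[j - 1, k]) * inv[j]
            for j in range(n - 2, -1, -1):
                for k in range(nz):
                    b[j, k] -= cp[j] * b[j + 1, k]
    else:
        f = c.reshape(nx * ny, nz)
        for line in range(nx * ny):
            row = f[line]
            row[0] *= inv[0]
            for k in range(1, n):
                row[k] = (row[k] + alpha * row[k - 1]) * inv[k]
            for k in range(n - 2, -1, -1):
                row[k] -= cp[k] * row[k + 1]


@njit(cache=True)
def diffusion_block(
    conc,  # (n_sub, nx, ny, nz), modified in place
    diffusion,  # (n_sub,) µm²/min
    decay,  # (n_sub,) 1/min
    grid_dx,
    dt,
    n_steps,
    dir_start,  # (n_sub+1,) offsets into the flat Dirichlet arrays
    dir_i,
    dir_j,
    dir_k,
    dir_val,
    vox,  # (n_agents, 3) containing voxel of each agent
    kind,
    status,
    rho,
    if_saturation,
    if_secretion,
    o2_uptake_cancer,
    o2_uptake_tcell,
    i_o2,
    i_if,
):
    """``n_steps`` implicit LOD diffusion+decay+exchange substeps.

    Each substep applies the per-agent exchange for Δt/2, the implicit
    decay + LOD diffusion sweeps for Δt, the exchange for the remaining
    Δt/2, then re-clamps Dirichlet voxels. The symmetric (Strang)
    arrangement makes the diffusion↔exchange splitting second order,
    which matters in organoid voxels where the summed uptake rate is
    O(10/min). Mirrors :func:`cartsim.microenvironment.step_diffusion`
    composed with half-step :func:`apply_cell_exchange` calls; fused
    here so the Δt_diff subcycle stays cheap inside the mechanics loop.
    """
    n_sub = conc.shape[0]
    n_agents = vox.shape[0]
    half = 0.5 * dt
    for _ in range(n_steps):
        for pass_ in range(2):
            # half-step exchange (sequential per agent, positivity-safe)
            c_o2 = conc[i_o2]
            c_if = conc[i_if]
            for a in range(n_agents):
                if status[a] != 0:
                    continue
                i = vox[a, 0]
                j = vox[a, 1]
                k = vox[a, 2]
                if kind[a] == 0:
                    c_o2[i, j, k] = c_o2[i, j, k] / (
                        1.0 + half * rho[a] * o2_uptake_cancer
                    )
                    sdt = half * rho[a] * if_secretion
                    c_if[i, j, k] = (c_if[i, j, k] + sdt * if_saturation) / (1.0 + sdt)
                else:
                    c_o2[i, j, k] = c_o2[i, j, k] / (
                        1.0 + half * rho[a] * o2_uptake_tcell
                    )
            if pass_ == 1:
                break
            # full-step implicit decay + LOD diffusion
            for s in range(n_sub):
                c = conc[s]
                lam = decay[s]
                if lam != 0.0:
                    f = 1.0 / (1.0 + lam * dt)
                    for i in range(c.shape[0]):
                        for j in range(c.shape[1]):
                            for k in range(c.shape[2]):
                                c[i, j, k] *= f
                alpha = diffusion[s] * dt / (grid_dx * grid_dx)
                _thomas_sweep(c, 0, alpha)
                _thomas_sweep(c, 1, alpha)
                _thomas_sweep(c, 2, alpha)
        # Dirichlet re-clamp
        for s in range(n_sub):
            c = conc[s]
            for m in range(dir_start[s], dir_start[s + 1]):
                c[dir_i[m], dir_j[m], dir_k[m]] = dir_val[m]


@njit(cache=True)
def exchange_substep(
    conc_o2,
    conc_if,
    vox,
    kind,
    status,
    rho,
    dt,
    if_saturation,
    if_secretion,
    o2_uptake_cancer,
    o2_uptake_tcell,
):
    """Implicit rate-limited secretion/uptake, agents applied sequentially.

    Live cancer cells take up oxygen and secrete the immunostimulatory
    factor toward its saturation value; live CAR T-cells take up oxygen;
    dead cells exchange nothing.
    """
    n = vox.shape[0]
    for a in range(n):
        if status[a] != 0:
            continue
        i = vox[a, 0]
        j = vox[a, 1]
        k = vox[a, 2]
        if kind[a] == 0:
            conc_o2[i, j, k] = conc_o2[i, j, k] / (1.0 + dt * rho[a] * o2_uptake_cancer)
            s = dt * rho[a] * if_secretion
            conc_if[i, j, k] = (conc_if[i, j, k] + s * if_saturation) / (1.0 + s)
        else:
            conc_o2[i, j, k] = conc_o2[i, j, k] / (1.0 + dt * rho[a] * o2_uptake_tcell)
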