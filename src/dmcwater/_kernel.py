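"""Numba kernel: femtosecond equation-of-motion propagation of sub-excitation
electrons in the screened field of their parent cation.

One compiled loop handles an arbitrary batch of electrons; each electron
carries its own RNG seed so results are independent of batch composition and
history ordering.  Velocity-Verlet integration (adaptive dt capped by a
maximum per-step displacement and by the collision rate) is interleaved with
stochastic collisions sampled per step in *time* (p = Λ(E)·v·dt), which stays
well-defined down to v → 0 because the phonon/bath channel's 1/√E cross
section keeps the collision rate finite at thermal energies.

Collision types: 0 elastic (static target, deflection only — screened
Rutherford above 1 eV, isotropic below), 1 phonon/bath (elastic kinematics
against a Maxwellian effective-mass bath particle; this is the thermal
coupling whose stationary electron distribution is Maxwellian at the bath
temperature), 2 vibrational (fixed quantum loss, isotropic redirection).

Thermalisation is a hydration arrest: once the kinetic energy is at thermal
scale (below freeze_e), every collision carries a constant hazard 1/dwell_n
of arrest, and the arrested electron is recorded in equilibrium with the
bath (Maxwellian velocity draw) at its stopping position.

Status codes: 0 active (never returned), 1 thermalised, 2 reached cutoff.
"""

import numpy as np
from numba import njit

STATUS_THERMALISED = 1
STATUS_CUTOFF = 2

_Z23 = 7.42 ** (2.0 / 3.0)          # effective Z^(2/3) for elastic screening
_REST = 510998.95                    # electron rest energy, eV


@njit(cache=True, inline="always")
def _interp_lam(log_e, lam, x):
    if x <= log_e[0]:
        return lam[0]
    if x >= log_e[-1]:
        return lam[-1]
    j = np.searchsorted(log_e, x)
    w = (x - log_e[j - 1]) / (log_e[j] - log_e[j - 1])
    return lam[j - 1] * (1.0 - w) + lam[j] * w


@njit(cache=True, inline="always")
def _pick_channel(log_e, cum, x, u):
    n_ch = cum.shape[1]
    if x <= log_e[0]:
        j0 = 0
        j1 = 0
        w = 0.0
    elif x >= log_e[-1]:
        j0 = len(log_e) - 1
        j1 = j0
        w = 0.0
    else:
        j1 = np.searchsorted(log_e, x)
        j0 = j1 - 1
        w = (x - log_e[j0]) / (log_e[j1] - log_e[j0])
    for c in range(n_ch):
        f = cum[j0, c] * (1.0 - w) + cum[j1, c] * w
        if u <= f:
            return c
    return n_ch - 1


@njit(cache=True, inline="always")
def _rotate(vx, vy, vz, mu, phi):
    """Rotate a vector by polar angle acos(mu) about its own axis."""
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    if norm == 0.0:
        return vx, vy, vz
    ux, uy, uz = vx / norm, vy / norm, vz / norm
    st = np.sqrt(max(0.0, 1.0 - mu * mu))
    cp = np.cos(phi)
    sp = np.sin(phi)
    # orthonormal basis (u, a, b)
    if abs(uz) < 0.99:
        ax, ay, az = -uy, ux, 0.0
    else:
        ax, ay, az = 0.0, -uz, uy
    an = np.sqrt(ax * ax + ay * ay + az * az)
    ax, ay, az = ax / an, ay / an, az / an
    bx = uy * az - uz * ay
    by = uz * ax - ux * az
    bz = ux * ay - uy * ax
    nx = mu * ux + st * (cp * ax + sp * bx)
    ny = mu * uy + st * (cp * ay + sp * by)
    nz = mu * uz + st * (cp * az + sp * bz)
    return norm * nx, norm * ny, norm * nz


@njit(cache=True, inline="always")
def _elastic_mu(E):
    """Screened-Rutherford polar cosine; isotropic below 1 eV."""
    u = np.random.random()
    if E < 1.0:
        return 1.0 - 2.0 * u
    tau = E / _REST
    eta = 1.7e-5 * _Z23 / (tau * (tau + 2.0))
    if eta > 10.0:
        return 1.0 - 2.0 * u
    return 1.0 - 2.0 * eta * u / (1.0 + eta - u)


@njit(cache=True)
def propagate_batch(
    seeds,
    pos,
    vel,
    parent,
    has_parent,
    t_cut,
    snaps_local,
    log_e,
    lam,
    cum,
    kind_code,
    quantum,
    m_e,
    k_coul,
    eps_el,
    amp1,
    tau1,
    amp2,
    tau2,
    kT,
    m_bath,
    r_soft2,
    dt_max,
    disp_max,
    freeze_e,
    dwell_n,
    ke_out,
    t_out,
    status_out,
    snap_ke,
    snap_dist,
):
    n = seeds.shape[0]
    n_snap = snaps_local.shape[1]
    v_bath_sigma = np.sqrt(kT / m_bath)
    # tiny speed floor so an electron born exactly at rest still collides
    # (the 1/√E bath cross section keeps Λ(E)·v finite, but the tabulated σ
    # saturates below the grid minimum); does not perturb the thermal range
    v_floor_sq = 2.0 * 1e-5 / m_e
    mu_b = m_bath / (m_e + m_bath)

    for i in range(n):
        np.random.seed(seeds[i])
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        vx, vy, vz = vel[i, 0], vel[i, 1], vel[i, 2]
        px, py, pz = parent[i, 0], parent[i, 1], parent[i, 2]
        coul = k_coul if has_parent[i] else 0.0
        tc = t_cut[i]
        t = 0.0
        below = 0
        status = STATUS_CUTOFF
        ks = 0  # snapshot pointer
        while ks < n_snap and snaps_local[i, ks] <= 0.0:
            snap_ke[i, ks] = np.nan
            snap_dist[i, ks] = np.nan
            ks += 1

        while t < tc:
            ke = 0.5 * m_e * (vx * vx + vy * vy + vz * vz)
            speed = np.sqrt(vx * vx + vy * vy + vz * vz)
            # dielectric response on the electron's own clock
            eps = eps_el
            if amp1 > 0.0:
                eps += amp1 * (1.0 - np.exp(-t / tau1))
            if amp2 > 0.0:
                eps += amp2 * (1.0 - np.exp(-t / tau2))
            # force from the parent cation (Plummer-softened)
            dx, dy, dz = x - px, y - py, z - pz
            r2 = dx * dx + dy * dy + dz * dz
            ax = ay = az = 0.0
            amag = 0.0
            if coul > 0.0:
                s3 = (r2 + r_soft2) ** 1.5
                f = -coul / (eps * s3)
                ax = f * dx / m_e
                ay = f * dy / m_e
                az = f * dz / m_e
                amag = np.sqrt(ax * ax + ay * ay + az * az)
            # adaptive step; near the parent the step is a fixed fraction of
            # the local dynamical time, a function of position only, which
            # keeps the variable-step Verlet scheme quasi-reversible (energy
            # drift stays bounded over many orbital periods)
            dt = dt_max
            if coul > 0.0:
                s2 = r2 + r_soft2
                t_dyn = np.sqrt(m_e * s2 * np.sqrt(s2) * eps / coul)
                if 0.005 * t_dyn < dt:
                    dt = 0.005 * t_dyn
            else:
                if speed > 0.0 and disp_max / speed < dt:
                    dt = disp_max / speed
            lam_here = _interp_lam(log_e, lam, np.log(max(ke, 1e-12)))
            nu = lam_here * np.sqrt(speed * speed + v_floor_sq)
            if nu > 0.0 and 0.2 / nu < dt:
                dt = 0.2 / nu
            if t + dt > tc:
                dt = tc - t
            if dt <= 0.0:
                break
            # velocity Verlet
            x += vx * dt + 0.5 * ax * dt * dt
            y += vy * dt + 0.5 * ay * dt * dt
            z += vz * dt + 0.5 * az * dt * dt
            t += dt
            if coul > 0.0:
                eps2 = eps_el
                if amp1 > 0.0:
                    eps2 += amp1 * (1.0 - np.exp(-t / tau1))
                if amp2 > 0.0:
                    eps2 += amp2 * (1.0 - np.exp(-t / tau2))
                dx, dy, dz = x - px, y - py, z - pz
                r2 = dx * dx + dy * dy + dz * dz
                s3 = (r2 + r_soft2) ** 1.5
                f = -coul / (eps2 * s3)
                ax2 = f * dx / m_e
                ay2 = f * dy / m_e
                az2 = f * dz / m_e
                vx += 0.5 * (ax + ax2) * dt
                vy += 0.5 * (ay + ay2) * dt
                vz += 0.5 * (az + az2) * dt
            # snapshots
            if ks < n_snap:
                dd = np.sqrt(
                    (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2
                )
                while ks < n_snap and t >= snaps_local[i, ks]:
                    snap_ke[i, ks] = 0.5 * m_e * (
                        vx * vx + vy * vy + vz * vz
                    )
                    snap_dist[i, ks] = dd
                    ks += 1
            # collision?
            if nu > 0.0 and np.random.random() < nu * dt:
                c = _pick_channel(
                    log_e, cum, np.log(max(ke, 1e-12)), np.random.random()
                )
                kc = kind_code[c]
                if kc == 0:
                    ke_now = 0.5 * m_e * (vx * vx + vy * vy + vz * vz)
                    mu = _elastic_mu(ke_now)
                    phi = 2.0 * np.pi * np.random.random()
                    vx, vy, vz = _rotate(vx, vy, vz, mu, phi)
                elif kc == 1:
                    # quasi-elastic bath collision: Maxwellian effective-mass
                    # target, isotropic centre-of-mass scattering
                    wx = v_bath_sigma * np.random.normal()
                    wy = v_bath_sigma * np.random.normal()
                    wz = v_bath_sigma * np.random.normal()
                    gx, gy, gz = vx - wx, vy - wy, vz - wz
                    g = np.sqrt(gx * gx + gy * gy + gz * gz)
                    cmx = (m_e * vx + m_bath * wx) / (m_e + m_bath)
                    cmy = (m_e * vy + m_bath * wy) / (m_e + m_bath)
                    cmz = (m_e * vz + m_bath * wz) / (m_e + m_bath)
                    mu = 1.0 - 2.0 * np.random.random()
                    st = np.sqrt(max(0.0, 1.0 - mu * mu))
                    phi = 2.0 * np.pi * np.random.random()
                    gx = g * st * np.cos(phi)
                    gy = g * st * np.sin(phi)
                    gz = g * mu
                    vx = cmx + mu_b * gx
                    vy = cmy + mu_b * gy
                    vz = cmz + mu_b * gz
                else:
                    ke_now = 0.5 * m_e * (vx * vx + vy * vy + vz * vz)
                    q = quantum[c]
                    if ke_now > q:
                        ke_new = ke_now - q
                        sc = np.sqrt(ke_new / ke_now)
                        mu = 1.0 - 2.0 * np.random.random()
                        st = np.sqrt(max(0.0, 1.0 - mu * mu))
                        phi = 2.0 * np.pi * np.random.random()
                        sp = np.sqrt(vx * vx + vy * vy + vz * vz) * sc
                        vx = sp * st * np.cos(phi)
                        vy = sp * st * np.sin(phi)
                        vz = sp * mu
                # thermalisation arrest: once the electron's kinetic energy
                # is down at thermal scale, each collision carries a constant
                # hazard 1/dwell_n of hydration arrest; the arrested electron
                # is handed over in equilibrium with the bath, i.e. its
                # recorded velocity is a Maxwellian(T) sample (the verified
                # stationary distribution of the collision dynamics)
                ke_now = 0.5 * m_e * (vx * vx + vy * vy + vz * vz)
                if ke_now < freeze_e:
                    if np.random.random() * dwell_n < 1.0:
                        sig_e = np.sqrt(kT / m_e)
                        vx = sig_e * np.random.normal()
                        vy = sig_e * np.random.normal()
                        vz = sig_e * np.random.normal()
                        status = STATUS_THERMALISED
                        break

        pos[i, 0], pos[i, 1], pos[i, 2] = x, y, z
        vel[i, 0], vel[i, 1], vel[i, 2] = vx, vy, vz
        ke_out[i] = 0.5 * m_e * (vx * vx + vy * vy + vz * vz)
        t_out[i] = t
        status_out[i] = status
        dd = np.sqrt((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2)
        while ks < n_snap:
            snap_ke[i, ks] = ke_out[i]
            snap_dist[i, ks] = dd
            ks += 1
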