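"""Compiled inner loop of the Brownian-dynamics pulling simulator.

The kernel mirrors rdmpull.toy_pull_simulator._run_batch step for step
(overdamped Euler, spring force F = k(vt - x), EMA-based rupture detection)
but runs one trajectory at a time in compiled code, which is what makes
multi-decade pulling-speed sweeps tractable on one CPU.  The pure-Python
path and this kernel are cross-checked at T = 0 in the test suite.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def pull_fmax_kernel(
    seeds,  # (n,) uint32 per-trajectory RNG seeds
    r0,  # (3,) well position, nm
    well_shape,  # 0 = gaussian, 1 = smoothed linear ramp
    well_depth,
    well_width,
    well_smoothing,
    cpos,  # (m, 3) fixed charge positions
    cq,  # (m,) fixed charges, e
    qlig,  # bead net charge, e
    mu,  # (3,) bead dipole, e nm
    f_elec,  # Coulomb prefactor / dielectric
    softcore2,  # squared soft-core length, nm^2
    slab_c,  # dipole/interface-field coupling, kJ/mol (0 = no slab)
    slab_n,  # (3,) slab normal, unit
    slab_t2,  # squared slab thickness, nm^2
    slab_w2,  # squared slab lateral width, nm^2
    direction,  # (3,) unit pulling vector
    v,
    k,
    kbt,
    dt,
    gamma,
    n_steps,
    alpha,
    confirm_steps,
    rupture_fraction,
    noise_floor,
    min_peak,
    escape_distance,
):
    n = seeds.shape[0]
    m = cq.shape[0]
    fmax = np.zeros(n)
    ruptured = np.zeros(n, dtype=np.bool_)
    rupture_time = np.full(n, np.nan)
    w2 = well_width * well_width
    noise_scale = np.sqrt(2.0 * kbt * dt / gamma)
    use_dipole = mu[0] != 0.0 or mu[1] != 0.0 or mu[2] != 0.0

    for i in range(n):
        np.random.seed(seeds[i])
        rx, ry, rz = r0[0], r0[1], r0[2]
        ema = 0.0
        peak = 0.0
        fm = 0.0
        below = 0
        t = 0.0
        for step in range(n_steps + 1):
            dx0 = rx - r0[0]
            dy0 = ry - r0[1]
            dz0 = rz - r0[2]
            x = dx0 * direction[0] + dy0 * direction[1] + dz0 * direction[2]
            f = k * (v * t - x)
            ema += alpha * (f - ema)
            if ema > peak:
                peak = ema
            if ema > fm:
                fm = ema
            thr = rupture_fraction * peak
            if thr < noise_floor:
                thr = noise_floor
            if ema < thr and peak > min_peak and x > escape_distance:
                below += 1
            else:
                below = 0
            if below >= confirm_steps:
                ruptured[i] = True
                rupture_time[i] = t
                break
            if step == n_steps:
                break

            # gradient of the binding well
            s2 = dx0 * dx0 + dy0 * dy0 + dz0 * dz0
            if well_shape == 1:
                eps = well_smoothing
                s = np.sqrt(s2 + eps * eps)
                sig1 = 0.5 * (1.0 + np.tanh(0.5 * s / eps))
                sig2 = 0.5 * (1.0 + np.tanh(0.5 * (s - well_width) / eps))
                pref = well_depth / well_width * (sig1 - sig2) / s
            else:
                pref = well_depth / w2 * np.exp(-s2 / (2.0 * w2))
            gx = pref * dx0
            gy = pref * dy0
            gz = pref * dz0
            for j in range(m):
                ax = rx - cpos[j, 0]
                ay = ry - cpos[j, 1]
                az = rz - cpos[j, 2]
                d2 = ax * ax + ay * ay + az * az + softcore2
                d = np.sqrt(d2)
                d3 = d2 * d
                if qlig != 0.0:
                    cc = f_elec * qlig * cq[j] / d3
                    gx -= cc * ax
                    gy -= cc * ay
                    gz -= cc * az
                if use_dipole:
                    proj = mu[0] * ax + mu[1] * ay + mu[2] * az
                    d5 = d3 * d2
                    c1 = f_elec * cq[j] / d3
                    c2 = 3.0 * f_elec * cq[j] * proj / d5
                    gx -= c1 * mu[0] - c2 * ax
                    gy -= c1 * mu[1] - c2 * ay
                    gz -= c1 * mu[2] - c2 * az

            if slab_c != 0.0:
                zn = dx0 * slab_n[0] + dy0 * slab_n[1] + dz0 * slab_n[2]
                px = dx0 - zn * slab_n[0]
                py = dy0 - zn * slab_n[1]
                pz = dz0 - zn * slab_n[2]
                rho2 = px * px + py * py + pz * pz
                xs = slab_c * np.exp(-zn * zn / (2.0 * slab_t2) - rho2 / (2.0 * slab_w2))
                gx += xs * (zn / slab_t2 * slab_n[0] + px / slab_w2)
                gy += xs * (zn / slab_t2 * slab_n[1] + py / slab_w2)
                gz += xs * (zn / slab_t2 * slab_n[2] + pz / slab_w2)

            fx = -gx + f * direction[0]
            fy = -gy + f * direction[1]
            fz = -gz + f * direction[2]
            scale = dt / gamma
            if kbt > 0.0:
                rx += fx * scale + noise_scale * np.random.standard_normal()
                ry += fy * scale + noise_scale * np.random.standard_normal()
                rz += fz * scale + noise_scale * np.random.standard_normal()
            else:
                rx += fx * scale
                ry += fy * scale
                rz += fz * scale
            t += dt
        fmax[i] = fm
    return fmax, ruptured, rupture_time
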