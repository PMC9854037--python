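"""Numba transport kernel: analog photon Monte Carlo with kerma scoring.

One scalar history loop compiled with numba.  Geometry is the nested-cylinder
source assembly (core / capsule / proximal cable stub) centered in either a
water sphere or an air cube.  Free paths are sampled region by region with
exact distance-to-boundary ray tracing (the exponential free path is
memoryless, so resampling at each boundary crossing is exact).  Collision
kerma is scored with a track-length estimator over the medium segments that
intersect the cylindrical ring cells.

Interactions: Compton (Klein-Nishina composition-rejection sampling),
photoelectric absorption, and pair production as local absorption of the
kinetic surplus with two back-to-back 0.511 MeV annihilation photons.
Photons die below the 10 keV cutoff or on leaving the phantom.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# material slots in the coefficient arrays
MEDIUM, CORE, CAPSULE, CABLE = 0, 1, 2, 3
MEC2 = 0.51099895
MEV_TO_GY_CM2_G = 1.602176634e-10  # E[MeV] * mu_en/rho[cm^2/g] -> Gy cm^2

_TINY = 1e-12
_NUDGE = 1e-7  # cm pushed past each boundary crossing


@njit(cache=False, inline="always")
def _interp_log(loge, grid_loge, table):
    """Linear interpolation on the shared log-energy grid, clamped."""
    n = grid_loge.shape[0]
    if loge <= grid_loge[0]:
        return table[0]
    if loge >= grid_loge[n - 1]:
        return table[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if grid_loge[mid] <= loge:
            lo = mid
        else:
            hi = mid
    w = (loge - grid_loge[lo]) / (grid_loge[lo + 1] - grid_loge[lo])
    return table[lo] * (1.0 - w) + table[lo + 1] * w


@njit(cache=False, inline="always")
def _classify(x, y, z, core_r2, core_zlo, core_zhi,
              cap_r2, cap_zlo, cap_zhi, asm_zlo):
    rho2 = x * x + y * y
    if rho2 <= core_r2 and core_zlo <= z <= core_zhi:
        return CORE
    if rho2 <= cap_r2:
        if cap_zlo <= z <= cap_zhi:
            return CAPSULE
        if asm_zlo <= z < cap_zlo:
            return CABLE
    return MEDIUM


@njit(cache=False, inline="always")
def _min_pos_cyl(px, py, ux, uy, r2, t_min):
    a = ux * ux + uy * uy
    if a < 1e-30:
        return t_min
    b = px * ux + py * uy
    c = px * px + py * py - r2
    disc = b * b - a * c
    if disc <= 0.0:
        return t_min
    sq = np.sqrt(disc)
    t1 = (-b - sq) / a
    t2 = (-b + sq) / a
    if t1 > _TINY and t1 < t_min:
        t_min = t1
    if t2 > _TINY and t2 < t_min:
        t_min = t2
    return t_min


@njit(cache=False, inline="always")
def _min_pos_plane(pz, uz, z0, t_min):
    if abs(uz) < 1e-30:
        return t_min
    t = (z0 - pz) / uz
    if t > _TINY and t < t_min:
        t_min = t
    return t_min


@njit(cache=False, inline="always")
def _dist_boundary(x, y, z, ux, uy, uz,
                   core_r2, core_zlo, core_zhi,
                   cap_r2, cap_zlo, cap_zhi, asm_zlo,
                   phantom_kind, phantom_r):
    t = 1e30
    t = _min_pos_cyl(x, y, ux, uy, core_r2, t)
    t = _min_pos_cyl(x, y, ux, uy, cap_r2, t)
    t = _min_pos_plane(z, uz, core_zlo, t)
    t = _min_pos_plane(z, uz, core_zhi, t)
    t = _min_pos_plane(z, uz, cap_zlo, t)
    t = _min_pos_plane(z, uz, cap_zhi, t)
    t = _min_pos_plane(z, uz, asm_zlo, t)
    if phantom_kind == 0:  # sphere
        b = x * ux + y * uy + z * uz
        c = x * x + y * y + z * z - phantom_r * phantom_r
        disc = b * b - c
        if disc > 0.0:
            tp = -b + np.sqrt(disc)
            if _TINY < tp < t:
                t = tp
    else:  # cube of half-side phantom_r
        if abs(ux) > 1e-30:
            tp = ((phantom_r if ux > 0 else -phantom_r) - x) / ux
            if _TINY < tp < t:
                t = tp
        if abs(uy) > 1e-30:
            tp = ((phantom_r if uy > 0 else -phantom_r) - y) / uy
            if _TINY < tp < t:
                t = tp
        if abs(uz) > 1e-30:
            tp = ((phantom_r if uz > 0 else -phantom_r) - z) / uz
            if _TINY < tp < t:
                t = tp
    return t


@njit(cache=False, inline="always")
def _outside_phantom(x, y, z, phantom_kind, phantom_r):
    if phantom_kind == 0:
        return x * x + y * y + z * z >= phantom_r * phantom_r
    return (abs(x) >= phantom_r) or (abs(y) >= phantom_r) or (abs(z) >= phantom_r)


@njit(cache=False, inline="always")
def _score_segment(px, py, pz, ux, uy, uz, t, weight,
                   rho_in2, rho_out2, z_lo, z_hi, scores, ib):
    ncell = rho_in2.shape[0]
    for c in range(ncell):
        # z-slab interval
        lo = 0.0
        hi = t
        if abs(uz) < 1e-30:
            if pz < z_lo[c] or pz > z_hi[c]:
                continue
        else:
            t1 = (z_lo[c] - pz) / uz
            t2 = (z_hi[c] - pz) / uz
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > lo:
                lo = t1
            if t2 < hi:
                hi = t2
            if hi <= lo:
                continue
        a = ux * ux + uy * uy
        b = px * ux + py * uy
        rr = px * px + py * py
        if a < 1e-30:
            if rr > rho_out2[c] or rr < rho_in2[c]:
                continue
            length = hi - lo
        else:
            disc = b * b - a * (rr - rho_out2[c])
            if disc <= 0.0:
                continue
            sq = np.sqrt(disc)
            to1 = (-b - sq) / a
            to2 = (-b + sq) / a
            if to1 > lo:
                lo = to1
            if to2 < hi:
                hi = to2
            if hi <= lo:
                continue
            length = hi - lo
            if rho_in2[c] > 0.0:
                disc_i = b * b - a * (rr - rho_in2[c])
                if disc_i > 0.0:
                    sqi = np.sqrt(disc_i)
                    ti1 = (-b - sqi) / a
                    ti2 = (-b + sqi) / a
                    ov_lo = ti1 if ti1 > lo else lo
                    ov_hi = ti2 if ti2 < hi else hi
                    if ov_hi > ov_lo:
                        length -= ov_hi - ov_lo
        if length > 0.0:
            scores[ib, c] += length * weight


@njit(cache=False, inline="always")
def _sample_eps_kn(alpha):
    eps0 = 1.0 / (1.0 + 2.0 * alpha)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if np.random.random() * (a1 + a2) < a1:
            eps = np.exp(-a1 * np.random.random())
        else:
            eps = np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * np.random.random())
        t = (1.0 - eps) / (alpha * eps)
        sin2 = t * (2.0 - t)
        if np.random.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps


@njit(cache=False, inline="always")
def _rotate(ux, uy, uz, cos_t, phi):
    sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 0.0))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) < 0.99999:
        tmp = np.sqrt(1.0 - uz * uz)
        vx = ux * cos_t + sin_t * (ux * uz * cp - uy * sp) / tmp
        vy = uy * cos_t + sin_t * (uy * uz * cp + ux * sp) / tmp
        vz = uz * cos_t - tmp * sin_t * cp
    else:
        vx = sin_t * cp
        vy = sin_t * sp
        vz = cos_t if uz > 0 else -cos_t
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(cache=False)
def run_transport(seed, n_decays, n_batches,
                  core_r, core_zlo, core_zhi,
                  cap_r, cap_zlo, cap_zhi, asm_zlo,
                  phantom_kind, phantom_r,
                  grid_loge, log_mu_lin, f_pe, f_pe_pair, log_resp,
                  rho_in2, rho_out2, z_lo, z_hi,
                  e_lines, cutoff, primary_only):
    """Run ``n_decays`` two-photon decays; returns (scores, energy balance).

    scores: (n_batches, n_cells) summed track length x E x mu_en/rho x 1.602e-10
            (divide by cell volume x decays per batch... caller normalizes).
    ebal:   (n_batches, 3) emitted / absorbed / escaped energy, MeV.
    """
    np.random.seed(seed)
    ncell = rho_in2.shape[0]
    scores = np.zeros((n_batches, ncell))
    ebal = np.zeros((n_batches, 3))
    core_r2 = core_r * core_r
    cap_r2 = cap_r * cap_r

    # photon stack (per decay)
    sx = np.empty(8)
    sy = np.empty(8)
    sz = np.empty(8)
    sux = np.empty(8)
    suy = np.empty(8)
    suz = np.empty(8)
    se = np.empty(8)

    for d in range(n_decays):
        ib = (d * n_batches) // n_decays
        # decay position, uniform in the active core
        rho = core_r * np.sqrt(np.random.random())
        ang = 2.0 * np.pi * np.random.random()
        x0 = rho * np.cos(ang)
        y0 = rho * np.sin(ang)
        z0 = core_zlo + (core_zhi - core_zlo) * np.random.random()

        nstk = 0
        for k in range(e_lines.shape[0]):
            cz = 2.0 * np.random.random() - 1.0
            sq = np.sqrt(max(1.0 - cz * cz, 0.0))
            ph = 2.0 * np.pi * np.random.random()
            sx[nstk] = x0
            sy[nstk] = y0
            sz[nstk] = z0
            sux[nstk] = sq * np.cos(ph)
            suy[nstk] = sq * np.sin(ph)
            suz[nstk] = cz
            se[nstk] = e_lines[k]
            ebal[ib, 0] += e_lines[k]
            nstk += 1

        while nstk > 0:
            nstk -= 1
            x = sx[nstk]
            y = sy[nstk]
            z = sz[nstk]
            ux = sux[nstk]
            uy = suy[nstk]
            uz = suz[nstk]
            e = se[nstk]
            loge = np.log(e)
            alive = True
            nstep = 0
            while alive:
                nstep += 1
                if nstep > 100000:
                    ebal[ib, 1] += e
                    break
                region = _classify(x, y, z, core_r2, core_zlo, core_zhi,
                                   cap_r2, cap_zlo, cap_zhi, asm_zlo)
                mu = np.exp(_interp_log(loge, grid_loge, log_mu_lin[region]))
                tb = _dist_boundary(x, y, z, ux, uy, uz,
                                    core_r2, core_zlo, core_zhi,
                                    cap_r2, cap_zlo, cap_zhi, asm_zlo,
                                    phantom_kind, phantom_r)
                s = -np.log(np.random.random()) / mu
                interact = s < tb
                step = s if interact else tb
                if region == MEDIUM and ncell > 0:
                    resp = np.exp(_interp_log(loge, grid_loge, log_resp))
                    _score_segment(x, y, z, ux, uy, uz, step, resp,
                                   rho_in2, rho_out2, z_lo, z_hi, scores, ib)
                if not interact:
                    step = tb + _NUDGE
                x += ux * step
                y += uy * step
                z += uz * step
                if not interact:
                    if _outside_phantom(x, y, z, phantom_kind, phantom_r):
                        ebal[ib, 2] += e
                        alive = False
                    continue
                # interaction
                if primary_only:
                    ebal[ib, 1] += e
                    alive = False
                    continue
                fpe = _interp_log(loge, grid_loge, f_pe[region])
                fpp = _interp_log(loge, grid_loge, f_pe_pair[region])
                xi = np.random.random()
                if xi < fpe:
                    ebal[ib, 1] += e
                    alive = False
                elif xi < fpp and e > 2.0 * MEC2:
                    # pair production: local absorption of the kinetic surplus,
                    # two back-to-back annihilation photons
                    ebal[ib, 1] += e - 2.0 * MEC2
                    cz = 2.0 * np.random.random() - 1.0
                    sq = np.sqrt(max(1.0 - cz * cz, 0.0))
                    ph = 2.0 * np.pi * np.random.random()
                    ax = sq * np.cos(ph)
                    ay = sq * np.sin(ph)
                    az = cz
                    sx[nstk] = x
                    sy[nstk] = y
                    sz[nstk] = z
                    sux[nstk] = -ax
                    suy[nstk] = -ay
                    suz[nstk] = -az
                    se[nstk] = MEC2
                    nstk += 1
                    ux = ax
                    uy = ay
                    uz = az
                    e = MEC2
                    loge = np.log(e)
                else:
                    # Compton scatter
                    alpha = e / MEC2
                    eps = _sample_eps_kn(alpha)
                    cos_t = 1.0 - (1.0 - eps) / (alpha * eps)
                    if cos_t > 1.0:
                        cos_t = 1.0
                    elif cos_t < -1.0:
                        cos_t = -1.0
                    phi = 2.0 * np.pi * np.random.random()
                    ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi)
                    ebal[ib, 1] += e * (1.0 - eps)
                    e *= eps
                    if e < cutoff:
                        ebal[ib, 1] += e
                        alive = False
                    else:
                        loge = np.log(e)
    return scores, ebal
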