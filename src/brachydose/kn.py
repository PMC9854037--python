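"""Klein-Nishina Compton scattering on free stationary electrons.

Closed-form total and scattered-energy-weighted cross sections per electron,
the Compton energy-angle relation, and the standard composition-rejection
sampler of the differential cross section (the same scheme production photon
transport codes use).  Doppler broadening and electron binding are not
modeled; at the Co-60 line energies both are sub-percent effects.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MEC2", "RE2",
    "compton_energy", "kn_total", "kn_scatter", "kn_transfer",
    "kn_differential", "sample_compton",
]

MEC2 = 0.51099895  # electron rest energy, MeV
RE2 = 2.8179403262e-13 ** 2  # classical electron radius squared, cm^2


def compton_energy(energy_mev, theta):
    """Scattered photon energy for incident energy and scattering angle."""
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    return e / (1.0 + (e / MEC2) * (1.0 - np.cos(theta)))


def kn_total(energy_mev):
    """Total Klein-Nishina cross section per electron, cm^2."""
    a = np.asarray(energy_mev, dtype=float) / MEC2
    if np.any(a <= 0):
        raise ValueError("energy must be positive")
    t = np.log1p(2 * a)
    return 2 * np.pi * RE2 * (
        (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - t / a)
        + t / (2 * a) - (1 + 3 * a) / (1 + 2 * a) ** 2
    )


def kn_scatter(energy_mev):
    """Scattered-energy-weighted cross section (sigma_s), cm^2.

    ``sigma_s / sigma_total`` is the mean fraction of the incident energy
    retained by the scattered photon.
    """
    a = np.asarray(energy_mev, dtype=float) / MEC2
    if np.any(a <= 0):
        raise ValueError("energy must be positive")
    t = np.log1p(2 * a)
    return np.pi * RE2 * (
        t / a**3
        + 2 * (1 + a) * (2 * a**2 - 2 * a - 1) / (a**2 * (1 + 2 * a) ** 2)
        + 8 * a**2 / (3 * (1 + 2 * a) ** 3)
    )


def kn_transfer(energy_mev):
    """Energy-transfer cross section (to the Compton electron), cm^2."""
    return kn_total(energy_mev) - kn_scatter(energy_mev)


def kn_differential(energy_mev, eps):
    """d(sigma)/d(eps) per electron, with eps = E'/E in [1/(1+2a), 1]."""
    a = float(energy_mev) / MEC2
    eps = np.asarray(eps, dtype=float)
    cos_t = 1.0 - (1.0 / eps - 1.0) / a
    sin2 = 1.0 - cos_t**2
    return np.pi * RE2 * (eps + 1.0 / eps - sin2) / a


def sample_compton(energy_mev, rng, size=None):
    """Draw (scattered energy MeV, scattering angle rad) from Klein-Nishina.

    Uses the standard two-branch composition-rejection sampler of
    eps = E'/E.  ``rng`` is a seeded :class:`numpy.random.Generator`.
    """
    e = float(energy_mev)
    if e <= 0:
        raise ValueError("energy must be positive")
    scalar = size is None
    n = 1 if scalar else int(size)
    a = e / MEC2
    eps0 = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0**2)

    out_eps = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        u1, u2, u3 = rng.random((3, todo.size))
        branch1 = u1 < a1 / (a1 + a2)
        eps = np.where(branch1, np.exp(-a1 * u2), np.sqrt(eps0**2 + (1 - eps0**2) * u2))
        t = (1.0 - eps) / (a * eps)
        sin2 = t * (2.0 - t)
        accept = u3 <= 1.0 - eps * sin2 / (1.0 + eps**2)
        out_eps[todo[accept]] = eps[accept]
        todo = todo[~accept]

    cos_t = np.clip(1.0 - (1.0 / out_eps - 1.0) / a, -1.0, 1.0)
    theta = np.arccos(cos_t)
    e_out = e * out_eps
    if scalar:
        return float(e_out[0]), float(theta[0])
    return e_out, theta
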