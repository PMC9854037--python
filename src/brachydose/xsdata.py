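"""Packaged photon-interaction coefficient tables.

Each material ships a table of total mass attenuation mu/rho, mass
energy-absorption mu_en/rho (both cm^2/g) and per-interaction fractions
(Compton / photoelectric-absorptive / pair) on a common log energy grid from
10 keV to 2 MeV.  Coefficients are interpolated log-log between grid points;
interaction fractions linearly in log E.  Mixtures follow mass-fraction
additivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["CrossSectionTable", "load_xs", "mix_tables", "XS_MATERIALS"]

XS_MATERIALS = ("water", "air", "cobalt", "steel1", "steel2")


@dataclass(frozen=True)
class CrossSectionTable:
    material: str
    energy: np.ndarray  # MeV, ascending
    mu_rho: np.ndarray  # cm^2/g
    mu_en_rho: np.ndarray  # cm^2/g
    f_compton: np.ndarray
    f_photo: np.ndarray
    f_pair: np.ndarray

    def __post_init__(self):
        if np.any(self.mu_rho <= 0) or np.any(self.mu_en_rho <= 0):
            raise ValueError("coefficients must be positive")
        s = self.f_compton + self.f_photo + self.f_pair
        if np.max(np.abs(s - 1.0)) > 1e-9:
            raise ValueError("interaction fractions must sum to 1 at every energy")

    def _loglog(self, table: np.ndarray, energy_mev) -> np.ndarray:
        e = np.clip(np.asarray(energy_mev, dtype=float),
                    self.energy[0], self.energy[-1])
        return np.exp(np.interp(np.log(e), np.log(self.energy), np.log(table)))

    def mu_rho_at(self, energy_mev) -> np.ndarray:
        """Total mass attenuation coefficient, cm^2/g (log-log interpolated)."""
        return self._loglog(self.mu_rho, energy_mev)

    def mu_en_rho_at(self, energy_mev) -> np.ndarray:
        """Mass energy-absorption coefficient, cm^2/g."""
        return self._loglog(self.mu_en_rho, energy_mev)

    def fractions_at(self, energy_mev) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Compton, photoelectric, pair) interaction fractions at an energy."""
        loge = np.log(np.clip(np.asarray(energy_mev, dtype=float),
                              self.energy[0], self.energy[-1]))
        lg = np.log(self.energy)
        fc = np.interp(loge, lg, self.f_compton)
        fp = np.interp(loge, lg, self.f_photo)
        fpp = np.interp(loge, lg, self.f_pair)
        s = fc + fp + fpp
        return fc / s, fp / s, fpp / s


def load_xs(material: str) -> CrossSectionTable:
    """Load a packaged coefficient table by material name."""
    if material not in XS_MATERIALS:
        raise ValueError(f"no packaged coefficients for {material!r}")
    ref = resources.files("brachydose").joinpath(f"data/xs/{material}.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return CrossSectionTable(
        material=material,
        energy=df["energy_mev"].to_numpy(),
        mu_rho=df["mu_rho"].to_numpy(),
        mu_en_rho=df["mu_en_rho"].to_numpy(),
        f_compton=df["f_compton"].to_numpy(),
        f_photo=df["f_photo"].to_numpy(),
        f_pair=df["f_pair"].to_numpy(),
    )


def mix_tables(components: list[tuple[CrossSectionTable, float]],
               name: str = "mixture") -> CrossSectionTable:
    """Combine tables by mass-fraction additivity (shared energy grid)."""
    if not components:
        raise ValueError("need at least one component")
    e = components[0][0].energy
    for tab, _ in components:
        if not np.allclose(tab.energy, e):
            raise ValueError("component tables must share the energy grid")
    wsum = sum(w for _, w in components)
    mu = sum(w * t.mu_rho for t, w in components) / wsum
    mu_en = sum(w * t.mu_en_rho for t, w in components) / wsum
    mu_c = sum(w * t.mu_rho * t.f_compton for t, w in components) / wsum
    mu_p = sum(w * t.mu_rho * t.f_photo for t, w in components) / wsum
    mu_pp = sum(w * t.mu_rho * t.f_pair for t, w in components) / wsum
    return CrossSectionTable(name, e, mu, mu_en,
                             mu_c / mu, mu_p / mu, mu_pp / mu)
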