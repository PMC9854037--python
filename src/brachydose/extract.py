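"""TG-43 parameter extraction from scored dose grids.

Inverts the TG-43 equations on a :class:`~brachydose.grids.DoseGrid` (simulated
or reconstructed) plus an air-kerma strength result:

* ``Lambda = Ddot(1 cm, 90 deg) / S_k`` (both per decay, so the activity
  normalization cancels),
* ``g(r) = [Ddot(r, 90) G(1, 90)] / [Ddot(1, 90) G(r, 90)]``,
* ``F(r, theta) = [Ddot(r, theta) G(r, 90)] / [Ddot(r, 90) G(r, theta)]``,
* ``phi_an(r) = Int_0^pi Ddot(r, theta) sin(theta) dtheta / [2 Ddot(r, 90)]``
  by composite trapezoid over the tabulated angles, with the integrand
  clamped (constant F) beyond the tabulated theta range.

Also provides the cross-code/cross-source comparison statistics and the
quadrature uncertainty budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import R0, THETA0, TG43ParameterSet, geometry_factor
from .grids import AirKermaResult, DoseGrid

__all__ = [
    "dose_rate_constant", "radial_dose_function", "anisotropy_2d",
    "anisotropy_1d", "extract_parameters", "compare_radial_tables",
    "UncertaintyBudget", "uncertainty_budget",
]

PER_DECAY_TO_PER_BQ_HOUR = 100.0 * 3600.0  # Gy/decay -> cGy/h per Bq

#: polar angles evaluated this close to the axis are nudged off it, because a
#: ring scoring cell centered on the axis has zero radius (the geometry factor
#: itself stays finite there)
THETA_EDGE = 0.5


def _theta_eff(theta):
    return float(np.clip(theta, THETA_EDGE, 180.0 - THETA_EDGE))


def dose_rate_constant(water: DoseGrid, air: AirKermaResult) -> tuple[float, float]:
    """(Lambda in cGy h^-1 U^-1, propagated type-A relative uncertainty)."""
    d_ref = water.value_at(R0, THETA0) * PER_DECAY_TO_PER_BQ_HOUR
    lam = d_ref / air.sk_per_bq
    rel = float(np.hypot(water.uncertainty_at(R0, THETA0), air.rel_uncertainty))
    return lam, rel


def radial_dose_function(water: DoseGrid, L: float) -> pd.DataFrame:
    """g(r) from the transverse-axis cells; g(1 cm) = 1 by construction."""
    cells = [(i, c) for i, c in enumerate(water.grid.cells)
             if abs(c.theta - THETA0) < 1e-9]
    if not cells:
        raise ValueError("grid has no transverse-axis (theta = 90 deg) cells")
    radii = np.array([c.r for _, c in cells])
    if not np.any(np.abs(radii - R0) < 1e-9):
        raise ValueError("grid lacks the reference cell at r = 1 cm")
    d = np.array([water.kerma[i] for i, _ in cells])
    d_ref = d[np.argmin(np.abs(radii - R0))]
    if d_ref <= 0:
        raise ValueError("reference cell at r = 1 cm scored no kerma")
    keep = d > 0  # unscored cells carry no information
    radii, d = radii[keep], d[keep]
    g = (d * geometry_factor(R0, THETA0, L)) / (d_ref * geometry_factor(radii, THETA0, L))
    order = np.argsort(radii)
    return pd.DataFrame({"r_cm": radii[order], "g": g[order]})


def anisotropy_2d(water: DoseGrid, L: float) -> pd.DataFrame:
    """F(r, theta) table (theta rows, one column per radius); F(r, 90) = 1."""
    radii = sorted({c.r for c in water.grid.cells})
    thetas = sorted({c.theta for c in water.grid.cells})
    if THETA0 not in thetas:
        raise ValueError("grid lacks transverse cells (theta = 90 deg)")
    out = np.full((len(thetas), len(radii)), np.nan)
    for j, r in enumerate(radii):
        try:
            d_ref = water.value_at(r, THETA0)
        except KeyError:
            raise ValueError(f"missing transverse cell at r = {r}")
        if d_ref <= 0:
            continue  # column stays missing
        for i, th in enumerate(thetas):
            try:
                d = water.value_at(r, th)
            except KeyError:
                continue
            if d <= 0:
                continue  # unscored cell -> missing, never zero
            gf = geometry_factor(r, THETA0, L) / geometry_factor(r, _theta_eff(th), L)
            out[i, j] = d / d_ref * gf
    df = pd.DataFrame(out, columns=[repr(float(r)) for r in radii])
    df.insert(0, "theta_deg", thetas)
    return df


def _phi_from_profile(thetas: np.ndarray, F: np.ndarray, r: float, L: float) -> float:
    """Normalized sin-weighted trapezoid with clamped-F tails to 0/180 deg."""
    ok = ~np.isnan(F)
    thetas, F = thetas[ok], F[ok]
    if thetas.size < 3 or thetas.min() > 5.0 + 1e-9 or thetas.max() < 175.0 - 1e-9:
        raise ValueError(
            "insufficient theta coverage for the 1D anisotropy integral "
            f"(have {thetas.min() if thetas.size else 'none'}-"
            f"{thetas.max() if thetas.size else 'none'} deg)")
    th = np.concatenate([[0.0], thetas, [180.0]])
    f = np.concatenate([[F[0]], F, [F[-1]]])
    g_ref = geometry_factor(r, THETA0, L)
    gvals = np.array([geometry_factor(r, _theta_eff(t), L) for t in th])
    sin_th = np.sin(np.radians(th))
    integrand = gvals / g_ref * f * sin_th
    # normalize by the discrete quadrature of sin(theta) (exactly 2 in the
    # continuum limit) so that an isotropic profile integrates to exactly 1
    # and the O(dtheta^2) trapezoid bias cancels
    rad = np.radians(th)
    return float(np.trapezoid(integrand, rad) / np.trapezoid(sin_th, rad))


def anisotropy_1d(source, r: float, L: float) -> float:
    """phi_an(r) from either an F table (DataFrame) or a DoseGrid.

    The dose profile is reconstructed as Ddot(r, theta) ~ G(r, theta) *
    F(r, theta) and integrated per the 1D anisotropy definition.
    """
    if isinstance(source, DoseGrid):
        thetas = np.array(sorted({c.theta for c in source.grid.cells
                                  if abs(c.r - r) < 1e-9}))
        d_ref = source.value_at(r, THETA0)
        d = np.array([source.value_at(r, t) for t in thetas])
        gv = np.array([geometry_factor(r, _theta_eff(t), L) for t in thetas])
        F = d / d_ref * geometry_factor(r, THETA0, L) / gv
    else:
        df = source
        cols = [c for c in df.columns if c != "theta_deg"]
        rvals = np.array([float(c) for c in cols])
        j = int(np.argmin(np.abs(rvals - r)))
        if abs(rvals[j] - r) > 1e-9:
            raise ValueError(f"F table has no column at r = {r}")
        thetas = df["theta_deg"].to_numpy(dtype=float)
        F = df[cols[j]].to_numpy(dtype=float)
    return _phi_from_profile(np.asarray(thetas, float), np.asarray(F, float), r, L)


def extract_parameters(water: DoseGrid, air: AirKermaResult, L: float,
                       code_label: str = "brachydose-mc") -> TG43ParameterSet:
    """Full TG43ParameterSet (Lambda, g, F, phi_an) from one simulation pair."""
    lam, _ = dose_rate_constant(water, air)
    gdf = radial_dose_function(water, L)
    fdf = anisotropy_2d(water, L)
    cols = [c for c in fdf.columns if c != "theta_deg"]
    radii = np.array([float(c) for c in cols])
    phi_r, phi = [], []
    for r in radii:
        try:
            phi.append(anisotropy_1d(fdf, r, L))
            phi_r.append(r)
        except ValueError:
            continue
    return TG43ParameterSet(
        channel=water.channel, code_label=code_label, L=L,
        dose_rate_constant=lam,
        g_r=gdf["r_cm"].to_numpy(), g=gdf["g"].to_numpy(),
        F_r=radii, F_theta=fdf["theta_deg"].to_numpy(),
        F=fdf[cols].to_numpy(),
        phi_r=np.array(phi_r), phi_an=np.array(phi),
        sk_per_bq=air.sk_per_bq,
    )


def compare_radial_tables(g_a, g_b, convention: str = "relative_to_a"):
    """Percent differences between two g tables on a shared r grid.

    ``relative_to_a`` gives (g_b - g_a) / g_a x 100 per point (the cross-code
    convention with table A as denominator); ``relative_to_b`` uses g_b as
    denominator (the cross-source literature convention).  Returns
    (per-point %, max |%|).
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tables must share the r grid")
    if convention not in ("relative_to_a", "relative_to_b"):
        raise ValueError(f"unknown convention {convention!r}")
    den = a if convention == "relative_to_a" else b
    diff = (b - a) / den * 100.0
    return diff, float(np.max(np.abs(diff)))


@dataclass
class UncertaintyBudget:
    """Quadrature-combined uncertainty budget, percent."""

    components: list[tuple[str, float, str]]  # (label, %, "A"|"B")
    total: float  # %

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.total, ndigits)


def uncertainty_budget(components) -> UncertaintyBudget:
    """Root-sum-square of relative uncertainty components (percent)."""
    comps = []
    for label, pct, kind in components:
        if pct < 0:
            raise ValueError(f"negative uncertainty component {label!r}")
        if kind not in ("A", "B"):
            raise ValueError(f"component type must be 'A' or 'B', got {kind!r}")
        comps.append((str(label), float(pct), kind))
    total = float(np.sqrt(sum(p * p for _, p, _ in comps)))
    return UncertaintyBudget(components=comps, total=total)
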