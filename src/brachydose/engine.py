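"""Forward TG-43 dose reconstruction.

Implements the line-source geometry factor G(r, theta) = beta / (L r sin
theta), interpolation of the tabulated radial dose function g(r) and 2D
anisotropy function F(r, theta), the 1D/2D dose-rate equations

    Ddot(r, theta) = S_k * Lambda * [G(r, theta) / G(r0, theta0)]
                     * g(r) * F(r, theta)

with reference point (r0, theta0) = (1 cm, 90 deg), and along-away QA table
generation on a (y, z) grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "geometry_factor", "TG43ParameterSet", "AlongAwayTable",
    "interp_parameters", "dose_rate_2d", "dose_rate_1d", "along_away_table",
]

R0, THETA0 = 1.0, 90.0


def geometry_factor(r, theta, L):
    """Line-source geometry factor, cm^-2.

    ``beta`` is computed as the difference of the two arctangents subtended
    by the active-length endpoints, which stays accurate at small theta and
    large r.  On the long axis (theta in {0, 180}) the degenerate limit
    1 / (r^2 - L^2/4) applies; a zero active length gives the point-source
    1 / r^2.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if np.any((theta < 0) | (theta > 180)):
        raise ValueError("theta must lie in [0, 180] degrees")
    if L < 0:
        raise ValueError("active length must be >= 0")
    if L == 0:
        return np.broadcast_to(1.0 / r**2, np.broadcast_shapes(r.shape, theta.shape)).copy()

    th = np.radians(theta)
    rho = r * np.sin(th)
    z = r * np.cos(th)
    on_axis = np.abs(rho) < 1e-12
    if np.any(on_axis & (np.abs(z) <= L / 2 + 1e-12)):
        raise ValueError("field point lies on the active line segment")
    # off-axis: beta from endpoint angles; on-axis: degenerate limit
    rho_safe = np.where(on_axis, 1.0, rho)
    beta = np.arctan2(rho_safe, z - L / 2) - np.arctan2(rho_safe, z + L / 2)
    g_line = beta / (L * rho_safe)
    g_axis = 1.0 / (r**2 - L**2 / 4.0)
    out = np.where(on_axis, g_axis, g_line)
    return out if out.shape else float(out)


@dataclass
class TG43ParameterSet:
    """TG-43 parameters of one source/channel as produced by one code."""

    channel: str
    code_label: str
    L: float  # active length, cm
    dose_rate_constant: float  # Lambda, cGy h^-1 U^-1
    g_r: np.ndarray  # radii of the g table, cm
    g: np.ndarray  # radial dose function, g(1 cm) = 1
    F_r: np.ndarray  # radii of the F table
    F_theta: np.ndarray  # polar angles, degrees
    F: np.ndarray  # (n_theta, n_r), F(r, 90 deg) = 1; NaN marks missing
    phi_r: np.ndarray = field(default_factory=lambda: np.empty(0))
    phi_an: np.ndarray = field(default_factory=lambda: np.empty(0))
    sk_per_bq: float = float("nan")  # cGy cm^2 h^-1 Bq^-1

    def __post_init__(self):
        for name in ("g_r", "g", "F_r", "F_theta", "phi_r", "phi_an"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.F = np.asarray(self.F, dtype=float)
        i1 = np.argmin(np.abs(self.g_r - R0))
        if abs(self.g_r[i1] - R0) > 1e-9 or abs(self.g[i1] - 1.0) > 1e-9:
            raise ValueError("g table must contain g(1 cm) = 1")
        j90 = np.argmin(np.abs(self.F_theta - THETA0))
        if abs(self.F_theta[j90] - THETA0) > 1e-9:
            raise ValueError("F table must contain theta = 90 deg")
        row = self.F[j90]
        if np.nanmax(np.abs(row - 1.0)) > 1e-9:
            raise ValueError("F(r, 90 deg) must equal 1 for all tabulated r")
        if np.any(self.g <= 0) or np.nanmin(self.F) <= 0:
            raise ValueError("table values must be positive")

    # -- persistence -----------------------------------------------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"r_cm": self.g_r, "g": self.g}).to_csv(
            path / "g.csv", index=False, float_format="%.17g")
        fdf = pd.DataFrame(self.F, columns=[repr(float(r)) for r in self.F_r])
        fdf.insert(0, "theta_deg", self.F_theta)
        fdf.to_csv(path / "F.csv", index=False, float_format="%.17g")
        pd.DataFrame({"r_cm": self.phi_r, "phi_an": self.phi_an}).to_csv(
            path / "phi_an.csv", index=False, float_format="%.17g")
        (path / "meta.json").write_text(json.dumps({
            "channel": self.channel, "code_label": self.code_label,
            "L": self.L, "dose_rate_constant": self.dose_rate_constant,
            "sk_per_bq": self.sk_per_bq,
        }, indent=1))

    @classmethod
    def from_dir(cls, path) -> "TG43ParameterSet":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        gdf = pd.read_csv(path / "g.csv", float_precision="round_trip")
        fdf = pd.read_csv(path / "F.csv", float_precision="round_trip")
        pdf = pd.read_csv(path / "phi_an.csv", float_precision="round_trip")
        return cls(
            channel=meta["channel"], code_label=meta["code_label"],
            L=meta["L"], dose_rate_constant=meta["dose_rate_constant"],
            g_r=gdf["r_cm"].to_numpy(), g=gdf["g"].to_numpy(),
            F_r=np.array([float(c) for c in fdf.columns[1:]]),
            F_theta=fdf["theta_deg"].to_numpy(),
            F=fdf.iloc[:, 1:].to_numpy(),
            phi_r=pdf["r_cm"].to_numpy(), phi_an=pdf["phi_an"].to_numpy(),
            sk_per_bq=meta.get("sk_per_bq", float("nan")),
        )


def _interp_f(params: TG43ParameterSet, r: float, theta: float) -> float:
    """Bilinear F with theta clamped to the tabulated range; missing entries
    fall back to the nearest tabulated angle at that radius."""
    th = np.clip(theta, params.F_theta[0], params.F_theta[-1])
    jr = np.searchsorted(params.F_r, r)
    jr = np.clip(jr, 1, len(params.F_r) - 1)
    jt = np.searchsorted(params.F_theta, th)
    jt = np.clip(jt, 1, len(params.F_theta) - 1)
    wr = (r - params.F_r[jr - 1]) / (params.F_r[jr] - params.F_r[jr - 1])
    wt = (th - params.F_theta[jt - 1]) / (params.F_theta[jt] - params.F_theta[jt - 1])
    vals = np.empty((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            v = params.F[jt - 1 + a, jr - 1 + b]
            if np.isnan(v):
                col = params.F[:, jr - 1 + b]
                ok = ~np.isnan(col)
                v = np.interp(params.F_theta[jt - 1 + a],
                              params.F_theta[ok], col[ok])
            vals[a, b] = v
    top = vals[0, 0] * (1 - wr) + vals[0, 1] * wr
    bot = vals[1, 0] * (1 - wr) + vals[1, 1] * wr
    return float(top * (1 - wt) + bot * wt)


def interp_parameters(params: TG43ParameterSet, r: float, theta: float = THETA0,
                      extrapolate: bool = False) -> tuple[float, float]:
    """(g, F) at (r, theta): g linear in r, F bilinear with theta clamping."""
    r_min, r_max = params.g_r[0], params.g_r[-1]
    if (r < r_min - 1e-12 or r > r_max + 1e-12) and not extrapolate:
        raise ValueError(f"r = {r} outside tabulated range [{r_min}, {r_max}]")
    rc = float(np.clip(r, r_min, r_max))
    g = float(np.interp(rc, params.g_r, params.g))
    rf = float(np.clip(r, params.F_r[0], params.F_r[-1]))
    F = _interp_f(params, rf, theta)
    return g, F


def dose_rate_2d(params: TG43ParameterSet, sk: float, r: float,
                 theta: float, extrapolate: bool = False) -> float:
    """2D dose rate, cGy/h, for air-kerma strength ``sk`` in U."""
    g, F = interp_parameters(params, r, theta, extrapolate)
    gf = geometry_factor(r, theta, params.L) / geometry_factor(R0, THETA0, params.L)
    return sk * params.dose_rate_constant * gf * g * F


def dose_rate_1d(params: TG43ParameterSet, sk: float, r: float) -> float:
    """1D (transverse-equivalent) dose rate using phi_an(r), cGy/h."""
    if params.phi_r.size == 0:
        raise ValueError("parameter set has no phi_an table")
    pr = params.phi_r[~np.isnan(params.phi_an)]
    pv = params.phi_an[~np.isnan(params.phi_an)]
    if r < min(pr.min(), params.g_r[0]) - 1e-12 or r > params.g_r[-1] + 1e-12:
        raise ValueError(f"r = {r} outside tabulated range")
    g, _ = interp_parameters(params, r)
    phi = float(np.interp(r, pr, pv))
    gf = geometry_factor(r, THETA0, params.L) / geometry_factor(R0, THETA0, params.L)
    return sk * params.dose_rate_constant * gf * g * phi


@dataclass
class AlongAwayTable:
    """Dose rate per unit S_k on the (y away, z along) QA grid, cGy h^-1 U^-1."""

    y: np.ndarray  # away, cm, >= 0
    z: np.ndarray  # along, cm, signed
    values: np.ndarray  # (n_z, n_y), NaN where undefined
    channel: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[repr(float(v)) for v in self.y])
        df.insert(0, "z_cm", self.z)
        return df


def along_away_table(params: TG43ParameterSet, y_grid, z_grid,
                     sk: float = 1.0) -> AlongAwayTable:
    """TG-43 reconstruction on a QA grid; cells outside the tabulated radial
    range (or inside the source) are marked missing."""
    y = np.asarray(y_grid, dtype=float)
    z = np.asarray(z_grid, dtype=float)
    vals = np.full((z.size, y.size), np.nan)
    r_min, r_max = params.g_r[0], params.g_r[-1]
    for i, zi in enumerate(z):
        for j, yj in enumerate(y):
            r = float(np.hypot(yj, zi))
            if r < r_min or r > r_max:
                continue
            theta = float(np.degrees(np.arctan2(yj, zi)))
            vals[i, j] = dose_rate_2d(params, sk, r, theta)
    return AlongAwayTable(y=y, z=z, values=vals, channel=params.channel)
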