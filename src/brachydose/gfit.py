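"""Radial dose function model fitting.

The radial dose function is modeled as a fifth-order polynomial times an
exponential,

    g(r) = (a0 r^-2 + a1 r^-1 + a2 + a3 r + a4 r^2) exp(-a5 r),

fitted by profiled least squares: for each trial decay constant a5 the
polynomial coefficients a0..a4 solve a linear least-squares problem, and a5
itself is located by a deterministic grid scan over [0, 1] cm^-1 followed by
bounded local refinement.  This keeps the fit reproducible bit-for-bit and
immune to local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["FitResult", "eval_model", "fit_radial"]

A5_GRID = np.linspace(0.0, 1.0, 101)  # cm^-1


@dataclass
class FitResult:
    coefficients: np.ndarray  # a0..a5 (cm^2, cm, -, cm^-1, cm^-2, cm^-1)
    r_squared: float
    r: np.ndarray  # fitted radii, cm
    rel_deviation_pct: np.ndarray  # per-point |model - data| / data x 100
    max_deviation_pct: float
    fit_range: tuple[float, float]

    def predict(self, r):
        return eval_model(self.coefficients, r)


def eval_model(coefficients, r):
    """Evaluate the polynomial-times-exponential g(r) model."""
    a = np.asarray(coefficients, dtype=float)
    if a.shape != (6,):
        raise ValueError("expected six coefficients a0..a5")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    poly = a[0] / r**2 + a[1] / r + a[2] + a[3] * r + a[4] * r**2
    out = poly * np.exp(-a[5] * r)
    return out if out.shape else float(out)


def _linear_fit(r, g, a5):
    basis = np.column_stack([r**-2, r**-1, np.ones_like(r), r, r**2])
    design = basis * np.exp(-a5 * r)[:, None]
    coef, *_ = np.linalg.lstsq(design, g, rcond=None)
    resid = design @ coef - g
    return coef, float(resid @ resid)


def fit_radial(r, g, r_range=(0.25, 10.0)) -> FitResult:
    """Least-squares fit of the g(r) model over ``r_range`` (unweighted)."""
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = (r >= r_range[0] - 1e-12) & (r <= r_range[1] + 1e-12)
    r, g = r[mask], g[mask]
    if r.size < 7:
        raise ValueError(f"need >= 7 points in range, have {r.size}")
    if np.any(g <= 0):
        raise ValueError("g values must be positive")

    sse_grid = np.array([_linear_fit(r, g, a5)[1] for a5 in A5_GRID])
    k = int(np.argmin(sse_grid))
    lo = A5_GRID[max(k - 1, 0)]
    hi = A5_GRID[min(k + 1, A5_GRID.size - 1)]
    res = minimize_scalar(lambda a5: _linear_fit(r, g, a5)[1],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    a5 = float(res.x)
    coef, sse = _linear_fit(r, g, a5)
    if sse_grid[k] < sse:  # keep whichever is better; both deterministic
        a5 = float(A5_GRID[k])
        coef, sse = _linear_fit(r, g, a5)

    model = eval_model(np.append(coef, a5), r)
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    dev = np.abs(model - g) / g * 100.0
    return FitResult(
        coefficients=np.append(coef, a5),
        r_squared=float(r2),
        r=r,
        rel_deviation_pct=dev,
        max_deviation_pct=float(dev.max()),
        fit_range=(float(r_range[0]), float(r_range[1])),
    )
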