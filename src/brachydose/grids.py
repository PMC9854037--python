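"""Cylindrical-ring scoring grids and scored dose/kerma containers.

The simulation scores collision kerma in thin cylindrical rings coaxial with
the source.  Ring dimensions follow the three-zone sampling scheme: radial
thickness x axial height of 0.025 x 0.005 cm for 0 < r <= 1 cm, 0.05 x 0.05
cm for 1 < r < 3 cm and 0.1 x 0.1 cm for 3 <= r <= 10 cm, where r is the
distance of the ring center from the source center.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ring_dimensions", "RingCell", "ScoringGrid", "build_scoring_grid",
    "DoseGrid", "AirKermaResult",
]

#: below this radius collision kerma only approximates dose (no charged-
#: particle equilibrium); cells there are flagged.
KERMA_APPROX_RADIUS = 0.7


def ring_dimensions(r: float) -> tuple[float, float]:
    """(radial thickness, axial height) in cm of the ring zone containing r."""
    if r <= 0 or r > 10.0:
        raise ValueError(f"sample radius {r} outside (0, 10] cm")
    if r <= 1.0:
        return 0.025, 0.005
    if r < 3.0:
        return 0.05, 0.05
    return 0.1, 0.1


@dataclass(frozen=True)
class RingCell:
    """One scoring ring, addressed by its spherical center (r, theta)."""

    r: float  # cm from source center
    theta: float  # degrees from +z
    thickness: float  # radial, cm
    height: float  # axial, cm

    @property
    def rho_bounds(self) -> tuple[float, float]:
        rho0 = self.r * math.sin(math.radians(self.theta))
        lo = rho0 - self.thickness / 2.0
        return (max(lo, 0.0), rho0 + self.thickness / 2.0)

    @property
    def z_bounds(self) -> tuple[float, float]:
        z0 = self.r * math.cos(math.radians(self.theta))
        return (z0 - self.height / 2.0, z0 + self.height / 2.0)

    def volume(self) -> float:
        """Analytic ring volume, cm^3."""
        rho_in, rho_out = self.rho_bounds
        z_lo, z_hi = self.z_bounds
        return math.pi * (rho_out**2 - rho_in**2) * (z_hi - z_lo)


@dataclass(frozen=True)
class ScoringGrid:
    cells: tuple[RingCell, ...]

    def __len__(self):
        return len(self.cells)

    def arrays(self):
        """(rho_in, rho_out, z_lo, z_hi, volume) arrays for the kernel."""
        rho = np.array([c.rho_bounds for c in self.cells])
        z = np.array([c.z_bounds for c in self.cells])
        vol = np.array([c.volume() for c in self.cells])
        return rho[:, 0], rho[:, 1], z[:, 0], z[:, 1], vol

    def index_of(self, r: float, theta: float = 90.0) -> int:
        for i, c in enumerate(self.cells):
            if abs(c.r - r) < 1e-9 and abs(c.theta - theta) < 1e-9:
                return i
        raise KeyError(f"no cell at (r={r}, theta={theta})")


def build_scoring_grid(r_samples, theta_samples=(90.0,)) -> ScoringGrid:
    """One ring cell per requested (r, theta) sample, zone-sized by r."""
    cells = []
    for r in np.atleast_1d(np.asarray(r_samples, dtype=float)):
        t, h = ring_dimensions(float(r))
        for theta in np.atleast_1d(np.asarray(theta_samples, dtype=float)):
            if not 0.0 <= theta <= 180.0:
                raise ValueError(f"theta {theta} outside [0, 180] degrees")
            cells.append(RingCell(float(r), float(theta), t, h))
    if not cells:
        raise ValueError("empty scoring grid")
    return ScoringGrid(tuple(cells))


@dataclass
class DoseGrid:
    """Per-ring collision kerma per decay with type-A uncertainties."""

    channel: str
    grid: ScoringGrid
    kerma: np.ndarray  # Gy per decay, per cell
    rel_uncertainty: np.ndarray  # fractional type-A
    n_histories: int
    seed: int
    mode: str = "full"  # or "primary_only"
    estimator: str = "collision kerma, track-length"

    def __post_init__(self):
        self.kerma = np.asarray(self.kerma, dtype=float)
        self.rel_uncertainty = np.asarray(self.rel_uncertainty, dtype=float)
        if np.any(self.kerma < 0) or np.any(self.rel_uncertainty < 0):
            raise ValueError("kerma and uncertainties must be non-negative")

    def value_at(self, r: float, theta: float = 90.0) -> float:
        return float(self.kerma[self.grid.index_of(r, theta)])

    def uncertainty_at(self, r: float, theta: float = 90.0) -> float:
        return float(self.rel_uncertainty[self.grid.index_of(r, theta)])

    def kerma_approximation_flags(self) -> np.ndarray:
        """True where r < 0.7 cm, i.e. kerma only approximates dose."""
        return np.array([c.r < KERMA_APPROX_RADIUS for c in self.grid.cells])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_cm": [c.r for c in self.grid.cells],
            "theta_deg": [c.theta for c in self.grid.cells],
            "kerma_gy_per_decay": self.kerma,
            "rel_uncertainty": self.rel_uncertainty,
            "kerma_approximation": self.kerma_approximation_flags(),
        })

    def to_csv(self, path) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        meta = {
            "channel": self.channel, "n_histories": int(self.n_histories),
            "seed": int(self.seed), "mode": self.mode, "estimator": self.estimator,
            "cells": [
                {"r": c.r, "theta": c.theta, "thickness": c.thickness,
                 "height": c.height}
                for c in self.grid.cells
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "DoseGrid":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        meta = json.loads(path.with_suffix(".json").read_text())
        cells = tuple(
            RingCell(c["r"], c["theta"], c["thickness"], c["height"])
            for c in meta["cells"]
        )
        return cls(
            channel=meta["channel"], grid=ScoringGrid(cells),
            kerma=df["kerma_gy_per_decay"].to_numpy(),
            rel_uncertainty=df["rel_uncertainty"].to_numpy(),
            n_histories=meta["n_histories"], seed=meta["seed"],
            mode=meta["mode"], estimator=meta["estimator"],
        )


@dataclass
class AirKermaResult:
    """Air-kerma strength per decay rate, cGy cm^2 h^-1 Bq^-1."""

    sk_per_bq: float
    rel_uncertainty: float
    scoring_distance: float  # cm
    n_histories: int = 0
    seed: int = 0
    channel: str = ""

    def __post_init__(self):
        if self.sk_per_bq <= 0:
            raise ValueError("air-kerma strength must be positive")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "sk_per_bq": self.sk_per_bq,
            "rel_uncertainty": self.rel_uncertainty,
            "scoring_distance": self.scoring_distance,
            "n_histories": int(self.n_histories),
            "seed": int(self.seed),
            "channel": self.channel,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "AirKermaResult":
        return cls(**json.loads(Path(path).read_text()))
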