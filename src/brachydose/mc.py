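"""Analog photon Monte Carlo producing water dose grids and air-kerma strength.

This is the package's simulation engine: a kerma-scoring analog photon
transport of the two-line Co-60 spectrum (1.17 and 1.33 MeV, both photons per
decay) through the encapsulated source into either a 30-cm-radius water
sphere or a 3-m air cube.  Collision kerma is scored with a track-length
estimator (track length in cell x E x mu_en/rho / cell mass), so results
approximate absorbed dose wherever charged-particle equilibrium holds
(r >~ 0.7 cm for Co-60); cells closer in carry a kerma-approximation flag.

Statistical (type A) uncertainties come from the variance over history
batches (100 batches by default).  Everything is normalized per decay;
conversions to clinical units happen at the reporting boundary
(1 Bq = 3600 decays/h, 1 U = 1 cGy cm^2 h^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .grids import AirKermaResult, DoseGrid, ScoringGrid, build_scoring_grid
from .sources import SourceSpec
from .xsdata import load_xs

__all__ = [
    "PhotonState", "CO60_LINES", "CUTOFF_MEV",
    "WATER_PHANTOM_RADIUS", "AIR_CUBE_SIDE",
    "sample_decay", "run_water_simulation", "run_air_simulation",
]

CO60_LINES = (1.17, 1.33)  # MeV, one photon of each per decay
CUTOFF_MEV = 0.010
WATER_PHANTOM_RADIUS = 30.0  # cm
AIR_CUBE_SIDE = 300.0  # cm
N_BATCHES = 100


@dataclass
class PhotonState:
    position: np.ndarray  # cm
    direction: np.ndarray  # unit vector
    energy: float  # MeV
    weight: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy < CUTOFF_MEV:
            raise ValueError("photon energy below transport cutoff")


def sample_decay(spec: SourceSpec, rng: np.random.Generator) -> list[PhotonState]:
    """One Co-60 decay: two photons from a common point uniform in the core."""
    rho = spec.core_radius * np.sqrt(rng.random())
    ang = 2 * np.pi * rng.random()
    z_lo, z_hi = spec.core_z
    pos = np.array([rho * np.cos(ang), rho * np.sin(ang),
                    z_lo + (z_hi - z_lo) * rng.random()])
    photons = []
    for e in CO60_LINES:
        cz = 2 * rng.random() - 1
        ph = 2 * np.pi * rng.random()
        sq = np.sqrt(1 - cz**2)
        photons.append(PhotonState(pos.copy(),
                                   np.array([sq * np.cos(ph), sq * np.sin(ph), cz]),
                                   e))
    return photons


def _material_arrays(spec: SourceSpec, medium: str):
    """Shared log-E grid plus per-region mu_lin / branch-fraction arrays."""
    tables = []
    densities = []
    for mat in (None, spec.core_material, spec.capsule_material, spec.cable_material):
        if mat is None:
            tab = load_xs(medium)
            rho = {"water": 1.0, "air": 0.001205}[medium]
        else:
            tab = load_xs(mat.name)
            rho = mat.density
        tables.append(tab)
        densities.append(rho)
    grid_loge = np.log(tables[0].energy)
    nmat, ng = len(tables), grid_loge.size
    log_mu_lin = np.empty((nmat, ng))
    f_pe = np.empty((nmat, ng))
    f_pe_pair = np.empty((nmat, ng))
    for i, (tab, rho) in enumerate(zip(tables, densities)):
        log_mu_lin[i] = np.log(tab.mu_rho * rho)
        f_pe[i] = tab.f_photo
        f_pe_pair[i] = tab.f_photo + tab.f_pair
    med = tables[0]
    log_resp = np.log(med.energy * med.mu_en_rho * _kernels.MEV_TO_GY_CM2_G)
    return grid_loge, log_mu_lin, f_pe, f_pe_pair, log_resp


def _geometry(spec: SourceSpec):
    cz = spec.core_z
    kz = spec.capsule_z
    return (spec.core_radius, cz[0], cz[1],
            spec.capsule_radius, kz[0], kz[1], kz[0] - spec.cable_length)


def _normalize(scores, volumes, n_histories):
    """Batch sums -> per-decay kerma and type-A relative uncertainty.

    Scores are track length x E x (mu_en/rho) x (MeV->Gy conversion); dividing
    by cell volume turns the track-length fluence estimate into kerma in Gy.
    """
    nb = scores.shape[0]
    counts = np.diff(np.ceil(np.arange(nb + 1) * n_histories / nb)).astype(np.int64)
    kerma = scores.sum(axis=0) / volumes / n_histories
    batch_means = scores / counts[:, None] / volumes[None, :]
    sem = batch_means.std(axis=0, ddof=1) / np.sqrt(nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(kerma > 0, sem / np.where(kerma > 0, kerma, 1.0), 0.0)
    return kerma, rel


def run_water_simulation(spec: SourceSpec, grid: ScoringGrid, n_histories: int,
                         seed: int, mode: str = "full") -> DoseGrid:
    """Score collision kerma per decay on ring cells in the 30-cm water sphere."""
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    if mode not in ("full", "primary_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(grid) == 0:
        raise ValueError("empty scoring grid")
    for c in grid.cells:
        if c.r > 10.0 + 1e-9:
            raise ValueError("scoring cells must lie within r <= 10 cm")
    rho_in, rho_out, z_lo, z_hi, vol = grid.arrays()
    arrays = _material_arrays(spec, "water")
    scores, _ = _kernels.run_transport(
        int(seed) & 0x7FFFFFFF, int(n_histories), N_BATCHES,
        *_geometry(spec), 0, WATER_PHANTOM_RADIUS, *arrays,
        rho_in**2, rho_out**2, z_lo, z_hi,
        np.array(CO60_LINES), CUTOFF_MEV, mode == "primary_only",
    )
    kerma, rel = _normalize(scores, vol, n_histories)
    return DoseGrid(channel=spec.channel_id, grid=grid, kerma=kerma,
                    rel_uncertainty=rel, n_histories=n_histories,
                    seed=int(seed), mode=mode)


def run_air_simulation(spec: SourceSpec, n_histories: int, seed: int,
                       scoring_distance: float = 100.0) -> AirKermaResult:
    """Air-kerma strength per decay rate from the 3-m dry-air cube.

    A 0.1 cm (radial) x 0.1 cm (axial) ring on the transverse axis at
    ``scoring_distance`` scores air collision kerma; S_k is the kerma rate
    times distance squared, in cGy cm^2 h^-1 per Bq (3600 decays/h).
    """
    if scoring_distance <= spec.capsule_radius:
        raise ValueError("scoring distance must exceed the capsule radius")
    if scoring_distance >= AIR_CUBE_SIDE / 2:
        raise ValueError("scoring distance must lie inside the air cube")
    d = float(scoring_distance)
    rho_in = np.array([d - 0.05])
    rho_out = np.array([d + 0.05])
    z_lo = np.array([-0.05])
    z_hi = np.array([0.05])
    vol = np.pi * (rho_out**2 - rho_in**2) * (z_hi - z_lo)
    arrays = _material_arrays(spec, "air")
    scores, _ = _kernels.run_transport(
        int(seed) & 0x7FFFFFFF, int(n_histories), N_BATCHES,
        *_geometry(spec), 1, AIR_CUBE_SIDE / 2, *arrays,
        rho_in**2, rho_out**2, z_lo, z_hi,
        np.array(CO60_LINES), CUTOFF_MEV, False,
    )
    kerma, rel = _normalize(scores, vol, n_histories)
    sk = float(kerma[0]) * d * d * 100.0 * 3600.0  # Gy -> cGy, per-decay -> per-hour
    return AirKermaResult(sk_per_bq=sk, rel_uncertainty=float(rel[0]),
                          scoring_distance=d, n_histories=n_histories,
                          seed=int(seed), channel=spec.channel_id)


def energy_balance(spec: SourceSpec, n_histories: int, seed: int,
                   medium: str = "water") -> np.ndarray:
    """(emitted, absorbed, escaped) MeV totals — conservation diagnostic."""
    arrays = _material_arrays(spec, medium)
    kind = 0 if medium == "water" else 1
    size = WATER_PHANTOM_RADIUS if medium == "water" else AIR_CUBE_SIDE / 2
    empty = np.empty(0)
    _, ebal = _kernels.run_transport(
        int(seed) & 0x7FFFFFFF, int(n_histories), N_BATCHES,
        *_geometry(spec), kind, size, *arrays,
        empty, empty, empty, empty,
        np.array(CO60_LINES), CUTOFF_MEV, False,
    )
    return ebal.sum(axis=0)
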