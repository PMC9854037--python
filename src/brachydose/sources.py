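"""Source geometry and materials for the GZP3 Co-60 afterloader.

The afterloader drives two encapsulated cylindrical Co-60 source designs:
channels 1 and 2 share a 0.5 mm radius x 1 mm long active core, channel 3 a
0.5 mm radius x 2 mm long core.  The core sits centered in a stainless-steel
capsule (2.1 mm outer diameter, 5.8 mm long); a stainless-steel cable stub of
configurable length is attached to the proximal (-z) capsule end and is the
only structure shadowing the theta -> 180 deg directions.

Coordinates: z along the source long axis with +z toward the distal tip,
origin at the active-core center; the polar angle theta is measured from +z,
so theta0 = 90 deg is the transverse plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "MaterialSpec",
    "SourceSpec",
    "MATERIALS",
    "builtin_source",
    "bare_point_source",
    "path_lengths",
    "load_source_config",
    "dump_source_config",
]


@dataclass(frozen=True)
class MaterialSpec:
    """A material as a density plus elemental mass fractions."""

    name: str
    density: float  # g/cm^3
    composition: tuple[tuple[str, float], ...]  # (element symbol, mass fraction)

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1 +- 1e-3"
            )


#: Materials of the source assembly and phantoms, as specified by the vendor.
MATERIALS: dict[str, MaterialSpec] = {
    "cobalt": MaterialSpec("cobalt", 8.85, (("Co", 1.0),)),
    "steel1": MaterialSpec(
        "steel1",
        7.98,
        (("C", 0.001), ("Si", 0.007), ("Mn", 0.01), ("Cr", 0.18),
         ("Ni", 0.1), ("Ti", 0.004), ("Fe", 0.698)),
    ),
    "steel2": MaterialSpec(
        "steel2",
        7.93,
        (("C", 0.001), ("Si", 0.007), ("Mn", 0.01), ("Cr", 0.18),
         ("Ni", 0.09), ("Fe", 0.712)),
    ),
    "air": MaterialSpec(
        "air",
        0.001205,
        (("C", 0.000124), ("N", 0.755268), ("O", 0.231781), ("Ar", 0.012827)),
    ),
    "water": MaterialSpec("water", 1.0, (("H", 0.111901), ("O", 0.888099))),
}


@dataclass(frozen=True)
class SourceSpec:
    """Geometry and materials of one encapsulated cylindrical source."""

    channel_id: str  # "1_2", "3" (or "point" for the bare test source)
    core_radius: float  # cm
    core_length: float  # cm (the TG-43 active length L)
    capsule_outer_diameter: float  # cm
    capsule_length: float  # cm
    core_material: MaterialSpec = MATERIALS["cobalt"]
    capsule_material: MaterialSpec = MATERIALS["steel1"]
    core_axial_offset: float = 0.0  # cm, core center relative to capsule center
    cable_material: MaterialSpec = MATERIALS["steel2"]
    cable_length: float = 2.0  # cm, proximal stub; 0 disables it

    def __post_init__(self):
        r_cap = self.capsule_outer_diameter / 2.0
        if self.core_radius > r_cap + 1e-12:
            raise ValueError("core does not fit radially inside the capsule")
        half = self.capsule_length / 2.0
        lo = self.core_axial_offset - self.core_length / 2.0
        hi = self.core_axial_offset + self.core_length / 2.0
        if lo < -half - 1e-12 or hi > half + 1e-12:
            raise ValueError("core does not fit axially inside the capsule")
        if self.cable_length < 0:
            raise ValueError("cable_length must be >= 0")

    # -- derived extents, in the core-centered frame ---------------------
    @property
    def capsule_radius(self) -> float:
        return self.capsule_outer_diameter / 2.0

    @property
    def core_z(self) -> tuple[float, float]:
        return (-self.core_length / 2.0, self.core_length / 2.0)

    @property
    def capsule_z(self) -> tuple[float, float]:
        half = self.capsule_length / 2.0
        return (-self.core_axial_offset - half, -self.core_axial_offset + half)

    @property
    def assembly_z(self) -> tuple[float, float]:
        z_lo, z_hi = self.capsule_z
        return (z_lo - self.cable_length, z_hi)

    @property
    def L(self) -> float:
        """TG-43 active length, cm."""
        return self.core_length


_BUILTIN = {
    "1_2": dict(core_length=0.1),
    "3": dict(core_length=0.2),
}


def builtin_source(channel_id: str, **overrides) -> SourceSpec:
    """Packaged source design for a channel (``"1_2"`` or ``"3"``).

    Keyword overrides replace any :class:`SourceSpec` field (e.g. a perturbed
    ``core_radius`` for the geometry-tolerance sweep).
    """
    key = str(channel_id).replace("&", "_").replace("12", "1_2")
    if key not in _BUILTIN:
        raise ValueError(f"unknown channel id {channel_id!r}; expected '1_2' or '3'")
    fields = dict(
        channel_id=key,
        core_radius=0.05,
        capsule_outer_diameter=0.21,
        capsule_length=0.58,
        **_BUILTIN[key],
    )
    fields.update(overrides)
    return SourceSpec(**fields)


def bare_point_source(radius: float = 1e-4) -> SourceSpec:
    """A near-point, unencapsulated source used by transport oracles.

    The 'core' is a tiny water cylinder (no self-absorption, no capsule, no
    cable), so primary transport reduces to the closed-form exp(-mu d)/d^2 law.
    """
    return SourceSpec(
        channel_id="point",
        core_radius=radius,
        core_length=2 * radius,
        capsule_outer_diameter=2 * radius,
        capsule_length=2 * radius,
        core_material=MATERIALS["water"],
        capsule_material=MATERIALS["water"],
        cable_length=0.0,
    )


# ---------------------------------------------------------------------------
# ray-path queries through the nested cylinder geometry
# ---------------------------------------------------------------------------

def _cyl_radial_ts(px, py, ux, uy, radius):
    """Both parameters where the ray crosses an infinite cylinder rho=radius."""
    a = ux * ux + uy * uy
    if a < 1e-30:
        return ()
    b = px * ux + py * uy
    c = px * px + py * py - radius * radius
    disc = b * b - a * c
    if disc <= 0.0:
        return ()
    sq = math.sqrt(disc)
    return ((-b - sq) / a, (-b + sq) / a)


def _plane_t(pz, uz, z0):
    if abs(uz) < 1e-30:
        return ()
    return ((z0 - pz) / uz,)


def _region_of(spec: SourceSpec, x, y, z):
    rho2 = x * x + y * y
    c_lo, c_hi = spec.core_z
    if rho2 <= spec.core_radius**2 + 1e-15 and c_lo - 1e-12 <= z <= c_hi + 1e-12:
        return spec.core_material.name
    k_lo, k_hi = spec.capsule_z
    if rho2 <= spec.capsule_radius**2 + 1e-15:
        if k_lo - 1e-12 <= z <= k_hi + 1e-12:
            return spec.capsule_material.name
        if spec.cable_length > 0 and k_lo - spec.cable_length - 1e-12 <= z < k_lo:
            return spec.cable_material.name
    return None


def path_lengths(
    spec: SourceSpec,
    origin: Sequence[float],
    direction: Sequence[float],
) -> list[tuple[str, float]]:
    """Ordered (material, segment length) pairs along a ray through the source.

    The ray starts at ``origin`` (which must lie inside or on the source
    assembly, capsule plus cable stub) and is followed until it exits the
    assembly; segment lengths are >= 0 and sum to the chord length through the
    assembly cylinder.
    """
    p = np.asarray(origin, dtype=float)
    u = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(u))
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"direction must be a unit vector (|u| = {norm})")
    a_lo, a_hi = spec.assembly_z
    rho = math.hypot(p[0], p[1])
    if rho > spec.capsule_radius + 1e-9 or not (a_lo - 1e-9 <= p[2] <= a_hi + 1e-9):
        raise ValueError("origin lies outside the source assembly")

    # candidate boundary crossings
    ts = set()
    for t in _cyl_radial_ts(p[0], p[1], u[0], u[1], spec.core_radius):
        ts.add(t)
    for t in _cyl_radial_ts(p[0], p[1], u[0], u[1], spec.capsule_radius):
        ts.add(t)
    for z0 in (*spec.core_z, *spec.capsule_z, a_lo):
        for t in _plane_t(p[2], u[2], z0):
            ts.add(t)

    # exit parameter from the assembly cylinder
    t_exit = math.inf
    for t in _cyl_radial_ts(p[0], p[1], u[0], u[1], spec.capsule_radius):
        if t > 1e-12:
            t_exit = min(t_exit, t)
    rad_exit = t_exit
    for z0 in (a_lo, a_hi):
        for t in _plane_t(p[2], u[2], z0):
            if t > 1e-12:
                t_exit = min(t_exit, t)
    if not math.isfinite(t_exit):  # ray along axis inside: exits via a z plane
        raise ValueError("ray never exits the assembly (degenerate direction)")
    # a radial exit below the capsule z-range is spurious when ray leaves via caps
    del rad_exit

    knots = sorted({0.0, t_exit} | {t for t in ts if 1e-12 < t < t_exit})
    segments: list[tuple[str, float]] = []
    for t0, t1 in zip(knots[:-1], knots[1:]):
        tm = 0.5 * (t0 + t1)
        q = p + tm * u
        mat = _region_of(spec, q[0], q[1], q[2])
        if mat is None:
            continue
        if segments and segments[-1][0] == mat:
            segments[-1] = (mat, segments[-1][1] + (t1 - t0))
        else:
            segments.append((mat, t1 - t0))
    return segments


# ---------------------------------------------------------------------------
# plain-config serialization
# ---------------------------------------------------------------------------

def _material_to_dict(m: MaterialSpec) -> dict:
    return {
        "name": m.name,
        "density": m.density,
        "composition": {el: w for el, w in m.composition},
    }


def _material_from_dict(d: dict) -> MaterialSpec:
    return MaterialSpec(
        d["name"], float(d["density"]),
        tuple((el, float(w)) for el, w in d["composition"].items()),
    )


def dump_source_config(spec: SourceSpec, path) -> None:
    doc = {
        "channel_id": spec.channel_id,
        "core_radius": spec.core_radius,
        "core_length": spec.core_length,
        "capsule_outer_diameter": spec.capsule_outer_diameter,
        "capsule_length": spec.capsule_length,
        "core_axial_offset": spec.core_axial_offset,
        "cable_length": spec.cable_length,
        "core_material": _material_to_dict(spec.core_material),
        "capsule_material": _material_to_dict(spec.capsule_material),
        "cable_material": _material_to_dict(spec.cable_material),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_source_config(path) -> SourceSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("core_material", "capsule_material", "cable_material"):
        if key in doc:
            doc[key] = _material_from_dict(doc[key])
    return SourceSpec(**doc)
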