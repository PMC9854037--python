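"""Source geometry: builtin specs, materials, and ray-path queries."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from brachydose.sources import (MATERIALS, MaterialSpec, SourceSpec,
                                bare_point_source, builtin_source,
                                dump_source_config, load_source_config,
                                path_lengths)


class TestMaterials:
    def test_all_compositions_sum_to_one(self):
        for mat in MATERIALS.values():
            assert abs(sum(w for _, w in mat.composition) - 1.0) <= 1e-3

    def test_vendor_densities(self):
        assert MATERIALS["cobalt"].density == 8.85
        assert MATERIALS["steel1"].density == 7.98
        assert MATERIALS["steel2"].density == 7.93
        assert MATERIALS["air"].density == 0.001205

    def test_invalid_materials_rejected(self):
        with pytest.raises(ValueError):
            MaterialSpec("bad", -1.0, (("Fe", 1.0),))
        with pytest.raises(ValueError):
            MaterialSpec("bad", 1.0, (("Fe", 0.5), ("Cr", 0.4)))


class TestBuiltinSource:
    @pytest.mark.parametrize("channel, L", [("1_2", 0.1), ("3", 0.2)])
    def test_active_lengths(self, channel, L):
        spec = builtin_source(channel)
        assert spec.core_length == pytest.approx(L)
        assert spec.core_radius == pytest.approx(0.05)
        assert spec.capsule_outer_diameter == pytest.approx(0.21)
        assert spec.capsule_length == pytest.approx(0.58)

    def test_core_material_is_cobalt(self):
        spec = builtin_source("1_2")
        assert spec.core_material.name == "cobalt"
        assert spec.core_material.density == pytest.approx(8.85)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            builtin_source("7")

    def test_core_must_fit_inside_capsule(self):
        with pytest.raises(ValueError):
            builtin_source("1_2", core_length=0.6)
        with pytest.raises(ValueError):
            builtin_source("1_2", core_radius=0.2)


class TestPathLengths:
    def test_transverse_steel_thickness(self, source_12):
        segs = path_lengths(source_12, (0, 0, 0), (1, 0, 0))
        assert [m for m, _ in segs] == ["cobalt", "steel1"]
        assert segs[0][1] == pytest.approx(0.05, abs=1e-12)
        assert segs[1][1] == pytest.approx(0.105 - 0.05, abs=1e-12)

    def test_distal_axial_steel_thickness(self, source_12):
        segs = path_lengths(source_12, (0, 0, 0), (0, 0, 1.0))
        assert segs[0] == ("cobalt", pytest.approx(0.05))
        assert segs[1][0] == "steel1"
        assert segs[1][1] == pytest.approx((0.58 - 0.1) / 2, abs=1e-12)

    def test_proximal_ray_crosses_cable(self, source_12):
        segs = path_lengths(source_12, (0, 0, 0), (0, 0, -1.0))
        assert [m for m, _ in segs] == ["cobalt", "steel1", "steel2"]
        assert segs[2][1] == pytest.approx(source_12.cable_length, abs=1e-12)

    def test_non_unit_direction_rejected(self, source_12):
        with pytest.raises(ValueError):
            path_lengths(source_12, (0, 0, 0), (0.5, 0, 0))

    def test_origin_outside_rejected(self, source_12):
        with pytest.raises(ValueError):
            path_lengths(source_12, (1.0, 0, 0), (1, 0, 0))

    def test_segments_sum_to_chord_on_random_rays(self, source_12):
        """Sum of material segments equals the forward chord through the
        assembly cylinder, for >= 1000 random interior rays."""
        rng = np.random.default_rng(42)
        spec = source_12
        R = spec.capsule_radius
        z_lo, z_hi = spec.assembly_z
        for _ in range(1000):
            rho = R * math.sqrt(rng.random())
            ang = 2 * math.pi * rng.random()
            p = np.array([rho * math.cos(ang), rho * math.sin(ang),
                          z_lo + (z_hi - z_lo) * rng.random()])
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            segs = path_lengths(spec, p, u)
            total = sum(ln for _, ln in segs)
            # independent chord: forward exit distance from the convex cylinder
            a = u[0] ** 2 + u[1] ** 2
            t_rad = math.inf
            if a > 1e-30:
                b = p[0] * u[0] + p[1] * u[1]
                disc = b * b - a * (p[0] ** 2 + p[1] ** 2 - R * R)
                t_rad = (-b + math.sqrt(disc)) / a
            t_cap = math.inf
            if abs(u[2]) > 1e-30:
                t_cap = ((z_hi if u[2] > 0 else z_lo) - p[2]) / u[2]
            assert total == pytest.approx(min(t_rad, t_cap), abs=1e-4)

    def test_material_segments_match_ray_marching(self, source_12):
        """Per-material lengths agree with a brute-force ray-marching oracle."""
        rng = np.random.default_rng(7)
        spec = source_12
        step = 1e-5
        for _ in range(40):
            p = np.array([0.04 * rng.random(), 0.04 * rng.random(),
                          -0.04 + 0.08 * rng.random()])
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            segs = dict()
            for m, ln in path_lengths(spec, p, u):
                segs[m] = segs.get(m, 0.0) + ln
            # march
            n = int(3.0 / step)
            ts = (np.arange(n) + 0.5) * step
            pts = p[None, :] + ts[:, None] * u[None, :]
            rho2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
            z = pts[:, 2]
            in_core = (rho2 <= spec.core_radius**2) & (np.abs(z) <= spec.core_length / 2)
            k_lo, k_hi = spec.capsule_z
            in_cap = (rho2 <= spec.capsule_radius**2) & (z >= k_lo) & (z <= k_hi) & ~in_core
            in_cab = ((rho2 <= spec.capsule_radius**2) & (z >= k_lo - spec.cable_length)
                      & (z < k_lo))
            oracle = {
                "cobalt": in_core.sum() * step,
                "steel1": in_cap.sum() * step,
                "steel2": in_cab.sum() * step,
            }
            for m, ln in oracle.items():
                assert segs.get(m, 0.0) == pytest.approx(ln, abs=5e-4)

    @given(st.floats(-0.9, 0.9), st.floats(0, 2 * math.pi))
    def test_mirror_symmetry_without_cable(self, cz, phi):
        """With a centered core and no cable the geometry is mirror-symmetric
        about the capsule mid-plane."""
        spec = builtin_source("1_2", cable_length=0.0)
        sq = math.sqrt(1 - cz * cz)
        u = (sq * math.cos(phi), sq * math.sin(phi), cz)
        um = (u[0], u[1], -u[2])
        a = path_lengths(spec, (0.02, 0.0, 0.01), u)
        b = path_lengths(spec, (0.02, 0.0, -0.01), um)
        assert [m for m, _ in a] == [m for m, _ in b]
        np.testing.assert_allclose([x for _, x in a], [x for _, x in b], atol=1e-9)


class TestConfigRoundTrip:
    def test_packaged_defaults_match_builtin_sources(self):
        from importlib import resources
        for ch, tag in (("1_2", "12"), ("3", "3")):
            ref = resources.files("brachydose").joinpath(f"data/source_ch{tag}.yaml")
            with resources.as_file(ref) as path:
                assert load_source_config(path) == builtin_source(ch)

    def test_yaml_round_trip(self, tmp_path, source_3):
        path = tmp_path / "source.yaml"
        dump_source_config(source_3, path)
        loaded = load_source_config(path)
        assert loaded == source_3

    def test_bare_point_source_has_no_metal(self):
        spec = bare_point_source()
        assert spec.core_material.name == "water"
        assert spec.cable_length == 0.0
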