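"""Field construction, monotone enforcement, layers, rescaling, features."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iczone as iz
from conftest import pava_nonincreasing, random_synthetic_field


class TestDomainTypes:
    def test_profile_rejects_inconsistent_heights(self):
        with pytest.raises(iz.ValidationError):
            iz.AnthropometricProfile("x", 175, 109, 139, 84)  # shoulder below elbow

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(body_height=-1),
            dict(body_mass=0),
            dict(limb_side="both"),
            dict(reach_convention="elbow"),
        ],
    )
    def test_profile_field_validation(self, kwargs):
        base = dict(
            subject_id="x", body_height=175.0, shoulder_height=139.0,
            elbow_height=109.0, body_mass=84.0,
        )
        base.update(kwargs)
        with pytest.raises(iz.ValidationError):
            iz.AnthropometricProfile(**base)

    @pytest.mark.parametrize(
        "alpha,z,r,force", [(200, 139, 30, 50), (0, 139, -1, 50), (0, 139, 30, -5)]
    )
    def test_sample_validation(self, alpha, z, r, force):
        with pytest.raises(iz.ValidationError):
            iz.StrengthSample(alpha=alpha, z=z, r=r, force=force)

    def test_grid_spec_must_be_positive(self):
        with pytest.raises(iz.ValidationError):
            iz.GridSpec(d_r=0)

    def test_sample_beyond_declared_reach_rejected(self, profile):
        samples = tuple(
            iz.StrengthSample(0.0, 139.0, float(r), 100.0) for r in (10, 30, 70)
        )
        with pytest.raises(iz.ValidationError, match="beyond its reach"):
            iz.ICZModel(profile, samples, reach_boundary={(0.0, 139.0): 50.0})


class TestBuildStrengthField:
    def test_linear_ray_reproduced_exactly(self, linear_field):
        """Piecewise-linear interpolation of a linear force law is exact."""
        for r in linear_field.rs:
            assert linear_field.value_at(0.0, 139.0, float(r)) == pytest.approx(
                200.0 * (1 - r / 70.0), abs=1e-6
            )

    def test_extrapolation_toward_body_axis(self, linear_field):
        # samples start at r=10; the lattice reaches r=0 by linear extension
        assert linear_field.value_at(0.0, 139.0, 0.0) == pytest.approx(200.0, abs=1e-6)

    def test_non_monotone_dip_is_pooled(self, profile):
        """A single non-monotone dip (150, 140, 145, 90 N) is averaged down.

        The least-squares monotone projection pools the violating pair to
        142.5 N, so the field at the third radius cannot exceed it.
        """
        forces = [150.0, 140.0, 145.0, 90.0]
        radii = [10.0, 20.0, 30.0, 40.0]
        samples = tuple(
            iz.StrengthSample(0.0, 139.0, r, f) for r, f in zip(radii, forces)
        )
        field = iz.build_strength_field(iz.ICZModel(profile, samples))
        assert field.value_at(0.0, 139.0, 30.0) <= 142.5 + 1e-9
        vals = [field.value_at(0.0, 139.0, float(r)) for r in field.rs]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
        expected = pava_nonincreasing(forces)
        for r, e in zip(radii, expected):
            assert field.value_at(0.0, 139.0, r) == pytest.approx(e, abs=1e-9)

    def test_too_few_radii_raises_coverage_error(self, profile):
        samples = (
            iz.StrengthSample(0.0, 139.0, 10.0, 100.0),
            iz.StrengthSample(0.0, 139.0, 40.0, 60.0),
        )
        with pytest.raises(iz.CoverageError, match="alpha=0.0"):
            iz.build_strength_field(iz.ICZModel(profile, samples))

    def test_incomplete_ray_grid_raises_coverage_error(self, profile):
        # rays (0, 139) and (60, 109) present, but not their grid complements
        samples = tuple(
            iz.StrengthSample(a, z, float(r), 100.0)
            for a, z in ((0.0, 139.0), (60.0, 109.0))
            for r in (10, 30, 50)
        )
        with pytest.raises(iz.CoverageError, match="complete"):
            iz.build_strength_field(iz.ICZModel(profile, samples))

    def test_field_monotone_in_r_everywhere(self):
        field = random_synthetic_field(seed=7, noise_sd=8.0)
        diffs = np.diff(field.values, axis=2)
        assert (diffs <= 1e-9).all()

    def test_duplicate_radii_are_averaged(self, profile):
        samples = tuple(
            iz.StrengthSample(0.0, 139.0, r, f)
            for r, f in [(10, 100), (10, 110), (30, 80), (50, 40)]
        )
        field = iz.build_strength_field(iz.ICZModel(profile, samples))
        assert field.value_at(0.0, 139.0, 10.0) == pytest.approx(105.0, abs=1e-9)


class TestMonotoneEnforcement:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=300), min_size=2, max_size=25))
    def test_matches_pava_oracle_and_idempotent(self, forces):
        r = np.arange(len(forces), dtype=float)
        once = iz.enforce_monotone_decreasing(r, np.array(forces))
        assert np.allclose(once, pava_nonincreasing(forces), atol=1e-9)
        twice = iz.enforce_monotone_decreasing(r, once)
        assert np.allclose(twice, once, atol=1e-12)

    def test_adjustment_cost_not_above_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            f = rng.uniform(0, 200, size=rng.integers(3, 20))
            r = np.arange(f.size, dtype=float)
            ours = iz.enforce_monotone_decreasing(r, f)
            oracle = np.array(pava_nonincreasing(f))
            assert np.abs(ours - f).sum() <= np.abs(oracle - f).sum() + 1e-9


class TestConstantStrengthLayers:
    def test_linear_field_closed_form_boundary(self, linear_field):
        layer = iz.extract_constant_strength_layer(linear_field, 100.0)
        assert not layer.empty
        assert layer.boundary_at(0.0, 139.0) == pytest.approx(35.0, abs=1e-9)

    def test_level_above_maximum_gives_empty_layer(self, linear_field):
        layer = iz.extract_constant_strength_layer(linear_field, 250.0)
        assert layer.empty
        assert layer.boundary.max() == 0.0

    def test_level_must_be_positive(self, linear_field):
        with pytest.raises(iz.ValidationError):
            iz.extract_constant_strength_layer(linear_field, 0.0)

    def test_two_ray_boundaries_match_dense_scan(self, profile):
        """Per-ray boundary agrees with a brute-force 0.01 cm scan of the field."""
        samples = []
        for r in range(10, 71, 10):
            samples.append(iz.StrengthSample(0.0, 139.0, float(r), 200.0 * (1 - r / 70.0)))
        for r in range(10, 51, 8):
            samples.append(iz.StrengthSample(60.0, 139.0, float(r), 150.0 * (1 - r / 50.0) ** 2))
        field = iz.build_strength_field(iz.ICZModel(profile, tuple(samples)))
        for level in (20.0, 60.0, 110.0):
            layer = iz.extract_constant_strength_layer(field, level)
            for alpha in (0.0, 60.0):
                scan = np.arange(0.0, field.rs[-1] + 0.005, 0.01)
                ok = [r for r in scan if field.value_at(alpha, 139.0, float(r)) >= level]
                expected = max(ok) if ok else 0.0
                assert layer.boundary_at(alpha, 139.0) == pytest.approx(expected, abs=0.011)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=50),
        l1=st.floats(min_value=5, max_value=120),
        gap=st.floats(min_value=1, max_value=120),
    )
    def test_layers_nest(self, seed, l1, gap):
        """A higher force level always yields a boundary inside a lower one."""
        field = random_synthetic_field(seed)
        lo = iz.extract_constant_strength_layer(field, l1)
        hi = iz.extract_constant_strength_layer(field, l1 + gap)
        assert (hi.boundary <= lo.boundary + 1e-9).all()

    def test_boundary_never_exceeds_reach(self):
        field = random_synthetic_field(seed=11)
        layer = iz.extract_constant_strength_layer(field, 5.0)
        assert (layer.boundary <= field.reach + 1e-9).all()


class TestRescaleForces:
    def test_identity_at_k_one(self, linear_field):
        out = iz.rescale_forces(linear_field, 1.0)
        assert np.array_equal(out.values, linear_field.values)

    @pytest.mark.parametrize("k", [0.0, -0.5, 1.5])
    def test_scale_outside_unit_interval_rejected(self, linear_field, k):
        with pytest.raises(iz.ValidationError):
            iz.rescale_forces(linear_field, k)

    def test_halved_field_layer_matches_original_exactly(self, linear_field):
        """layer(0.5*F field, 50 N) has the same geometry as layer(F field, 100 N)."""
        original = iz.extract_constant_strength_layer(linear_field, 100.0)
        rescaled = iz.extract_constant_strength_layer(
            iz.rescale_forces(linear_field, 0.5), 50.0
        )
        assert np.array_equal(rescaled.boundary, original.boundary)

    def test_allowable_force_closed_form(self, linear_field):
        # k = 0.35 on 200*(1 - r/70): the 35 N allowable layer sits at r = 35 cm
        fd = iz.rescale_forces(linear_field, 0.35)
        layer = iz.extract_constant_strength_layer(fd, 35.0)
        assert layer.boundary_at(0.0, 139.0) == pytest.approx(35.0, abs=1e-9)

    def test_rescaling_a_layer_scales_its_level_only(self, linear_field):
        layer = iz.extract_constant_strength_layer(linear_field, 100.0)
        out = iz.rescale_forces(layer, 0.5)
        assert out.level == pytest.approx(50.0)
        assert np.array_equal(out.boundary, layer.boundary)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=30),
        m=st.integers(min_value=1, max_value=4),
        level=st.floats(min_value=10, max_value=150),
    )
    def test_commutation_bitwise_for_binary_scales(self, seed, m, level):
        """layer(rescale(field, 2^-m), 2^-m * L) == layer(field, L) bit-for-bit."""
        field = random_synthetic_field(seed)
        k = 2.0**-m
        a = iz.extract_constant_strength_layer(iz.rescale_forces(field, k), k * level)
        b = iz.extract_constant_strength_layer(field, level)
        assert np.array_equal(a.boundary, b.boundary)

    def test_commutation_near_exact_for_general_scales(self):
        field = random_synthetic_field(seed=5)
        for k in (0.35, 0.61, 0.93):
            for level in (20.0, 75.0):
                a = iz.extract_constant_strength_layer(
                    iz.rescale_forces(field, k), k * level
                )
                b = iz.extract_constant_strength_layer(field, level)
                assert np.allclose(a.boundary, b.boundary, atol=1e-9)


class TestSimplifiedFeatureExtraction:
    def test_constant_field_features(self, profile):
        """Radially constant 100 N with 60 cm reach: F1 = F3 = 100, D1 = 60."""
        samples = tuple(
            iz.StrengthSample(a, z, float(r), 100.0)
            for a in (0.0, 60.0)
            for z in (109.0, 139.0)
            for r in (20, 40, 60)
        )
        feats = iz.extract_simplified_features(iz.ICZModel(profile, samples))
        assert feats.f1 == pytest.approx(100.0, abs=1e-9)
        assert feats.f3 == pytest.approx(100.0, abs=1e-9)
        assert feats.d1 == pytest.approx(60.0, abs=1e-9)

    def test_missing_sagittal_ray_names_d1(self, profile):
        samples = tuple(
            iz.StrengthSample(a, z, float(r), 100.0)
            for a in (10.0, 60.0)
            for z in (109.0, 139.0)
            for r in (20, 40, 60)
        )
        with pytest.raises(iz.CoverageError, match="D1"):
            iz.extract_simplified_features(iz.ICZModel(profile, samples))

    def test_missing_elbow_height_names_f4(self, profile):
        samples = tuple(
            iz.StrengthSample(a, 139.0, float(r), 100.0)
            for a in (0.0, 60.0)
            for r in (20, 40, 60)
        )
        with pytest.raises(iz.CoverageError, match="F4"):
            iz.extract_simplified_features(iz.ICZModel(profile, samples))


class TestModelJsonRoundTrip:
    def test_round_trip_preserves_model(self, tmp_path, profile):
        samples = tuple(
            iz.StrengthSample(a, z, float(r), 120.0 - r)
            for a in (0.0, 60.0)
            for z in (109.0, 139.0)
            for r in (15, 35, 55)
        )
        model = iz.ICZModel(profile, samples, reach_boundary={(0.0, 139.0): 60.0})
        path = iz.save_icz_model(model, tmp_path / "m.json")
        back = iz.load_icz_model(path)
        assert back.profile == model.profile
        assert back.samples == model.samples
        assert back.reach_boundary == model.reach_boundary

    def test_missing_key_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"profile": {}}')
        with pytest.raises(iz.SchemaError, match="samples"):
            iz.load_icz_model(p)

    def test_invalid_json_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("not json")
        with pytest.raises(iz.SchemaError):
            iz.load_icz_model(p)


class TestMeshExport:
    def test_obj_and_stl_are_ascii_and_nested(self, tmp_path):
        field = random_synthetic_field(seed=2)
        low = iz.extract_constant_strength_layer(field, 35.0)
        high = iz.extract_constant_strength_layer(field, 60.0)
        p_obj = low.export_mesh(tmp_path / "low.obj")
        p_stl = high.export_mesh(tmp_path / "high.stl")
        assert p_obj.read_text().lstrip().startswith(("#", "v "))
        assert p_stl.read_text().lstrip().startswith("solid")
        # nesting visible in the exported geometry: max radius shrinks
        assert high.boundary.max() <= low.boundary.max() + 1e-9

    def test_unknown_extension_rejected(self, tmp_path):
        field = random_synthetic_field(seed=2)
        layer = iz.extract_constant_strength_layer(field, 35.0)
        with pytest.raises(iz.ValidationError):
            layer.export_mesh(tmp_path / "x.ply")
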