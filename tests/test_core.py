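import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import mmphasor.core as core
from mmphasor.core import (
    EquivalentRetarder,
    LayeredMediumSpec,
    MuellerImage,
    RetarderSpec,
    double_pass_correct,
    equivalent_retarder,
    flip_circular_handedness,
    fold_orientation,
    intensities_from_stokes,
    layered_mueller,
    propagate,
    retardance_from_physical,
    retarder_mueller,
    stokes_from_intensities,
    wrap_retardance,
)


class TestStokes:
    def test_pure_h(self):
        np.testing.assert_allclose(
            stokes_from_intensities(1, 0.5, 0, 0.5, 0.5, 0.5), [1, 1, 0, 0])

    def test_pure_45(self):
        np.testing.assert_allclose(
            stokes_from_intensities(0.5, 1, 0.5, 0, 0.5, 0.5), [1, 0, 1, 0])

    def test_pure_rcp(self):
        np.testing.assert_allclose(
            stokes_from_intensities(0.5, 0.5, 0.5, 0.5, 1, 0), [1, 0, 0, 1])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            stokes_from_intensities(-0.1, 0.5, 0, 0.5, 0.5, 0.5)

    def test_intensities_from_h(self):
        np.testing.assert_allclose(
            intensities_from_stokes([1, 1, 0, 0]), (1, 0, 0.5, 0.5))

    def test_intensities_from_45(self):
        np.testing.assert_allclose(
            intensities_from_stokes([1, 0, 1, 0]), (0.5, 0.5, 1, 0))

    def test_intensities_general(self):
        # Direct evaluation of the projection formulas.
        np.testing.assert_allclose(
            intensities_from_stokes([2, 1, -1, 0]), (1.5, 0.5, 0.5, 1.5))


class TestPropagate:
    def test_identity(self):
        np.testing.assert_allclose(propagate(np.eye(4), [1, 1, 0, 0]), [1, 1, 0, 0])

    def test_half_wave_flips_circular(self):
        m = retarder_mueller(180.0, 0.0)
        np.testing.assert_allclose(propagate(m, [1, 0, 0, 1]), [1, 0, 0, -1],
                                   atol=1e-12)

    def test_reference_film_times_h(self, film_matrix_printed):
        # Matrix-vector product over the printed entries.
        out = propagate(film_matrix_printed, [1, 1, 0, 0])
        np.testing.assert_allclose(out, [1.012, 1.011, 0.383, 0.032], atol=1e-12)


class TestRetarderMueller:
    def test_zero_retardance_is_identity(self):
        for alpha in (0.0, 30.0, -60.0):
            np.testing.assert_allclose(retarder_mueller(0.0, alpha), np.eye(4),
                                       atol=1e-15)

    def test_half_wave_axis_zero(self):
        np.testing.assert_allclose(retarder_mueller(180.0, 0.0),
                                   np.diag([1, 1, -1, -1]), atol=1e-12)

    def test_quarter_wave_at_45(self):
        expected = np.array([[1, 0, 0, 0],
                             [0, 0, 0, -1],
                             [0, 0, 1, 0],
                             [0, 1, 0, 0]], dtype=float)
        np.testing.assert_allclose(retarder_mueller(90.0, 45.0), expected,
                                   atol=1e-12)

    def test_rotation_block_is_orthogonal(self, rng):
        r = rng.uniform(0, 180, 20)
        a = rng.uniform(-90, 90, 20)
        m = retarder_mueller(r, a)
        block = m[..., 1:, 1:]
        np.testing.assert_allclose(block @ np.swapaxes(block, -1, -2),
                                   np.broadcast_to(np.eye(3), block.shape),
                                   atol=1e-12)

    def test_accepts_spec(self):
        spec = RetarderSpec(60.0, 30.0)
        np.testing.assert_allclose(retarder_mueller(spec),
                                   retarder_mueller(60.0, 30.0))


class TestPhysicalRetardance:
    def test_collagen_layer(self):
        assert retardance_from_physical(0.0017, 50.0, 808.0) == pytest.approx(
            37.87, abs=0.005)

    def test_zero_birefringence(self):
        assert retardance_from_physical(0.0, 10.0, 500.0) == 0.0

    def test_thick_film_unwrapped(self):
        assert retardance_from_physical(0.0077, 500.0, 808.0) == pytest.approx(
            1715.3, abs=0.05)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            retardance_from_physical(0.001, -1.0, 808.0)
        with pytest.raises(ValueError):
            retardance_from_physical(0.001, 1.0, 0.0)


class TestWrapAndDoublePass:
    @pytest.mark.parametrize("raw,expected", [(55.0, 55.0), (275.4, 84.6),
                                              (360.0, 0.0), (180.0, 180.0)])
    def test_wrap(self, raw, expected):
        assert wrap_retardance(raw) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(0.0, 180.0))
    def test_wrap_idempotent_on_observable_range(self, r):
        assert wrap_retardance(r) == pytest.approx(r, abs=1e-9)

    def test_wrap_rejects_negative(self):
        with pytest.raises(ValueError):
            wrap_retardance(-1.0)

    @pytest.mark.parametrize("meas,exact", [(360.0, 0.0), (304.5, 55.5),
                                            (180.0, 180.0)])
    def test_double_pass(self, meas, exact):
        assert double_pass_correct(meas) == pytest.approx(exact)

    def test_double_pass_domain(self):
        with pytest.raises(ValueError):
            double_pass_correct(400.0)


class TestFoldOrientation:
    def test_alias(self):
        assert fold_orientation(94.3) == pytest.approx(-85.7)

    def test_upper_bound_included(self):
        assert fold_orientation(90.0) == 90.0
        assert fold_orientation(-90.0) == 90.0

    @given(st.floats(-1000, 1000), st.integers(-5, 5))
    def test_periodicity(self, a, k):
        assert fold_orientation(a + 180.0 * k) == pytest.approx(
            fold_orientation(a), abs=1e-6)


class TestLayered:
    def test_single_layer(self):
        spec = RetarderSpec(37.87, 10.0)
        np.testing.assert_allclose(layered_mueller([spec]),
                                   retarder_mueller(spec))

    def test_coaxial_sum(self):
        a = RetarderSpec(30.0, 25.0)
        b = RetarderSpec(45.0, 25.0)
        np.testing.assert_allclose(layered_mueller([a, b]),
                                   retarder_mueller(75.0, 25.0), atol=1e-12)

    def test_two_layer_equivalent_retardance(self):
        layers = [RetarderSpec(37.87, 0.0), RetarderSpec(37.87, 10.0)]
        eq = equivalent_retarder(layers)
        # Co-axial composition identity:
        # cos(R_eq/2) = cos^2(R/2) - sin^2(R/2) cos(2 delta_alpha)
        h = np.radians(37.87 / 2)
        expected = 2 * np.degrees(np.arccos(
            np.cos(h) ** 2 - np.sin(h) ** 2 * np.cos(np.radians(20.0))))
        assert eq.total_deg == pytest.approx(expected, abs=1e-9)
        assert eq.total_deg == pytest.approx(74.5, abs=0.1)

    def test_product_is_nondepolarizing_retarder(self, rng):
        from mmphasor.lucchipman import lc_decompose

        layers = [RetarderSpec(rng.uniform(10, 170), rng.uniform(-90, 90))
                  for _ in range(4)]
        res = lc_decompose(layered_mueller(layers))
        assert res.D < 1e-9
        assert res.P_d == pytest.approx(1.0, abs=1e-9)

    def test_order_flag(self):
        layers = [RetarderSpec(60.0, 0.0), RetarderSpec(60.0, 30.0)]
        fwd = layered_mueller(layers)
        rev = layered_mueller(layers, order="reversed")
        np.testing.assert_allclose(rev, layered_mueller(layers[::-1]))
        assert not np.allclose(fwd, rev)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            layered_mueller([])


class TestEquivalentRetarder:
    def _oracle_total(self, layers):
        """Independent composition oracle via scipy rotations.

        A retarder acts on the Poincare sphere as the rotation by R about
        the axis (cos 2a, sin 2a, 0); the equivalent retarder's total angle
        is the magnitude of the composed rotation.
        """
        rot = Rotation.identity()
        for spec in layers:
            axis = np.array([np.cos(np.radians(2 * spec.orientation_deg)),
                             np.sin(np.radians(2 * spec.orientation_deg)), 0.0])
            rot = Rotation.from_rotvec(np.radians(spec.retardance_deg) * axis) * rot
        angle = np.degrees(np.linalg.norm(rot.as_rotvec()))
        return min(angle, 360.0 - angle)

    def test_matches_rotation_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(1, 5)
            layers = [RetarderSpec(float(rng.uniform(5, 175)),
                                   float(rng.uniform(-90, 90)))
                      for _ in range(n)]
            eq = equivalent_retarder(layers)
            assert eq.total_deg == pytest.approx(self._oracle_total(layers),
                                                 abs=1e-8)

    def test_linear_part_matches_mueller_element(self, rng):
        # For the composed Mueller matrix, m33 = cos(R_linear) of the
        # circular-linear factorization; cross-check against the product.
        for _ in range(25):
            layers = [RetarderSpec(float(rng.uniform(5, 175)),
                                   float(rng.uniform(-90, 90)))
                      for _ in range(3)]
            eq = equivalent_retarder(layers)
            m = layered_mueller(layers)
            assert np.cos(np.radians(eq.linear_deg)) == pytest.approx(
                m[3, 3], abs=1e-9)

    def test_accepts_medium_spec(self):
        spec = LayeredMediumSpec((RetarderSpec(30.0, 0.0),))
        eq = equivalent_retarder(spec)
        assert isinstance(eq, EquivalentRetarder)
        assert eq.total_deg == pytest.approx(30.0)


class TestHandednessFlip:
    def test_involution(self, film_matrix_printed):
        flipped = flip_circular_handedness(film_matrix_printed)
        np.testing.assert_allclose(flip_circular_handedness(flipped),
                                   film_matrix_printed)

    def test_touches_only_circular_row_col(self, film_matrix_printed):
        flipped = flip_circular_handedness(film_matrix_printed)
        np.testing.assert_allclose(flipped[:3, :3], film_matrix_printed[:3, :3])
        np.testing.assert_allclose(flipped[3, :3], -film_matrix_printed[3, :3])
        np.testing.assert_allclose(flipped[:3, 3], -film_matrix_printed[:3, 3])
        assert flipped[3, 3] == film_matrix_printed[3, 3]


class TestRetarderSpec:
    def test_physical_triple_consistent(self):
        spec = RetarderSpec.from_physical(0.0017, 50.0, 808.0, orientation=5.0)
        assert spec.retardance_deg == pytest.approx(37.87, abs=0.005)
        assert spec.orientation_deg == 5.0

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError):
            RetarderSpec(90.0, 0.0, "deg", birefringence=0.0017,
                         thickness_um=50.0, wavelength_nm=808.0)

    def test_radian_unit(self):
        spec = RetarderSpec(np.pi / 2, 0.0, "rad")
        assert spec.retardance_deg == pytest.approx(90.0)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            RetarderSpec(90.0, 0.0, "turns")


class TestMuellerImage:
    def test_plane_round_trip_row_major(self, rng):
        img = MuellerImage(rng.normal(size=(5, 7, 4, 4)))
        planes = img.to_planes()
        back = MuellerImage.from_planes(planes)
        np.testing.assert_array_equal(back.m, img.m)

    def test_plane_round_trip_column_major(self, rng):
        img = MuellerImage(rng.normal(size=(5, 7, 4, 4)))
        planes = img.to_planes(order="column-major")
        back = MuellerImage.from_planes(planes, order="column-major")
        np.testing.assert_array_equal(back.m, img.m)
        wrong = MuellerImage.from_planes(planes, order="row-major")
        np.testing.assert_array_equal(wrong.m, np.swapaxes(img.m, -1, -2))

    def test_wrong_plane_count(self, rng):
        with pytest.raises(ValueError):
            MuellerImage.from_planes(rng.normal(size=(15, 4, 4)))

    def test_uniform_and_normalize(self):
        img = MuellerImage.uniform(2.0 * np.eye(4), (3, 3))
        norm = img.normalize()
        assert norm.normalized
        np.testing.assert_allclose(norm.m[0, 0], np.eye(4))
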