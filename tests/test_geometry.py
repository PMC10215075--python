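"""Geometry construction, occupancy queries and perturbation invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from mcfrw.errors import GeometryError, ParameterError
from mcfrw.fixtures import (oracle_platelet_overlaps, oracle_point_blocked,
                            oracle_segment_blocked)
from mcfrw.geometry import (AxisDistribution, CollagenLattice, DimRanges,
                            MCFGeometry, PerturbationConfig, Platelet,
                            PlateletDims, axial_gap, build_lattice,
                            default_dim_ranges, estimate_volume_fraction,
                            load_geometry, perturb, point_is_blocked,
                            sample_platelet_dims, save_geometry)


class TestAxialGap:
    def test_default_gap_value(self):
        """Mean platelet length and the 67 nm period give a_L = 39.49 nm."""
        assert axial_gap(94.51, 67.0) == pytest.approx(39.49, abs=1e-9)

    def test_platelet_filling_two_periods_has_zero_gap(self):
        assert axial_gap(134.0, 67.0) == pytest.approx(0.0, abs=1e-12)

    def test_direct_evaluation(self):
        assert axial_gap(67.0, 67.0) == pytest.approx(67.0)

    def test_negative_gap_is_an_error(self):
        with pytest.raises(GeometryError):
            axial_gap(140.0, 67.0)

    @given(st.floats(min_value=0.1, max_value=133.9))
    @settings(max_examples=50, deadline=None)
    def test_gap_plus_length_spans_two_periods(self, length):
        assert length + axial_gap(length, 67.0) == pytest.approx(134.0)


class TestDimSampling:
    def test_zero_sd_returns_the_means_exactly(self, rng):
        ranges = default_dim_ranges(calibrated=False, sd_fraction=0.0)
        dims = sample_platelet_dims(rng, ranges)
        assert (dims.width, dims.thickness, dims.length) == (41.80, 3.55,
                                                             94.51)

    def test_degenerate_range_collapses_to_the_point(self, rng):
        ax = AxisDistribution(7.0, 7.0, 7.0, 1.0)
        ranges = DimRanges(width=ax, thickness=ax, length=ax)
        for _ in range(5):
            d = sample_platelet_dims(rng, ranges)
            assert d.width == d.thickness == d.length == 7.0

    def test_thickness_draws_match_truncated_gaussian_moment(self, rng):
        """Sample mean agrees with the quadrature mean of the truncated density."""
        ranges = default_dim_ranges()
        ax = ranges.thickness
        draws = np.array([sample_platelet_dims(rng, ranges).thickness
                          for _ in range(100_000)])
        assert draws.min() >= 2.0 and draws.max() <= 5.0
        pdf = stats.norm(ax.mean, ax.sd).pdf
        norm, _ = integrate.quad(pdf, 2.0, 5.0)
        mean, _ = integrate.quad(lambda x: x * pdf(x), 2.0, 5.0)
        mean /= norm
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_calibrated_means_hit_the_model_averages(self):
        r = default_dim_ranges(calibrated=True)
        assert r.width.truncated_mean() == pytest.approx(41.80, abs=1e-6)
        assert r.thickness.truncated_mean() == pytest.approx(3.55, abs=1e-6)
        assert r.length.truncated_mean() == pytest.approx(94.51, abs=1e-6)

    def test_invalid_parameters(self, rng):
        with pytest.raises(ParameterError):
            AxisDistribution(5.0, 2.0, 3.0, 1.0)  # inverted range
        with pytest.raises(ParameterError):
            AxisDistribution(2.0, 5.0, 3.0, -1.0)  # negative sd
        with pytest.raises(ParameterError):
            PlateletDims(1.0, -1.0, 1.0)


class TestBuildLattice:
    def test_no_platelets_means_zero_mineral(self):
        geom = build_lattice(rng=0, n_platelet_layers=0)
        est = estimate_volume_fraction(geom, 10_000, rng=1)
        assert est.fraction == 0.0

    def test_column_spacing_is_twice_the_axial_period(self):
        """Unperturbed zero-scatter lattice: L-centres 134 nm apart per column."""
        ranges = default_dim_ranges(calibrated=False, sd_fraction=0.0)
        geom = build_lattice(dim_ranges=ranges, rng=0)
        centers = np.array([p.center for p in geom.platelets])
        col = centers[(np.abs(centers[:, 0] - centers[0, 0]) < 1e-9)
                      & (np.abs(centers[:, 1] - centers[0, 1]) < 1e-9)]
        z = np.sort(col[:, 2])
        assert len(z) >= 3
        assert np.allclose(np.diff(z), 134.0, atol=1e-9)

    def test_envelope_smaller_than_a_platelet_fails(self):
        with pytest.raises(GeometryError):
            build_lattice(rng=0, envelope_radius=10.0, envelope_length=50.0)

    def test_built_lattice_is_overlap_free(self, small_geometry):
        assert oracle_platelet_overlaps(small_geometry) == []

    def test_single_box_volume_fraction_matches_closed_form(self):
        from mcfrw.fixtures import make_fixture
        geom = make_fixture("single_box")  # 10x10x10 box, R=100, L=1000
        est = estimate_volume_fraction(geom, 400_000, rng=2)
        expected = 1000.0 / (math.pi * 100.0 ** 2 * 1000.0)
        assert abs(est.fraction - expected) < 3 * max(est.standard_error,
                                                      1e-6)

    def test_default_mineral_fraction_near_32_percent(self, default_fibril):
        est = estimate_volume_fraction(default_fibril, 200_000, rng=5)
        assert abs(est.fraction - 0.32) < 0.015


class TestPerturb:
    def test_zero_moves_is_identity(self, small_geometry):
        out = perturb(small_geometry, PerturbationConfig(n_moves=0))
        for a, b in zip(out.platelets, small_geometry.platelets):
            assert np.array_equal(a.center, b.center)
            assert np.array_equal(a.rotation, b.rotation)

    def test_zero_magnitude_moves_change_nothing(self, small_geometry):
        cfg = PerturbationConfig(n_moves=1000, max_translation_per_move=0.0,
                                 max_rotation_per_move=0.0, rng_seed=4)
        out = perturb(small_geometry, cfg)
        for a, b in zip(out.platelets, small_geometry.platelets):
            assert np.allclose(a.center, b.center)
            assert np.allclose(a.rotation, b.rotation)

    def test_perturbed_geometry_invariants(self, default_fibril):
        """Inclination bound and overlap freedom hold after the full schedule."""
        incl = np.array([p.inclination for p in default_fibril.platelets])
        assert incl.max() <= math.radians(20.0) + 1e-9
        assert oracle_platelet_overlaps(default_fibril) == []

    def test_determinism(self, small_geometry):
        cfg = PerturbationConfig(n_moves=50_000, rng_seed=11)
        a = perturb(small_geometry, cfg)
        b = perturb(small_geometry, cfg)
        for pa, pb in zip(a.platelets, b.platelets):
            assert np.array_equal(pa.center, pb.center)
            assert np.array_equal(pa.rotation, pb.rotation)

    def test_rotations_are_proper(self, small_geometry):
        out = perturb(small_geometry,
                      PerturbationConfig(n_moves=50_000, rng_seed=2))
        for p in out.platelets[::25]:
            R = p.rotation
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestOccupancy:
    def test_platelet_center_is_blocked(self, small_geometry):
        p = small_geometry.platelets[0]
        assert point_is_blocked(small_geometry, p.center)

    def test_point_outside_envelope_is_blocked(self, small_geometry):
        assert point_is_blocked(small_geometry, (1e4, 0.0, 10.0))

    def test_indexed_point_query_matches_brute_force(self, small_geometry):
        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.uniform(-35, 35, 10_000),
                               rng.uniform(-35, 35, 10_000),
                               rng.uniform(-20, 320, 10_000)])
        for p in pts:
            assert point_is_blocked(small_geometry, p) == \
                oracle_point_blocked(small_geometry, p)

    def test_segment_detects_crossing_between_free_endpoints(self):
        from mcfrw.fixtures import make_fixture
        from mcfrw.geometry import segment_is_blocked
        geom = make_fixture("single_box")  # box centred at (0, 0, 500)
        p0, p1 = (-20.0, 0.0, 500.0), (20.0, 0.0, 500.0)
        assert not point_is_blocked(geom, p0)
        assert not point_is_blocked(geom, p1)
        assert segment_is_blocked(geom, p0, p1)
        assert not segment_is_blocked(geom, p0, p0)

    def test_segment_query_agrees_with_dense_sampling(self, small_geometry):
        from mcfrw.geometry import segment_is_blocked
        rng = np.random.default_rng(8)
        starts = np.column_stack([rng.uniform(-30, 30, 400),
                                  rng.uniform(-30, 30, 400),
                                  rng.uniform(0, 300, 400)])
        deltas = rng.normal(0.0, 1.5, (400, 3))
        for p0, d in zip(starts, deltas):
            hit = segment_is_blocked(small_geometry, p0, p0 + d)
            # the sampling oracle is one-sided: every oracle hit must be
            # caught by the exact slab/cylinder tests
            if oracle_segment_blocked(small_geometry, p0, p0 + d, 1500):
                assert hit


class TestSerialization:
    def test_roundtrip_preserves_geometry(self, small_geometry, tmp_path):
        path = tmp_path / "geom.txt"
        save_geometry(small_geometry, path, include_cylinders=False)
        back = load_geometry(path)
        assert len(back.platelets) == len(small_geometry.platelets)
        assert back.envelope_radius == small_geometry.envelope_radius
        for a, b in zip(back.platelets, small_geometry.platelets):
            assert np.allclose(a.center, b.center)
            assert np.allclose(a.rotation, b.rotation)
            assert a.dims == b.dims
        # identical occupancy at a few probe points
        rng = np.random.default_rng(3)
        for _ in range(200):
            pt = rng.uniform([-32, -32, -5], [32, 32, 305])
            assert point_is_blocked(back, pt) == \
                point_is_blocked(small_geometry, pt)

    def test_collagen_lattice_validation(self):
        with pytest.raises(ParameterError):
            CollagenLattice(radius=1.0, spacing=1.5)
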