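"""Feature models: rendering, curve geometry, and parameter packing."""

import numpy as np
import pytest

from spindletrack.errors import (
    DegenerateTangentError,
    InvalidParameterError,
    StepTooLargeError,
    UnderDeterminedError,
)
from spindletrack.features import (
    CompositeModel,
    CurveFeature,
    FourierCurvature,
    Grid,
    ImageStack,
    LineFeature,
    Spot,
    curvature_from_path,
    feature_from_dict,
    fit_curvature_fourier,
    local_curvature,
    reconstruct_curve,
    render_curve,
    render_line,
    render_model,
    render_spot,
)

WIDTHS = np.array([0.15, 0.15, 0.4])


def grid_um(shape=(7, 32, 32), voxel=(0.1, 0.1, 0.5)):
    return ImageStack(np.zeros(shape), voxel).grid


def sample_value(field, grid, point):
    """Field value at the voxel whose centre is nearest to a physical point."""
    i = int(np.argmin(np.abs(grid.xs - point[0])))
    j = int(np.argmin(np.abs(grid.ys - point[1])))
    k = int(np.argmin(np.abs(grid.zs - point[2])))
    return field[k, j, i], np.array([grid.xs[i], grid.ys[j], grid.zs[k]])


class TestParameterCounts:
    def test_packing_sizes_match_model_definitions(self):
        spot = Spot(1.0, np.array([1, 1, 1.0]), WIDTHS)
        line = LineFeature(1.0, np.zeros(3), np.ones(3), WIDTHS)
        curve = CurveFeature(
            1.0, np.zeros(3), 0.1, np.pi / 2,
            FourierCurvature(0.1, np.pi, [0.0, 0.0], [0.0, 0.0]), 1.0, WIDTHS,
        )
        assert spot.to_vector().size == 7
        assert line.to_vector().size == 10
        assert curve.to_vector().size == 15
        assert CurveFeature.n_params_for(2) == 15


class TestRenderSpot:
    def test_amplitude_at_centre_and_one_sigma_falloff(self):
        g = grid_um()
        centre = np.array([g.xs[16], g.ys[16], g.zs[3]])  # a voxel centre
        spot = Spot(2.0, centre, np.array([1.0, 0.3, 0.6]))
        field = render_spot(spot, g)
        v, _ = sample_value(field, g, centre)
        assert v == pytest.approx(2.0)
        v1, _ = sample_value(field, g, centre + np.array([1.0, 0, 0]))
        assert v1 == pytest.approx(2.0 * np.exp(-1.0), rel=1e-12)

    def test_total_intensity_matches_gaussian_integral(self):
        # numerical-integration oracle: sum × voxel volume ≈ A·π^{3/2}·σxσyσz
        voxel = (0.05, 0.05, 0.05)
        g = ImageStack(np.zeros((80, 80, 80)), voxel).grid
        sig = np.array([0.2, 0.25, 0.3])
        spot = Spot(1.7, np.array([2.0, 2.0, 2.0]), sig)
        total = render_spot(spot, g).sum() * np.prod(voxel)
        expected = 1.7 * np.pi**1.5 * np.prod(sig)
        assert total == pytest.approx(expected, rel=0.01)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            Spot(1.0, np.zeros(3), np.array([0.1, -0.1, 0.1]))


class TestRenderLine:
    def test_degenerate_line_renders_like_spot(self, small_grid):
        p = np.array([1.6, 1.6, 1.75])
        line = LineFeature(1.3, p, p.copy(), WIDTHS)
        spot = Spot(1.3, p, WIDTHS)
        np.testing.assert_allclose(
            render_line(line, small_grid), render_spot(spot, small_grid), rtol=1e-9
        )

    def test_erf_matches_fine_trapezoid_oracle(self, small_grid):
        line = LineFeature(
            1.0, np.array([0.5, 0.6, 1.2]), np.array([2.0, 2.1, 2.2]), WIDTHS
        )
        field = render_line(line, small_grid, method="erf")
        ts = np.linspace(0.0, 1.0, 100_001)
        pts = line.point_at(ts)
        mid = line.point_at(np.array([0.5]))[0]
        v, at = sample_value(field, small_grid, mid)
        d = (at[None, :] - pts) / WIDTHS
        oracle = np.trapezoid(np.exp(-np.sum(d**2, axis=1)), ts)
        assert v == pytest.approx(oracle, rel=1e-9)

    def test_erf_and_quadrature_agree_on_random_lines(self, small_grid):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.uniform(0.5, 2.5, 3) * np.array([1, 1, 1.2])
            b = rng.uniform(0.5, 2.5, 3) * np.array([1, 1, 1.2])
            line = LineFeature(rng.uniform(0.5, 3.0), a, b, WIDTHS)
            fe = render_line(line, small_grid, method="erf")
            fq = render_line(line, small_grid, method="quadrature")
            assert np.abs(fe - fq).max() / fe.max() < 1e-6

    def test_unknown_method_rejected(self, small_grid):
        line = LineFeature(1.0, np.zeros(3), np.ones(3), WIDTHS)
        with pytest.raises(InvalidParameterError):
            render_line(line, small_grid, method="simpson")

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            LineFeature(1.0, np.array([np.nan, 0, 0]), np.ones(3), WIDTHS)


class TestCurvature:
    def test_straight_line_has_zero_curvature(self):
        assert local_curvature([0.0, 1.0], [0.0, 0.0], 0.3) == pytest.approx(0.0)

    def test_parabola_curvature_at_vertex(self):
        # x=t, y=t²: K(0) = 2 from the planar curvature formula
        assert local_curvature([0, 1], [0, 0, 1], 0.0) == pytest.approx(2.0)

    def test_circle_curvature_from_sampled_path(self):
        r = 2.5
        t = np.linspace(0, np.pi / 2, 400)
        path = np.stack([r * np.cos(t), r * np.sin(t)], axis=1)
        k = curvature_from_path(path, np.array([0.5]))
        assert abs(k[0]) == pytest.approx(1.0 / r, rel=1e-3)

    def test_vanishing_speed_raises(self):
        with pytest.raises(DegenerateTangentError):
            local_curvature([0.0], [0.0], 0.0)


class TestFourierCurvature:
    def test_constant_samples_recovered_as_k0(self):
        t = np.linspace(0, 1, 40)
        fit = fit_curvature_fourier(t, np.full_like(t, 0.7), n_terms=2)
        assert fit.k0 == pytest.approx(0.7, abs=1e-9)
        assert np.allclose(fit.p, 0, atol=1e-8)
        assert np.allclose(fit.q, 0, atol=1e-8)

    def test_noiseless_roundtrip_recovers_coefficients(self):
        truth = FourierCurvature(0.3, 2.2, [0.5, -0.2], [0.1, 0.4])
        t = np.linspace(0, 1, 200)
        fit = fit_curvature_fourier(t, truth(t), n_terms=2)
        np.testing.assert_allclose(fit(t), truth(t), atol=1e-6)

    def test_nested_models_one_term_fits_worse(self):
        truth = FourierCurvature(0.0, 3.0, [0.4, 0.6], [0.2, -0.5])
        t = np.linspace(0, 1, 120)
        k = truth(t)
        f1 = fit_curvature_fourier(t, k, n_terms=1)
        f2 = fit_curvature_fourier(t, k, n_terms=2)
        rss1 = np.sum((f1(t) - k) ** 2)
        rss2 = np.sum((f2(t) - k) ** 2)
        assert rss1 > rss2

    def test_too_few_samples_raise(self):
        with pytest.raises(UnderDeterminedError):
            fit_curvature_fourier(np.array([0.0, 0.5, 1.0]), np.zeros(3), n_terms=2)


class TestReconstructCurve:
    def test_zero_curvature_gives_straight_segment(self):
        flat = FourierCurvature(0.0, 1.0, [0.0], [0.0])
        pts = reconstruct_curve(np.zeros(3), np.array([0, 1, 0.0]), flat, 2.0, 0.01)
        assert np.allclose(pts[-1], [0, 2.0, 0], atol=1e-9)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert seg == pytest.approx(2.0, rel=1e-9)

    def test_constant_curvature_traces_a_circle(self):
        k = 0.8
        length = np.pi / k  # half circle of radius 1/k
        pts = reconstruct_curve(
            np.zeros(3),
            np.array([1.0, 0, 0]),
            FourierCurvature(k, 1.0, [0.0], [0.0]),
            length,
            length / 10_000,
        )
        expected = np.array([0.0, 2.0 / k, 0.0])
        assert np.linalg.norm(pts[-1] - expected) < 1e-3 * length

    def test_halving_step_improves_endpoint(self):
        k = FourierCurvature(1.2, 2.0, [0.3], [0.1])
        ref = reconstruct_curve(np.zeros(3), np.array([1, 0, 0.0]), k, 2.0, 2.0 / 40_000)
        errs = []
        for n in (200, 400, 800):
            pts = reconstruct_curve(np.zeros(3), np.array([1, 0, 0.0]), k, 2.0, 2.0 / n)
            errs.append(np.linalg.norm(pts[-1] - ref[-1]))
        assert errs[0] > errs[1] > errs[2]

    def test_reconstruction_reproduces_input_curvature(self):
        truth = FourierCurvature(0.6, 2.5, [0.2, -0.1], [0.15, 0.05])
        pts = reconstruct_curve(
            np.zeros(3), np.array([1, 0, 0.0]), truth, 1.5, 1e-4 * 1.5
        )
        ts = np.linspace(0.05, 0.95, 19)
        k_rec = curvature_from_path(pts[:, :2], ts)
        np.testing.assert_allclose(k_rec, truth(ts), rtol=0.01, atol=0.005)

    def test_step_not_smaller_than_length_raises(self):
        with pytest.raises(StepTooLargeError):
            reconstruct_curve(
                np.zeros(3), np.ones(3), FourierCurvature(0, 1, [0], [0]), 1.0, 1.0
            )


class TestRenderCurve:
    def curve(self, k0=0.0, amp=2.0):
        return CurveFeature(
            amplitude=amp,
            origin=np.array([0.8, 1.0, 1.75]),
            azimuth=0.4,
            polar=np.pi / 2,
            curvature=FourierCurvature(k0, np.pi, [0.0, 0.0], [0.0, 0.0]),
            length=1.6,
            widths=WIDTHS,
        )

    def test_zero_curvature_curve_equals_line(self, small_grid):
        c = self.curve()
        line = LineFeature(
            c.amplitude, c.origin, c.origin + c.length * c.initial_tangent, WIDTHS
        )
        fc = render_curve(c, small_grid)
        fl = render_line(line, small_grid, method="quadrature")
        assert np.abs(fc - fl).max() < 1e-6 * c.amplitude

    def test_quadrature_order_converged(self, small_grid):
        c = self.curve(k0=0.7)
        f20 = render_curve(c, small_grid, order=20)
        f40 = render_curve(c, small_grid, order=40)
        assert np.abs(f20 - f40).max() / f40.max() < 1e-6

    def test_amplitude_linearity(self, small_grid):
        c1 = self.curve(k0=0.5, amp=1.0)
        c2 = self.curve(k0=0.5, amp=2.0)
        np.testing.assert_allclose(
            2.0 * render_curve(c1, small_grid), render_curve(c2, small_grid), rtol=1e-12
        )


class TestCompositeModel:
    def test_empty_model_is_uniform_background(self, small_grid):
        m = CompositeModel(0.7, [])
        assert np.all(render_model(m, small_grid) == 0.7)

    def test_single_spot_without_background_equals_spot_render(self, small_grid):
        spot = Spot(1.5, np.array([1.2, 1.4, 1.75]), WIDTHS)
        m = CompositeModel(0.0, [spot])
        np.testing.assert_array_equal(render_model(m, small_grid), render_spot(spot, small_grid))

    def test_feature_order_does_not_matter(self, small_grid):
        s = Spot(1.5, np.array([1.2, 1.4, 1.75]), WIDTHS)
        l = LineFeature(1.0, np.array([0.5, 0.5, 1.0]), np.array([2.5, 1.5, 2.0]), WIDTHS)
        a = render_model(CompositeModel(0.2, [s, l]), small_grid)
        b = render_model(CompositeModel(0.2, [l, s]), small_grid)
        # equal up to float-addition reassociation
        np.testing.assert_allclose(a, b, rtol=0, atol=1e-12)

    def test_translation_equivariance(self):
        # shifting the feature by an exact voxel pitch shifts the render
        g = grid_um((7, 32, 32))
        dx, dy, dz = g.voxel_size
        line = LineFeature(1.0, np.array([0.8, 0.9, 1.4]), np.array([1.9, 1.7, 2.0]), WIDTHS)
        shifted = LineFeature(
            1.0, line.start + [2 * dx, dy, dz], line.end + [2 * dx, dy, dz], WIDTHS
        )
        f0 = render_line(line, g)
        f1 = render_line(shifted, g)
        np.testing.assert_allclose(f1[1:, 1:, 2:], f0[:-1, :-1, :-2], rtol=1e-10)


class TestSerialization:
    @pytest.mark.parametrize(
        "feature",
        [
            Spot(1.0, np.array([1, 2, 0.5]), WIDTHS),
            LineFeature(2.0, np.zeros(3), np.array([1.0, 2.0, 1.5]), WIDTHS),
            CurveFeature(
                1.5, np.array([0.5, 0.5, 1.0]), 0.3, 1.4,
                FourierCurvature(0.2, 2.0, [0.1, 0.0], [0.0, -0.1]), 1.2, WIDTHS,
            ),
        ],
        ids=["spot", "line", "curve"],
    )
    def test_feature_json_roundtrip(self, feature):
        back = feature_from_dict(feature.to_dict())
        np.testing.assert_allclose(back.to_vector(), feature.to_vector())

    def test_model_roundtrip_keeps_topology_and_attachments(self):
        m = CompositeModel(
            0.4,
            [Spot(1.0, np.zeros(3), WIDTHS), LineFeature(1.0, np.zeros(3), np.ones(3), WIDTHS)],
            topology="monopolar",
            attachments={1: 0},
        )
        back = CompositeModel.from_dict(m.to_dict())
        assert back.topology == "monopolar"
        assert back.attachments == {1: 0}
        assert back.background == m.background
        assert len(back.features) == 2
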