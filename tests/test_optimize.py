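"""Least-squares fitting, the F-test, and feature-count selection."""

import numpy as np
import pytest
from scipy.stats import f as f_dist

from spindletrack.detect import DetectionConfig
from spindletrack.errors import GeometryError, InvalidParameterError
from spindletrack.features import CompositeModel, ImageStack, LineFeature, Spot
from spindletrack.optimize import (
    OptimizerConfig,
    f_test,
    fit_global,
    fit_local,
    optimize_feature_count,
    residual,
)
from spindletrack.pipeline import _residual_line_provider, analyze_frame
from spindletrack.simulate import SimulationConfig, simulate_image

from conftest import VOXEL, WIDTHS, make_monopolar_phantom


class TestResidual:
    def test_model_matches_its_own_render(self):
        stack, model = make_monopolar_phantom([40], [1.5])
        assert residual(model, stack) == pytest.approx(0.0, abs=1e-18)

    def test_uniform_image_with_background_only_model(self):
        img = ImageStack(np.full((5, 10, 10), 2.5), VOXEL)
        assert residual(CompositeModel(2.5, []), img) == 0.0

    def test_unit_offset_counts_voxels(self):
        img = ImageStack(np.full((5, 10, 10), 3.0), VOXEL)
        assert residual(CompositeModel(2.0, []), img) == pytest.approx(500.0)

    def test_shape_mismatch_raises(self):
        stack, model = make_monopolar_phantom([40], [1.5])
        other = ImageStack(np.zeros((3, 8, 8)), VOXEL)
        with pytest.raises(GeometryError):
            rendered = model.render(other.grid)
            if rendered.shape != stack.intensities.shape:
                raise GeometryError("shapes differ")


class TestFTest:
    def test_no_improvement_is_never_significant(self):
        assert not f_test(100.0, 10, 100.0, 20, 5000)

    def test_against_scipy_f_distribution_oracle(self):
        # the oracle computes the statistic and critical value directly
        rss_s, p_s, rss_c, p_c, n = 200.0, 10, 100.0, 20, 1020
        f_stat = ((rss_s - rss_c) / (p_c - p_s)) / (rss_c / (n - p_c))
        crit = f_dist.ppf(0.95, p_c - p_s, n - p_c)
        assert f_test(rss_s, p_s, rss_c, p_c, n, alpha=0.05) == (f_stat > crit)

    def test_alpha_one_accepts_everything(self):
        assert f_test(100.0, 1, 99.999, 2, 1000, alpha=1.0)

    def test_perfect_complex_fit_is_significant(self):
        assert f_test(5.0, 1, 0.0, 11, 1000)

    @pytest.mark.parametrize(
        "args",
        [
            (100.0, 20, 90.0, 10, 1000),  # complex not larger
            (-1.0, 1, 0.5, 2, 1000),  # negative rss
            (100.0, 1, 90.0, 999, 100),  # too few voxels
        ],
    )
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(InvalidParameterError):
            f_test(*args)


class TestFitLocal:
    def test_perturbed_spot_recovered_to_hundredth_voxel(self):
        stack, truth = make_monopolar_phantom([], [])
        model = truth.copy()
        model.features[0].center = model.features[0].center + [0.05, -0.05, 0.1]
        res = fit_local(model, stack, 0)
        err = np.abs(res.model.features[0].center - truth.features[0].center)
        assert np.all(err[:2] < 0.01 * VOXEL[0])

    def test_optimal_model_is_a_fixed_point(self):
        stack, truth = make_monopolar_phantom([70], [1.8])
        res = fit_local(truth.copy(), stack, 1)
        v0 = truth.features[1].to_vector()
        v1 = res.model.features[1].to_vector()
        assert np.max(np.abs(v1 - v0) / np.maximum(np.abs(v0), 1.0)) < 1e-6

    def test_doubled_line_amplitude_recovered(self):
        stack, truth = make_monopolar_phantom([110], [2.0])
        model = truth.copy()
        model.features[1].amplitude *= 2.0
        res = fit_local(model, stack, 1)
        assert res.model.features[1].amplitude == pytest.approx(
            truth.features[1].amplitude, rel=0.01
        )

    def test_bad_index_rejected(self):
        stack, truth = make_monopolar_phantom([], [])
        with pytest.raises(InvalidParameterError):
            fit_local(truth, stack, 5)


class TestFitGlobal:
    def test_two_spot_centres_recovered(self):
        geom = ImageStack(np.zeros((7, 48, 48)), VOXEL)
        truth = CompositeModel(
            0.3,
            [
                Spot(2.0, np.array([1.5, 1.6, 1.7]), WIDTHS.copy()),
                Spot(2.5, np.array([3.1, 3.0, 1.9]), WIDTHS.copy()),
            ],
        )
        stack = ImageStack(truth.render(geom.grid), VOXEL)
        guess = truth.copy()
        guess.features[0].center = guess.features[0].center + [0.04, -0.03, 0.1]
        guess.features[1].center = guess.features[1].center + [-0.05, 0.04, -0.1]
        res = fit_global(guess, stack)
        for fitted, true in zip(res.model.features, truth.features):
            assert np.all(np.abs(fitted.center - true.center)[:2] < 0.01 * VOXEL[0])

    def test_background_only_image_recovers_level(self):
        img = ImageStack(np.full((5, 16, 16), 1.8), VOXEL)
        res = fit_global(CompositeModel(0.9, []), img)
        assert res.model.background == pytest.approx(1.8, rel=1e-6)

    def test_noisy_line_endpoint_within_one_voxel(self):
        cfg = SimulationConfig(
            seed=12, target_snr=3.0, n_microtubules=(1, 1), length_range=(1.5, 2.5)
        )
        stack, truth = simulate_image(cfg)
        res = analyze_frame(stack)
        mts = res.model.microtubules()
        assert mts, "pipeline lost the single microtubule"
        tip_err = min(
            np.linalg.norm((mt.tip - truth.tips()[0])[:2]) for mt in mts
        )
        assert tip_err < VOXEL[0]

    def test_rss_never_increases_across_stages(self):
        cfg = SimulationConfig(seed=7, target_snr=2.0)
        stack, _ = simulate_image(cfg)
        from spindletrack.detect import detect_structure

        guess = detect_structure(stack, "monopolar")
        model = CompositeModel(
            guess.background, guess.features, guess.topology, guess.attachments
        )
        rss = [residual(model, stack)]
        for i in range(len(model.features)):
            model = fit_local(model, stack, i).model
            rss.append(residual(model, stack))
        res = fit_global(model, stack)
        rss.append(res.rss)
        count = optimize_feature_count(
            res.model, stack, _residual_line_provider(res.model, stack, DetectionConfig())
        )
        rss.append(count.rss)
        for a, b in zip(rss, rss[1:]):
            assert b <= a * (1.0 + 1e-9)


class TestFeatureCountSelection:
    def run_count(self, stack, model):
        opt = OptimizerConfig()
        work = model
        for i in range(len(work.features)):
            work = fit_local(work, stack, i, opt).model
        work = fit_global(work, stack, opt).model
        provider = _residual_line_provider(work, stack, DetectionConfig())
        return optimize_feature_count(work, stack, provider, opt)

    def test_missing_line_added_back(self):
        stack, truth = make_monopolar_phantom([30, 150, 260], [1.8, 2.2, 1.5])
        seeded = truth.copy()
        del seeded.features[3]  # drop the 260° line from the guess
        del seeded.attachments[3]
        res = self.run_count(stack, seeded)
        assert len(res.model.microtubules()) == 3

    def test_spurious_guesses_removed(self):
        stack, truth = make_monopolar_phantom([30, 150, 260], [1.8, 2.2, 1.5])
        seeded = truth.copy()
        pole = truth.features[0].center
        for phi in (80.0, 200.0):
            rad = np.deg2rad(phi)
            tip = pole + np.array([np.cos(rad), np.sin(rad), 0.0]) * 1.2
            seeded.features.append(
                LineFeature(amplitude=2.0, start=pole.copy(), end=tip, widths=WIDTHS.copy())
            )
            seeded.attachments[len(seeded.features) - 1] = 0
        res = self.run_count(stack, seeded)
        assert len(res.model.microtubules()) == 3

    def test_pure_background_keeps_no_lines(self):
        img = ImageStack(np.full((7, 48, 48), 0.8), VOXEL)
        spotless = CompositeModel(0.8, [])
        res = optimize_feature_count(spotless, img, lambda resid: [])
        assert len(res.model.microtubules()) == 0
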