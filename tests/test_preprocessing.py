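"""Image-stack preprocessing: bleach correction, irradiance calibration,
ROI reduction, and the generator/preprocessing chain identity."""

import numpy as np
import pytest

from trastkit.preprocessing import (ImageStack, bleach_correct,
                                    fit_gaussian_waist, irradiance_map,
                                    stack_to_trast_curve)
from trastkit.synthetic import (NOISELESS, NoiseModel, StackGeometry,
                                gaussian_reference_image, make_design,
                                simulate_image_stack)


@pytest.fixture(scope="module")
def ir700_condition():
    design = make_design("IR700_IRRADIANCE")
    return design.conditions[2], design.truth


@pytest.fixture(scope="module")
def clean_stack(ir700_condition):
    cond, truth = ir700_condition
    return simulate_image_stack(cond, truth, NOISELESS, seed=3)


class TestBleachCorrection:
    def test_constant_references_leave_stack_unchanged(self, clean_stack):
        stack, _ = clean_stack
        corrected = bleach_correct(stack)
        assert np.allclose(corrected.frames, stack.frames, rtol=1e-12)

    def test_injected_decay_removed(self, ir700_condition):
        cond, truth = ir700_condition
        noise = NoiseModel(mult_sigma=0.0, bleach_amplitude=0.08)
        stack, ref_curve = simulate_image_stack(cond, truth, noise, seed=3)
        curve = stack_to_trast_curve(stack, None, roi_radius_um=8.0)
        assert np.max(np.abs(curve.value - ref_curve.value)
                      / ref_curve.value) < 5e-3

    def test_correction_factors_for_decaying_references(self, clean_stack):
        stack, _ = clean_stack
        n = len(stack.reference_frames)
        decay = np.linspace(1.0, 0.92, n)
        fading = ImageStack(
            frames=stack.frames, frame_w_s=stack.frame_w_s,
            acquisition_index=stack.acquisition_index,
            reference_frames=stack.reference_frames * decay[:, None, None],
            reference_positions=stack.reference_positions,
            reference_w_s=stack.reference_w_s,
            pixel_size_um=stack.pixel_size_um, t_ill_s=stack.t_ill_s)
        corrected = bleach_correct(fading)
        assert np.all(corrected.frames >= fading.frames - 1e-12)

    def test_nonpositive_reference_rejected(self, clean_stack):
        stack, _ = clean_stack
        bad = ImageStack(
            frames=stack.frames, frame_w_s=stack.frame_w_s,
            acquisition_index=stack.acquisition_index,
            reference_frames=np.zeros_like(stack.reference_frames),
            reference_positions=stack.reference_positions,
            reference_w_s=stack.reference_w_s)
        with pytest.raises(ValueError):
            bleach_correct(bad)

    def test_excessive_bleaching_warns(self, clean_stack):
        stack, _ = clean_stack
        n = len(stack.reference_frames)
        decay = np.linspace(1.0, 0.8, n)
        fading = ImageStack(
            frames=stack.frames, frame_w_s=stack.frame_w_s,
            acquisition_index=stack.acquisition_index,
            reference_frames=stack.reference_frames * decay[:, None, None],
            reference_positions=stack.reference_positions,
            reference_w_s=stack.reference_w_s)
        with pytest.warns(RuntimeWarning):
            bleach_correct(fading)


class TestIrradianceMap:
    def test_uniform_image(self):
        img = np.ones((10, 10))
        m = irradiance_map(img, 1e-3, pixel_size_um=1.0)
        area = 100 * (1e-4) ** 2
        assert np.allclose(m.irradiance_W_cm2, 1e-3 / area)

    def test_integral_matches_power(self):
        geom = StackGeometry()
        img = gaussian_reference_image(geom)
        m = irradiance_map(img, 2e-3, geom.pixel_size_um)
        total = m.irradiance_W_cm2.sum() * m.pixel_area_cm2
        assert total == pytest.approx(2e-3, rel=1e-9)

    def test_gaussian_waist_recovered(self):
        geom = StackGeometry(waist_um=10.0)
        img = gaussian_reference_image(geom)
        m = irradiance_map(img, 1e-3, geom.pixel_size_um)
        waist, _ = fit_gaussian_waist(m)
        assert waist == pytest.approx(geom.waist_um, rel=0.02)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            irradiance_map(np.zeros((5, 5)), 1e-3, 1.0)


class TestStackToCurve:
    def test_noiseless_chain_identity(self, clean_stack):
        stack, ref_curve = clean_stack
        curve = stack_to_trast_curve(stack, None, roi_radius_um=8.0)
        assert np.max(np.abs(curve.value - ref_curve.value)) < 1e-6

    def test_value_at_w0_is_one(self, clean_stack):
        stack, _ = clean_stack
        curve = stack_to_trast_curve(stack, None, roi_radius_um=8.0)
        assert curve.value[0] == pytest.approx(1.0, abs=1e-12)

    def test_acquisition_order_irrelevant(self, ir700_condition):
        cond, truth = ir700_condition
        s1, _ = simulate_image_stack(cond, truth, NOISELESS, seed=1)
        s2, _ = simulate_image_stack(cond, truth, NOISELESS, seed=99)
        c1 = stack_to_trast_curve(s1, None, roi_radius_um=8.0)
        c2 = stack_to_trast_curve(s2, None, roi_radius_um=8.0)
        assert np.allclose(c1.value, c2.value, atol=1e-12)

    def test_intensity_scale_invariance(self, clean_stack):
        stack, _ = clean_stack
        doubled = ImageStack(
            frames=(stack.frames - stack.background) * 2 + stack.background,
            frame_w_s=stack.frame_w_s,
            acquisition_index=stack.acquisition_index,
            reference_frames=(stack.reference_frames - stack.background) * 2
            + stack.background,
            reference_positions=stack.reference_positions,
            reference_w_s=stack.reference_w_s,
            background=stack.background,
            pixel_size_um=stack.pixel_size_um, t_ill_s=stack.t_ill_s)
        c1 = stack_to_trast_curve(stack, None, roi_radius_um=8.0)
        c2 = stack_to_trast_curve(doubled, None, roi_radius_um=8.0)
        assert np.allclose(c1.value, c2.value, rtol=1e-12)

    def test_background_offset_fully_removed(self, ir700_condition):
        cond, truth = ir700_condition
        g1 = StackGeometry(background_offset=0.0)
        g2 = StackGeometry(background_offset=50.0)
        s1, _ = simulate_image_stack(cond, truth, NOISELESS, seed=3, geom=g1)
        s2, _ = simulate_image_stack(cond, truth, NOISELESS, seed=3, geom=g2)
        c1 = stack_to_trast_curve(s1, None, roi_radius_um=8.0)
        c2 = stack_to_trast_curve(s2, None, roi_radius_um=8.0)
        assert np.allclose(c1.value, c2.value, atol=1e-10)

    def test_roi_mean_irradiance_attached(self, clean_stack):
        stack, ref_curve = clean_stack
        img = gaussian_reference_image(StackGeometry())
        m = irradiance_map(img, 1e-3, stack.pixel_size_um)
        curve = stack_to_trast_curve(stack, m, roi_radius_um=8.0)
        assert curve.meta["irradiance_W_cm2"] > 0


def test_tiff_round_trip(tmp_path, clean_stack):
    stack, _ = clean_stack
    path = tmp_path / "stack.tiff"
    stack.write_tiff(path)
    back = ImageStack.read_tiff(path)
    assert np.array_equal(back.frames, stack.frames)
    assert np.array_equal(back.frame_w_s, stack.frame_w_s)
    assert back.meta == stack.meta
    c1 = stack_to_trast_curve(stack, None, roi_radius_um=8.0)
    c2 = stack_to_trast_curve(back, None, roi_radius_um=8.0)
    assert np.allclose(c1.value, c2.value, rtol=1e-12)


def test_h5_round_trip(tmp_path, clean_stack):
    stack, _ = clean_stack
    path = tmp_path / "stack.h5"
    stack.write_h5(path)
    back = ImageStack.read_h5(path)
    assert np.array_equal(back.frames, stack.frames)
    assert np.array_equal(back.frame_w_s, stack.frame_w_s)
    assert np.array_equal(back.reference_positions, stack.reference_positions)
    assert back.meta == stack.meta
    assert back.t_ill_s == stack.t_ill_s
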