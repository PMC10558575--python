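"""TRAST curve simulation: normalization, beam handling, symmetries, I/O."""

import numpy as np
import pytest

from trastkit.state_models import Environment, PARAMETER_PRESETS
from trastkit.trast import (BeamProfile, ExcitationProtocol, TrastCurve,
                            gaussian_peak_from_mean, simulate_trast_curve,
                            trast_value_uniform)


@pytest.fixture
def protocol():
    return ExcitationProtocol.default(431.0)


class TestUniform:
    def test_value_at_w0_is_one(self, mb_air, env_lowph):
        v = trast_value_uniform("MB_LOWPH_4", mb_air, env_lowph, 431.0,
                                1e-7, 1e-7)
        assert v == pytest.approx(1.0, abs=1e-12)

    def test_no_isc_gives_flat_curve(self, ir700):
        params = ir700.updated(kISC=0.0)
        w = np.geomspace(1e-7, 1e-3, 10)
        v = trast_value_uniform("IR700_3", params, Environment(), 4500.0,
                                w, 1e-7)
        assert np.allclose(v, 1.0, atol=1e-12)

    def test_irradiance_deepens_and_speeds_decay(self, ir700):
        """Higher irradiance: larger dark-state amplitude, earlier midpoint."""
        w = np.geomspace(1e-7, 1e-3, 60)
        lo = trast_value_uniform("IR700_3", ir700, Environment(), 500.0,
                                 w, 1e-7)
        hi = trast_value_uniform("IR700_3", ir700, Environment(), 4500.0,
                                 w, 1e-7)
        assert hi[-1] < lo[-1]  # larger amplitude
        mid = lambda v: w[np.argmin(np.abs(v - (1 + v[-1]) / 2))]
        assert mid(hi) < mid(lo)  # earlier decay


class TestGaussianBeam:
    def test_uniform_beam_matches_closed_form(self, protocol, preset_system):
        model, params, env, _ = preset_system
        curve = simulate_trast_curve(model, params, env, protocol,
                                     BeamProfile(kind="uniform"),
                                     check_recovery=False)
        direct = trast_value_uniform(model, params, env,
                                     protocol.irradiance_W_cm2,
                                     protocol.w_grid_s, protocol.w0_s)
        assert np.allclose(curve.value, direct, atol=1e-12)

    def test_radial_self_convergence(self, mb_air, env_lowph, protocol):
        v64 = simulate_trast_curve("MB_LOWPH_4", mb_air, env_lowph, protocol,
                                   BeamProfile(kind="gaussian", n_annuli=64),
                                   check_recovery=False).value
        v128 = simulate_trast_curve("MB_LOWPH_4", mb_air, env_lowph, protocol,
                                    BeamProfile(kind="gaussian", n_annuli=128),
                                    check_recovery=False).value
        assert np.max(np.abs(v64 - v128)) < 1e-4

    def test_value_between_peak_and_edge_uniform_values(self, mb_air,
                                                        env_lowph, protocol):
        """Gaussian-beam curve interpolates the uniform-beam values at the
        extreme irradiances present in the ROI."""
        beam = BeamProfile(kind="gaussian", waist_um=20.0, roi_radius_um=15.0)
        curve = simulate_trast_curve("MB_LOWPH_4", mb_air, env_lowph,
                                     protocol, beam, check_recovery=False)
        peak = gaussian_peak_from_mean(431.0, 20.0, 15.0)
        edge = peak * np.exp(-2 * 15.0 ** 2 / 20.0 ** 2)
        v_pk = trast_value_uniform("MB_LOWPH_4", mb_air, env_lowph, peak,
                                   protocol.w_grid_s, protocol.w0_s)
        v_ed = trast_value_uniform("MB_LOWPH_4", mb_air, env_lowph, edge,
                                   protocol.w_grid_s, protocol.w0_s)
        lo = np.minimum(v_pk, v_ed) - 1e-12
        hi = np.maximum(v_pk, v_ed) + 1e-12
        assert np.all((curve.value >= lo) & (curve.value <= hi))

    def test_mean_irradiance_preserved(self):
        """Annulus-averaged irradiance equals the requested ROI mean."""
        from trastkit.trast import _annulus_irradiances
        beam = BeamProfile(kind="gaussian", waist_um=20.0, roi_radius_um=15.0,
                           n_annuli=4096)
        irr = _annulus_irradiances(beam, 431.0)
        assert irr.mean() == pytest.approx(431.0, rel=1e-5)

    def test_roi_larger_than_waist_rejected(self):
        with pytest.raises(ValueError):
            BeamProfile(kind="gaussian", waist_um=10.0, roi_radius_um=15.0)

    def test_fiber_preset_scaling(self):
        beam = BeamProfile.fiber()
        assert beam.effective_waist_um == pytest.approx(12.5 * 0.7)


class TestSymmetries:
    def test_deoxygenation_raises_dark_amplitude(self, env_highph, protocol):
        """At high pH, removing O2 slows triplet decay and deepens the
        TRAST decay at matched irradiance."""
        air = PARAMETER_PRESETS["MB_AIR"]
        deox = PARAMETER_PRESETS["MB_DEOX"]
        beam = BeamProfile(kind="gaussian")
        v_air = simulate_trast_curve("MB_HIGHPH_4", air, env_highph, protocol,
                                     beam, check_recovery=False).value
        v_deox = simulate_trast_curve("MB_HIGHPH_4", deox, env_highph,
                                      protocol, beam,
                                      check_recovery=False).value
        mid = len(v_air) // 2
        assert v_deox[mid] < v_air[mid]
        assert (1 - v_deox).max() > (1 - v_air).max()

    def test_time_rescaling_invariance(self, ir700):
        """Scaling all rates up and pulse widths down by a common factor
        leaves the curve unchanged."""
        env = Environment()
        w = np.geomspace(1e-7, 1e-3, 15)
        base = trast_value_uniform("IR700_3", ir700, env, 4500.0, w, w[0])
        s = 10.0
        scaled_params = ir700.updated(
            kISC=ir700.kISC * s, kT=ir700.kT * s,
            tau_f_s=ir700.tau_f_s / s,
            sigma_exc_cm2=ir700.sigma_exc_cm2 * s)
        scaled = trast_value_uniform("IR700_3", scaled_params, env, 4500.0,
                                     w / s, w[0] / s)
        assert np.allclose(base, scaled, rtol=1e-9)


class TestCurveIO:
    def test_csv_round_trip_bit_exact(self, tmp_path, mb_air, env_lowph,
                                      protocol):
        curve = simulate_trast_curve("MB_LOWPH_4", mb_air, env_lowph,
                                     protocol, BeamProfile(kind="gaussian"),
                                     check_recovery=False)
        p1 = tmp_path / "c.csv"
        curve.write(p1)
        back = TrastCurve.read(p1)
        p2 = tmp_path / "c2.csv"
        back.write(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(back.w_s, curve.w_s)
        assert np.array_equal(back.value, curve.value)
        assert back.meta == curve.meta

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ExcitationProtocol(np.array([1e-6, 1e-3]), 431.0, w0_s=1e-5)
        with pytest.raises(ValueError):
            ExcitationProtocol(np.array([1e-6]), 431.0, duty_cycle=0.0)
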