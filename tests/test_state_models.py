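"""Rate relations, rate-matrix assembly, and model-reduction limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trastkit.state_models import (ConfigurationError, Environment,
                                   PARAMETER_PRESETS, RateParameters,
                                   build_rate_matrix, compound_triplet_decay,
                                   deprotonation_rate, excitation_rate,
                                   get_model, linked_rate)
from trastkit import kinetics

from conftest import PRESET_SYSTEMS, preset_matrix


class TestExcitationRate:
    def test_photon_flux_value(self):
        # sigma*I*lambda/(h c) computed by hand for the quoted conditions
        k01 = excitation_rate(431.0, 638.0, 1.9e-16)
        assert k01 == pytest.approx(2.63e5, rel=2e-3)

    def test_zero_irradiance_and_linearity(self):
        assert excitation_rate(0.0, 638.0, 1.9e-16) == 0.0
        one = excitation_rate(100.0, 638.0, 1.9e-16)
        assert excitation_rate(200.0, 638.0, 1.9e-16) == pytest.approx(2 * one)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            excitation_rate(100.0, -1.0, 1.9e-16)
        with pytest.raises(ValueError):
            excitation_rate(100.0, 638.0, 0.0)


class TestCompoundTripletDecay:
    def test_midpoint_is_arithmetic_mean(self):
        assert compound_triplet_decay(7.2, 0.825, 0.473, 7.2) == \
            pytest.approx((0.825 + 0.473) / 2)

    def test_acid_and_base_limits(self):
        assert compound_triplet_decay(0.0, 0.825, 0.473, 7.2) == \
            pytest.approx(0.473, rel=1e-6)
        assert compound_triplet_decay(14.0, 0.825, 0.473, 7.2) == \
            pytest.approx(0.825, rel=1e-6)

    @given(ph=st.floats(0, 14), kt1=st.floats(0, 10), kt2=st.floats(0, 10),
           pka=st.floats(2, 12))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bounded_by_the_two_rates(self, ph, kt1, kt2, pka):
        kt = compound_triplet_decay(ph, kt1, kt2, pka)
        assert min(kt1, kt2) - 1e-12 <= kt <= max(kt1, kt2) + 1e-12

    def test_monotone_in_ph(self):
        phs = np.linspace(2, 12, 40)
        kts = [compound_triplet_decay(p, 0.825, 0.473, 7.2) for p in phs]
        assert np.all(np.diff(kts) > 0)  # toward the unprotonated rate


class TestLinks:
    def test_linked_rate_examples(self):
        assert linked_rate(0.1, 0.508, 12.0) == pytest.approx(6.196)
        assert linked_rate(0.3, 0.5, 0.0) == 0.3
        assert linked_rate(0.3, 0.0, 99.0) == 0.3

    def test_deprotonation_decade_and_value(self):
        assert deprotonation_rate(2.0, 7.2, 7.2) == pytest.approx(2.0)
        assert deprotonation_rate(2.0, 8.2, 7.2) == pytest.approx(20.0)
        assert deprotonation_rate(6.196, 5.0, 7.2) == pytest.approx(0.0391,
                                                                    rel=1e-2)

    @pytest.mark.parametrize("field,concs", [
        ("buffer_mM", [0.0, 4.0, 8.0, 12.0]),
        ("KI_mM", [0.0, 2.0, 5.0, 10.0]),
    ])
    def test_environment_links_are_affine(self, field, concs):
        """rate(c) - rate(0) proportional to c for every link target."""
        params = PARAMETER_PRESETS["MB_AIR_KI"]
        model = get_model("MB_FULL_5")
        base_env = Environment(pH=5.0, buffer_mM=0.0)
        from trastkit.state_models import effective_rates
        r0 = effective_rates(model, params, base_env, 431.0)
        sym = {"buffer_mM": "kH", "KI_mM": "kISC"}[field]
        deltas = []
        for c in concs[1:]:
            env = Environment(**{**base_env.to_dict(), field: c})
            r = effective_rates(model, params, env, 431.0)
            deltas.append((r[sym] - r0[sym]) / c)
        assert np.allclose(deltas, deltas[0], rtol=1e-12)


class TestRateMatrix:
    def test_columns_sum_to_zero_all_presets(self):
        for model_id, preset, env in PRESET_SYSTEMS:
            M = preset_matrix(model_id, preset, env)
            assert np.allclose(M.sum(axis=0), 0.0, atol=1e-10)

    def test_k10_from_lifetime(self, mb_air):
        # 1/345 ps minus the ISC rate
        assert mb_air.k10 == pytest.approx(1748.6, rel=1e-3)

    def test_zero_irradiance_steady_state_is_ground(self, mb_air, env_lowph):
        M = build_rate_matrix(get_model("MB_LOWPH_4"), mb_air, env_lowph, 0.0)
        p = kinetics.steady_state(M)
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalue_structure(self):
        """One zero eigenvalue, the rest with negative real part."""
        for model_id, preset, env in PRESET_SYSTEMS:
            lam = np.linalg.eigvals(preset_matrix(model_id, preset, env))
            lam = lam[np.argsort(np.abs(lam))]
            assert abs(lam[0]) < 1e-8
            assert np.all(np.real(lam[1:]) < 0)

    def test_missing_symbol_raises(self, env_lowph):
        params = RateParameters(sigma_exc_cm2=1.9e-16, tau_f_s=345e-12,
                                kISC=1150.0)  # no kT2/kOX
        with pytest.raises(ConfigurationError):
            build_rate_matrix(get_model("MB_LOWPH_4"), params, env_lowph, 431.0)

    def test_excessive_kisc_raises(self, env_lowph):
        params = PARAMETER_PRESETS["MB_AIR"].updated(kISC=4000.0)
        with pytest.raises(ConfigurationError):
            build_rate_matrix(get_model("MB_LOWPH_4"), params, env_lowph, 431.0)


class TestModelReduction:
    """The full 5-state system collapses onto the reduced models in the
    fast-protonation and no-protonation limits."""

    def _populations(self, model_id, params, env, t_us):
        M = build_rate_matrix(get_model(model_id), params, env, 431.0)
        sol = kinetics.eigen_solve(M)
        return kinetics.populations_at(sol, t_us), get_model(model_id)

    def test_fast_protonation_reduces_to_lowph_model(self, mb_air):
        env = Environment(pH=3.0, buffer_mM=12.0)
        fast = mb_air.updated(kH0=1e4, kH_PBS=0.0)  # kH >> all triplet rates
        t = np.geomspace(0.01, 500, 12)
        p5, m5 = self._populations("MB_FULL_5", fast, env, t)
        p4, m4 = self._populations("MB_LOWPH_4", mb_air, env, t)
        for sid in ("S0", "S1", "R"):
            assert np.allclose(p5[m5.index(sid)], p4[m4.index(sid)], atol=2e-3)
        # pooled triplet matches the single protonated triplet
        trip5 = p5[m5.index("T1")] + p5[m5.index("T1H")]
        assert np.allclose(trip5, p4[m4.index("T1H")], atol=2e-3)

    def test_negligible_protonation_reduces_to_highph_model(self, mb_air):
        env = Environment(pH=12.0, buffer_mM=0.0)
        slow = mb_air.updated(kH0=1e-8, kH_PBS=0.0)
        t = np.geomspace(0.01, 500, 12)
        p5, m5 = self._populations("MB_FULL_5", slow, env, t)
        p4, m4 = self._populations("MB_HIGHPH_4", mb_air, env, t)
        for sid in ("S0", "S1", "T1", "R"):
            assert np.allclose(p5[m5.index(sid)], p4[m4.index(sid)], atol=1e-6)


def test_parameter_serialization_round_trip(mb_air):
    text = mb_air.to_json()
    back = RateParameters.from_json(text)
    assert back == mb_air


def test_environment_validation():
    with pytest.raises(ConfigurationError):
        Environment(pH=15.0)
    with pytest.raises(ConfigurationError):
        Environment(KI_mM=-1.0)
    assert Environment(O2_fraction=0.5).O2_mM == pytest.approx(0.135)
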