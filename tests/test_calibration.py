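"""Two-line calibration regression, Fick conversion and derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calbold import (
    CalibrationPoint,
    SignalModelParams,
    delta_y_act,
    fick_rcmro2,
    fit_calibration,
    forward_r2s,
    percent_bold_to_dr2s,
    rescale_q_act,
    voxelwise_maps,
)
from calbold.calibration import dr2s_to_percent_bold


def noiseless_points(params: SignalModelParams, qh_levels, n_per_level=1):
    """Exact forward-model calibration points relative to normoxic rest."""
    r2_base = forward_r2s(params, 0.0, False)
    pts = []
    for qh in qh_levels:
        for _ in range(n_per_level):
            pts.append(
                CalibrationPoint(
                    q_h=qh,
                    dr2s_rest=forward_r2s(params, qh, False) - r2_base,
                    dr2s_act=forward_r2s(params, qh, True) - r2_base,
                )
            )
    return pts


class TestPercentBoldConversion:
    def test_zero_maps_to_zero(self):
        assert percent_bold_to_dr2s(0.0, 0.025) == 0.0

    def test_plug_in_value(self):
        assert percent_bold_to_dr2s(2.5, 0.025) == pytest.approx(-1.0)

    def test_round_trip(self):
        x = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(
            dr2s_to_percent_bold(percent_bold_to_dr2s(x, 0.025), 0.025), x
        )

    def test_rejects_nonpositive_te(self):
        with pytest.raises(ValueError):
            percent_bold_to_dr2s(1.0, 0.0)


class TestForwardModel:
    def test_rest_equals_active_without_response(self):
        p = SignalModelParams(dv_act=0.0, q_act=0.0)
        assert forward_r2s(p, -0.1, True) == pytest.approx(
            forward_r2s(p, -0.1, False)
        )

    def test_slope_ratio_is_one_plus_rvcbv(self):
        p = SignalModelParams()
        rest_slope = forward_r2s(p, 0.0, False) - forward_r2s(p, -1.0, False)
        act_slope = forward_r2s(p, 0.0, True) - forward_r2s(p, -1.0, True)
        assert act_slope / rest_slope == pytest.approx(1.0 + p.dv_act / p.v0)

    def test_intercept_gap_at_zero_abscissa(self):
        # at abscissa (1+q_h) = 0 the rest/active gap is k(V0+dV)Q0*q_act
        p = SignalModelParams()
        gap = forward_r2s(p, -1.0, True) - forward_r2s(p, -1.0, False)
        assert gap == pytest.approx(p.k * (p.v0 + p.dv_act) * p.q0 * p.q_act)


class TestFitCalibration:
    def test_noiseless_two_point_recovery(self):
        p = SignalModelParams(v0=0.03, dv_act=0.32 * 0.03, q0=0.4, q_act=-0.39)
        fit = fit_calibration(noiseless_points(p, [0.0, -0.17]), te=p.te)
        assert fit.rvcbv == pytest.approx(0.32, abs=1e-10)
        assert fit.q_act == pytest.approx(-0.39, abs=1e-10)
        assert fit.m == pytest.approx(p.m_percent, rel=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(
        v0=st.floats(min_value=0.01, max_value=0.1),
        rv=st.floats(min_value=-0.3, max_value=1.0),
        q_act=st.floats(min_value=-0.6, max_value=0.3),
        qh=st.floats(min_value=-0.3, max_value=-0.05),
    )
    def test_noiseless_recovery_property(self, v0, rv, q_act, qh):
        p = SignalModelParams(v0=v0, dv_act=rv * v0, q_act=q_act)
        fit = fit_calibration(noiseless_points(p, [0.0, qh, qh / 2]), te=p.te)
        assert fit.rvcbv == pytest.approx(rv, abs=1e-10)
        assert fit.q_act == pytest.approx(q_act, abs=1e-10)

    def test_slope_pair_gives_one_third_rvcbv(self):
        # slopes corresponding to M = 36 %, M' = 48 %
        p = SignalModelParams()  # defaults produce exactly these values
        fit = fit_calibration(noiseless_points(p, [0.0, -0.17]), te=0.025)
        assert (fit.m, fit.m_prime) == (
            pytest.approx(36.0),
            pytest.approx(48.0),
        )
        assert fit.rvcbv == pytest.approx(1.0 / 3.0)

    def test_duplicated_points_leave_fit_unchanged(self):
        p = SignalModelParams()
        f1 = fit_calibration(noiseless_points(p, [0.0, -0.17], 1), te=p.te)
        f2 = fit_calibration(noiseless_points(p, [0.0, -0.17], 3), te=p.te)
        assert f1.rvcbv == pytest.approx(f2.rvcbv, rel=1e-12)
        assert f1.q_act == pytest.approx(f2.q_act, rel=1e-12)

    def test_single_level_is_rank_deficient(self):
        p = SignalModelParams()
        with pytest.raises(ValueError, match="rank"):
            fit_calibration(noiseless_points(p, [-0.17], 4), te=p.te)

    def test_nonpositive_rest_slope_rejected(self):
        pts = [
            CalibrationPoint(q_h=0.0, dr2s_rest=0.0, dr2s_act=0.0),
            CalibrationPoint(q_h=-0.2, dr2s_rest=1.0, dr2s_act=1.0),
        ]
        with pytest.raises(ValueError, match="non-physical"):
            fit_calibration(pts, te=0.025)

    def test_rvcbv_invariant_to_assumed_q0(self):
        # rescaling every q_h by a constant rescales both slopes equally
        p = SignalModelParams()
        base = fit_calibration(noiseless_points(p, [0.0, -0.17]), te=p.te)
        for scale in (0.5, 0.8, 1.6):
            pts = [
                CalibrationPoint(q.q_h * scale, q.dr2s_rest, q.dr2s_act)
                for q in noiseless_points(p, [0.0, -0.17])
            ]
            fit = fit_calibration(pts, te=p.te)
            assert fit.rvcbv == pytest.approx(base.rvcbv, abs=1e-12)

    def test_rescale_is_exactly_linear_in_q0_ratio(self):
        # first-order propagation: q_act scales with q0_assumed/q0_measured
        for c in (0.5, 0.9434, 1.3):
            assert rescale_q_act(-0.29, 0.4 * c, 0.4) == pytest.approx(
                -0.29 * c, rel=1e-12
            )

    @pytest.mark.parametrize("c", [0.9434, 0.8826, 1.2])
    def test_exact_refit_under_qh_rescaling(self, c):
        # hand-derived identity: refitting with q_h scaled by c gives
        # c*q_act + (c-1)*rvCBV/(1+rvCBV); the published first-order
        # propagation (rescale_q_act) is its rvCBV -> 0 limit
        p = SignalModelParams()
        base = fit_calibration(noiseless_points(p, [0.0, -0.17]), te=p.te)
        pts = [
            CalibrationPoint(q.q_h * c, q.dr2s_rest, q.dr2s_act)
            for q in noiseless_points(p, [0.0, -0.17])
        ]
        refit = fit_calibration(pts, te=p.te)
        rv = base.rvcbv
        assert refit.q_act == pytest.approx(
            c * base.q_act + (c - 1.0) * rv / (1.0 + rv), rel=1e-9
        )
        assert refit.rvcbv == pytest.approx(rv, abs=1e-12)

    def test_forward_inverse_consistency_of_baseline_bold(self):
        # hyperoxia baseline %BOLD predicted by the fit equals -M*q_h
        p = SignalModelParams()
        qh = -0.17
        fit = fit_calibration(noiseless_points(p, [0.0, qh]), te=p.te)
        rest_pct = dr2s_to_percent_bold(
            forward_r2s(p, qh, False) - forward_r2s(p, 0.0, False), p.te
        )
        assert rest_pct == pytest.approx(-fit.m * qh, rel=1e-10)


class TestFick:
    def test_null_change(self):
        assert fick_rcmro2(0.0, 0.0).rcmro2 == 0.0

    def test_worked_subject_row(self):
        # rCBF 58.0 %, q_act -29.0 % -> rCMRO2 12.2 %
        assert 100 * fick_rcmro2(-0.290, 0.580).rcmro2 == pytest.approx(
            12.2, abs=0.05
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-0.5, max_value=2.0))
    def test_exact_cancellation_identity(self, rcbf):
        q_act = -rcbf / (1.0 + rcbf)
        assert fick_rcmro2(q_act, rcbf).rcmro2 == pytest.approx(0.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fick_rcmro2(-1.0, 0.5)
        with pytest.raises(ValueError):
            fick_rcmro2(0.0, -1.2)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "q_act,q0,expected",
        [(0.0, 0.4, 0.0), (-0.369, 0.4, 0.148), (-0.434, 0.4, 0.174)],
    )
    def test_delta_y_act(self, q_act, q0, expected):
        assert delta_y_act(q_act, q0) == pytest.approx(expected, abs=5e-4)

    def test_rescale_identity_and_worked_value(self):
        assert rescale_q_act(-0.3, 0.4, 0.4) == pytest.approx(-0.3)
        assert rescale_q_act(-0.290, 0.4, 0.424) == pytest.approx(-0.274, abs=5e-4)


class TestVoxelwiseMaps:
    def _volume_from_params(self, params, paradigm, qh, shape):
        from calbold import SimulationConfig
        from calbold.simulate import simulate_bold

        cfg = SimulationConfig(params=params, qh_hyperoxia=qh, tsnr=np.inf)
        tc = simulate_bold(cfg, 0, paradigm)
        vol = np.broadcast_to(tc.values, shape + (tc.values.size,)).copy()
        return vol

    def test_uniform_volume_gives_constant_maps(self, paradigm_a):
        p = SignalModelParams()
        qh_blocks = [0.0 if b.label == "normoxia" else -0.17 for b in paradigm_a.blocks]
        vol = self._volume_from_params(p, paradigm_a, -0.17, (3, 3))
        mask = np.ones((3, 3), dtype=bool)
        maps = voxelwise_maps(vol, mask, paradigm_a, qh_blocks, te=p.te)
        np.testing.assert_allclose(maps["rvcbv"], p.rvcbv, rtol=1e-6)
        np.testing.assert_allclose(maps["q_act"], p.q_act, rtol=1e-6)

    def test_two_region_phantom_recovers_both_truths(self, paradigm_a):
        p1 = SignalModelParams(dv_act=0.01)  # rvCBV 1/3
        p2 = SignalModelParams(dv_act=0.006)  # rvCBV 0.2
        qh_blocks = [0.0 if b.label == "normoxia" else -0.17 for b in paradigm_a.blocks]
        v1 = self._volume_from_params(p1, paradigm_a, -0.17, (2, 2))
        v2 = self._volume_from_params(p2, paradigm_a, -0.17, (2, 2))
        vol = np.concatenate([v1, v2], axis=0)  # (4, 2, nt)
        mask = np.ones((4, 2), dtype=bool)
        maps = voxelwise_maps(vol, mask, paradigm_a, qh_blocks, te=p1.te)
        assert np.nanmean(maps["rvcbv"][:2]) == pytest.approx(p1.rvcbv, rel=1e-6)
        assert np.nanmean(maps["rvcbv"][2:]) == pytest.approx(p2.rvcbv, rel=1e-6)

    def test_zero_variance_voxel_flagged_nan(self, paradigm_a):
        p = SignalModelParams()
        qh_blocks = [0.0 if b.label == "normoxia" else -0.17 for b in paradigm_a.blocks]
        vol = self._volume_from_params(p, paradigm_a, -0.17, (2, 1))
        vol[1, 0, :] = 100.0  # flat series: no response, fit must fail
        mask = np.ones((2, 1), dtype=bool)
        maps = voxelwise_maps(vol, mask, paradigm_a, qh_blocks, te=p.te)
        assert np.isfinite(maps["rvcbv"][0, 0])
        assert np.isnan(maps["rvcbv"][1, 0])

    def test_empty_mask_rejected(self, paradigm_a):
        vol = np.zeros((2, 2, len(paradigm_a.sample_times())))
        with pytest.raises(ValueError, match="empty mask"):
            voxelwise_maps(vol, np.zeros((2, 2), bool), paradigm_a, [0.0] * 5, 0.025)
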