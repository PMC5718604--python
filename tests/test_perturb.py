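"""Flow perturbation, SUVR computation and sweep machinery."""

import numpy as np
import pytest

from flowsuvr import (
    FrameSchedule,
    InputFunction,
    KineticParams,
    PerturbationSpec,
    RegionalTAC,
    compose_global,
    compute_suvr,
    delta_suvr,
    delta_suvr_time_course,
    fit_cubic,
    macro_parameters,
    perturb_flow,
    relative_delivery,
    simulate_tac,
    sweep_delta_suvr,
)
from flowsuvr.perturb import DeltaSUVRCurve


class TestPerturbFlow:
    def test_identity_at_zero(self, hc):
        assert perturb_flow(hc["precuneus"], 0.0) == hc["precuneus"]

    @pytest.mark.parametrize(
        "k1, pct, expected",
        [(0.77, -40, 0.46), (0.77, +40, 1.08), (0.66, -40, 0.40)],
    )
    def test_extreme_grid_endpoints(self, k1, pct, expected):
        p = KineticParams(K1=k1, k2=0.17, k3=0.01, k4=0.02, Vb=0.05)
        assert round(perturb_flow(p, pct).K1, 2) == expected

    def test_distribution_volumes_invariant(self, hc):
        rng = np.random.default_rng(3)
        for p in hc.values():
            for pct in rng.uniform(-80, 100, 25):
                m0, m1 = macro_parameters(p), macro_parameters(perturb_flow(p, pct))
                assert abs(m1.VND - m0.VND) < 1e-12
                assert abs(m1.VT - m0.VT) < 1e-11
                assert abs(m1.BPND - m0.BPND) < 1e-12

    def test_total_shutdown_rejected(self, hc):
        with pytest.raises(ValueError):
            perturb_flow(hc["CB"], -100.0)


def _const_tac(value, schedule, region="r"):
    return RegionalTAC(region=region, schedule=schedule,
                       values=np.full(len(schedule), float(value)))


class TestComputeSuvr:
    def test_self_ratio_is_one(self, input_function, frames, hc):
        tac = simulate_tac(hc["CB"], input_function, frames)
        assert compute_suvr(tac, tac) == 1.0

    def test_constant_ratio(self, frames):
        assert compute_suvr(
            _const_tac(2.68, frames), _const_tac(2.0, frames)
        ) == pytest.approx(1.34)

    def test_window_straddling_unequal_frames(self, input_function, frames, hc):
        """A window covering parts of two frames must weight each frame mean
        by its overlap duration; checked against fine-grained integration of
        the frame-step representation."""
        tac_t = simulate_tac(hc["precuneus"], input_function, frames)
        tac_r = simulate_tac(hc["CB"], input_function, frames)
        window = (38.0, 52.0)  # 3 min of one frame, 5+5 of two more, 1 of a fourth

        def oracle_mean(tac):
            tt = np.linspace(window[0], window[1], 200001)
            idx = np.searchsorted(tac.schedule.ends, tt, side="right")
            step = tac.values[np.clip(idx, 0, len(tac.values) - 1)]
            return np.trapezoid(step, tt) / (window[1] - window[0])

        expected = oracle_mean(tac_t) / oracle_mean(tac_r)
        assert compute_suvr(tac_t, tac_r, window) == pytest.approx(expected, rel=1e-6)

    def test_empty_window_rejected(self, frames):
        with pytest.raises(ValueError):
            compute_suvr(_const_tac(1, frames), _const_tac(1, frames), (70.0, 80.0))

    def test_zero_reference_rejected(self, frames):
        with pytest.raises(ValueError):
            compute_suvr(_const_tac(1, frames), _const_tac(0, frames))


class TestDeltaAndComposition:
    def test_delta_suvr_arithmetic(self):
        assert delta_suvr(1.34, 1.34) == 0.0
        assert delta_suvr(1.482, 1.340) == pytest.approx(10.6, abs=0.05)
        assert delta_suvr(0.67, 1.34) == pytest.approx(-50.0)
        with pytest.raises(ValueError):
            delta_suvr(1.0, 0.0)

    def test_compose_identity_factor(self):
        for x in (-40.0, -5.0, 0.0, 12.5):
            assert compose_global(x, 0.0) == pytest.approx(x)

    def test_compose_is_multiplicative(self):
        assert compose_global(10.6, -10.2) == pytest.approx(-0.68, abs=5e-3)
        assert compose_global(50.0, 50.0) == pytest.approx(125.0)

    def test_relative_delivery(self, hc):
        assert relative_delivery(1.0, 1.0) == 1.0
        assert relative_delivery(hc["precuneus"].K1, hc["CB"].K1) == pytest.approx(
            1.167, abs=5e-4
        )
        scaled = perturb_flow(hc["precuneus"], -40)
        assert relative_delivery(scaled.K1, hc["CB"].K1) == pytest.approx(
            0.6 * 1.1667, abs=1e-3
        )
        with pytest.raises(ValueError):
            relative_delivery(1.0, 0.0)


class TestSweep:
    def test_zero_grid_gives_zero_curve(self, input_function, frames, hc):
        spec = PerturbationSpec(mode="target-only", grid_pct=(0.0,))
        c = sweep_delta_suvr(hc["precuneus"], hc["CB"], input_function, spec, frames)
        assert c.delta_suvr_pct[0] == 0.0

    def test_global_factorizes_exactly(self, input_function, frames, hc):
        kw = dict(grid_pct=(-40.0, -10.0, 10.0, 40.0))
        ct = sweep_delta_suvr(hc["precuneus"], hc["CB"], input_function,
                              PerturbationSpec(mode="target-only", **kw), frames)
        cr = sweep_delta_suvr(hc["precuneus"], hc["CB"], input_function,
                              PerturbationSpec(mode="reference-only", **kw), frames)
        cg = sweep_delta_suvr(hc["precuneus"], hc["CB"], input_function,
                              PerturbationSpec(mode="global", **kw), frames)
        composed = [compose_global(a, b)
                    for a, b in zip(ct.delta_suvr_pct, cr.delta_suvr_pct)]
        np.testing.assert_allclose(cg.delta_suvr_pct, composed, rtol=1e-9)

    def test_target_curve_independent_of_reference(self, input_function, frames, hc):
        grids = dict(grid_pct=(-40.0, -20.0, 20.0, 40.0))
        a = sweep_delta_suvr(hc["precuneus"], hc["CB"], input_function,
                             PerturbationSpec(mode="target-only", reference="CB", **grids),
                             frames)
        b = sweep_delta_suvr(hc["precuneus"], hc["WM"], input_function,
                             PerturbationSpec(mode="target-only", reference="WM", **grids),
                             frames)
        np.testing.assert_allclose(a.delta_suvr_pct, b.delta_suvr_pct, rtol=1e-12)

    def test_reference_curve_independent_of_target(self, input_function, frames, hc):
        grids = dict(grid_pct=(-40.0, 40.0))
        a = sweep_delta_suvr(hc["precuneus"], hc["CB"], input_function,
                             PerturbationSpec(mode="reference-only", **grids), frames)
        b = sweep_delta_suvr(hc["WM"], hc["CB"], input_function,
                             PerturbationSpec(mode="reference-only", target="WM", **grids),
                             frames)
        np.testing.assert_allclose(a.delta_suvr_pct, b.delta_suvr_pct, rtol=1e-12)

    def test_flow_reduction_sign_pattern(self, input_function, frames, hc):
        """-40% flow: target SUVR up; CB-referenced SUVR down; WM-referenced up."""
        g = dict(grid_pct=(-40.0,))
        d_target = sweep_delta_suvr(
            hc["precuneus"], hc["CB"], input_function,
            PerturbationSpec(mode="target-only", **g), frames).delta_suvr_pct[0]
        d_cb = sweep_delta_suvr(
            hc["precuneus"], hc["CB"], input_function,
            PerturbationSpec(mode="reference-only", **g), frames).delta_suvr_pct[0]
        d_wm = sweep_delta_suvr(
            hc["precuneus"], hc["WM"], input_function,
            PerturbationSpec(mode="reference-only", reference="WM", **g),
            frames).delta_suvr_pct[0]
        assert d_target > 0 and d_cb < 0 and d_wm > 0

    def test_target_curve_strictly_decreasing(self, input_function, frames, hc):
        c = sweep_delta_suvr(hc["precuneus"], hc["CB"], input_function,
                             PerturbationSpec(mode="target-only"), frames)
        assert np.all(np.diff(c.delta_suvr_pct) < 0)

    def test_white_matter_suv_turns_over(self, input_function, frames, hc):
        """White-matter SUV rises with K1 up to ~0.4 mL/min/mL then falls:
        the discrete derivative changes sign between +40% and +80% scaling."""
        def wm_suv(pct):
            p = perturb_flow(hc["WM"], pct) if pct else hc["WM"]
            return simulate_tac(p, input_function, frames).values[-2:].mean()

        assert wm_suv(40.0) > wm_suv(0.0)
        assert wm_suv(80.0) < wm_suv(40.0)


class TestCubicFit:
    @staticmethod
    def _curve(x, y):
        return DeltaSUVRCurve(
            grid_pct=np.asarray(x, float), delta_suvr_pct=np.asarray(y, float),
            baseline_suvr=1.0, mode="target-only", target="t", reference="r",
        )

    def test_four_points_interpolated_exactly(self):
        _, r2 = fit_cubic(self._curve([-2, -1, 1, 2], [3.0, -1.0, 2.0, 5.0]))
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_recovers_known_cubic(self):
        x = np.array([-40, -20, -10, -5, 5, 10, 20, 40], float)
        true = np.array([1e-4, -2e-3, -0.3, 0.7])
        coeffs, r2 = fit_cubic(self._curve(x, np.polyval(true, x)))
        np.testing.assert_allclose(coeffs, true, rtol=1e-9, atol=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_r2_undefined(self):
        _, r2 = fit_cubic(self._curve([-2, -1, 0, 1, 2], [0.0] * 5))
        assert np.isnan(r2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cubic(self._curve([0, 1, 2], [0.0, 1.0, 2.0]))


class TestTimeCourse:
    def test_zero_change_gives_zero_series(self, input_function, frames, hc):
        _, tc = delta_suvr_time_course(
            hc["precuneus"], hc["CB"], input_function, "target-only", 0.0, frames)
        valid = ~np.isnan(tc)
        np.testing.assert_array_equal(tc[valid], 0.0)

    def test_flow_reduction_positive_late_and_relaxing(self, input_function, frames, hc):
        _, tc = delta_suvr_time_course(
            hc["precuneus"], hc["CB"], input_function, "target-only", -40.0, frames)
        late = tc[-5:]
        assert np.all(late > 0)
        assert np.all(np.diff(late) < 0)  # relaxing toward equilibrium (0)

    def test_constant_infusion_late_windows_unbiased(self, constant_input, hc):
        """At constant input, late-window SUVR depends only on V_T (+Vb),
        which the perturbation preserves: dSUVR must vanish."""
        fr = FrameSchedule.from_durations([10.0] * 70)  # 0-700 min
        _, tc = delta_suvr_time_course(
            hc["precuneus"], hc["CB"], constant_input, "target-only", -40.0, fr)
        assert abs(tc[-1]) < 0.5

    def test_cumulative_windowing_option(self, input_function, frames, hc):
        _, inst = delta_suvr_time_course(
            hc["precuneus"], hc["CB"], input_function, "target-only", -40.0, frames)
        _, cum = delta_suvr_time_course(
            hc["precuneus"], hc["CB"], input_function, "target-only", -40.0, frames,
            cumulative=True)
        assert not np.allclose(inst[-1], cum[-1])
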