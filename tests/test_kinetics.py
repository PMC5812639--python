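"""Forward-model and convolution-primitive checks against independent oracles."""
import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, solve_ivp

from irrevkin import (
    PUTAMEN,
    FrameSchedule,
    RateConstants,
    SampledCurve,
    convolve_exp,
    fit_patlak,
    macroparameters,
    simulate_tac,
)
from irrevkin.kinetics import TacModel, frame_average


def test_convolution_theta_zero_is_running_integral(ca):
    conv = convolve_exp(0.0, ca)
    f = ca.interp(conv.times)
    oracle = cumulative_trapezoid(f, conv.times, initial=0.0)
    np.testing.assert_allclose(conv.values, oracle, rtol=1e-12, atol=1e-12)


def test_convolution_of_zero_curve_is_zero():
    zero = SampledCurve(np.linspace(0, 10, 11), np.zeros(11))
    conv = convolve_exp(0.7, zero)
    assert np.all(conv.values == 0.0)


def test_convolution_matches_fine_riemann_quadrature(ca, schedule):
    """Exact piecewise-linear recursion vs brute-force quadrature on a 10x
    finer grid, compared at every frame midpoint."""
    theta = 0.149
    conv = convolve_exp(theta, ca, grid_step=1.0 / 60.0)
    h = 1.0 / 600.0
    fine_t = np.arange(int(round(ca.last_time / h)) + 1) * h
    f = ca.interp(fine_t)
    kernel = np.exp(-theta * fine_t)
    # trapezoid-rule discrete convolution
    brute = h * (
        np.convolve(f, kernel)[: fine_t.size]
        - 0.5 * (f[0] * kernel + f * kernel[0])
    )
    mids = schedule.midpoints
    ours = np.interp(mids, conv.times, conv.values)
    theirs = np.interp(mids, fine_t, brute)
    np.testing.assert_allclose(ours, theirs, rtol=1e-3, atol=1e-6 * brute.max())


def test_convolution_rejects_bad_inputs(ca):
    with pytest.raises(ValueError):
        convolve_exp(-0.1, ca)
    with pytest.raises(ValueError):
        SampledCurve(np.array([0.0, 2.0, 1.0]), np.ones(3))


@pytest.mark.parametrize(
    "rc",
    [
        PUTAMEN,
        RateConstants(K1=0.16, k2=0.04, k3=0.0049, VB=0.05),
        RateConstants(K1=0.36, k2=0.18, k3=0.098, VB=0.1),
        RateConstants(K1=0.31, k2=0.1, k3=0.0, VB=0.05),
    ],
)
def test_forward_model_matches_ode_integration(rc, ca, cb, schedule):
    """Frame-averaged model vs stiff-safe integration of the compartmental
    ODE system, within 0.1% per frame."""
    tac = simulate_tac(rc, ca, cb, schedule)

    def rhs(t, y):
        cav = np.interp(t, ca.times, ca.values, left=0.0)
        c1, c2, integral = y
        return [rc.K1 * cav - (rc.k2 + rc.k3) * c1, rc.k3 * c1, c1 + c2]

    edges = np.unique(np.concatenate([schedule.starts, schedule.ends]))
    sol = solve_ivp(
        rhs, (0.0, schedule.end_time), [0.0, 0.0, 0.0],
        method="LSODA", t_eval=edges, rtol=1e-10, atol=1e-12,
    )
    cum_tissue = dict(zip(edges, sol.y[2]))
    model = TacModel(ca, cb, schedule)
    ode_frames = np.array(
        [
            (1 - rc.VB) * (cum_tissue[e] - cum_tissue[s]) / (e - s)
            for s, e in zip(schedule.starts, schedule.ends)
        ]
    ) + rc.VB * model.cb_frames
    # atol floors the comparison on the empty pre-arrival frame
    np.testing.assert_allclose(
        tac.values, ode_frames, rtol=1e-3, atol=1e-9 * np.max(ode_frames)
    )


def test_vascular_only_voxel_is_scaled_whole_blood(ca, cb, schedule):
    rc = RateConstants(K1=0.0, k2=0.0, k3=0.0, VB=0.05)
    tac = simulate_tac(rc, ca, cb, schedule)
    model = TacModel(ca, cb, schedule)
    np.testing.assert_allclose(tac.values, 0.05 * model.cb_frames, rtol=1e-12)


def test_k3_zero_collapses_to_one_tissue_model(ca, cb, schedule):
    rc = RateConstants(K1=0.31, k2=0.1, k3=0.0, VB=0.05)
    tac = simulate_tac(rc, ca, cb, schedule)
    conv = convolve_exp(rc.k2, ca)
    model = TacModel(ca, cb, schedule)
    one_tissue = (1 - rc.VB) * rc.K1 * frame_average(
        conv.times, conv.values, schedule
    ) + rc.VB * model.cb_frames
    np.testing.assert_allclose(tac.values, one_tissue, rtol=1e-10)


def test_model_linear_in_blood_curves_and_homogeneous_in_k1(ca, cb, schedule):
    rc = PUTAMEN
    base = simulate_tac(rc, ca, cb, schedule)
    scaled_inputs = simulate_tac(
        rc,
        SampledCurve(ca.times, 2.5 * ca.values),
        SampledCurve(cb.times, 2.5 * cb.values),
        schedule,
    )
    np.testing.assert_allclose(scaled_inputs.values, 2.5 * base.values, rtol=1e-12)
    rc0 = rc.replace(VB=0.0)
    np.testing.assert_allclose(
        simulate_tac(rc0.replace(K1=3 * rc0.K1), ca, cb, schedule).values,
        3 * simulate_tac(rc0, ca, cb, schedule).values,
        rtol=1e-12,
    )


def test_theta_to_zero_limit_is_continuous(ca, cb, schedule):
    tiny = simulate_tac(
        RateConstants(K1=0.31, k2=5e-7, k3=5e-7, VB=0.0), ca, cb, schedule
    )
    limit = simulate_tac(
        RateConstants(K1=0.31, k2=0.0, k3=0.0, VB=0.0), ca, cb, schedule
    )
    np.testing.assert_allclose(tiny.values, limit.values, rtol=1e-4)


def test_schedule_beyond_curve_support_errors(ca, cb):
    sched = FrameSchedule(np.array([[0.0, 30.0], [30.0, 90.0]]))
    with pytest.raises(ValueError, match="extends"):
        simulate_tac(PUTAMEN, ca, cb, sched)


def test_macroparameters_putamen_hand_values():
    mp = macroparameters(PUTAMEN)
    assert mp.Ki == pytest.approx(0.1019, abs=5e-5)
    assert mp.lambda_k3 == pytest.approx(0.1519, abs=5e-5)
    assert mp.VND == pytest.approx(3.1)
    assert mp.theta == pytest.approx(0.149)


def test_macroparameters_edge_cases():
    assert macroparameters(RateConstants(K1=0.3, k2=0.1, k3=0.0)).Ki == 0.0
    assert macroparameters(RateConstants(K1=0.3, k2=0.1, k3=0.0)).lambda_k3 == 0.0
    with pytest.warns(RuntimeWarning, match="k2 = 0"):
        mp = macroparameters(RateConstants(K1=0.3, k2=0.0, k3=0.05))
    assert mp.Ki == pytest.approx(0.3)  # Ki -> K1 when trapping dominates


def test_ki_sensitivity_to_k3_reduction():
    """A 90% k3 reduction cuts Ki by ~82% when k3 = k2 and 75% when k3 = 2k2."""
    def reduction(k2, k3):
        before = macroparameters(RateConstants(K1=0.3, k2=k2, k3=k3)).Ki
        after = macroparameters(RateConstants(K1=0.3, k2=k2, k3=0.1 * k3)).Ki
        return 100 * (1 - after / before)

    assert reduction(0.1, 0.1) == pytest.approx(81.818, abs=1e-2)
    assert reduction(0.1, 0.2) == pytest.approx(75.0, abs=1e-9)


def test_ki_matches_asymptotic_patlak_slope(ca, cb, schedule):
    """Self-consistency: the analytic net influx rate equals the late-time
    graphical slope of a noise-free, blood-free TAC within 5%."""
    rc = PUTAMEN.replace(VB=0.0)
    tac = simulate_tac(rc, ca, cb, schedule)
    res = fit_patlak(tac, ca, cb, tstar=27.25, vb=0.0)
    assert res.Ki == pytest.approx(macroparameters(rc).Ki, rel=0.05)
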