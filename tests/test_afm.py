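"""Force-curve inversion: contact detection, slope fit, tension/pressure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blebmech.afm import (
    AfmConfig,
    CantileverCalibration,
    CellGeometry,
    ForceCurve,
    MechanicalEstimate,
    analyze_curve,
    detect_contact_point,
    fit_deflection_slope,
    pressure_from_tension,
    summarize_cell,
    tension_from_slope,
)
from blebmech.errors import (
    DegenerateBaseline,
    InsufficientPoints,
    NoContact,
    RigidContact,
)
from blebmech.synthetic import gen_force_curve

CAL = CantileverCalibration(spring_constant=0.1)


def make_curve(z, d, k_c=0.1):
    return ForceCurve(z=z, d=d, calibration=CantileverCalibration(spring_constant=k_c))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def test_force_curve_sorts_and_averages_duplicates():
    z = np.array([3.0, 1.0, 2.0, 2.0] + list(np.arange(4.0, 20.0)))
    d = np.array([3.0, 1.0, 2.0, 4.0] + list(np.arange(4.0, 20.0)))
    c = make_curve(z, d)
    assert np.all(np.diff(c.z) > 0)
    # duplicate z=2 averaged to d=3
    assert c.d[np.searchsorted(c.z, 2.0)] == 3.0


def test_force_curve_rejects_short_and_nonfinite():
    with pytest.raises(ValueError):
        make_curve(np.arange(5.0), np.arange(5.0))
    z = np.arange(20.0)
    d = np.arange(20.0)
    d[3] = np.nan
    with pytest.raises(ValueError):
        make_curve(z, d)


def test_geometry_validation():
    with pytest.raises(ValueError):
        CellGeometry(radius=-1e-6)
    with pytest.raises(ValueError):
        CellGeometry(radius=1e-6, cortex_thickness=5e-6)


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------

def test_contact_noiseless_piecewise_linear_exact():
    z = np.linspace(0, 4000, 1024)
    d = 0.05 * np.clip(z - 1000.0, 0, None)
    z0 = detect_contact_point(make_curve(z, d))
    assert abs(z0 - 1000.0) <= z[1] - z[0]


def test_contact_flat_zero_trace_is_no_contact():
    z = np.linspace(0, 4000, 256)
    c = make_curve(z, np.zeros_like(z))
    with pytest.raises(NoContact):
        detect_contact_point(c)
    with pytest.raises(DegenerateBaseline):
        detect_contact_point(c)


def test_contact_noisy_flat_trace_is_no_contact(rng):
    z = np.linspace(0, 4000, 256)
    c = make_curve(z, rng.normal(0, 0.5, size=z.shape))
    with pytest.raises(NoContact):
        detect_contact_point(c)


def test_contact_monte_carlo_within_50nm(rng):
    """Noise SD 0.5 nm, true Z0 = 1200 nm: >= 95% of estimates within 50 nm."""
    hits = 0
    n = 200
    for _ in range(n):
        c, _ = gen_force_curve(
            tension=1e-3, contact_z0_nm=1200.0, noise_sd_nm=0.5, seed=rng
        )
        hits += abs(detect_contact_point(c, k_sigma=3.0) - 1200.0) <= 50.0
    assert hits >= 0.95 * n


# ---------------------------------------------------------------------------
# slope fit
# ---------------------------------------------------------------------------

def test_fit_exact_linear_input():
    z = np.linspace(0, 2000, 512)
    d = 0.5 * np.clip(z - 500.0, 0, None)
    s, r2, n = fit_deflection_slope(make_curve(z, d), 500.0)
    assert s == pytest.approx(0.5, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)
    assert n >= 8


def test_fit_noiseless_generator_round_trip():
    curve, truth = gen_force_curve(tension=1e-3, noise_sd_nm=0.0)
    s, r2, _ = fit_deflection_slope(curve, truth["contact_z0_nm"])
    assert s == pytest.approx(truth["slope"], rel=1e-9)
    assert r2 == pytest.approx(1.0, abs=1e-9)


def test_fit_mid_window_jump_degrades_r2(rng):
    """A deflection discontinuity inside the window must break the fit."""
    curve, _ = gen_force_curve(tension=1e-3, noise_sd_nm=0.5, slip=True, seed=rng)
    z0 = detect_contact_point(curve)
    _, r2, _ = fit_deflection_slope(curve, z0)
    assert r2 < 0.9


def test_fit_insufficient_points():
    z = np.linspace(0, 2000, 20)
    d = np.clip(z - 1950.0, 0, None)
    with pytest.raises(InsufficientPoints):
        fit_deflection_slope(make_curve(z, d), 1950.0)


# ---------------------------------------------------------------------------
# tension & pressure
# ---------------------------------------------------------------------------

def test_tension_examples():
    assert tension_from_slope(0.0, 0.1) == 0.0
    # s = 0.5 means Z/d = 2, so T = k_c/pi
    assert tension_from_slope(0.5, 0.1) == pytest.approx(0.1 / math.pi, rel=1e-12)
    with pytest.raises(RigidContact):
        tension_from_slope(1.0, 0.1)


@settings(deadline=None, derandomize=True)
@given(
    s1=st.floats(0.0, 0.99),
    ds=st.floats(1e-6, 0.009),
    k1=st.floats(0.01, 1.0),
    dk=st.floats(1e-6, 1.0),
)
def test_tension_strictly_monotone(s1, ds, k1, dk):
    assert tension_from_slope(s1 + ds, k1) > tension_from_slope(s1, k1)
    if s1 > 1e-12:  # k_c * s underflows to 0 for subnormal slopes
        assert tension_from_slope(s1, k1 + dk) > tension_from_slope(s1, k1)


def test_pressure_laplace(geometry):
    assert pressure_from_tension(0.0, geometry) == 0.0
    # T = 1 mN/m, R = 10 um -> 200 Pa
    assert pressure_from_tension(1e-3, geometry) == pytest.approx(200.0, rel=1e-12)
    # doubling R halves P
    big = CellGeometry(radius=20e-6)
    assert pressure_from_tension(1e-3, big) == pytest.approx(100.0, rel=1e-12)


# ---------------------------------------------------------------------------
# analyze_curve & aggregation
# ---------------------------------------------------------------------------

def test_analyze_clean_curve_recovers_truth(geometry, rng):
    curve, _ = gen_force_curve(tension=1e-3, noise_sd_nm=0.3, seed=rng)
    est = analyze_curve(curve, geometry)
    assert est.accepted and est.reason == "ok"
    assert est.tension == pytest.approx(1e-3, rel=0.10)
    assert est.pressure == pytest.approx(200.0, rel=0.10)


def test_analyze_laplace_identity_exact(geometry, rng):
    curve, _ = gen_force_curve(tension=1e-3, noise_sd_nm=0.3, seed=rng)
    est = analyze_curve(curve, geometry)
    # same floating path as the implementation: P is literally 2T/R
    assert est.pressure == 2.0 * est.tension / geometry.radius


def test_analyze_slip_curve_rejected_low_r2(geometry, rng):
    curve, _ = gen_force_curve(tension=1e-3, noise_sd_nm=0.5, slip=True, seed=rng)
    est = analyze_curve(curve, geometry)
    assert not est.accepted and est.reason == "low_r2"
    assert math.isnan(est.tension)


def test_analyze_flat_curve_rejected_no_contact(geometry, rng):
    z = np.linspace(0, 4000, 512)
    curve = make_curve(z, rng.normal(0, 0.5, size=z.shape))
    est = analyze_curve(curve, geometry)
    assert not est.accepted and est.reason == "no_contact"


def test_noiseless_round_trip_high_precision(geometry):
    """Forward model -> full analysis recovers T to 1e-6 relative."""
    for T in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1):
        for k_c in (0.08, 0.1, 0.11):
            curve, _ = gen_force_curve(
                tension=T, spring_constant=k_c, noise_sd_nm=0.0
            )
            est = analyze_curve(curve, geometry)
            assert est.accepted
            assert est.tension == pytest.approx(T, rel=1e-6)


def test_per_point_oracle_matches_slope_estimate(geometry):
    """T from pointwise k_c/(pi((z-z0)/d - 1)) averaged over the window
    agrees with the slope-based estimate on noiseless curves (both are
    algebraic forms of the same force balance)."""
    curve, truth = gen_force_curve(tension=2e-3, noise_sd_nm=0.0)
    est = analyze_curve(curve, geometry)
    z0 = truth["contact_z0_nm"]
    x = curve.z - z0
    sel = (x > 1.0) & (x <= 400.0) & (curve.d > 0)
    T_pts = 0.1 / (math.pi * (x[sel] / curve.d[sel] - 1.0))
    assert np.mean(T_pts) == pytest.approx(est.tension, rel=0.01)


def test_summarize_constant_estimates():
    ests = [
        MechanicalEstimate(cell_id="c", tension=2e-3, pressure=400.0, accepted=True)
        for _ in range(10)
    ]
    s = summarize_cell(ests, "c")
    assert s.tension_mean == pytest.approx(2e-3)
    assert s.tension_sd == pytest.approx(0.0, abs=1e-12)
    assert s.n_curves_accepted == 10


def test_summarize_mixed_accepted():
    acc = [
        MechanicalEstimate(tension=1e-3, pressure=200.0, accepted=True)
        for _ in range(7)
    ]
    rej = [MechanicalEstimate(accepted=False, reason="low_r2") for _ in range(3)]
    s = summarize_cell(acc + rej, "c")
    assert s.n_curves_total == 10 and s.n_curves_accepted == 7
    assert s.tension_mean == pytest.approx(1e-3)


def test_summarize_none_accepted_flags_nan():
    s = summarize_cell([MechanicalEstimate(accepted=False)], "c")
    assert s.n_curves_accepted == 0
    assert math.isnan(s.tension_mean)


def test_summarize_noisy_recoveries_close_to_truth(geometry, rng):
    ests = []
    for i in range(10):
        curve, _ = gen_force_curve(tension=1e-3, noise_sd_nm=0.5, seed=rng)
        ests.append(analyze_curve(curve, geometry))
    s = summarize_cell(ests, "sim")
    assert s.tension_mean == pytest.approx(1e-3, rel=0.05)
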