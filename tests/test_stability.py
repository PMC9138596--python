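"""Wave theory, Morison forces, sliding/overturning checks, slab sizing."""

import math

import numpy as np
import pytest

from reefscore import (
    DesignWave,
    ForceCoefficients,
    SlabInfeasibleError,
    WaveConditions,
    cnoidal_kinematics,
    linear_kinematics,
    morison_force,
    size_slab,
    solve_dispersion,
    stability_check,
)
from reefscore.errors import WaveTheoryError
from reefscore.stability import (
    G,
    cnoidal_parameters,
    cnoidal_surface,
    design_wave,
    submerged_weight,
)

from conftest import make_cube


def bisect_dispersion(period, depth):
    """Independent bisection oracle for the dispersion relation."""
    omega = 2 * math.pi / period
    target = omega**2 / G
    lo, hi = 1e-8, 100.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid * math.tanh(mid * depth) < target:
            lo = mid
        else:
            hi = mid
    return 2 * math.pi / (0.5 * (lo + hi))


def wave_from(height, period, depth, theory="linear"):
    L = solve_dispersion(period, depth)
    return DesignWave(
        height=height,
        period=period,
        wavelength=L,
        wavenumber=2 * math.pi / L,
        theory=theory,
        breaking_limited=False,
    )


# ---------------------------------------------------------------------
# dispersion

class TestDispersion:
    def test_deep_water_closed_form(self):
        L = solve_dispersion(16.1, 5_000.0)
        assert L == pytest.approx(G * 16.1**2 / (2 * math.pi), rel=1e-9)

    def test_shallow_limit_phase_speed(self):
        for h in (0.5, 0.1, 0.02):
            L = solve_dispersion(60.0, h)
            assert L / 60.0 == pytest.approx(math.sqrt(G * h), rel=0.02)

    def test_intermediate_depth_against_bisection_oracle(self):
        assert solve_dispersion(8.0, 10.0) == pytest.approx(
            bisect_dispersion(8.0, 10.0), rel=1e-8
        )
        assert solve_dispersion(8.0, 10.0) == pytest.approx(70.9, abs=0.05)

    def test_residual_below_tolerance_across_grid(self):
        for T in np.linspace(2.0, 25.0, 12):
            for h in np.geomspace(1.0, 200.0, 12):
                L = solve_dispersion(float(T), float(h))
                k = 2 * math.pi / L
                omega = 2 * math.pi / T
                residual = abs(G * k * math.tanh(k * h) - omega**2) / omega**2
                assert residual < 1e-10


# ---------------------------------------------------------------------
# design wave

class TestDesignWave:
    def test_rayleigh_statistic_maps_severe_sea_state_to_about_ten_metres(self):
        cond = WaveConditions(hs=5.5, tp=16.1, depth=500.0, n_waves=1000)
        wave = design_wave(cond)
        assert wave.height == pytest.approx(5.5 * math.sqrt(math.log(1000) / 2))
        assert 9.5 <= wave.height <= 10.5
        assert not wave.breaking_limited

    def test_null_sea_state(self):
        cond = WaveConditions(hs=0.0, tp=10.0, depth=10.0)
        assert design_wave(cond).height == 0.0

    def test_depth_limited_height(self):
        cond = WaveConditions(hs=50.0, tp=14.0, depth=5.0)
        wave = design_wave(cond, gamma=0.78)
        assert wave.height == pytest.approx(3.9)
        assert wave.breaking_limited

    def test_theory_selection_by_ursell_number(self):
        shallow = design_wave(WaveConditions(hs=3.0, tp=14.0, depth=6.0))
        deep = design_wave(WaveConditions(hs=3.0, tp=8.0, depth=400.0))
        assert shallow.theory == "cnoidal"
        assert deep.theory == "linear"


# ---------------------------------------------------------------------
# kinematics

class TestLinearKinematics:
    def test_no_wave_returns_current_only(self):
        wave = wave_from(0.0, 10.0, 8.0)
        for phase in (0.0, 1.0, 3.0):
            u, a = linear_kinematics(wave, 8.0, 2.0, current=0.3, phase=phase)
            assert u == 0.3 and a == 0.0

    def test_velocity_peaks_and_acceleration_vanishes_at_crest(self):
        wave = wave_from(2.0, 10.0, 8.0)
        u0, a0 = linear_kinematics(wave, 8.0, 1.0, phase=0.0)
        assert a0 == pytest.approx(0.0, abs=1e-12)
        for phase in np.linspace(0.1, 2 * math.pi - 0.1, 25):
            u, _ = linear_kinematics(wave, 8.0, 1.0, phase=float(phase))
            assert u < u0

    def test_matches_airy_closed_form(self):
        H, T, h, z = 2.0, 10.0, 8.0, 1.0
        k = 2 * math.pi / bisect_dispersion(T, h)
        omega = 2 * math.pi / T
        expected = 0.5 * H * omega * math.cosh(k * z) / math.sinh(k * h)
        wave = wave_from(H, T, h)
        u, _ = linear_kinematics(wave, h, z, phase=0.0)
        assert u == pytest.approx(expected, rel=1e-7)
        _, a = linear_kinematics(wave, h, z, phase=math.pi / 2)
        assert a == pytest.approx(expected * omega, rel=1e-7)

    def test_elevation_outside_column_rejected(self):
        wave = wave_from(2.0, 10.0, 8.0)
        with pytest.raises(ValueError):
            linear_kinematics(wave, 8.0, 9.0)


class TestCnoidalKinematics:
    def test_small_ursell_limit_matches_depth_averaged_airy(self):
        h, T, H = 4.0, 30.0, 0.0005
        wave = wave_from(H, T, h, theory="cnoidal")
        k = 2 * math.pi / wave.wavelength
        omega = 2 * math.pi / T
        for phase in (0.0, 0.8, 2.0, math.pi):
            uc, _ = cnoidal_kinematics(wave, h, 1.0, phase=phase)
            ua = 0.5 * H * omega * math.cos(phase) / (k * h)
            assert uc == pytest.approx(ua, abs=0.01 * 0.5 * H * omega / (k * h))

    def test_large_m_limit_recovers_solitary_profile(self):
        """As m -> 1 the crest-referenced cn^2 profile approaches the
        solitary closed form H sech^2(sqrt(3H/4h^3) x)."""
        from scipy.special import ellipe, ellipk

        h, T, H = 5.0, 30.0, 1.0
        m, L, c = cnoidal_parameters(H, T, h)
        assert m > 0.999
        K, E = ellipk(m), ellipe(m)
        trough = (H / m) * (1.0 - m - E / K)
        for frac in (0.0, 0.01, 0.03, 0.06):
            x = frac * L
            eta = cnoidal_surface(H, h, m, 2 * math.pi * frac)
            solitary = H / math.cosh(math.sqrt(3 * H / (4 * h**3)) * x) ** 2
            assert eta - trough == pytest.approx(solitary, abs=0.01 * H)

    def test_crest_velocity_exceeds_trough_speed(self):
        for H, T, h in [(0.5, 12.0, 4.0), (1.5, 14.0, 5.0), (2.5, 16.0, 6.0)]:
            wave = wave_from(H, T, h, theory="cnoidal")
            u_crest, _ = cnoidal_kinematics(wave, h, 1.0, phase=0.0)
            u_trough, _ = cnoidal_kinematics(wave, h, 1.0, phase=math.pi)
            assert u_crest > 0 > u_trough
            assert u_crest > abs(u_trough)

    def test_surface_profile_has_zero_mean(self):
        H, T, h = 1.5, 14.0, 5.0
        m, _, _ = cnoidal_parameters(H, T, h)
        phases = np.linspace(0, 2 * math.pi, 20_001)
        eta = [cnoidal_surface(H, h, m, float(p)) for p in phases]
        assert np.trapezoid(eta, phases) / (2 * math.pi) == pytest.approx(
            0.0, abs=1e-3 * H
        )

    def test_zero_height_rejected_by_parameter_solve(self):
        with pytest.raises(WaveTheoryError):
            cnoidal_parameters(0.0, 10.0, 5.0)

    def test_continuity_in_phase(self):
        wave = wave_from(1.0, 12.0, 4.0, theory="cnoidal")
        phases = np.linspace(0, 2 * math.pi, 721)
        u = np.array([cnoidal_kinematics(wave, 4.0, 1.0, float(p))[0] for p in phases])
        assert np.max(np.abs(np.diff(u))) < 0.05 * (u.max() - u.min())


# ---------------------------------------------------------------------
# forces

class TestMorison:
    def test_null_flow(self):
        assert morison_force(0.0, 0.0, 2.0, 3.0) == 0.0

    def test_drag_hand_value(self):
        f = morison_force(2.0, 0.0, 2.25, 0.0, rho=1025, cd=1.05, cm=0.0)
        assert f == pytest.approx(4_843.1, abs=0.1)

    def test_drag_quadratic_and_odd_in_velocity(self):
        f1 = morison_force(1.5, 0.0, 2.0, 0.0, cd=1.2, cm=0.0)
        f2 = morison_force(3.0, 0.0, 2.0, 0.0, cd=1.2, cm=0.0)
        assert f2 == pytest.approx(4 * f1)
        assert morison_force(-1.5, 0.0, 2.0, 0.0, cd=1.2, cm=0.0) == -f1

    def test_inertia_linear_in_acceleration(self):
        f1 = morison_force(0.0, 0.7, 0.0, 3.0)
        f2 = morison_force(0.0, 1.4, 0.0, 3.0)
        f3 = morison_force(0.0, -0.7, 0.0, 3.0)
        assert f2 == pytest.approx(2 * f1)
        assert f3 == pytest.approx(-f1)


# ---------------------------------------------------------------------
# stability and slab sizing

MILD = WaveConditions(hs=1.2, tp=8.0, depth=6.0)
# spans the three sizing regimes for a 1.5 m cube: stable bare,
# sliding-limited (slab helps), overturning-dominated (slab cannot help)
SEA_STATES = [
    WaveConditions(hs=0.8, tp=7.0, depth=6.0),
    WaveConditions(hs=1.75, tp=9.0, depth=6.0),
    WaveConditions(hs=2.4, tp=10.0, depth=7.0),
]


class TestStabilityCheck:
    def test_sliding_safety_factor_arithmetic(self):
        # submerged weight 30 kN, mu = 0.6, F_H = 10 kN, no lift -> SF 1.8
        assert 0.6 * 30_000 / 10_000 == pytest.approx(1.8)
        # and the report reproduces the same formula on a real load case
        design = make_cube(edge=1.5)
        wave = design_wave(MILD)
        report = stability_check(design, wave, MILD)
        w = submerged_weight(design, ForceCoefficients(), MILD.rho)
        assert report.submerged_weight == pytest.approx(w)
        assert report.sliding_sf == pytest.approx(
            0.6 * w / report.horizontal_force
        )

    def test_zero_wave_zero_current_is_no_load(self):
        design = make_cube(edge=1.5)
        cond = WaveConditions(hs=0.0, tp=8.0, depth=6.0)
        report = stability_check(design, design_wave(cond), cond)
        assert report.no_load_case
        assert math.isinf(report.sliding_sf)
        assert math.isinf(report.overturning_sf)

    def test_safety_factors_decrease_with_wave_height(self):
        design = make_cube(edge=1.5)
        sliding, overturning = [], []
        for hs in (0.4, 0.8, 1.2, 1.6):
            cond = WaveConditions(hs=hs, tp=8.0, depth=6.0)
            report = stability_check(design, design_wave(cond), cond)
            sliding.append(report.sliding_sf)
            overturning.append(report.overturning_sf)
        assert all(a > b for a, b in zip(sliding, sliding[1:]))
        assert all(a > b for a, b in zip(overturning, overturning[1:]))

    def test_strip_integration_close_to_midheight_point(self):
        design = make_cube(edge=1.5)
        wave = design_wave(MILD)
        point = stability_check(design, wave, MILD, ForceCoefficients(strips=1))
        strips = stability_check(design, wave, MILD, ForceCoefficients(strips=12))
        assert strips.horizontal_force == pytest.approx(
            point.horizontal_force, rel=0.1
        )


class TestSlabSizing:
    def test_stable_bare_unit_needs_no_slab(self):
        design = make_cube(edge=1.5)
        cond = WaveConditions(hs=0.3, tp=7.0, depth=6.0)
        assert size_slab(design, design_wave(cond), cond) == 0.0

    def test_sizing_is_inverse_of_check(self):
        """The returned height passes both targets; one step less fails."""
        exercised = 0
        for cond in SEA_STATES:
            wave = design_wave(cond)
            design = make_cube(edge=1.5)
            coeffs = ForceCoefficients()
            try:
                h = size_slab(
                    design, wave, cond, coeffs, resolution=0.02, max_height=2.0
                )
            except SlabInfeasibleError as err:
                assert err.limiting_mode in ("sliding", "overturning")
                continue
            passing = stability_check(
                design.model_copy(update={"slab_height": h}), wave, cond, coeffs
            )
            assert passing.sliding_sf >= 1.2
            assert passing.overturning_sf >= 1.2
            if h > 0:
                exercised += 1
                failing = stability_check(
                    design.model_copy(update={"slab_height": h - 0.02}),
                    wave,
                    cond,
                    coeffs,
                )
                assert (
                    failing.sliding_sf < 1.2 or failing.overturning_sf < 1.2
                )
        assert exercised >= 1  # at least one sea state genuinely needs ballast

    def test_required_height_non_increasing_in_mass(self):
        """Heavier units need less (never more) ballast; an infeasible
        case counts as an unbounded requirement."""
        cond = SEA_STATES[1]
        wave = design_wave(cond)
        heights = []
        for mass in (6.5, 7.5, 8.5, 10.0, 14.0):
            design = make_cube(edge=1.5).model_copy(
                update={"mass_tonnes": mass}
            )
            try:
                heights.append(
                    size_slab(design, wave, cond, resolution=0.02, max_height=2.5)
                )
            except SlabInfeasibleError:
                heights.append(math.inf)
        assert all(a >= b for a, b in zip(heights, heights[1:]))
        assert any(0 < h < math.inf for h in heights)

    def test_relaxed_targets_never_need_more_slab(self):
        cond = SEA_STATES[1]
        wave = design_wave(cond)
        design = make_cube(edge=1.5)
        strict = size_slab(
            design, wave, cond, target_sliding=1.3, target_overturning=1.3,
            resolution=0.02, max_height=2.5,
        )
        relaxed = size_slab(
            design, wave, cond, target_sliding=0.65, target_overturning=0.65,
            resolution=0.02, max_height=2.5,
        )
        assert relaxed <= strict

    def test_infeasible_case_names_limiting_mode(self):
        design = make_cube(edge=1.5)
        cond = WaveConditions(hs=8.0, tp=14.0, depth=10.0)
        with pytest.raises(SlabInfeasibleError) as err:
            size_slab(design, design_wave(cond), cond, resolution=0.1,
                      max_height=1.0)
        assert err.value.limiting_mode in ("sliding", "overturning")
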