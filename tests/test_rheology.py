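"""Dual-trap microrheology: calibration, step relaxation, tension,
lock-in, stiffness inversion, shear modulus and the Maxwell fit."""

import numpy as np
import pandas as pd
import pytest

from condmech import rheology, synth
from condmech.rheology import (
    TrapCalibration,
    TensionEstimate,
    calibrate_trap_stiffness,
    contact_polynomial,
    droplet_spring_constant,
    fit_maxwell,
    fit_step_relaxation,
    lockin_amplitude,
    maxwell_modulus,
    resting_stiffness_and_tension,
    shear_modulus,
    system_spring_constant,
    tension_prefactor,
)


# ---------------------------------------------------------------- calibration

class TestTrapCalibration:
    def test_exact_line_recovers_slope(self):
        x = np.linspace(-0.1, 0.1, 21)
        k, r2, degen = calibrate_trap_stiffness(x, 50.0 * x)
        assert k == pytest.approx(50.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)
        assert not degen

    def test_cubic_profile_matches_normal_equations(self):
        # OLS slope on the windowed points, checked against the closed-form
        # normal equations computed independently
        x = np.linspace(-0.1, 0.1, 21)
        f = 50.0 * x + 200.0 * x**3
        k, r2, _ = calibrate_trap_stiffness(x, f, window_um=0.1)
        xc = x - x.mean()
        slope_hand = np.sum(xc * (f - f.mean())) / np.sum(xc**2)
        assert k == pytest.approx(slope_hand, rel=1e-12)
        assert r2 < 1.0

    def test_all_zero_forces_reports_degenerate(self):
        x = np.linspace(-0.1, 0.1, 21)
        k, r2, degen = calibrate_trap_stiffness(x, np.zeros_like(x))
        assert k == 0.0
        assert degen

    def test_too_few_points_refused(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            calibrate_trap_stiffness(np.array([-1.0, 1.0]), np.array([0.0, 0.0]))


# ----------------------------------------------------------- step relaxation

class TestStepRelaxation:
    def test_noiseless_fit_recovers_parameters(self, material, traps):
        t, f1, f2, onsets = synth.simulate_step_relaxation(
            material, traps, 1.0, 3.0, -1.0, -3.0, tau=0.5)
        fit = fit_step_relaxation(t, f1, f2, onsets)
        assert fit.f0[0] == pytest.approx(1.0, rel=1e-9)
        assert fit.fp[0] == pytest.approx(3.0, rel=1e-9)
        assert fit.tau[0] == pytest.approx(0.5, rel=1e-9)
        assert fit.f0[1] == pytest.approx(-1.0, rel=1e-9)

    def test_trace_value_at_tau_matches_hand_evaluation(self, material, traps):
        # F0=1, Fp=3, tau=0.5 -> F(0.5 s) = 1 + 2 e^-1 = 1.7358 pN
        t, f1, _, _ = synth.simulate_step_relaxation(
            material, traps, 1.0, 3.0, -1.0, -3.0, tau=0.5, n_steps=1)
        i = np.argmin(np.abs(t - 0.5))
        assert f1[i] == pytest.approx(1.0 + 2.0 * np.exp(-1.0), abs=1e-6)

    def test_constant_trace_flagged_degenerate(self, material, traps):
        t, f1, f2, onsets = synth.simulate_step_relaxation(
            material, traps, 2.0, 2.0, -2.0, -2.0, tau=0.5)
        fit = fit_step_relaxation(t, f1, f2, onsets)
        assert fit.degenerate == (True, True)
        assert fit.fp[0] == fit.f0[0]
        assert np.isnan(fit.tau[0])

    def test_nonpositive_tau_refused(self, material, traps):
        with pytest.raises(ValueError, match="tau"):
            synth.simulate_step_relaxation(material, traps, 1, 3, -1, -3, tau=0.0)

    def test_noisy_tau_recovery_median_within_one_percent(self, material):
        taus = []
        for seed in range(100):
            tr = synth.TrapTruth(noise_sd_force=0.02, seed=seed)  # 1% of step
            t, f1, f2, onsets = synth.simulate_step_relaxation(
                material, tr, 1.0, 3.0, -1.0, -3.0, tau=0.5)
            taus.append(fit_step_relaxation(t, f1, f2, onsets).tau[0])
        assert np.median(taus) == pytest.approx(0.5, rel=0.01)


# --------------------------------------------------------- resting stiffness

class TestRestingStiffnessAndTension:
    CAL = TrapCalibration(k1=50.0, k2=50.0)

    def _fit(self, f0_1, f0_2):
        from condmech.rheology import StepRelaxationFit
        return StepRelaxationFit(f0=(f0_1, f0_2), fp=(f0_1, f0_2),
                                 tau=(0.5, 0.5))

    def test_worked_value(self):
        # A=0.1 um, k=50, F0 = +/-1 pN, theta0=0.5:
        # Delta_x0 = 0.14 um, chi0 = 7.1429 pN/um, gamma = 3.1220 pN/um
        est = resting_stiffness_and_tension(self._fit(1.0, -1.0), self.CAL,
                                            0.1, 0.5)
        assert est.delta_x0_um == pytest.approx(0.14, abs=1e-12)
        assert est.chi0_pn_um == pytest.approx(7.1429, abs=1e-4)
        assert est.gamma_pn_um == pytest.approx(3.1220, abs=1e-4)

    def test_unloaded_droplet(self):
        est = resting_stiffness_and_tension(self._fit(0.0, 0.0), self.CAL,
                                            0.1, 0.5)
        assert est.delta_x0_um == pytest.approx(0.1)
        assert est.chi0_pn_um == 0.0
        assert est.gamma_pn_um == 0.0

    def test_theta0_near_one_limit(self):
        # -ln(1) = 0, so gamma -> 0.68 chi0 / pi
        est = resting_stiffness_and_tension(self._fit(1.0, -1.0), self.CAL,
                                            0.1, 1.0 - 1e-12)
        assert est.gamma_pn_um == pytest.approx(0.68 * est.chi0_pn_um / np.pi,
                                                rel=1e-9)

    def test_nonphysical_geometry_refused(self):
        with pytest.raises(ValueError, match="non-physical"):
            resting_stiffness_and_tension(self._fit(-10.0, 10.0), self.CAL,
                                          0.1, 0.5)


# -------------------------------------------------------------------- lock-in

class TestLockin:
    def test_pure_tone_amplitude(self):
        fs, f0 = 5000.0, 4.0
        t = np.arange(int(10 * fs / f0)) / fs  # 10 cycles
        amp = lockin_amplitude(3.0 * np.sin(2 * np.pi * f0 * t), t, f0)
        assert abs(amp) == pytest.approx(3.0, rel=1e-9)

    def test_zero_signal_gives_zero(self):
        t = np.arange(5000) / 5000.0
        assert abs(lockin_amplitude(np.zeros_like(t), t, 4.0)) < 1e-12

    def test_noisy_amplitude_unbiased(self, rng):
        fs, f0, n = 5000.0, 4.0, int(10 * 5000 / 4)
        t = np.arange(n) / fs
        clean = 3.0 * np.sin(2 * np.pi * f0 * t)
        amps = [abs(lockin_amplitude(clean + 0.3 * rng.standard_normal(n), t, f0))
                for _ in range(100)]
        assert np.median(amps) == pytest.approx(3.0, rel=0.01)

    def test_zero_drive_gives_near_zero_lockin(self, material):
        tr = synth.TrapTruth(step_amplitude_A=0.0, noise_sd_force=0.1, seed=3)
        sweep = synth.simulate_dual_trap_sweep(material, tr)
        amps = rheology.lockin_spectrum(sweep)
        assert np.all(np.abs(amps["x_sys"]) < 1e-12)
        assert np.all(np.abs(amps["F1"]) < 0.05)  # noise floor only


# ------------------------------------------------------- stiffness inversion

class TestSpringConstants:
    def test_system_spring_constant_direct(self):
        amps = pd.DataFrame({"F1": [5.0 + 0j], "F2": [-5.0 + 0j],
                             "x_sys": [1.0 + 0j]}, index=[4.0])
        out = system_spring_constant(amps)
        assert out["chi_sys"].iloc[0] == pytest.approx(5.0)

    def test_equal_forces_give_zero(self):
        amps = pd.DataFrame({"F1": [2.0 + 0j], "F2": [2.0 + 0j],
                             "x_sys": [1.0 + 0j]}, index=[4.0])
        assert system_spring_constant(amps)["chi_sys"].iloc[0] == 0.0

    def test_zero_drive_frequency_dropped(self):
        amps = pd.DataFrame({"F1": [1 + 0j, 2 + 0j], "F2": [-1 + 0j, -2 + 0j],
                             "x_sys": [0j, 1.0 + 0j]}, index=[2.0, 4.0])
        out = system_spring_constant(amps)
        assert list(out.index) == [4.0]
        assert out.attrs["dropped_frequencies"] == [2.0]

    def test_droplet_spring_constant_zero_drag(self):
        # xi=0, k1=k2=50, chi_sys=5 -> chi = 5/(1 - 5*100/2500) = 6.25
        cal = TrapCalibration(k1=50.0, k2=50.0)
        chi, flagged = droplet_spring_constant(
            np.array([5.0 + 0j]), np.array([4.0]), cal, xi_pn_s_um=0.0)
        assert chi[0] == pytest.approx(6.25)
        assert not flagged[0]

    def test_zero_chi_sys_maps_to_zero(self):
        cal = TrapCalibration(k1=50.0, k2=50.0)
        chi, _ = droplet_spring_constant(np.array([0j]), np.array([4.0]),
                                         cal, 0.01)
        assert chi[0] == 0.0

    def test_stiff_trap_limit_first_order(self):
        # relative deviation ~ |chi|(1/k1 + 1/k2): halves when k doubles
        chi_sys = np.array([5.0 + 0j])
        f = np.array([4.0])
        devs = []
        for ratio in (200.0, 400.0):
            cal = TrapCalibration(k1=5.0 * ratio, k2=5.0 * ratio)
            chi, _ = droplet_spring_constant(chi_sys, f, cal, 0.0)
            devs.append(abs(chi[0] - chi_sys[0]) / abs(chi_sys[0]))
        assert devs[0] == pytest.approx(2.0 / 200.0, rel=0.05)
        assert devs[1] == pytest.approx(devs[0] / 2.0, rel=0.05)


# --------------------------------------------------------------- G* and units

class TestShearModulus:
    TENSION = TensionEstimate(delta_x0_um=0.14, chi0_pn_um=7.14,
                              gamma_pn_um=1.0, theta0=0.5)

    def test_geometry_coefficients_at_half(self):
        assert contact_polynomial(0.5) == pytest.approx(1.8571875, abs=1e-7)
        assert tension_prefactor(0.5) == pytest.approx(2.34, abs=1e-12)

    def test_worked_value(self):
        # chi=6.25, gamma=1, theta0=0.5, R=2.5 -> G* = 3.91/(2.5*1.8571875)
        spec = shear_modulus(np.array([6.25 + 0j]), np.array([4.0]),
                             self.TENSION, radius_um=2.5)
        assert spec.g_star[0].real == pytest.approx(0.8421, abs=1e-4)

    def test_pure_capillarity_gives_zero_modulus(self):
        chi = np.array([tension_prefactor(0.5) * 1.0 + 0j])
        spec = shear_modulus(chi, np.array([4.0]), self.TENSION, 2.5)
        assert spec.g_star[0] == 0.0

    def test_invalid_theta0_refused_with_range(self):
        bad = TensionEstimate(0.14, 7.14, 1.0, theta0=0.001)
        with pytest.raises(ValueError, match="theta0"):
            shear_modulus(np.array([1 + 0j]), np.array([4.0]), bad, 2.5)

    def test_units_resolve_to_pascal(self, material, traps):
        # pN/um / um = Pa end to end: a droplet twice the radius with the
        # same chi (post-tension) must report half the modulus
        t = TensionEstimate(0.14, 7.14, 0.0, 0.5)
        chi = np.array([3.0 + 1.0j])
        f = np.array([4.0])
        g1 = shear_modulus(chi, f, t, radius_um=2.5).g_star[0]
        g2 = shear_modulus(chi, f, t, radius_um=5.0).g_star[0]
        assert g1 == pytest.approx(2.0 * g2)


# ---------------------------------------------------------------- Maxwell fit

def _exact_spectrum(E=2.0, eta=0.1,
                    freqs=(0.5, 1, 2, 4, 8, 16, 32, 64)):
    f = np.asarray(freqs, float)
    g = maxwell_modulus(2 * np.pi * f, E, eta)
    return rheology.ModulusSpectrum(
        frequency_hz=f, chi_sys=np.zeros(f.size, complex),
        chi=np.zeros(f.size, complex), g_star=g, drag_pn_s_um=0.0)


class TestMaxwellFit:
    def test_exact_curves_recover_crossover(self):
        fit = fit_maxwell(_exact_spectrum())
        assert fit.omega_c_hz == pytest.approx(2.0 / (2 * np.pi * 0.1),
                                               rel=1e-6)
        assert np.max(np.abs(fit.residuals)) < 1e-6

    def test_crossover_identity_g_prime_equals_g_doubleprime(self):
        fit = fit_maxwell(_exact_spectrum())
        w_c = 2 * np.pi * fit.omega_c_hz  # rad/s
        g = maxwell_modulus(np.array([w_c]), fit.E_pa, fit.eta_pa_s)[0]
        assert g.real == pytest.approx(g.imag, rel=1e-9)
        assert g.real == pytest.approx(fit.E_pa / 2.0, rel=1e-9)

    def test_low_high_frequency_regimes(self):
        fit = fit_maxwell(_exact_spectrum())
        w = 2 * np.pi * np.array([fit.omega_c_hz / 4, fit.omega_c_hz * 4])
        g = maxwell_modulus(w, fit.E_pa, fit.eta_pa_s)
        assert g[0].imag > g[0].real  # below crossover the droplet flows
        assert g[1].real > g[1].imag  # above it, stress is transmitted

    def test_noisy_spectra_recover_crossover(self, rng):
        omegas = []
        for _ in range(20):
            spec = _exact_spectrum()
            noisy = spec.g_star * (
                1 + 0.05 * rng.standard_normal(spec.g_star.size)
                + 0.05j * rng.standard_normal(spec.g_star.size))
            spec = rheology.ModulusSpectrum(
                frequency_hz=spec.frequency_hz, chi_sys=spec.chi_sys,
                chi=spec.chi, g_star=noisy, drag_pn_s_um=0.0)
            omegas.append(fit_maxwell(spec).omega_c_hz)
        truth = 2.0 / (2 * np.pi * 0.1)
        assert np.median(omegas) == pytest.approx(truth, rel=0.10)

    def test_too_few_frequencies_refused(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_maxwell(_exact_spectrum(freqs=(1, 2, 4)))

    def test_crossover_outside_band_flagged(self):
        fit = fit_maxwell(_exact_spectrum(E=2.0, eta=10.0))  # f_c ~ 0.03 Hz
        assert fit.extrapolated


# ------------------------------------------------------------ full-chain

class TestFullChain:
    def test_round_trip_recovers_material(self, material, traps):
        sweep = synth.simulate_dual_trap_sweep(material, traps)
        cal = TrapCalibration(k1=traps.k1, k2=traps.k2)
        tension = TensionEstimate(
            0.14, 7.14, material.surface_tension_gamma,
            material.contact_parameter_theta0)
        _, fit = rheology.analyze_sweep(sweep, cal, tension)
        assert fit.E_pa == pytest.approx(material.plateau_modulus_E, rel=1e-3)
        assert fit.eta_pa_s == pytest.approx(material.dashpot_viscosity,
                                             rel=1e-3)
        assert fit.omega_c_hz == pytest.approx(material.crossover_hz, rel=1e-3)

    def test_round_trip_recovers_gamma_through_steps(self, material, traps):
        f0_1, f0_2 = synth.consistent_step_forces(material, traps)
        t, f1, f2, onsets = synth.simulate_step_relaxation(
            material, traps, f0_1, f0_1 + 1, f0_2, f0_2 - 1, tau=0.5)
        cal = TrapCalibration(k1=traps.k1, k2=traps.k2)
        fit = fit_step_relaxation(t, f1, f2, onsets)
        est = resting_stiffness_and_tension(
            fit, cal, traps.amplitude_um, material.contact_parameter_theta0)
        assert est.gamma_pn_um == pytest.approx(
            material.surface_tension_gamma, rel=1e-6)
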