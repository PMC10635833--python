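"""Dual-trap active microrheology of protein droplets.

A droplet is held between two optically trapped microspheres (trap
stiffnesses ``k1``, ``k2``); trap 1 applies sinusoidal indentations at a
ladder of frequencies while trap 2 clamps the droplet and records the
transmitted force.  The analysis chain converts the recorded force pair
into, successively:

1. per-frequency complex force/position amplitudes (single-bin lock-in),
2. the coupled system spring constant  chi*_sys = (F1~ - F2~) / (2 x~_sys),
3. the droplet spring constant chi*(w), correcting for finite trap
   stiffness and the viscous drag xi = 3*pi*eta_medium*D of the droplet,
4. the complex shear modulus G*(w) after removing the capillary
   (surface-tension) contribution parameterized by the contact parameter
   theta0,
5. a Maxwell-element fit (spring E in series with dashpot eta) yielding
   the crossover frequency  omega_c = E / (2*pi*eta)  in Hz.

A separate step-indentation protocol yields force-relaxation traces
F(t) = F0 + (Fp - F0) exp(-t/tau) from which the resting droplet spring
constant chi0 and surface tension gamma are estimated.

Unit conventions: forces in pN, lengths in um, stiffness in pN/um, time
in s, moduli in Pa (pN/um divided by um gives pN/um^2 = Pa).  Drive
frequencies are quoted in Hz; every product ``xi*omega`` and the Maxwell
relaxation use angular frequency omega = 2*pi*f.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "TrapCalibration",
    "ForceSweep",
    "StepRelaxationFit",
    "TensionEstimate",
    "ModulusSpectrum",
    "MaxwellFit",
    "calibrate_trap_stiffness",
    "fit_step_relaxation",
    "resting_stiffness_and_tension",
    "lockin_spectrum",
    "system_spring_constant",
    "droplet_spring_constant",
    "shear_modulus",
    "fit_maxwell",
    "analyze_sweep",
    "maxwell_modulus",
    "contact_polynomial",
    "tension_prefactor",
    "droplet_drag",
]


# --------------------------------------------------------------------------
# geometry helpers (capillary correction of the droplet spring constant)
# --------------------------------------------------------------------------

def contact_polynomial(theta0: float) -> float:
    """Geometric polynomial relating chi* to G*R for contact parameter theta0."""
    t = theta0
    return (5.47 * t**5 - 29.28 * t**4 + 23.29 * t**3
            - 5.08 * t**2 + 3.79 * t - 0.02)


def tension_prefactor(theta0: float) -> float:
    """Coefficient of the surface-tension term in the droplet stiffness."""
    return 1.25 + 4.36 * theta0**2


def droplet_drag(medium_viscosity_pa_s: float, diameter_um: float) -> float:
    """Viscous drag xi = 3*pi*eta*D of the droplet, in pN*s/um.

    1 Pa*s * 1 um = 1e-6 N*s/m^2 * m = ... the mixed unit system
    (pN, um, s) makes Pa*s * um = pN*s/um numerically, so no conversion
    factor is needed.
    """
    return 3.0 * np.pi * medium_viscosity_pa_s * diameter_um


def maxwell_modulus(omega_rad_s: np.ndarray, E: float, eta: float) -> np.ndarray:
    """Complex shear modulus of a Maxwell element (spring E in series with
    dashpot eta):  G*(w) = i*w*tau*E / (1 + i*w*tau),  tau = eta/E."""
    tau = eta / E
    iwt = 1j * np.asarray(omega_rad_s) * tau
    return E * iwt / (1.0 + iwt)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class TrapCalibration:
    """Linear trap stiffnesses from force-vs-displacement profiles."""

    k1: float  # pN/um
    k2: float  # pN/um
    fit_window_um: float = 0.1
    r_squared: tuple[float, float] = (np.nan, np.nan)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and (self.k1 <= 0 or self.k2 <= 0):
            raise ValueError("trap stiffnesses must be positive")


@dataclass
class ForceSweep:
    """One droplet's sinusoidal frequency sweep.

    ``data`` columns: time_s, x_trap1_um, f1_pN, f2_pN, segment.
    Each segment holds an integer number of cycles of one drive frequency.
    """

    data: pd.DataFrame
    drive_frequencies_hz: np.ndarray
    drive_amplitude_um: float
    sampling_rate_hz: float
    droplet_diameter_um: float
    medium_viscosity_pa_s: float = 1e-3
    meta: dict = field(default_factory=dict)

    REQUIRED_COLUMNS = ("time_s", "x_trap1_um", "f1_pN", "f2_pN", "segment")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ForceSweep table missing columns: {missing}")
        self.drive_frequencies_hz = np.asarray(self.drive_frequencies_hz, float)

    @property
    def drag_pn_s_um(self) -> float:
        return droplet_drag(self.medium_viscosity_pa_s, self.droplet_diameter_um)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def to_hdf5(self, path, group: str = "droplet") -> None:
        import h5py

        with h5py.File(path, "a") as h5:
            g = h5.require_group(group)
            for col in self.REQUIRED_COLUMNS:
                if col in g:
                    del g[col]
                g.create_dataset(col, data=self.data[col].to_numpy())
            g.attrs["drive_frequencies_hz"] = self.drive_frequencies_hz
            g.attrs["drive_amplitude_um"] = self.drive_amplitude_um
            g.attrs["sampling_rate_hz"] = self.sampling_rate_hz
            g.attrs["droplet_diameter_um"] = self.droplet_diameter_um
            g.attrs["medium_viscosity_pa_s"] = self.medium_viscosity_pa_s

    @classmethod
    def from_hdf5(cls, path, group: str = "droplet") -> "ForceSweep":
        import h5py

        with h5py.File(path, "r") as h5:
            g = h5[group]
            data = pd.DataFrame({c: g[c][()] for c in cls.REQUIRED_COLUMNS})
            return cls(
                data=data,
                drive_frequencies_hz=np.asarray(g.attrs["drive_frequencies_hz"]),
                drive_amplitude_um=float(g.attrs["drive_amplitude_um"]),
                sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                droplet_diameter_um=float(g.attrs["droplet_diameter_um"]),
                medium_viscosity_pa_s=float(g.attrs["medium_viscosity_pa_s"]),
            )


@dataclass
class StepRelaxationFit:
    """Per-trap exponential relaxation parameters F0 + (Fp - F0) e^{-t/tau}."""

    f0: tuple[float, float]   # resting force per trap, pN
    fp: tuple[float, float]   # peak force per trap, pN
    tau: tuple[float, float]  # relaxation time per trap, s
    covariance: tuple[np.ndarray | None, np.ndarray | None] = (None, None)
    degenerate: tuple[bool, bool] = (False, False)


@dataclass
class TensionEstimate:
    """Resting stiffness and surface tension of a trapped droplet."""

    delta_x0_um: float
    chi0_pn_um: float
    gamma_pn_um: float
    theta0: float


@dataclass
class ModulusSpectrum:
    """Frequency-resolved complex stiffness and shear modulus."""

    frequency_hz: np.ndarray
    chi_sys: np.ndarray        # complex, pN/um
    chi: np.ndarray            # complex, pN/um
    g_star: np.ndarray         # complex, Pa
    drag_pn_s_um: float
    dropped: np.ndarray | None = None  # frequencies dropped as unrecoverable

    @property
    def g_prime(self) -> np.ndarray:
        return self.g_star.real

    @property
    def g_double_prime(self) -> np.ndarray:
        return self.g_star.imag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "f_Hz": self.frequency_hz,
            "G_prime_Pa": self.g_prime,
            "G_doubleprime_Pa": self.g_double_prime,
        })


@dataclass
class MaxwellFit:
    """Maxwell-element fit of a modulus spectrum."""

    E_pa: float
    eta_pa_s: float
    omega_c_hz: float
    omega_c_ci95: tuple[float, float]
    tau_char_s: float
    residuals: np.ndarray
    extrapolated: bool = False

    def __post_init__(self) -> None:
        # crossover identity of the Maxwell element
        assert np.isclose(self.omega_c_hz,
                          self.E_pa / (2.0 * np.pi * self.eta_pa_s),
                          rtol=1e-12)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def calibrate_trap_stiffness(
    displacement_um: np.ndarray,
    force_pn: np.ndarray,
    window_um: float = 0.1,
) -> tuple[float, float, bool]:
    """Fit F = k*x over the linear window |x| <= window_um.

    Returns ``(k, r_squared, degenerate)``; a constant-zero profile gives
    k = 0 with the degenerate flag raised instead of an error.
    """
    x = np.asarray(displacement_um, float)
    f = np.asarray(force_pn, float)
    sel = np.abs(x) <= window_um
    if sel.sum() < 3:
        raise ValueError(
            f"fewer than 3 points inside calibration window +/-{window_um} um")
    x, f = x[sel], f[sel]
    # OLS line with intercept; slope is the stiffness
    A = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(A, f, rcond=None)
    k = float(coef[0])
    pred = A @ coef
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot == 0.0:
        return k, np.nan, True
    r2 = 1.0 - float(np.sum((f - pred) ** 2)) / ss_tot
    return k, r2, False


def _fit_one_relaxation(
    t: np.ndarray, f: np.ndarray
) -> tuple[float, float, float, np.ndarray | None, bool]:
    """Fit F0 + (Fp - F0) e^{-t/tau} to one aligned relaxation trace."""
    f = np.asarray(f, float)
    t = np.asarray(t, float)
    if t.size < 10:
        raise ValueError("relaxation segment needs >= 10 samples")
    if np.ptp(f) == 0.0 or np.allclose(f, f[0], rtol=0, atol=1e-12 * max(1, abs(f[0]))):
        # constant trace: Fp = F0, tau unidentifiable
        return float(f[0]), float(f[0]), np.nan, None, True

    model = lmfit.Model(lambda t, f0, fp, tau: f0 + (fp - f0) * np.exp(-t / tau))
    span = t[-1] - t[0]
    params = model.make_params(
        f0=f[-1], fp=f[0],
        tau=dict(value=max(span / 5.0, 1e-6), min=1e-12),
    )
    res = model.fit(f, params, t=t)
    if not res.success:
        raise RuntimeError(
            f"step-relaxation fit failed to converge; initial guess "
            f"(f0={f[-1]}, fp={f[0]}); residual norm "
            f"{np.linalg.norm(res.residual):.3g}")
    cov = res.covar
    return (float(res.params["f0"].value), float(res.params["fp"].value),
            float(res.params["tau"].value), cov, False)


def fit_step_relaxation(
    time_s: np.ndarray,
    force1_pn: np.ndarray,
    force2_pn: np.ndarray,
    step_onsets_s: np.ndarray | list[float],
) -> StepRelaxationFit:
    """Exponential relaxation fit per trap, averaging aligned step segments.

    Segments start at each onset and end at the next onset (or the trace
    end); they are aligned to the onset and averaged sample-wise before a
    single fit per trap.
    """
    t = np.asarray(time_s, float)
    onsets = np.sort(np.asarray(step_onsets_s, float))
    if onsets.size == 0:
        raise ValueError("need at least one step onset")

    bounds = list(onsets) + [t[-1] + (t[1] - t[0] if t.size > 1 else 0.0)]
    results = []
    for f in (np.asarray(force1_pn, float), np.asarray(force2_pn, float)):
        segs = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            sel = (t >= a) & (t < b)
            if sel.sum() >= 10:
                segs.append((t[sel] - a, f[sel]))
        if not segs:
            raise ValueError("no relaxation segment with >= 10 samples")
        n = min(s[1].size for s in segs)
        t_al = segs[0][0][:n]
        f_avg = np.mean([s[1][:n] for s in segs], axis=0)
        results.append(_fit_one_relaxation(t_al, f_avg))

    (f0a, fpa, taua, cova, dega), (f0b, fpb, taub, covb, degb) = results
    return StepRelaxationFit(
        f0=(f0a, f0b), fp=(fpa, fpb), tau=(taua, taub),
        covariance=(cova, covb), degenerate=(dega, degb),
    )


def resting_stiffness_and_tension(
    fit: StepRelaxationFit,
    cal: TrapCalibration,
    step_amplitude_um: float,
    theta0: float,
) -> TensionEstimate:
    """Resting droplet spring constant and surface tension from step fits.

    Delta_x0 = A + F0(1)/k1 - F0(2)/k2
    chi0     = (F0(1) - F0(2)) / (2 Delta_x0)
    gamma    = (chi0/pi) (-ln theta0 + 0.68)
    """
    if step_amplitude_um <= 0:
        raise ValueError("step amplitude must be positive")
    if not (0.0 < theta0 < 1.0):
        raise ValueError("theta0 must lie in (0, 1)")
    f0_1, f0_2 = fit.f0
    delta_x0 = step_amplitude_um + f0_1 / cal.k1 - f0_2 / cal.k2
    if delta_x0 <= 0:
        raise ValueError(
            f"non-physical geometry: Delta_x0 = {delta_x0:.4g} um <= 0")
    chi0 = (f0_1 - f0_2) / (2.0 * delta_x0)
    gamma = (chi0 / np.pi) * (-np.log(theta0) + 0.68)
    return TensionEstimate(delta_x0_um=float(delta_x0), chi0_pn_um=float(chi0),
                           gamma_pn_um=float(gamma), theta0=theta0)


def lockin_amplitude(
    signal: np.ndarray, time_s: np.ndarray, frequency_hz: float
) -> complex:
    """Single-bin discrete Fourier projection at one frequency.

    Returns the complex amplitude ``S = X + iY`` such that, for a signal
    ``X sin(wt) + Y cos(wt)`` spanning an integer number of cycles, the
    projection is exact.  Phase is relative to a sine at the segment's own
    time origin.
    """
    t = np.asarray(time_s, float)
    s = np.asarray(signal, float)
    w = 2.0 * np.pi * frequency_hz
    tt = t - t[0]
    n = s.size
    x = 2.0 / n * np.sum(s * np.sin(w * tt))
    y = 2.0 / n * np.sum(s * np.cos(w * tt))
    return complex(x, y)


def lockin_spectrum(sweep: ForceSweep) -> pd.DataFrame:
    """Per-frequency complex amplitudes of F1, F2 and x_sys.

    The system coordinate is x_sys = x_trap2 - x_trap1; trap 2 is held
    fixed, so x~_sys = -x~_trap1 from the commanded trajectory.
    Returns a DataFrame indexed by drive frequency with complex columns
    ``F1``, ``F2``, ``x_sys``.
    """
    df = sweep.data
    rows = []
    for i, f_hz in enumerate(sweep.drive_frequencies_hz):
        seg = df[df["segment"] == i]
        n = len(seg)
        if n < 2 or f_hz * n / sweep.sampling_rate_hz < 1.0:
            raise ValueError(
                f"drive frequency {f_hz} Hz not resolvable in a segment of "
                f"{n} samples at {sweep.sampling_rate_hz} Hz")
        t = seg["time_s"].to_numpy()
        f1 = lockin_amplitude(seg["f1_pN"].to_numpy(), t, f_hz)
        f2 = lockin_amplitude(seg["f2_pN"].to_numpy(), t, f_hz)
        x1 = lockin_amplitude(seg["x_trap1_um"].to_numpy(), t, f_hz)
        rows.append({"f_Hz": f_hz, "F1": f1, "F2": f2, "x_sys": -x1})
    return pd.DataFrame(rows).set_index("f_Hz")


def system_spring_constant(amps: pd.DataFrame, min_drive_um: float = 1e-12
                           ) -> pd.DataFrame:
    """Coupled system spring constant chi*_sys = (F1~ - F2~)/(2 x~_sys).

    Frequencies with vanishing drive amplitude are dropped with a warning
    flag in the returned frame's attrs.
    """
    drive = np.abs(amps["x_sys"].to_numpy())
    ok = drive > min_drive_um
    out = amps.loc[ok].copy()
    out["chi_sys"] = (out["F1"] - out["F2"]) / (2.0 * out["x_sys"])
    out.attrs["dropped_frequencies"] = list(amps.index[~ok])
    return out


def droplet_spring_constant(
    chi_sys: np.ndarray,
    frequency_hz: np.ndarray,
    cal: TrapCalibration,
    xi_pn_s_um: float,
    denom_tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Droplet spring constant chi*(w), correcting for trap stiffness and drag.

    chi* = chi_sys [4 k1 k2 + i xi w (k1 + k2)]
           / (2 k1 (2 k2 + i xi w) - 4 chi_sys (k1 + k2 + i xi w))

    with w = 2*pi*f in rad/s.  Returns (chi, flagged) where ``flagged``
    marks frequencies whose denominator was within tolerance of zero.
    """
    k1, k2 = cal.k1, cal.k2
    w = 2.0 * np.pi * np.asarray(frequency_hz, float)
    cs = np.asarray(chi_sys, complex)
    num = cs * (4.0 * k1 * k2 + 1j * xi_pn_s_um * w * (k1 + k2))
    den = (2.0 * k1 * (2.0 * k2 + 1j * xi_pn_s_um * w)
           - 4.0 * cs * (k1 + k2 + 1j * xi_pn_s_um * w))
    scale = 4.0 * k1 * k2
    flagged = np.abs(den) <= denom_tol * scale
    chi = np.where(flagged, np.nan + 0j, num / np.where(flagged, 1.0, den))
    return chi, flagged


def shear_modulus(
    chi: np.ndarray,
    frequency_hz: np.ndarray,
    tension: TensionEstimate,
    radius_um: float,
    *,
    chi_sys: np.ndarray | None = None,
    drag_pn_s_um: float = 0.0,
) -> ModulusSpectrum:
    """Complex shear modulus from the droplet spring constant.

    G*(w) = [chi*(w) - (1.25 + 4.36 theta0^2) gamma]
            / [R * P(theta0)]

    with P the contact polynomial.  Raises if P(theta0) <= 0, reporting
    the validity range of theta0.
    """
    if radius_um <= 0:
        raise ValueError("droplet radius must be positive")
    theta0 = tension.theta0
    poly = contact_polynomial(theta0)
    if poly <= 0:
        raise ValueError(
            f"contact polynomial non-positive at theta0={theta0:.3g}; "
            "theta0 must lie where 5.47t^5-29.28t^4+23.29t^3-5.08t^2"
            "+3.79t-0.02 > 0 (roughly theta0 > 0.0053 within (0,1))")
    chi = np.asarray(chi, complex)
    g = (chi - tension_prefactor(theta0) * tension.gamma_pn_um) / (radius_um * poly)
    f = np.asarray(frequency_hz, float)
    order = np.argsort(f)
    return ModulusSpectrum(
        frequency_hz=f[order],
        chi_sys=(np.asarray(chi_sys, complex)[order]
                 if chi_sys is not None else np.full(f.size, np.nan + 0j)),
        chi=chi[order],
        g_star=g[order],
        drag_pn_s_um=drag_pn_s_um,
    )


def fit_maxwell(spectrum: ModulusSpectrum) -> MaxwellFit:
    """Joint fit of G', G'' to a Maxwell element with relative weighting.

    G'(w)  = E (w tau)^2 / (1 + (w tau)^2)
    G''(w) = E  w tau    / (1 + (w tau)^2),   tau = eta/E, w in rad/s.

    Residuals are relative (each modulus divided by its magnitude), since
    the moduli span decades across the sweep.  The 95% CI of
    omega_c = E/(2 pi eta) follows by first-order propagation from the
    (E, eta) covariance.
    """
    f = spectrum.frequency_hz
    if f.size < 4:
        raise ValueError("need >= 4 frequencies to fit the Maxwell element")
    w = 2.0 * np.pi * f
    gp = spectrum.g_prime
    gpp = spectrum.g_double_prime

    def residual(params):
        g = maxwell_modulus(w, params["E"].value, params["eta"].value)
        # relative residuals, floored to avoid division blow-up at ~0 moduli
        scale_p = np.maximum(np.abs(gp), 1e-12 * max(np.abs(gp).max(), 1e-30))
        scale_pp = np.maximum(np.abs(gpp), 1e-12 * max(np.abs(gpp).max(), 1e-30))
        return np.concatenate([(g.real - gp) / scale_p,
                               (g.imag - gpp) / scale_pp])

    # initial guesses: E from the high-frequency plateau of G',
    # crossover near the frequency where G' = G''
    e0 = max(float(np.abs(gp[-1])), 1e-9)
    cross = np.argmin(np.abs(gp - gpp))
    tau0 = 1.0 / max(w[cross], 1e-9)
    params = lmfit.Parameters()
    params.add("E", value=e0, min=1e-12)
    params.add("eta", value=e0 * tau0, min=1e-15)
    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError("Maxwell fit did not converge")

    E = float(out.params["E"].value)
    eta = float(out.params["eta"].value)
    omega_c = E / (2.0 * np.pi * eta)

    # first-order propagation of var(omega_c) from (E, eta) covariance
    ci = (np.nan, np.nan)
    if out.covar is not None and out.covar.shape == (2, 2):
        dE = 1.0 / (2.0 * np.pi * eta)
        deta = -E / (2.0 * np.pi * eta**2)
        grad = np.array([dE, deta])
        var = float(grad @ out.covar @ grad)
        if var >= 0:
            half = 1.959963984540054 * np.sqrt(var)
            ci = (omega_c - half, omega_c + half)

    extrapolated = not (f.min() <= omega_c <= f.max())
    return MaxwellFit(
        E_pa=E, eta_pa_s=eta, omega_c_hz=omega_c, omega_c_ci95=ci,
        tau_char_s=1.0 / omega_c, residuals=np.asarray(out.residual),
        extrapolated=extrapolated,
    )


def analyze_sweep(
    sweep: ForceSweep,
    cal: TrapCalibration,
    tension: TensionEstimate,
) -> tuple[ModulusSpectrum, MaxwellFit]:
    """Full chain: lock-in -> chi*_sys -> chi* -> G* -> Maxwell fit."""
    amps = lockin_spectrum(sweep)
    sys_df = system_spring_constant(amps)
    xi = sweep.drag_pn_s_um
    f = sys_df.index.to_numpy(float)
    chi, flagged = droplet_spring_constant(
        sys_df["chi_sys"].to_numpy(), f, cal, xi)
    keep = ~flagged
    spectrum = shear_modulus(
        chi[keep], f[keep], tension,
        radius_um=sweep.droplet_diameter_um / 2.0,
        chi_sys=sys_df["chi_sys"].to_numpy()[keep],
        drag_pn_s_um=xi,
    )
    fit = fit_maxwell(spectrum)
    return spectrum, fit
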