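"""Forward model of the dual-trap droplet microrheology experiment.

The droplet is a Maxwell element (spring E in series with dashpot eta)
with surface tension gamma, held between two harmonic traps of stiffness
k1 and k2; the droplet feels a viscous drag xi = 3*pi*eta_medium*D.  The
generator is constructed as the exact algebraic inverse of the analysis
chain: the programmed complex shear modulus is mapped through the
capillary geometry to the droplet spring constant chi*, then through the
trap-coupling relation (solved for chi*_sys), and finally emitted as
force/position time series whose per-frequency lock-in amplitudes satisfy
the forward model exactly before noise.  The split of the differential
force between the two channels is antisymmetric (+/- chi*_sys x~_sys);
the analysis only ever uses F1 - F2, so the split is unobservable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from condmech.rheology import (
    ForceSweep,
    contact_polynomial,
    droplet_drag,
    maxwell_modulus,
    tension_prefactor,
)

__all__ = [
    "MaterialTruth",
    "TrapTruth",
    "simulate_dual_trap_sweep",
    "simulate_step_relaxation",
    "consistent_step_forces",
]

#: octave ladder of drive frequencies used in the sweep protocol, Hz
DEFAULT_FREQUENCIES_HZ = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


@dataclass
class MaterialTruth:
    """Ground-truth viscoelastic and capillary parameters of one droplet."""

    plateau_modulus_E: float        # Pa
    dashpot_viscosity: float        # Pa*s
    surface_tension_gamma: float    # pN/um
    contact_parameter_theta0: float  # dimensionless, in (0, 1)
    droplet_diameter_D: float = 5.0  # um
    medium_viscosity: float = 1e-3   # Pa*s

    def __post_init__(self) -> None:
        for name in ("plateau_modulus_E", "dashpot_viscosity",
                     "surface_tension_gamma", "droplet_diameter_D",
                     "medium_viscosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.contact_parameter_theta0 < 1.0):
            raise ValueError("contact_parameter_theta0 must lie in (0, 1)")
        if not np.isfinite(self.crossover_hz) or self.crossover_hz <= 0:
            raise ValueError("analytic crossover frequency must be finite "
                             "and positive")

    @property
    def radius_um(self) -> float:
        return self.droplet_diameter_D / 2.0

    @property
    def crossover_hz(self) -> float:
        """Analytic Maxwell crossover f_c = E / (2 pi eta), Hz."""
        return self.plateau_modulus_E / (2.0 * np.pi * self.dashpot_viscosity)

    @property
    def drag_pn_s_um(self) -> float:
        return droplet_drag(self.medium_viscosity, self.droplet_diameter_D)


@dataclass
class TrapTruth:
    """Trap and acquisition parameters for the simulated experiment."""

    k1: float = 50.0                 # pN/um
    k2: float = 50.0                 # pN/um
    sampling_rate: float = 5000.0    # Hz
    step_amplitude_A: float = 100.0  # nm; also the sinusoid amplitude
    drive_frequencies: tuple = DEFAULT_FREQUENCIES_HZ
    cycles_per_frequency: int = 10
    noise_sd_force: float = 0.0      # pN, additive
    noise_relative: float = 0.0      # dimensionless, multiplicative
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("trap stiffnesses must be positive")
        if self.cycles_per_frequency < 4:
            raise ValueError("need >= 4 cycles per frequency")
        fmax = max(self.drive_frequencies)
        if self.sampling_rate < 20.0 * fmax:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz too low for the "
                f"highest drive frequency {fmax} Hz (need >= 20x)")

    @property
    def amplitude_um(self) -> float:
        return self.step_amplitude_A / 1000.0


def programmed_chi_sys(material: MaterialTruth, traps: TrapTruth,
                       frequency_hz: np.ndarray) -> np.ndarray:
    """Complex system spring constant the generator encodes per frequency.

    chi* = G* R P(theta0) + (1.25 + 4.36 theta0^2) gamma, then the
    trap-coupling relation solved for chi*_sys.
    """
    theta0 = material.contact_parameter_theta0
    w = 2.0 * np.pi * np.asarray(frequency_hz, float)
    g = maxwell_modulus(w, material.plateau_modulus_E,
                        material.dashpot_viscosity)
    chi = (g * material.radius_um * contact_polynomial(theta0)
           + tension_prefactor(theta0) * material.surface_tension_gamma)
    k1, k2 = traps.k1, traps.k2
    xi = material.drag_pn_s_um
    return (2.0 * k1 * (2.0 * k2 + 1j * xi * w) * chi
            / (4.0 * k1 * k2 + 1j * xi * w * (k1 + k2)
               + 4.0 * chi * (k1 + k2 + 1j * xi * w)))


def _segment_samples(f_hz: float, fs: float, min_cycles: int) -> tuple[int, int]:
    """Smallest (n_samples, n_cycles) with n_cycles >= min_cycles and the
    drive exactly bin-centred (f * n / fs integer), avoiding leakage."""
    ratio = Fraction(f_hz / fs).limit_denominator(10**6)  # cycles per sample
    q = ratio.denominator  # samples per whole number of cycles
    cycles_per_q = ratio.numerator
    reps = int(np.ceil(min_cycles / cycles_per_q))
    return reps * q, reps * cycles_per_q


def simulate_dual_trap_sweep(material: MaterialTruth,
                             traps: TrapTruth) -> ForceSweep:
    """Simulate one droplet's sinusoidal frequency sweep.

    Trap 1 is driven as x_trap1(t) = A sin(w t) within each frequency
    segment; trap 2 is fixed, so x_sys = -x_trap1.  Forces are split
    antisymmetrically: F1 = +chi*_sys x_sys, F2 = -chi*_sys x_sys (as
    complex amplitudes in the sin/cos basis of the segment).  Gaussian
    force noise (additive sd in pN and/or multiplicative relative sd) is
    added from one seeded generator.
    """
    rng = np.random.default_rng(traps.seed)
    freqs = np.asarray(traps.drive_frequencies, float)
    chi_sys = programmed_chi_sys(material, traps, freqs)
    A = traps.amplitude_um
    fs = traps.sampling_rate

    frames = []
    t0 = 0.0
    for i, f_hz in enumerate(freqs):
        n, _cycles = _segment_samples(f_hz, fs, traps.cycles_per_frequency)
        t_loc = np.arange(n) / fs
        w = 2.0 * np.pi * f_hz
        s, c = np.sin(w * t_loc), np.cos(w * t_loc)
        x1 = A * s
        # complex amplitudes in the (sin, cos) basis
        amp1 = chi_sys[i] * (-A)   # F1~ = +chi_sys * x_sys~, x_sys~ = -A
        f1 = amp1.real * s + amp1.imag * c
        f2 = -f1
        frames.append(pd.DataFrame({
            "time_s": t0 + t_loc,
            "x_trap1_um": x1,
            "f1_pN": f1,
            "f2_pN": f2,
            "segment": i,
        }))
        t0 += n / fs
    data = pd.concat(frames, ignore_index=True)

    for col in ("f1_pN", "f2_pN"):
        v = data[col].to_numpy()
        if traps.noise_relative > 0:
            v = v * (1.0 + traps.noise_relative * rng.standard_normal(v.size))
        if traps.noise_sd_force > 0:
            v = v + traps.noise_sd_force * rng.standard_normal(v.size)
        data[col] = v

    return ForceSweep(
        data=data,
        drive_frequencies_hz=freqs,
        drive_amplitude_um=A,
        sampling_rate_hz=fs,
        droplet_diameter_um=material.droplet_diameter_D,
        medium_viscosity_pa_s=material.medium_viscosity,
        meta={
            "seed": traps.seed,
            "truth": {
                "E_pa": material.plateau_modulus_E,
                "eta_pa_s": material.dashpot_viscosity,
                "gamma_pn_um": material.surface_tension_gamma,
                "theta0": material.contact_parameter_theta0,
                "omega_c_hz": material.crossover_hz,
            },
        },
    )


def consistent_step_forces(material: MaterialTruth, traps: TrapTruth
                           ) -> tuple[float, float]:
    """Antisymmetric resting forces (F0_1, F0_2) consistent with the
    material's surface tension through the resting-stiffness relations.

    chi0 = pi * gamma / (-ln theta0 + 0.68); with F0_2 = -F0_1 the
    geometry gives F0_1 = chi0 A / (1 - chi0 (1/k1 + 1/k2)).
    """
    theta0 = material.contact_parameter_theta0
    chi0 = np.pi * material.surface_tension_gamma / (-np.log(theta0) + 0.68)
    A = traps.amplitude_um
    denom = 1.0 - chi0 * (1.0 / traps.k1 + 1.0 / traps.k2)
    if denom <= 0:
        raise ValueError("traps too soft for the requested resting stiffness")
    f0 = chi0 * A / denom
    return float(f0), float(-f0)


def simulate_step_relaxation(
    material: MaterialTruth,
    traps: TrapTruth,
    f0_1: float,
    fp_1: float,
    f0_2: float,
    fp_2: float,
    tau: float,
    n_steps: int = 5,
    step_period_s: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Step-indentation force relaxation traces for both traps.

    Each step restarts F(t) = F0 + (Fp - F0) exp(-t/tau) at its onset
    (step protocol: 0.2 Hz, i.e. one step every 5 s by default).  Returns
    (time_s, force1_pN, force2_pN, onsets_s).
    """
    if tau <= 0:
        raise ValueError("relaxation time tau must be positive")
    rng = np.random.default_rng(traps.seed)
    fs = traps.sampling_rate
    n_per = int(round(step_period_s * fs))
    t_loc = np.arange(n_per) / fs
    onsets = np.arange(n_steps) * step_period_s
    time = np.concatenate([o + t_loc for o in onsets])

    traces = []
    for f0, fp in ((f0_1, fp_1), (f0_2, fp_2)):
        seg = f0 + (fp - f0) * np.exp(-t_loc / tau)
        trace = np.tile(seg, n_steps).astype(float)
        if traps.noise_sd_force > 0:
            trace = trace + traps.noise_sd_force * rng.standard_normal(trace.size)
        traces.append(trace)
    return time, traces[0], traces[1], onsets
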