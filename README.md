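# condmech

Mechanics and transport analysis of protein condensates probed in living
neurons: dual-optical-trap microrheology of single droplets, FRAP recovery
kinetics, punctum tracking and mobility, and bleedthrough-corrected FRET /
colocalization statistics — plus synthetic-data generators that are exact
algebraic inverses of each analysis, so every stage is validated by
parameter recovery.

## The scientific problem

Membraneless condensates in touch receptor neurons behave like Maxwell
viscoelastic liquids when young and progressively solidify. The material
fingerprint is the complex shear modulus G*(ω) of a micron-scale droplet
held between two optical traps: the frequency where the storage modulus G′
crosses the loss modulus G″ is ω_c = E/(2πη), the inverse of the material's
relaxation time. Getting G* out of trap data requires undoing two
couplings: the finite trap stiffness / medium drag (which mixes the
droplet response χ* into the measured system response χ*_sys) and the
droplet's own surface tension γ (which adds a capillary stiffness on top
of the bulk modulus). Companion measurements — FRAP mobile fractions,
punctum mobility along the neurite, FRET tension sensors — track the same
liquid-to-solid transition from different angles. The original recordings
are not publicly deposited, so this package ships generators with known
ground truth instead of fixtures, and proves the analysis by round trip.

## Worked example: one droplet, full rheology chain

```python
from condmech import rheology, synth

material = synth.MaterialTruth(
    plateau_modulus_E=2.0, dashpot_viscosity=0.1,
    surface_tension_gamma=1.0, contact_parameter_theta0=0.5,
    droplet_diameter_D=5.0)
traps = synth.TrapTruth(k1=50.0, k2=50.0, noise_relative=0.02, seed=7)

sweep = synth.simulate_dual_trap_sweep(material, traps)
cal = rheology.TrapCalibration(k1=50.0, k2=50.0)

# surface tension from opposed force steps at rest
f0_1, f0_2 = synth.consistent_step_forces(material, traps)
t, f1, f2, onsets = synth.simulate_step_relaxation(
    material, traps, f0_1, f0_1 + 1.0, f0_2, f0_2 - 1.0, tau=0.5)
step_fit = rheology.fit_step_relaxation(t, f1, f2, onsets)
tension = rheology.resting_stiffness_and_tension(
    step_fit, cal, step_amplitude_um=0.1, theta0=0.5)

# lock-in -> trap/drag correction -> capillary correction -> Maxwell fit
spectrum, fit = rheology.analyze_sweep(sweep, cal, tension)
print(f"surface tension gamma = {tension.gamma_pn_um:.4f} pN/um (truth 1.0)")
print(f"E = {fit.E_pa:.4f} Pa (truth 2.0)")
print(f"eta = {fit.eta_pa_s:.4f} Pa.s (truth 0.1)")
print(f"crossover = {fit.omega_c_hz:.4f} Hz (analytic {material.crossover_hz:.4f})")
```

Output (2% multiplicative force noise on the simulated sweep):

```
surface tension gamma = 1.0000 pN/um (truth 1.0)
E = 2.0006 Pa (truth 2.0)
eta = 0.1000 Pa.s (truth 0.1)
crossover = 3.1838 Hz (analytic 3.1831)
```

## Layout

- `src/condmech/` — library: `rheology`, `frap`, `motion`, `imaging`,
  `synth` (generators), `config`/`pipeline`/`report`/`cli` (orchestration)
- `analysis/` — numbered narrative drivers
- `tests/` — unit, property and generator-contract tests;
  `tests/test_acceptance.py` holds the acceptance criteria
- `docs/methods.md` — model, formulas, assumptions and design choices
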