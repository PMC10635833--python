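#!/usr/bin/env python
"""Generate every synthetic input dataset used by the downstream drivers.

Writes under scratch/data/ (large, regenerable; not part of the results):
  - dual-trap force sweep (HDF5) and step-relaxation traces (CSV)
  - FRAP recordings, clean and noisy (CSV)
  - particle tracks for MSD / mobility (CSV)

Ground truth: E = 2 Pa, dashpot 0.1 Pa.s, gamma = 1 pN/um, theta0 = 0.5,
D = 5 um, k1 = k2 = 50 pN/um — a droplet whose analytic Maxwell crossover
is E/(2 pi eta) = 3.18 Hz.
"""

import json
from pathlib import Path

import pandas as pd

from condmech import synth

SEED = 20240101
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    material = synth.MaterialTruth(
        plateau_modulus_E=2.0, dashpot_viscosity=0.1,
        surface_tension_gamma=1.0, contact_parameter_theta0=0.5,
        droplet_diameter_D=5.0, medium_viscosity=1e-3)
    traps = synth.TrapTruth(k1=50.0, k2=50.0, noise_relative=0.02, seed=SEED)

    sweep = synth.simulate_dual_trap_sweep(material, traps)
    sweep.to_hdf5(OUT / "force_sweep.h5")

    f0_1, f0_2 = synth.consistent_step_forces(material, traps)
    t, f1, f2, onsets = synth.simulate_step_relaxation(
        material, traps, f0_1, f0_1 + 1.0, f0_2, f0_2 - 1.0, tau=0.5)
    pd.DataFrame({"time_s": t, "f1_pN": f1, "f2_pN": f2}).to_csv(
        OUT / "step_relaxation.csv", index=False)
    (OUT / "step_onsets.json").write_text(json.dumps(list(onsets)))

    for label, noise in (("clean", 0.0), ("noisy", 5.0)):
        raw = synth.simulate_frap(0.6, 5.0, noise_sd=noise, seed=SEED,
                                  bleach_radius_um=1.0)
        raw.to_frame().to_csv(OUT / f"frap_{label}.csv", index=False)

    tracks = pd.concat([
        synth.simulate_tracks("directed", n_tracks=30, speed_um_s=1.0,
                              loc_noise_sd_um=0.05, seed=SEED,
                              bin_label="CB-30"),
        synth.simulate_tracks("stationary", n_tracks=70,
                              loc_noise_sd_um=0.05, seed=SEED + 1,
                              start_id=30, bin_label="30-60"),
    ], ignore_index=True)
    tracks.to_csv(OUT / "tracks.csv", index=False)

    truth = {"E_pa": 2.0, "eta_pa_s": 0.1, "gamma_pn_um": 1.0,
             "theta0": 0.5, "omega_c_hz": material.crossover_hz,
             "frap_mobile_fraction": 0.6, "frap_t_half_s": 5.0,
             "seed": SEED}
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
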