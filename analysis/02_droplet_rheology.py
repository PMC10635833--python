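#!/usr/bin/env python
"""Droplet microrheology: steps -> tension, sweep -> modulus -> Maxwell fit.

Reads scratch/data/ (run 01_simulate_inputs.py first), writes
results/rheology/: the modulus spectrum table, the Maxwell fit summary and
the diagnostic figures.
"""

import json
from pathlib import Path

import pandas as pd

from condmech import rheology
from condmech.report import write_report

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
OUT = ROOT / "results" / "rheology"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((DATA / "ground_truth.json").read_text())
    cal = rheology.TrapCalibration(k1=50.0, k2=50.0)

    steps = pd.read_csv(DATA / "step_relaxation.csv")
    onsets = json.loads((DATA / "step_onsets.json").read_text())
    step_fit = rheology.fit_step_relaxation(
        steps["time_s"].to_numpy(), steps["f1_pN"].to_numpy(),
        steps["f2_pN"].to_numpy(), onsets)
    tension = rheology.resting_stiffness_and_tension(
        step_fit, cal, step_amplitude_um=0.1, theta0=truth["theta0"])

    sweep = rheology.ForceSweep.from_hdf5(DATA / "force_sweep.h5")
    spectrum, fit = rheology.analyze_sweep(sweep, cal, tension)

    spectrum.to_frame().to_csv(OUT / "modulus_spectrum.csv", index=False)
    summary = {
        "E_pa": fit.E_pa, "eta_pa_s": fit.eta_pa_s,
        "omega_c_hz": fit.omega_c_hz,
        "omega_c_ci95_hz": list(fit.omega_c_ci95),
        "tau_char_s": fit.tau_char_s,
        "gamma_pn_um": tension.gamma_pn_um,
        "chi0_pn_um": tension.chi0_pn_um,
        "truth_E_pa": truth["E_pa"], "truth_eta_pa_s": truth["eta_pa_s"],
        "truth_omega_c_hz": truth["omega_c_hz"],
        "truth_gamma_pn_um": truth["gamma_pn_um"],
    }
    (OUT / "maxwell_fit.json").write_text(json.dumps(summary, indent=2))
    write_report({"rheology": {"spectrum": spectrum, "fit": fit,
                               "sweep": sweep}}, OUT)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
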