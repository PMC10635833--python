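#!/usr/bin/env python
"""FRAP kinetics: normalize recordings, fit recovery, report Mf / t1/2 / D.

Reads scratch/data/frap_*.csv (run 01_simulate_inputs.py first), writes
results/frap/.
"""

import json
from pathlib import Path

import pandas as pd

from condmech import frap as frap_mod
from condmech.report import write_report

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
OUT = ROOT / "results" / "frap"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for label in ("clean", "noisy"):
        raw = frap_mod.FrapRaw.from_frame(
            pd.read_csv(DATA / f"frap_{label}.csv"), bleach_radius_um=1.0)
        curve = frap_mod.normalize_frap(raw)
        fit = frap_mod.fit_frap(curve, bleach_radius_um=1.0)
        curve.to_csv(OUT / f"curve_{label}.csv", index=False)
        summary[label] = {
            "mobile_fraction": fit.mobile_fraction,
            "t_half_s": fit.t_half_s,
            "diffusion_um2_s": fit.diffusion_um2_s,
            "flagged": fit.flagged,
        }
        if label == "clean":
            write_report({"frap": {"curve": curve, "fit": fit}}, OUT)
    (OUT / "frap_fits.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
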