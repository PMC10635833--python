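"""Best-effort figure rendering for pipeline result bundles.

Renders the standard diagnostic plots: G'/G'' spectra with the Maxwell
overlay and crossover marker, per-frequency Lissajous force-displacement
ellipses, FRAP recovery overlays and log-log MSD curves.  Rendering never
raises; failures are logged and skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from condmech import rheology

log = logging.getLogger("condmech")

__all__ = ["write_report", "lissajous_data", "lissajous_area"]


def lissajous_data(sweep: rheology.ForceSweep, segment: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Force-vs-displacement pairs (x_sys, F1) for one frequency segment."""
    seg = sweep.data[sweep.data["segment"] == segment]
    return -seg["x_trap1_um"].to_numpy(), seg["f1_pN"].to_numpy()


def lissajous_area(amplitude_um: float, chi: complex) -> float:
    """Enclosed area of the force-displacement ellipse: pi A^2 Im(chi).

    The area measures the energy dissipated per cycle, so a
    viscous-dominated response encloses more area than an elastic one at
    the same amplitude.
    """
    return float(np.pi * amplitude_um**2 * np.imag(chi))


def write_report(results: dict, outdir: str | Path) -> list[Path]:
    """Render figures from a ``run_pipeline`` result bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not any(k for k in results if not k.startswith("_")):
        log.warning("empty result bundle: nothing to report")
        return written

    if "rheology" in results:
        try:
            r = results["rheology"]
            spectrum, fit, sweep = r["spectrum"], r["fit"], r["sweep"]
            fig, ax = plt.subplots()
            f = spectrum.frequency_hz
            ax.loglog(f, spectrum.g_prime, "o", label="G' (storage)")
            ax.loglog(f, spectrum.g_double_prime, "s", mfc="none",
                      label='G" (loss)')
            ff = np.geomspace(f.min(), f.max(), 200)
            g = rheology.maxwell_modulus(2 * np.pi * ff, fit.E_pa, fit.eta_pa_s)
            ax.loglog(ff, g.real, "-", color="k")
            ax.loglog(ff, g.imag, "--", color="k")
            ax.axvline(fit.omega_c_hz, color="r", ls=":",
                       label=f"crossover {fit.omega_c_hz:.2f} Hz")
            ax.set_xlabel("frequency (Hz)")
            ax.set_ylabel("modulus (Pa)")
            ax.legend()
            path = outdir / "modulus_spectrum.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)

            fig, axes = plt.subplots(1, len(sweep.drive_frequencies_hz),
                                     figsize=(3 * len(sweep.drive_frequencies_hz), 3))
            for i, ax in enumerate(np.atleast_1d(axes)):
                x, fo = lissajous_data(sweep, i)
                ax.plot(x, fo, lw=0.5)
                ax.set_title(f"{sweep.drive_frequencies_hz[i]:g} Hz")
            path = outdir / "lissajous.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
        except Exception as exc:  # best effort
            log.warning("rheology report failed: %s", exc)

    if "frap" in results:
        try:
            curve = results["frap"]["curve"]
            fit = results["frap"]["fit"]
            post = curve[curve["phase"].isin(("postbleach1", "postbleach2"))]
            fig, ax = plt.subplots()
            ax.plot(post["t_s"], post["intensity"], "o", ms=3)
            t0 = post["t_s"].iloc[0]
            tt = np.linspace(0, post["t_s"].iloc[-1] - t0, 200)
            ax.plot(t0 + tt, fit.mobile_fraction
                    * (1 - np.exp(-fit.rate_per_s * tt)), "-")
            ax.set_xlabel("time (s)")
            ax.set_ylabel("normalized intensity")
            path = outdir / "frap_recovery.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
        except Exception as exc:
            log.warning("FRAP report failed: %s", exc)

    if "msd" in results:
        try:
            curve = results["msd"]["curve"]
            fig, ax = plt.subplots()
            ax.loglog(curve.lag_s, curve.msd_um2, "o-")
            ax.set_xlabel("lag (s)")
            ax.set_ylabel("MSD (um^2)")
            if np.isfinite(curve.exponent):
                ax.set_title(f"power-law exponent n = {curve.exponent:.2f}")
            path = outdir / "msd.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
        except Exception as exc:
            log.warning("MSD report failed: %s", exc)

    return written
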