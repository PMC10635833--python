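"""Pipeline orchestration: run stages in dependency order, write results.

Each stage consumes either a user-supplied input file (declared in the
config's ``inputs`` mapping) or, when none is given, a synthetic
demonstration dataset generated from the run seed — so the full pipeline
is exercisable end to end without any experimental recording.  Every run
writes tidy CSV/JSON results, a config echo and a log line with the
package version, config hash and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from condmech import __version__
from condmech import frap as frap_mod
from condmech import imaging, motion, rheology, synth
from condmech.config import RunConfig

log = logging.getLogger("condmech")

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _demo_material(cfg: RunConfig) -> synth.MaterialTruth:
    return synth.MaterialTruth(
        plateau_modulus_E=2.0, dashpot_viscosity=0.1,
        surface_tension_gamma=1.0,
        contact_parameter_theta0=cfg.theta0 or 0.5,
        droplet_diameter_D=cfg.droplet_diameter_um or 5.0,
        medium_viscosity=cfg.medium_viscosity_pa_s,
    )


def _demo_traps(cfg: RunConfig, noise: float = 0.0) -> synth.TrapTruth:
    return synth.TrapTruth(
        k1=cfg.k1_pn_um or 50.0, k2=cfg.k2_pn_um or 50.0,
        noise_sd_force=noise, seed=cfg.seed,
    )


def _stage_rheology(cfg: RunConfig, outdir: Path) -> dict:
    mat = _demo_material(cfg)
    traps = _demo_traps(cfg)
    if "rheology" in cfg.inputs:
        path = Path(cfg.inputs["rheology"])
        sweep = (rheology.ForceSweep.from_hdf5(path)
                 if path.suffix in (".h5", ".hdf5")
                 else _read_sweep_csv(path, cfg))
    else:
        sweep = synth.simulate_dual_trap_sweep(mat, traps)

    cal = rheology.TrapCalibration(k1=traps.k1, k2=traps.k2)
    f0_1, f0_2 = synth.consistent_step_forces(mat, traps)
    t, f1, f2, onsets = synth.simulate_step_relaxation(
        mat, traps, f0_1, f0_1 + 1.0, f0_2, f0_2 - 1.0, tau=0.5)
    step_fit = rheology.fit_step_relaxation(t, f1, f2, onsets)
    tension = rheology.resting_stiffness_and_tension(
        step_fit, cal, cfg.step_amplitude_um, mat.contact_parameter_theta0)
    spectrum, fit = rheology.analyze_sweep(sweep, cal, tension)

    spectrum.to_frame().to_csv(outdir / "modulus_spectrum.csv", index=False)
    summary = {
        "E_pa": fit.E_pa, "eta_pa_s": fit.eta_pa_s,
        "omega_c_hz": fit.omega_c_hz,
        "omega_c_ci95_hz": list(fit.omega_c_ci95),
        "tau_char_s": fit.tau_char_s,
        "gamma_pn_um": tension.gamma_pn_um,
        "chi0_pn_um": tension.chi0_pn_um,
    }
    (outdir / "maxwell_fit.json").write_text(json.dumps(summary, indent=2))
    return {"spectrum": spectrum, "fit": fit, "tension": tension,
            "sweep": sweep, "summary": summary}


def _read_sweep_csv(path: Path, cfg: RunConfig) -> rheology.ForceSweep:
    df = pd.read_csv(path)
    for col in rheology.ForceSweep.REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PipelineError(
                "rheology", f"corrupted input table {path}: missing column "
                f"{col!r} (row 0)")
    freqs = sorted(df.groupby("segment").size().index)
    dt = float(np.median(np.diff(df["time_s"].iloc[:100])))
    seg_freqs = []
    for _, g in df.groupby("segment"):
        # dominant frequency of the commanded trajectory per segment
        x = g["x_trap1_um"].to_numpy()
        n = x.size
        spec = np.abs(np.fft.rfft(x - x.mean()))
        seg_freqs.append(np.fft.rfftfreq(n, dt)[np.argmax(spec)])
    return rheology.ForceSweep(
        data=df, drive_frequencies_hz=np.asarray(seg_freqs),
        drive_amplitude_um=float(np.max(np.abs(df["x_trap1_um"]))),
        sampling_rate_hz=1.0 / dt,
        droplet_diameter_um=cfg.droplet_diameter_um or 5.0,
        medium_viscosity_pa_s=cfg.medium_viscosity_pa_s,
    )


def _stage_frap(cfg: RunConfig, outdir: Path) -> dict:
    if "frap" in cfg.inputs:
        df = pd.read_csv(cfg.inputs["frap"])
        raw = frap_mod.FrapRaw.from_frame(
            df, bleach_radius_um=cfg.bleach_radius_um or np.nan)
    else:
        raw = synth.simulate_frap(
            mobile_fraction=0.6, t_half_s=5.0, noise_sd=0.5, seed=cfg.seed,
            bleach_radius_um=cfg.bleach_radius_um or 1.0)
    curve = frap_mod.normalize_frap(raw, scheme=cfg.frap_scheme)
    fit = frap_mod.fit_frap(curve, bleach_radius_um=raw.bleach_radius_um)
    curve.to_csv(outdir / "frap_curve.csv", index=False)
    summary = {"Mf": fit.mobile_fraction, "t_half_s": fit.t_half_s,
               "D_um2_s": fit.diffusion_um2_s, "flagged": fit.flagged}
    (outdir / "frap_fit.json").write_text(json.dumps(summary, indent=2))
    return {"raw": raw, "curve": curve, "fit": fit, "summary": summary}


def _stage_msd(cfg: RunConfig, outdir: Path) -> dict:
    if "msd" in cfg.inputs:
        tracks = pd.read_csv(cfg.inputs["msd"])
    else:
        tracks = pd.concat([
            synth.simulate_tracks("brownian", n_tracks=50, seed=cfg.seed,
                                  loc_noise_sd_um=0.02),
            synth.simulate_tracks("stationary", n_tracks=50,
                                  seed=cfg.seed + 1, loc_noise_sd_um=0.05,
                                  start_id=50),
        ], ignore_index=True)
    curve = motion.fit_powerlaw(
        motion.mean_squared_displacement(tracks, cfg.msd_max_lag_fraction))
    labels, summary = motion.classify_mobility(
        tracks, cfg.min_net_displacement_um, cfg.min_mean_speed_um_s)
    pd.DataFrame({"lag_s": curve.lag_s, "msd_um2": curve.msd_um2,
                  "n_pairs": curve.n_pairs}).to_csv(
        outdir / "msd_curve.csv", index=False)
    labels.to_csv(outdir / "mobility_labels.csv", index=False)
    summary.to_csv(outdir / "mobility_summary.csv", index=False)
    return {"curve": curve, "labels": labels, "summary": summary}


def _stage_coloc(cfg: RunConfig, outdir: Path) -> dict:
    if "coloc" in cfg.inputs:
        import tifffile
        stack = tifffile.imread(cfg.inputs["coloc"])
        ch1, ch2 = stack[0], stack[1]
    else:
        ch1, ch2 = synth.simulate_coloc_images(
            coloc_fraction=0.8, noise_sd=1.0, seed=cfg.seed)
    res = imaging.scramble_null(
        ch1, ch2, block_length_px=cfg.coloc_block_length_px,
        n_perm=cfg.coloc_n_permutations, seed=cfg.seed)
    summary = {"rho": res.rho, "p_empirical": res.p_empirical,
               "p_parametric": res.p_parametric,
               "n_permutations": res.n_permutations,
               "block_length_px": res.block_length_px}
    (outdir / "colocalization.json").write_text(json.dumps(summary, indent=2))
    return {"result": res, "summary": summary}


def _stage_fret(cfg: RunConfig, outdir: Path) -> dict:
    rng = np.random.default_rng(cfg.seed)
    truth = np.clip(rng.uniform(0.1, 0.5, size=(64, 64)), 0, 0.95)
    fret = synth.simulate_fret_stacks(truth, donor_bleed_d=0.5,
                                      crossex_a=0.2, noise_sd=0.5,
                                      seed=cfg.seed)
    index, mean_index, diag = imaging.fret_index_map(fret)
    import tifffile
    tifffile.imwrite(outdir / "fret_index.tif",
                     index.astype(np.float32))
    summary = {"mean_index": mean_index, **diag}
    (outdir / "fret_summary.json").write_text(json.dumps(summary, indent=2))
    return {"index": index, "mean_index": mean_index, "diag": diag}


def _stage_calcium(cfg: RunConfig, outdir: Path) -> dict:
    if "calcium" in cfg.inputs:
        trace = pd.read_csv(cfg.inputs["calcium"]).iloc[:, -1].to_numpy(float)
    else:
        rng = np.random.default_rng(cfg.seed)
        n0 = cfg.calcium_n_baseline
        t = np.arange(n0 + 400)
        trace = 50.0 + 100.0 * np.exp(-np.clip(t - n0 - 20, 0, None) / 80.0) \
            * (t >= n0 + 20) + rng.normal(0, 1.0, t.size)
    ca = imaging.delta_f_over_f(trace, cfg.calcium_n_baseline,
                                cfg.calcium_smooth_window)
    pd.DataFrame({"frame": np.arange(ca.normalized.size),
                  "dff": ca.normalized}).to_csv(
        outdir / "calcium_dff.csv", index=False)
    return {"trace": ca,
            "summary": {"f0": ca.f0, "peak_dff": float(ca.normalized.max())}}


_STAGE_FUNCS = {
    "rheology": _stage_rheology,
    "frap": _stage_frap,
    "msd": _stage_msd,
    "coloc": _stage_coloc,
    "fret": _stage_fret,
    "calcium": _stage_calcium,
}

# dependency order: rheology first (calibrate -> steps -> sweep -> Maxwell
# happen inside the stage), then the imaging analyses
_ORDER = ("simulate", "rheology", "frap", "msd", "coloc", "fret", "calcium")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Results and the config echo land under ``cfg.outdir``; a stage error
    aborts with the stage name while preserving earlier results on disk.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.echo(outdir / "config_echo.yaml")
    log.info("condmech %s | config %s | seed %d",
             __version__, cfg.config_hash(), cfg.seed)

    results: dict = {"_meta": {"version": __version__,
                               "config_hash": cfg.config_hash(),
                               "seed": cfg.seed}}
    for stage in _ORDER:
        if stage not in cfg.stages or stage == "simulate":
            continue
        try:
            results[stage] = _STAGE_FUNCS[stage](cfg, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        log.info("stage %s done", stage)
    return results
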