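"""Condensate transport and spatial organization along the neurite.

Tracked puncta are summarized by their mean squared displacement
MSD(tau) = <(x(t) - x(t+tau))^2>, averaged over time within each track
(overlapping windows) and over the ensemble of tracks, and the power-law
exponent of MSD vs lag: ~2 for directed transport, ~1 for diffusion,
~0 for immobile puncta.  Tracks are classified mobile/immobile by net
displacement and drift speed, per distance-to-cell-body bin.  Puncta
positions along the neurite yield interpunctum intervals; labeled masks
yield per-object area, perimeter and roundness 4*pi*A/P^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from skimage import measure

__all__ = [
    "MsdCurve",
    "mean_squared_displacement",
    "fit_powerlaw",
    "classify_mobility",
    "interpunctum_intervals",
    "puncta_morphology",
]

TRACK_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um")


@dataclass
class MsdCurve:
    """Ensemble- and time-averaged MSD with its power-law fit."""

    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    exponent: float = np.nan
    exponent_ci95: tuple[float, float] = (np.nan, np.nan)
    prefactor: float = np.nan


def _track_msd(x: np.ndarray, y: np.ndarray, max_lag: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD of one track over overlapping pairs."""
    n = x.size
    msd = np.empty(max_lag)
    npairs = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        msd[k - 1] = np.mean(dx * dx + dy * dy)
        npairs[k - 1] = n - k
    return msd, npairs


def mean_squared_displacement(tracks: pd.DataFrame,
                              max_lag_fraction: float = 0.25) -> MsdCurve:
    """Combined time-and-ensemble MSD of a track table.

    Per track, overlapping-pair time averaging up to ``max_lag_fraction``
    of the track length; tracks are then averaged at each common lag,
    weighted by their pair counts.  Requires a uniform frame interval
    within each track.
    """
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if tracks.empty:
        raise ValueError("empty track table")

    per_lag: dict[int, list[tuple[float, int]]] = {}
    dt = None
    for _, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        if len(g) < 10:
            continue
        t = g["t_s"].to_numpy(float)
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform frame interval within a track")
        dt = steps[0] if dt is None else dt
        max_lag = max(1, int(np.floor((len(g) - 1) * max_lag_fraction)))
        msd, npairs = _track_msd(g["x_um"].to_numpy(float),
                                 g["y_um"].to_numpy(float), max_lag)
        for k in range(max_lag):
            per_lag.setdefault(k + 1, []).append((msd[k], npairs[k]))
    if not per_lag:
        raise ValueError("no track with >= 10 frames")

    lags = np.array(sorted(per_lag))
    msd_out = np.empty(lags.size)
    n_out = np.empty(lags.size, dtype=int)
    for i, k in enumerate(lags):
        vals = np.array([v for v, _ in per_lag[k]])
        wts = np.array([w for _, w in per_lag[k]], dtype=float)
        msd_out[i] = np.average(vals, weights=wts)
        n_out[i] = int(wts.sum())
    return MsdCurve(lag_s=lags * dt, msd_um2=msd_out, n_pairs=n_out)


def fit_powerlaw(msd: MsdCurve,
                 lag_window: tuple[float, float] | None = None) -> MsdCurve:
    """OLS of log(MSD) on log(lag); returns the curve with exponent filled.

    Zero or negative MSD values inside the window are excluded (they carry
    no log-log information); fewer than 4 usable lags is an error.
    """
    lag = msd.lag_s
    y = msd.msd_um2
    sel = y > 0
    if lag_window is not None:
        sel &= (lag >= lag_window[0]) & (lag <= lag_window[1])
    if sel.sum() < 4:
        raise ValueError("need >= 4 positive MSD values in the fit window")
    lx = np.log(lag[sel])
    ly = np.log(y[sel])
    A = np.column_stack([lx, np.ones_like(lx)])
    coef, res_ss, _, _ = np.linalg.lstsq(A, ly, rcond=None)
    n_fit, dof = lx.size, lx.size - 2
    ci = (np.nan, np.nan)
    if dof > 0:
        s2 = float(res_ss[0]) / dof if res_ss.size else 0.0
        sxx = float(np.sum((lx - lx.mean()) ** 2))
        se = np.sqrt(s2 / sxx) if sxx > 0 else np.nan
        from scipy import stats
        tcrit = stats.t.ppf(0.975, dof)
        ci = (coef[0] - tcrit * se, coef[0] + tcrit * se)
    msd.exponent = float(coef[0])
    msd.exponent_ci95 = ci
    msd.prefactor = float(np.exp(coef[1]))
    return msd


def classify_mobility(
    tracks: pd.DataFrame,
    min_net_displacement_um: float = 2.0,
    min_mean_speed_um_s: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each track mobile/immobile and summarize per distance bin.

    A track is mobile if its net end-to-end displacement reaches
    ``min_net_displacement_um`` OR its drift speed (net displacement over
    track duration) reaches ``min_mean_speed_um_s``.  Path-length speed is
    deliberately not used: localization noise dominates frame-to-frame
    steps of immobile puncta.

    Returns (per-track labels, per-bin summary).  The per-bin summary has
    mobile/immobile fractions and the ratio r = mobile/immobile; a bin
    with no immobile tracks reports ``r_infinite = True`` and NaN ratio.
    """
    rows = []
    for tid, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        dx = g["x_um"].iloc[-1] - g["x_um"].iloc[0]
        dy = g["y_um"].iloc[-1] - g["y_um"].iloc[0]
        net = float(np.hypot(dx, dy))
        duration = float(g["t_s"].iloc[-1] - g["t_s"].iloc[0])
        speed = net / duration if duration > 0 else 0.0
        mobile = (net >= min_net_displacement_um
                  or speed >= min_mean_speed_um_s)
        row = {"track_id": tid, "net_displacement_um": net,
               "drift_speed_um_s": speed, "mobile": bool(mobile)}
        if "bin" in tracks.columns:
            row["bin"] = g["bin"].iloc[0]
        rows.append(row)
    labels = pd.DataFrame(rows)

    group_key = "bin" if "bin" in labels.columns else None
    summaries = []
    groups = labels.groupby(group_key) if group_key else [("all", labels)]
    for name, g in groups:
        n_mob = int(g["mobile"].sum())
        n_imm = int((~g["mobile"]).sum())
        n = n_mob + n_imm
        summaries.append({
            "bin": name,
            "n_tracks": n,
            "fraction_mobile": n_mob / n,
            "fraction_immobile": n_imm / n,
            "ratio_mobile_immobile": (n_mob / n_imm) if n_imm else np.nan,
            "r_infinite": n_imm == 0,
        })
    return labels, pd.DataFrame(summaries)


def interpunctum_intervals(
    positions_um: np.ndarray | None = None,
    intensity_profile: tuple[np.ndarray, np.ndarray] | None = None,
    threshold: float = 0.0,
    min_separation_um: float = 0.5,
) -> dict:
    """Interpunctum intervals from peak positions along the neurite.

    Accepts either punctum positions directly, or a background-subtracted
    intensity profile (position_um, intensity) on which local maxima above
    ``threshold`` separated by >= ``min_separation_um`` are detected.
    Returns intervals plus their median and mean.
    """
    if positions_um is None:
        if intensity_profile is None:
            raise ValueError("provide positions or an intensity profile")
        pos_axis, inten = (np.asarray(a, float) for a in intensity_profile)
        dx = np.median(np.diff(pos_axis))
        distance = max(1, int(round(min_separation_um / dx)))
        peaks, _ = sps.find_peaks(inten, height=threshold, distance=distance)
        positions = pos_axis[peaks]
    else:
        positions = np.sort(np.asarray(positions_um, float))

    if positions.size < 2:
        return {"intervals_um": np.array([]), "median_um": np.nan,
                "mean_um": np.nan, "n_puncta": int(positions.size),
                "warning": "fewer than 2 puncta: no intervals"}
    intervals = np.diff(np.sort(positions))
    return {"intervals_um": intervals,
            "median_um": float(np.median(intervals)),
            "mean_um": float(np.mean(intervals)),
            "n_puncta": int(positions.size)}


def puncta_morphology(label_image: np.ndarray,
                      pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Per-object area, perimeter and roundness from a labeled mask.

    Roundness = 4 pi A / P^2 (1 for a circle).  Empty masks return an
    empty frame rather than an error.
    """
    labels = np.asarray(label_image)
    if labels.max() == 0:
        return pd.DataFrame(columns=["label", "area_um2", "perimeter_um",
                                     "roundness", "centroid_row_um",
                                     "centroid_col_um"])
    rows = []
    for rp in measure.regionprops(labels):
        area = rp.area * pixel_size_um**2
        # Crofton estimator: the default chain-code perimeter underestimates
        # thin objects badly enough to make a 1-px line look round.
        perim = rp.perimeter_crofton * pixel_size_um
        roundness = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
        rows.append({
            "label": rp.label,
            "area_um2": area,
            "perimeter_um": perim,
            "roundness": roundness,
            "centroid_row_um": rp.centroid[0] * pixel_size_um,
            "centroid_col_um": rp.centroid[1] * pixel_size_um,
        })
    return pd.DataFrame(rows)
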