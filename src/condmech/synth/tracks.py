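"""Synthetic 2-D particle tracks with known transport mode.

Three motion modes mirror the observed punctum populations: directed
(motor-driven transport with optional reversals), brownian (diffusive,
MSD slope 4D), and stationary (pure localization noise).  Tracks carry a
``truth_mobile`` column so classification accuracy can be scored against
ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_tracks"]

MODES = ("directed", "brownian", "stationary")


def simulate_tracks(
    mode: str,
    n_tracks: int = 10,
    speed_um_s: float = 1.0,
    d_coef_um2_s: float = 0.05,
    frame_dt_s: float = 0.1,
    n_frames: int = 100,
    loc_noise_sd_um: float = 0.0,
    seed: int = 0,
    reversal_prob: float = 0.0,
    start_id: int = 0,
    bin_label: str | None = None,
) -> pd.DataFrame:
    """Generate a track table (track_id, frame, t_s, x_um, y_um, truth_mobile).

    directed:   constant speed along a random direction; at each frame the
                direction reverses with probability ``reversal_prob``.
    brownian:   per-axis Gaussian steps of variance 2 D dt, so the 2-D MSD
                slope is 4 D.
    stationary: fixed position.
    Localization noise of sd ``loc_noise_sd_um`` is added per coordinate
    in all modes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if n_frames < 10:
        raise ValueError("need n_frames >= 10")
    rng = np.random.default_rng(seed)

    frames = np.arange(n_frames)
    t = frames * frame_dt_s
    out = []
    for i in range(n_tracks):
        origin = rng.uniform(0, 50, size=2)
        if mode == "directed":
            ang = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.cos(ang), np.sin(ang)])
            signs = np.ones(n_frames)
            if reversal_prob > 0:
                flips = rng.random(n_frames) < reversal_prob
                signs = np.cumprod(np.where(flips, -1.0, 1.0))
            step = speed_um_s * frame_dt_s
            disp = np.cumsum(signs[:, None] * direction[None, :] * step, axis=0)
            disp = np.vstack([[0.0, 0.0], disp[:-1]])
            xy = origin + disp
        elif mode == "brownian":
            steps = rng.normal(0.0, np.sqrt(2.0 * d_coef_um2_s * frame_dt_s),
                               size=(n_frames - 1, 2))
            xy = origin + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        else:
            xy = np.tile(origin, (n_frames, 1))
        if loc_noise_sd_um > 0:
            xy = xy + rng.normal(0.0, loc_noise_sd_um, size=xy.shape)
        df = pd.DataFrame({
            "track_id": start_id + i,
            "frame": frames,
            "t_s": t,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "truth_mobile": mode == "directed",
        })
        if bin_label is not None:
            df["bin"] = bin_label
        out.append(df)
    return pd.concat(out, ignore_index=True)
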