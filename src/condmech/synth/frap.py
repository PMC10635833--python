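"""Synthetic FRAP recordings with known recovery kinetics.

The generator emits raw intensities for the bleached ROI, the whole
punctum, the background and an unbleached reference punctum, constructed
so that the full-scale-normalized curve equals Mf (1 - exp(-tau t)) with
tau = ln 2 / t_half exactly before noise.  A single-exponential
acquisition-bleaching decay multiplies every fluorescent ROI so that the
normalization's bleaching correction is actually exercised; in
``whole_punctum_bleached`` mode the whole-punctum ROI additionally loses
intensity at the bleach itself, so only the reference-ROI (bleach-rate)
renormalization recovers the true curve.
"""

from __future__ import annotations

import numpy as np

from condmech.frap import FrapRaw

__all__ = ["simulate_frap", "default_schedule"]


def default_schedule() -> tuple[np.ndarray, np.ndarray]:
    """Frame schedule of the imaging protocol: 5 pre-bleach frames every
    371 ms, 5 bleach frames every 344 ms, 10 post-bleach frames every
    371 ms, then 10 frames every 20 s.  Returns (timestamps_s, phases)."""
    t, labels = [], []
    clock = 0.0
    for phase, n, dt in (("prebleach", 5, 0.371), ("bleach", 5, 0.344),
                         ("postbleach1", 10, 0.371), ("postbleach2", 10, 20.0)):
        for _ in range(n):
            t.append(clock)
            labels.append(phase)
            clock += dt
    return np.asarray(t), np.asarray(labels, object)


def simulate_frap(
    mobile_fraction: float,
    t_half_s: float,
    schedule: tuple[np.ndarray, np.ndarray] | None = None,
    noise_sd: float = 0.0,
    bleach_depth: float = 0.8,
    seed: int = 0,
    *,
    prebleach_intensity: float = 100.0,
    total_intensity: float = 400.0,
    background: float = 10.0,
    acquisition_bleach_rate: float = 0.002,  # 1/s, multiplies all ROIs
    bleach_radius_um: float = 1.0,
    whole_punctum_bleached: bool = False,
) -> FrapRaw:
    """Generate one raw FRAP recording with known (Mf, t_half).

    The bleached-ROI signal drops by ``bleach_depth`` of its pre-bleach
    level at the bleach and recovers as
    R(t) = R0 + (Rpre - R0) * Mf * (1 - exp(-tau (t - t0))) from the first
    post-bleach frame t0.  Gaussian noise of sd ``noise_sd`` (a.u.) is
    added to every ROI sample from one seeded generator.
    """
    if not (0.0 <= mobile_fraction <= 1.0):
        raise ValueError("mobile fraction must lie in [0, 1]")
    if t_half_s <= 0:
        raise ValueError("t_half must be positive")
    if bleach_depth <= 0 or bleach_depth > 1:
        raise ValueError("bleach depth must lie in (0, 1]: a zero-depth "
                         "bleach makes the normalization degenerate")

    if schedule is None:
        t, phase = default_schedule()
    else:
        t, phase = np.asarray(schedule[0], float), np.asarray(schedule[1], object)
    rng = np.random.default_rng(seed)

    tau = np.log(2.0) / t_half_s
    decay = np.exp(-acquisition_bleach_rate * t)

    pre = phase == "prebleach"
    post = (phase == "postbleach1") | (phase == "postbleach2")
    t0 = t[post][0]

    r_pre = prebleach_intensity
    r0 = r_pre * (1.0 - bleach_depth)
    recovery = np.where(
        post, r0 + (r_pre - r0) * mobile_fraction * (1.0 - np.exp(-tau * (t - t0))),
        np.nan)
    roi1_true = np.where(pre, r_pre, recovery)
    # during the bleach pulse itself, interpolate down to the bleached level
    bleach = phase == "bleach"
    if bleach.any():
        frac = np.linspace(0.0, 1.0, int(bleach.sum()))
        roi1_true[bleach] = r_pre - frac * (r_pre - r0)

    total_true = np.full(t.size, float(total_intensity))
    if whole_punctum_bleached:
        # the bleach removes fluorophores from the whole punctum, which
        # stays depressed: its intensity cannot correct for acquisition
        # bleaching, which is exactly why the reference ROI exists
        lost = bleach_depth * r_pre
        total_true[bleach | post] = total_intensity - lost
        if bleach.any():
            total_true[bleach] = total_intensity - lost * frac
    ref_true = np.full(t.size, 0.8 * total_intensity)

    roi1 = background + roi1_true * decay
    roi2 = background + total_true * decay
    roi3 = np.full(t.size, background)
    ref = background + ref_true * decay

    if noise_sd > 0:
        roi1 = roi1 + noise_sd * rng.standard_normal(t.size)
        roi2 = roi2 + noise_sd * rng.standard_normal(t.size)
        roi3 = roi3 + noise_sd * rng.standard_normal(t.size)
        ref = ref + noise_sd * rng.standard_normal(t.size)

    return FrapRaw(
        timestamps_s=t, phase=phase,
        roi_bleached=roi1, roi_total=roi2, roi_background=roi3,
        roi_reference=ref, bleach_radius_um=bleach_radius_um,
        meta={"seed": seed,
              "truth": {"mobile_fraction": mobile_fraction,
                        "t_half_s": t_half_s,
                        "bleach_depth": bleach_depth}},
    )
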