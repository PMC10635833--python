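"""Fluorescence recovery after photobleaching (FRAP) analysis.

Raw per-frame intensities from three regions of interest — the bleached
area (ROI1), the whole punctum/droplet (ROI2) and the background (ROI3),
optionally plus an unbleached reference punctum — are normalized in two
steps:

* double normalization, which corrects for acquisition bleaching via the
  total-fluorescence ROI (or, for sub-punctum bleaching where the whole
  punctum dims, via the reference ROI renormalized to its pre-bleach
  mean), and
* full-scale rescaling so the first post-bleach point is 0 and the
  pre-bleach level is 1, correcting for differences in bleach depth.

The normalized recovery is fit to I(t) = Mf (1 - exp(-tau t)) with the
time origin at the first post-bleach frame; the half-time is
t_1/2 = ln 2 / tau and the diffusion coefficient follows from the
Soumpasis relation D = 0.224 r^2 / t_1/2 with r the bleach-spot radius.
The half-time depends on the user-chosen bleach radius, so D — not
t_1/2 — is the quantity comparable across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "FrapRaw",
    "FrapFit",
    "normalize_frap",
    "fit_frap",
    "soumpasis_diffusion",
    "PHASES",
]

PHASES = ("prebleach", "bleach", "postbleach1", "postbleach2")


@dataclass
class FrapRaw:
    """Raw ROI intensity series for one FRAP recording."""

    timestamps_s: np.ndarray
    phase: np.ndarray              # labels from PHASES, contiguous & ordered
    roi_bleached: np.ndarray       # ROI1, a.u.
    roi_total: np.ndarray          # ROI2, a.u.
    roi_background: np.ndarray     # ROI3, a.u.
    roi_reference: np.ndarray | None = None  # unbleached punctum, a.u.
    bleach_radius_um: float = np.nan
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, float)
        self.phase = np.asarray(self.phase, object)
        if np.sum(self.phase == "prebleach") < 2:
            raise ValueError("need >= 2 prebleach frames")
        # phases must appear contiguously and in protocol order
        order = [p for p, _ in _group_runs(self.phase)]
        expected = [p for p in PHASES if p in set(order)]
        if order != expected:
            raise ValueError(f"phases must be contiguous and ordered; got {order}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t_s": self.timestamps_s,
            "phase": self.phase,
            "roi1": self.roi_bleached,
            "roi2": self.roi_total,
            "roi3": self.roi_background,
        })
        if self.roi_reference is not None:
            df["roi_ref"] = self.roi_reference
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bleach_radius_um: float = np.nan
                   ) -> "FrapRaw":
        return cls(
            timestamps_s=df["t_s"].to_numpy(float),
            phase=df["phase"].to_numpy(object),
            roi_bleached=df["roi1"].to_numpy(float),
            roi_total=df["roi2"].to_numpy(float),
            roi_background=df["roi3"].to_numpy(float),
            roi_reference=(df["roi_ref"].to_numpy(float)
                           if "roi_ref" in df.columns else None),
            bleach_radius_um=bleach_radius_um,
        )


def _group_runs(labels: np.ndarray):
    runs = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1] + 1)
        else:
            runs.append((lab, 1))
    return runs


@dataclass
class FrapFit:
    """Recovery kinetics of one normalized FRAP curve."""

    mobile_fraction: float
    mobile_fraction_ci95: tuple[float, float]
    rate_per_s: float          # tau in I(t) = Mf (1 - exp(-tau t)), 1/s
    t_half_s: float
    diffusion_um2_s: float = np.nan
    flagged: bool = False
    flag_reason: str = ""


def normalize_frap(
    raw: FrapRaw,
    scheme: str = "full_scale",
    bleach_rate_correction: bool = False,
) -> pd.DataFrame:
    """Normalize a raw FRAP recording.

    Double normalization:
        I_dn(t) = [mean_pre(total - bg) / (total(t) - bg)]
                  * [(roi1(t) - bg) / mean_pre(roi1 - bg)]
    Full-scale then rescales so the first post-bleach point is 0 and the
    pre-bleach level is 1.  With ``bleach_rate_correction`` the total ROI
    is replaced by the unbleached reference punctum renormalized to its
    pre-bleach mean (sub-punctum bleaching, where the whole punctum dims).

    Returns a tidy frame (t_s, phase, intensity) excluding bleach-phase
    frames; flagged frames (negative background-corrected intensity) are
    dropped and counted in ``attrs['n_excluded']``.
    """
    if scheme not in ("double", "full_scale"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    t = raw.timestamps_s
    phase = raw.phase
    bg = float(np.mean(raw.roi_background))
    pre = phase == "prebleach"

    if bleach_rate_correction:
        if raw.roi_reference is None:
            raise ValueError("bleach_rate_correction requires a reference ROI")
        total = raw.roi_reference
    else:
        total = raw.roi_total

    roi1 = raw.roi_bleached - bg
    tot = total - bg
    if np.mean(roi1[pre]) <= 0 or np.mean(tot[pre]) <= 0:
        raise ValueError("background exceeds signal in prebleach frames")

    bad = (roi1 < 0) | (tot <= 0)
    i_dn = (np.mean(tot[pre]) / tot) * (roi1 / np.mean(roi1[pre]))

    post = (phase == "postbleach1") | (phase == "postbleach2")
    keep = (pre | post) & ~bad
    n_excluded = int(np.sum((pre | post) & bad))

    out = pd.DataFrame({"t_s": t[keep], "phase": phase[keep],
                        "intensity": i_dn[keep]})
    if scheme == "full_scale":
        post_rows = out["phase"].isin(("postbleach1", "postbleach2"))
        if not post_rows.any():
            raise ValueError("no postbleach frames available")
        i0 = float(out.loc[post_rows, "intensity"].iloc[0])
        if np.isclose(i0, 1.0):
            raise ValueError("no detectable bleach: first postbleach "
                             "intensity equals the prebleach level")
        out["intensity"] = (out["intensity"] - i0) / (1.0 - i0)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["scheme"] = scheme
    return out


def fit_frap(curve: pd.DataFrame,
             fit_phases: tuple[str, ...] = ("postbleach1", "postbleach2"),
             bleach_radius_um: float = np.nan) -> FrapFit:
    """Fit I(t) = Mf (1 - exp(-tau t)) to the post-bleach recovery.

    Time origin is the first post-bleach frame; fitting uses real time
    stamps, never frame indices (the protocol's post-bleach intervals are
    strongly unequal).  An Mf above 1.1 or a non-converged fit is flagged
    rather than raised.
    """
    sel = curve["phase"].isin(fit_phases)
    t = curve.loc[sel, "t_s"].to_numpy(float)
    y = curve.loc[sel, "intensity"].to_numpy(float)
    if t.size < 6:
        raise ValueError("need >= 6 postbleach points to fit recovery")
    t = t - t[0]

    if np.allclose(y, 0.0, atol=1e-12):
        return FrapFit(mobile_fraction=0.0, mobile_fraction_ci95=(0.0, 0.0),
                       rate_per_s=np.nan, t_half_s=np.nan,
                       flagged=True, flag_reason="flat curve: rate unidentifiable")

    model = lmfit.Model(lambda t, mf, tau: mf * (1.0 - np.exp(-tau * t)))
    # initial rate from the earliest rise; Mf from the late plateau
    mf0 = float(np.clip(np.median(y[-3:]), 1e-3, 1.5))
    tau0 = 1.0 / max(t[max(1, t.size // 4)], 1e-3)
    params = model.make_params(mf=dict(value=mf0, min=0.0),
                               tau=dict(value=tau0, min=1e-9))
    res = model.fit(y, params, t=t)
    mf = float(res.params["mf"].value)
    tau = float(res.params["tau"].value)
    ci = (np.nan, np.nan)
    if res.covar is not None:
        sd = np.sqrt(max(res.covar[0, 0], 0.0))
        ci = (max(mf - 1.96 * sd, 0.0), min(mf + 1.96 * sd, 1.0))
    flagged = (not res.success) or mf > 1.1
    reason = "" if not flagged else (
        "fit did not converge" if not res.success else "Mf > 1.1")
    t_half = np.log(2.0) / tau
    d = (soumpasis_diffusion(t_half, bleach_radius_um)
         if np.isfinite(bleach_radius_um) else np.nan)
    return FrapFit(mobile_fraction=mf, mobile_fraction_ci95=ci,
                   rate_per_s=tau, t_half_s=t_half, diffusion_um2_s=d,
                   flagged=flagged, flag_reason=reason)


def soumpasis_diffusion(t_half_s: float, radius_um: float) -> float:
    """Diffusion coefficient from FRAP half-time: D = 0.224 r^2 / t_1/2."""
    if t_half_s <= 0 or radius_um <= 0:
        raise ValueError("t_half and bleach radius must be positive")
    return 0.224 * radius_um**2 / t_half_s


def average_curves(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Average normalized recovery curves sampled on a common schedule."""
    if not curves:
        raise ValueError("no curves to average")
    base = curves[0]
    stack = np.stack([c["intensity"].to_numpy(float) for c in curves])
    out = base.copy()
    out["intensity"] = stack.mean(axis=0)
    return out
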