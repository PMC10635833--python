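"""FRET tension indexing, colocalization statistics and calcium traces.

Three-cube FRET: the sensitized-emission channel (donor excitation,
acceptor emission) is contaminated by donor bleedthrough (factor d) and
acceptor cross-excitation (factor a), both measured from single-label
controls.  Linear unmixing gives the corrected FRET signal

    cF = (I_DA - bg) - d (I_DD - bg) - a (I_AA - bg)

and the pixelwise FRET index cF / ((I_DD - bg) + cF), evaluated inside a
mask on the acceptor channel.  In a tension-sensor construct a lower
index means higher tension across the module.

Colocalization of two punctate channels is scored by the Pearson
coefficient over a mask, with significance from a block-scramble null:
the straightened-neurite image is chopped into along-axis blocks that are
randomly permuted, destroying spatial correspondence while preserving the
intensity histogram exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

__all__ = [
    "FretSet",
    "ColocResult",
    "CalciumTrace",
    "estimate_bleedthrough",
    "fret_index_map",
    "fret_vs_load",
    "pearson_colocalization",
    "scramble_null",
    "delta_f_over_f",
]


@dataclass
class FretSet:
    """Registered donor / transfer / acceptor images with correction factors."""

    i_dd: np.ndarray   # donor ex / donor em
    i_da: np.ndarray   # donor ex / acceptor em (transfer channel)
    i_aa: np.ndarray   # acceptor ex / acceptor em
    donor_bleed_d: float = 0.0
    crossex_a: float = 0.0
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {np.shape(self.i_dd), np.shape(self.i_da), np.shape(self.i_aa)}
        if len(shapes) != 1:
            raise ValueError("FRET channels must be co-registered (same shape)")
        if self.donor_bleed_d < 0 or self.crossex_a < 0:
            raise ValueError("bleedthrough factors must be >= 0")


@dataclass
class ColocResult:
    """Pearson colocalization with its block-scramble permutation null."""

    rho: float
    p_parametric: float
    null_rho: np.ndarray
    p_empirical: float
    block_length_px: int
    n_permutations: int
    seed: int


@dataclass
class CalciumTrace:
    """Baseline-normalized calcium fluorescence (F - F0)/F0."""

    f_raw: np.ndarray
    f0: float
    normalized: np.ndarray
    smooth_window: int = 1
    meta: dict = field(default_factory=dict)


def _robust_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Theil-Sen slope, robust to the occasional saturated pixel."""
    res = stats.theilslopes(y, x)
    return float(res.slope)


def estimate_bleedthrough(
    donor_only: tuple[np.ndarray, np.ndarray],
    acceptor_only: tuple[np.ndarray, np.ndarray],
    background: float = 0.0,
    min_pixels: int = 100,
) -> tuple[float, float]:
    """Bleedthrough factors from single-fluorophore control stacks.

    ``donor_only`` is (I_DD, I_DA) from an animal expressing the donor
    alone; ``acceptor_only`` is (I_AA, I_DA) from the acceptor alone.
    Each factor is the robust slope of the transfer channel against the
    direct channel over pixels above background.
    """
    factors = []
    for direct, transfer in (donor_only, acceptor_only):
        direct = np.asarray(direct, float).ravel() - background
        transfer = np.asarray(transfer, float).ravel() - background
        bright = direct > 0
        if bright.sum() < min_pixels:
            raise ValueError(
                f"only {int(bright.sum())} pixels above background; "
                f"need >= {min_pixels} to estimate a bleedthrough factor")
        factors.append(max(_robust_slope(direct[bright], transfer[bright]), 0.0))
    return factors[0], factors[1]


def fret_index_map(fret: FretSet, mask_threshold: float | None = None
                   ) -> tuple[np.ndarray, float, dict]:
    """Pixelwise FRET index with linear-unmixing bleedthrough correction.

    cF = (I_DA - bg) - d (I_DD - bg) - a (I_AA - bg)
    index = cF / ((I_DD - bg) + cF), clipped to [0, 1].

    The mask is taken from the acceptor channel (Otsu by default, or a
    fixed threshold); pixels whose denominator is <= 0 are excluded and
    counted.  Returns (index map with NaN outside mask, mean index in
    mask, diagnostics).
    """
    bg_dd, bg_da, bg_aa = fret.background
    dd = np.asarray(fret.i_dd, float) - bg_dd
    da = np.asarray(fret.i_da, float) - bg_da
    aa = np.asarray(fret.i_aa, float) - bg_aa
    cf = da - fret.donor_bleed_d * dd - fret.crossex_a * aa

    if fret.mask is not None:
        mask = fret.mask.astype(bool)
    else:
        thr = threshold_otsu(aa) if mask_threshold is None else mask_threshold
        mask = aa > thr

    denom = dd + cf
    valid = mask & (denom > 0)
    n_excluded = int(np.sum(mask & ~valid))
    index = np.full(dd.shape, np.nan)
    raw = cf[valid] / denom[valid]
    n_clipped = int(np.sum((raw < 0) | (raw > 1)))
    index[valid] = np.clip(raw, 0.0, 1.0)
    mean_index = float(np.nanmean(index[valid])) if valid.any() else np.nan
    diag = {"n_mask": int(mask.sum()), "n_excluded_nonpositive": n_excluded,
            "n_clipped": n_clipped,
            "clip_fraction": n_clipped / max(int(valid.sum()), 1)}
    return index, mean_index, diag


def _fisher_ci_halfwidth(rho: float, n: int, alpha: float = 0.05) -> float:
    """Half-width of the Fisher-z confidence interval of rho."""
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return float((hi - lo) / 2.0)


def fret_vs_load(
    displacement_um: np.ndarray,
    mean_fret_index: np.ndarray,
    resting_before: float | None = None,
    resting_after: float | None = None,
    reversibility_tol: float = 0.05,
) -> dict:
    """Correlate mean FRET index with cuticle displacement across load steps.

    Reports the Pearson rho, the ratio statistic t = rho / r_omega with
    r_omega the half-width of rho's 95% Fisher CI, and — as the standard
    cross-check — the usual Pearson t-test with its two-sided p.  If
    resting values before loading and after release are given, the
    response is flagged reversible when they agree within tolerance.
    """
    x = np.asarray(displacement_um, float)
    y = np.asarray(mean_fret_index, float)
    if x.size < 3:
        raise ValueError("need >= 3 load steps")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant displacement or FRET: rho undefined")
    rho, p_std = stats.pearsonr(x, y)
    r_omega = _fisher_ci_halfwidth(rho, x.size)
    t_ratio = rho / r_omega if r_omega > 0 else np.inf
    n = x.size
    t_std = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
    out = {"rho": float(rho), "t_ratio": float(t_ratio),
           "r_omega": r_omega, "t_standard": float(t_std),
           "p_standard": float(p_std), "n_steps": n}
    if resting_before is not None and resting_after is not None:
        out["reversible"] = bool(
            abs(resting_after - resting_before) <= reversibility_tol)
    return out


def pearson_colocalization(ch1: np.ndarray, ch2: np.ndarray,
                           mask: np.ndarray | None = None
                           ) -> tuple[float, float]:
    """Pearson correlation of two channels over a mask, with parametric p."""
    a = np.asarray(ch1, float)
    b = np.asarray(ch2, float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty mask")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance channel: correlation undefined")
    rho, p = stats.pearsonr(a, b)
    return float(rho), float(p)


def scramble_blocks(image: np.ndarray, blocks: list[tuple[int, int]],
                    order: np.ndarray) -> np.ndarray:
    """Reassemble an image from its column blocks in the given order.

    A pure permutation: the pixel multiset (hence the intensity
    histogram) is preserved exactly.
    """
    return np.concatenate([image[:, s:e] for s, e in
                           (blocks[j] for j in order)], axis=1)


def scramble_null(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray | None = None,
    block_length_px: int = 16,
    n_perm: int = 1000,
    seed: int = 0,
) -> ColocResult:
    """Pearson colocalization against a block-scramble permutation null.

    The first channel is chopped into along-neurite blocks of columns
    (axis 1) of ``block_length_px``; a trailing remainder forms its own
    block.  Blocks are randomly permuted per iteration and rho recomputed,
    giving the null distribution and the empirical two-sided p
    (1 + #{|rho_null| >= |rho_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for a usable null")
    a = np.asarray(ch1, float)
    b = np.asarray(ch2, float)
    n_cols = a.shape[1]
    edges = list(range(0, n_cols, block_length_px)) + [n_cols]
    blocks = [(s, e) for s, e in zip(edges[:-1], edges[1:])]
    if len(blocks) < 4:
        raise ValueError(
            f"only {len(blocks)} blocks of {block_length_px} px in a "
            f"{n_cols}-px ROI: null too coarse (need >= 4)")

    rho_obs, p_param = pearson_colocalization(a, b, mask)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        order = rng.permutation(len(blocks))
        scrambled = scramble_blocks(a, blocks, order)
        # mask follows channel 2 (it is not scrambled)
        null[i], _ = pearson_colocalization(scrambled, b, mask)
    p_emp = (1.0 + np.sum(np.abs(null) >= abs(rho_obs))) / (n_perm + 1.0)
    return ColocResult(rho=rho_obs, p_parametric=p_param, null_rho=null,
                       p_empirical=float(p_emp),
                       block_length_px=block_length_px,
                       n_permutations=n_perm, seed=seed)


def pressure_to_displacement(table: "pd.DataFrame | str",
                             pressure_kpa: np.ndarray) -> np.ndarray:
    """Convert applied pressure to cuticle displacement via a calibration
    table (columns pressure_kPa, displacement_um) with linear interpolation.

    The table must be monotone in pressure; values outside its range raise
    rather than extrapolate.
    """
    if isinstance(table, str):
        table = pd.read_csv(table)
    p = table["pressure_kPa"].to_numpy(float)
    d = table["displacement_um"].to_numpy(float)
    order = np.argsort(p)
    p, d = p[order], d[order]
    if np.any(np.diff(d) < 0):
        raise ValueError("displacement must be monotone in pressure")
    q = np.asarray(pressure_kpa, float)
    if q.min() < p.min() or q.max() > p.max():
        raise ValueError("pressure outside the calibration table range")
    return np.interp(q, p, d)


def delta_f_over_f(trace: np.ndarray, n_baseline: int = 100,
                   smooth_window: int = 1) -> CalciumTrace:
    """Moving-average smoothing then baseline normalization (F - F0)/F0.

    F0 is the mean of the first ``n_baseline`` pre-stimulation frames of
    the smoothed trace; ``smooth_window`` of 1 applies no smoothing.
    """
    f = np.asarray(trace, float)
    if f.size <= n_baseline:
        raise ValueError("trace shorter than the baseline window")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        f_s = np.convolve(f, kernel, mode="same")
        # centered moving average distorts the edges; keep raw values there
        half = smooth_window // 2
        f_s[:half] = f[:half]
        f_s[-half:] = f[-half:] if half else f_s[-half:]
    else:
        f_s = f.copy()
    f0 = float(np.mean(f_s[:n_baseline]))
    if f0 <= 0:
        raise ValueError("baseline F0 must be positive")
    return CalciumTrace(f_raw=f, f0=f0, normalized=(f_s - f0) / f0,
                        smooth_window=smooth_window)
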