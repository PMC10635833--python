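"""Synthetic microscopy images: FRET triples and two-channel puncta.

The FRET generator inverts the linear-unmixing analysis: from a ground
truth index map and internally generated punctate donor/acceptor base
images it emits the three channels with programmed bleedthrough, so the
unmixing recovers the truth map exactly at zero noise.  The
colocalization generator places Gaussian puncta in two channels with a
controllable co-occurrence probability.
"""

from __future__ import annotations

import numpy as np

from condmech.imaging import FretSet

__all__ = ["simulate_fret_stacks", "simulate_coloc_images", "puncta_image"]


def puncta_image(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitude: float = 100.0,
    psf_sigma_px: float = 1.5,
) -> np.ndarray:
    """Render Gaussian puncta of equal amplitude at the given (row, col)
    positions on a zero background."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    img = np.zeros(shape)
    for r, c in np.atleast_2d(positions):
        img += amplitude * np.exp(-((rows - r) ** 2 + (cols - c) ** 2)
                                  / (2.0 * psf_sigma_px**2))
    return img


def simulate_fret_stacks(
    true_index_map: np.ndarray,
    donor_bleed_d: float,
    crossex_a: float,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    donor_level: float = 100.0,
    acceptor_level: float = 50.0,
) -> FretSet:
    """Emit (I_DD, I_DA, I_AA) consistent with a ground-truth index map.

    From index = cF / (I_DD + cF) the programmed FRET signal is
    cF = index * I_DD / (1 - index), and the transfer channel is
    I_DA = cF + d I_DD + a I_AA, all before the common additive
    background and Gaussian noise.  Donor and acceptor base images are
    smooth punctate fields generated internally from the seed.
    """
    idx = np.asarray(true_index_map, float)
    if np.any(idx < 0) or np.any(idx >= 1):
        raise ValueError("true index map must satisfy 0 <= index < 1")
    if donor_bleed_d < 0 or crossex_a < 0:
        raise ValueError("bleedthrough factors must be >= 0")
    rng = np.random.default_rng(seed)

    shape = idx.shape
    n_puncta = max(3, int(np.prod(shape) // 400))
    pos = np.column_stack([rng.uniform(0, shape[0], n_puncta),
                           rng.uniform(0, shape[1], n_puncta)])
    i_dd = donor_level * 0.2 + puncta_image(shape, pos, donor_level)
    i_aa = acceptor_level * 0.2 + puncta_image(shape, pos, acceptor_level)

    cf = idx * i_dd / (1.0 - idx)
    i_da = cf + donor_bleed_d * i_dd + crossex_a * i_aa

    channels = []
    for img in (i_dd, i_da, i_aa):
        img = img + background
        if noise_sd > 0:
            img = img + noise_sd * rng.standard_normal(shape)
        channels.append(img)

    return FretSet(i_dd=channels[0], i_da=channels[1], i_aa=channels[2],
                   donor_bleed_d=donor_bleed_d, crossex_a=crossex_a,
                   background=(background, background, background))


def simulate_coloc_images(
    n_puncta: int = 20,
    coloc_fraction: float = 1.0,
    psf_sigma_px: float = 1.5,
    image_shape: tuple[int, int] = (32, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel punctate images with controllable co-occurrence.

    Channel-2 puncta share channel-1 positions with probability
    ``coloc_fraction``; otherwise they land at independent uniform
    positions.  Identical seeds give bit-identical images.
    """
    if not (0.0 <= coloc_fraction <= 1.0):
        raise ValueError("coloc_fraction must lie in [0, 1]")
    # each punctum needs room: a crude density guard
    if n_puncta * (4 * psf_sigma_px) ** 2 > np.prod(image_shape):
        raise ValueError("puncta denser than the image can hold")
    rng = np.random.default_rng(seed)

    pos1 = np.column_stack([rng.uniform(0, image_shape[0], n_puncta),
                            rng.uniform(0, image_shape[1], n_puncta)])
    shared = rng.random(n_puncta) < coloc_fraction
    pos2 = pos1.copy()
    n_free = int((~shared).sum())
    if n_free:
        pos2[~shared] = np.column_stack([
            rng.uniform(0, image_shape[0], n_free),
            rng.uniform(0, image_shape[1], n_free)])

    ch1 = puncta_image(image_shape, pos1, amplitude, psf_sigma_px)
    ch2 = puncta_image(image_shape, pos2, amplitude, psf_sigma_px)
    if noise_sd > 0:
        ch1 = ch1 + noise_sd * rng.standard_normal(image_shape)
        ch2 = ch2 + noise_sd * rng.standard_normal(image_shape)
    return ch1, ch2
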