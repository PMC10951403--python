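"""Undecimated complex steerable pyramid in the frequency domain.

The image spectrum is partitioned by polar-separable masks: a raised-cosine
(in log2 radius) highpass/lowpass pair recursively splits octave annuli, and
each annulus is divided into ``K`` oriented lobes proportional to
``cos(theta - theta_k)^(K-1)`` restricted to a half plane, which makes the
oriented bands analytic (complex-valued, single-sided spectrum).  The masks
are normalized so that the squared two-sided responses tile the plane
exactly::

    H0^2 + sum_{s,k} (|M_sk(w)|^2 + |M_sk(-w)|^2) + L^2 = 1

which gives a machine-precision analysis->synthesis round trip and an exact
Parseval energy partition.  All bands are kept at full resolution (no
subsampling), so circularly shifting the input circularly shifts every band
and every derived magnitude map — spatial-average statistics computed from
this pyramid are exactly invariant to periodic translation.  Coarse scales
are analysed with correspondingly dilated correlation neighborhoods
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np

__all__ = ["SteerablePyramid", "build_pyramid", "reconstruct", "band_energies"]


def _radial_highpass(r: np.ndarray, r0: float) -> np.ndarray:
    """Raised-cosine highpass in log2 radius: 0 below r0/2, 1 above r0."""
    with np.errstate(divide="ignore"):
        lr = np.log2(np.maximum(r, 1e-12) / r0)
    h = np.where(lr >= 0, 1.0, np.where(lr <= -1, 0.0, np.cos(np.pi / 2 * (-lr))))
    return h


@lru_cache(maxsize=8)
def _masks(n: int, n_scales: int, n_orientations: int):
    """FFT-layout (origin at corner) masks: (highpass, bands[s][k], lowpass)."""
    k_ori = n_orientations
    w = 2 * np.pi * np.fft.fftfreq(n)
    wx, wy = np.meshgrid(w, w, indexing="ij")
    r = np.hypot(wx, wy)
    theta = np.arctan2(wy, wx)

    # angular lobes, normalized so the two-sided squared sum over k is 1
    norm = 1.0 / np.sqrt(k_ori * comb(2 * k_ori - 2, k_ori - 1) / 2 ** (2 * k_ori - 2))
    ang = []
    for k in range(k_ori):
        d = np.mod(theta - np.pi * k / k_ori + np.pi, 2 * np.pi) - np.pi
        a = np.where(np.abs(d) < np.pi / 2, np.cos(d) ** (k_ori - 1), 0.0) * norm
        ang.append(a)

    hi0 = _radial_highpass(r, np.pi)
    low_accum = np.sqrt(np.clip(1.0 - hi0**2, 0.0, 1.0))
    bands = []
    for s in range(1, n_scales + 1):
        hs = _radial_highpass(r, np.pi / 2**s)
        radial = low_accum * hs
        bands.append([radial * a for a in ang])
        low_accum = low_accum * np.sqrt(np.clip(1.0 - hs**2, 0.0, 1.0))
    return hi0, bands, low_accum


def _conj_reflect(a: np.ndarray) -> np.ndarray:
    """B[k] = conj(A[-k]) for FFT-layout arrays."""
    return np.conj(np.roll(a[::-1, ::-1], (1, 1), axis=(0, 1)))


@dataclass
class SteerablePyramid:
    """Oriented complex bands plus real highpass/lowpass residuals."""

    bands: dict  # (scale, orientation) -> complex ndarray, full resolution
    highpass: np.ndarray
    lowpass: np.ndarray
    n_scales: int
    n_orientations: int

    def band(self, scale: int, orientation: int) -> np.ndarray:
        """Oriented band; ``scale`` in 1..n_scales, ``orientation`` in 1..K."""
        return self.bands[(scale, orientation)]


def build_pyramid(
    image: np.ndarray, n_scales: int = 4, n_orientations: int = 4
) -> SteerablePyramid:
    """Decompose a square image into ``n_scales x n_orientations`` analytic
    oriented bands plus highpass and lowpass residuals."""
    img = np.asarray(getattr(image, "pixels", image), dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"image must be square 2-D, got {img.shape}")
    n = img.shape[0]
    if n % (2**n_scales) != 0:
        raise ValueError(f"side {n} not divisible by 2^{n_scales}")
    hi0, band_masks, low_mask = _masks(n, n_scales, n_orientations)
    spec = np.fft.fft2(img)
    bands = {}
    for s in range(1, n_scales + 1):
        for k in range(1, n_orientations + 1):
            bands[(s, k)] = np.fft.ifft2(spec * band_masks[s - 1][k - 1])
    return SteerablePyramid(
        bands=bands,
        highpass=np.fft.ifft2(spec * hi0).real,
        lowpass=np.fft.ifft2(spec * low_mask).real,
        n_scales=n_scales,
        n_orientations=n_orientations,
    )


def reconstruct(pyr: SteerablePyramid) -> np.ndarray:
    """Invert :func:`build_pyramid` (exact up to floating point)."""
    n = pyr.highpass.shape[0]
    hi0, band_masks, low_mask = _masks(n, pyr.n_scales, pyr.n_orientations)
    spec = np.fft.fft2(pyr.highpass) * hi0 + np.fft.fft2(pyr.lowpass) * low_mask
    for s in range(1, pyr.n_scales + 1):
        for k in range(1, pyr.n_orientations + 1):
            part = np.fft.fft2(pyr.bands[(s, k)]) * band_masks[s - 1][k - 1]
            spec = spec + part + _conj_reflect(part)
    return np.fft.ifft2(spec).real


def band_energies(pyr: SteerablePyramid) -> dict:
    """Mean-square energy per component.

    The oriented (analytic, single-sided) bands carry weight 2; the sum over
    all entries equals the mean-square of the input image exactly.
    """
    out = {
        "highpass": float(np.mean(pyr.highpass**2)),
        "lowpass": float(np.mean(pyr.lowpass**2)),
    }
    for key, b in pyr.bands.items():
        out[key] = 2.0 * float(np.mean(np.abs(b) ** 2))
    return out
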