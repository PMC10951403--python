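"""Portilla–Simoncelli texture statistics, per-group reduction, and
cluster geometry in stimulus-statistics space.

An image is decomposed with the undecimated complex steerable pyramid
(4 scales x 4 orientations by default) and summarized by four named groups:

``marginal``
    Skewness and kurtosis of the pixel histogram (2 values; population
    moment estimators, kurtosis not excess-corrected).
``spectral``
    Central 7x7 autocovariances of the lowpass image at each of the
    ``n_scales + 1`` levels (25 symmetry-deduplicated lags each, dilated by
    2^level), the 18 band magnitude means (16 oriented bands plus |highpass|
    and |lowpass|), the highpass variance, and skewness/kurtosis of the
    lowpass residual.
``linear_cc``
    Covariances of the real parts of oriented bands across orientations
    within each scale (6 pairs x 4 scales) and against the real/imaginary
    parts of the phase-doubled parent band across scales (4 x 4 x 2 x 3).
``energy_cc``
    Central 7x7 autocovariances of the band magnitudes (25 x 16), magnitude
    covariances across orientations within scale (6 x 4) and across scales
    (4 x 4 x 3).

With the defaults this inventory concatenates to exactly 740 coefficients.
All statistics are spatial averages over the full image with circular
boundary handling, hence exactly invariant to periodic translation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from sklearn.decomposition import PCA

from .pyramid import build_pyramid

__all__ = [
    "PSStatistics",
    "ReducedStats",
    "StatClusterGeometry",
    "compute_ps_statistics",
    "spectral_profile",
    "reduce_statistics",
    "stat_cluster_geometry",
    "bootstrap_distance_test",
    "sidak_level",
]

GROUPS = ("marginal", "spectral", "linear_cc", "energy_cc")


@dataclass
class PSStatistics:
    """Per-image coefficient vector split into the four named groups."""

    marginal: np.ndarray
    spectral: np.ndarray
    linear_cc: np.ndarray
    energy_cc: np.ndarray
    n_scales: int = 4
    n_orientations: int = 4
    neighborhood: int = 7

    @property
    def group_index(self) -> dict:
        """Map group name -> slice into the concatenated vector."""
        idx, start = {}, 0
        for g in GROUPS:
            n = len(getattr(self, g))
            idx[g] = slice(start, start + n)
            start += n
        return idx

    def concatenated(self) -> np.ndarray:
        return np.concatenate([getattr(self, g) for g in GROUPS])

    def __len__(self) -> int:
        return sum(len(getattr(self, g)) for g in GROUPS)


def _skew_kurt(x: np.ndarray) -> tuple[float, float]:
    """Population skewness and (plain, non-excess) kurtosis."""
    x = np.ravel(x)
    return (
        float(sp_stats.skew(x, bias=True)),
        float(sp_stats.kurtosis(x, fisher=False, bias=True)),
    )


def _autocov_lags(x: np.ndarray, half: int, dilation: int) -> np.ndarray:
    """Symmetry-deduplicated central autocovariance samples.

    Circular autocovariance via FFT, sampled on a (2*half+1)^2 grid of lags
    dilated by ``dilation``; the autocovariance is even, so only the center
    plus one half-plane of lags is kept: (M^2 + 1) / 2 values for M = 2*half+1.
    """
    xc = x - x.mean()
    n = x.shape[0]
    ac = np.fft.ifft2(np.abs(np.fft.fft2(xc)) ** 2).real / x.size
    vals = [ac[0, 0]]
    # half-plane: rows 1..half any column, plus row 0 columns 1..half
    for dj in range(1, half + 1):
        vals.append(ac[0, (dj * dilation) % n])
    for di in range(1, half + 1):
        for dj in range(-half, half + 1):
            vals.append(ac[(di * dilation) % n, (dj * dilation) % n])
    return np.array(vals)


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - a.mean()) * (b - b.mean())))


def compute_ps_statistics(
    img,
    n_scales: int = 4,
    n_orientations: int = 4,
    neighborhood: int = 7,
) -> PSStatistics:
    """Compute the four-group PS statistic vector of an image.

    ``neighborhood`` is the linear extent (in band samples) of the
    correlation neighborhood; it must be odd.  At scale ``s`` the lags are
    dilated by ``2**(s-1)`` to mirror the octave subsampling of the decimated
    construction.
    """
    if neighborhood % 2 != 1:
        raise ValueError("neighborhood must be odd")
    half = neighborhood // 2
    px = np.asarray(getattr(img, "pixels", img), dtype=float)
    pyr = build_pyramid(px, n_scales=n_scales, n_orientations=n_orientations)
    K, N = n_orientations, n_scales

    marginal = np.array(_skew_kurt(px))

    # progressively lowpassed images: level 0 = image minus highpass residual
    spec = np.fft.fft2(px)
    from .pyramid import _masks  # shared cached masks

    hi0, band_masks, low_mask = _masks(px.shape[0], N, K)
    low_accum = np.sqrt(np.clip(1.0 - hi0**2, 0.0, 1.0))
    lowpass_levels = [np.fft.ifft2(spec * low_accum).real]
    for s in range(1, N + 1):
        from .pyramid import _radial_highpass

        hs = _radial_highpass(
            np.hypot(
                *np.meshgrid(
                    2 * np.pi * np.fft.fftfreq(px.shape[0]),
                    2 * np.pi * np.fft.fftfreq(px.shape[0]),
                    indexing="ij",
                )
            ),
            np.pi / 2**s,
        )
        low_accum = low_accum * np.sqrt(np.clip(1.0 - hs**2, 0.0, 1.0))
        lowpass_levels.append(np.fft.ifft2(spec * low_accum).real)

    spectral = []
    for lev, lp in enumerate(lowpass_levels):
        spectral.append(_autocov_lags(lp, half, 2**lev))
    mags = {key: np.abs(b) for key, b in pyr.bands.items()}
    mag_means = [mags[(s, k)].mean() for s in range(1, N + 1) for k in range(1, K + 1)]
    mag_means += [np.abs(pyr.highpass).mean(), np.abs(pyr.lowpass).mean()]
    spectral.append(np.array(mag_means))
    spectral.append(np.array([pyr.highpass.var()]))
    spectral.append(np.array(_skew_kurt(pyr.lowpass)))
    spectral = np.concatenate(spectral)

    # phase-doubled parents for linear cross-scale statistics
    def _phase_double(b: np.ndarray) -> np.ndarray:
        m = np.abs(b)
        return np.where(m > 1e-300, b * b / np.maximum(m, 1e-300), 0.0)

    linear = []
    for s in range(1, N + 1):
        re = [pyr.band(s, k).real for k in range(1, K + 1)]
        for i in range(K):
            for j in range(i + 1, K):
                linear.append(_cov(re[i], re[j]))
    for s in range(1, N):
        parents = [_phase_double(pyr.band(s + 1, k)) for k in range(1, K + 1)]
        for i in range(K):
            child = pyr.band(s, i + 1).real
            for p in parents:
                linear.append(_cov(child, p.real))
                linear.append(_cov(child, p.imag))
    linear = np.array(linear)

    energy = []
    for s in range(1, N + 1):
        for k in range(1, K + 1):
            energy.append(_autocov_lags(mags[(s, k)], half, 2 ** (s - 1)))
    cross = []
    for s in range(1, N + 1):
        ms = [mags[(s, k)] for k in range(1, K + 1)]
        for i in range(K):
            for j in range(i + 1, K):
                cross.append(_cov(ms[i], ms[j]))
    for s in range(1, N):
        for i in range(K):
            for j in range(K):
                cross.append(_cov(mags[(s, i + 1)], mags[(s + 1, j + 1)]))
    energy.append(np.array(cross))
    energy = np.concatenate(energy)

    return PSStatistics(
        marginal=marginal,
        spectral=spectral,
        linear_cc=linear,
        energy_cc=energy,
        n_scales=N,
        n_orientations=K,
        neighborhood=neighborhood,
    )


DEFAULT_SF_EDGES = np.arange(0.01, 0.5 + 1e-9, 0.02)
DEFAULT_ORI_EDGES = np.arange(0.0, 180.0 + 1e-9, 15.0)


def spectral_profile(
    img,
    sf_edges: np.ndarray | None = None,
    ori_edges_deg: np.ndarray | None = None,
    normalize: bool = False,
    squared: bool = False,
):
    """Average Fourier amplitude in spatial-frequency and orientation slices.

    Returns ``(sf_amplitudes, ori_amplitudes)``; bins with no FFT samples are
    returned as NaN.  ``squared=True`` averages power instead of amplitude;
    ``normalize=True`` scales each curve to peak 1.
    """
    sf_edges = DEFAULT_SF_EDGES if sf_edges is None else np.asarray(sf_edges)
    ori_edges_deg = DEFAULT_ORI_EDGES if ori_edges_deg is None else np.asarray(ori_edges_deg)
    px = np.asarray(getattr(img, "pixels", img), dtype=float)
    ppd = getattr(img, "pixels_per_degree", 1.0)
    n = px.shape[0]
    amp = np.abs(np.fft.fft2(px))
    if squared:
        amp = amp**2
    amp[0, 0] = 0.0
    f = np.fft.fftfreq(n)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    r_cpd = np.hypot(fx, fy) * ppd
    ori = np.mod(np.degrees(np.arctan2(fy, fx)), 180.0)

    def _binned(coord, edges, mask_extra=None):
        out = np.full(len(edges) - 1, np.nan)
        for i in range(len(edges) - 1):
            m = (coord >= edges[i]) & (coord < edges[i + 1])
            if mask_extra is not None:
                m &= mask_extra
            if m.any():
                out[i] = amp[m].mean()
        return out

    sf_prof = _binned(r_cpd, sf_edges)
    in_band = (r_cpd >= sf_edges[0]) & (r_cpd < sf_edges[-1])
    ori_prof = _binned(ori, ori_edges_deg, mask_extra=in_band)
    if np.isnan(sf_prof).any() or np.isnan(ori_prof).any():
        warnings.warn("empty spectral bins flagged as NaN (image too small for bin grid)")
    if normalize:
        sf_prof = sf_prof / np.nanmax(sf_prof)
        ori_prof = ori_prof / np.nanmax(ori_prof)
    return sf_prof, ori_prof


@dataclass
class ReducedStats:
    """Images x features matrix of per-group PCA-reduced, re-z-scored stats."""

    matrix: np.ndarray
    group_blocks: dict  # group -> slice of columns
    pca_models: dict  # group -> dict(pca, kept_cols, col_mean, col_sd, score_mean, score_sd, ev)
    explained_variance: dict  # group -> fraction retained (marginal: 1.0)
    low_variance_flagged: list = field(default_factory=list)

    def group(self, name: str) -> np.ndarray:
        return self.matrix[:, self.group_blocks[name]]

    def features(self, n_pcs: int = 2) -> np.ndarray:
        """First ``n_pcs`` columns of every group (marginal contributes its
        two raw dimensions) — the encoding-model design matrix."""
        cols = []
        for g in GROUPS:
            block = self.matrix[:, self.group_blocks[g]]
            cols.append(block[:, : min(n_pcs, block.shape[1])])
        return np.hstack(cols)

    def project(self, stats: list[PSStatistics]) -> np.ndarray:
        """Project new images with the stored loadings and scalings."""
        rows = []
        for g in GROUPS:
            raw = np.array([getattr(s, g) for s in stats])
            m = self.pca_models[g]
            z = (raw[:, m["kept_cols"]] - m["col_mean"]) / m["col_sd"]
            scores = z if m["pca"] is None else m["pca"].transform(z) * m["sign"]
            rows.append((scores - m["score_mean"]) / m["score_sd"])
        return np.hstack(rows)


def _fix_pca_signs(pca: PCA) -> np.ndarray:
    """Flip components so the largest-magnitude loading is positive."""
    comp = pca.components_
    signs = np.sign(comp[np.arange(comp.shape[0]), np.argmax(np.abs(comp), axis=1)])
    signs[signs == 0] = 1.0
    pca.components_ = comp * signs[:, None]
    return signs


def reduce_statistics(
    stats: list[PSStatistics],
    max_components: int = 8,
    min_explained: float = 0.70,
) -> ReducedStats:
    """Per-group z-score -> PCA (<= ``max_components``) -> re-z-score.

    The marginal group (two raw dimensions) bypasses PCA and is only
    z-scored.  Zero-variance coefficient columns are dropped with a warning
    before z-scoring.  Groups whose retained explained variance falls below
    ``min_explained`` are flagged (not an error).
    """
    if len(stats) < 2:
        raise ValueError("need at least two images")
    blocks, models, evs, flagged = {}, {}, {}, []
    cols, start = [], 0
    for g in GROUPS:
        raw = np.array([getattr(s, g) for s in stats], dtype=float)
        sd = raw.std(axis=0)
        kept = np.flatnonzero(sd > 1e-12)
        if len(kept) < raw.shape[1]:
            warnings.warn(
                f"group '{g}': dropped {raw.shape[1] - len(kept)} zero-variance columns"
            )
        col_mean, col_sd = raw[:, kept].mean(axis=0), raw[:, kept].std(axis=0)
        z = (raw[:, kept] - col_mean) / col_sd
        if g == "marginal":
            pca, scores, ev, sign = None, z, 1.0, 1.0
        else:
            ncomp = min(max_components, z.shape[0] - 1, z.shape[1])
            pca = PCA(n_components=ncomp, svd_solver="full")
            scores = pca.fit_transform(z)
            sign = _fix_pca_signs(pca)
            scores = scores * sign
            ev = float(pca.explained_variance_ratio_.sum())
            if ev < min_explained:
                flagged.append(g)
        score_mean, score_sd = scores.mean(axis=0), scores.std(axis=0)
        score_sd = np.where(score_sd > 1e-12, score_sd, 1.0)
        zs = (scores - score_mean) / score_sd
        blocks[g] = slice(start, start + zs.shape[1])
        start += zs.shape[1]
        cols.append(zs)
        models[g] = dict(
            pca=pca, kept_cols=kept, col_mean=col_mean, col_sd=col_sd,
            score_mean=score_mean, score_sd=score_sd, sign=sign,
        )
        evs[g] = ev
    if flagged:
        warnings.warn(f"groups below {min_explained:.0%} retained variance: {flagged}")
    return ReducedStats(
        matrix=np.hstack(cols),
        group_blocks=blocks,
        pca_models=models,
        explained_variance=evs,
        low_variance_flagged=flagged,
    )


@dataclass
class StatClusterGeometry:
    """Centroids, radii r=(sx+sy)/2 and radius-normalized pair distances."""

    labels: list
    centroids: dict  # label -> (mx, my)
    radii: dict  # label -> r
    distances: dict  # (label_a, label_b) -> normalized distance


def _cluster_stats(points: np.ndarray):
    mu = points.mean(axis=0)
    sd = points.std(axis=0)
    return mu, float(sd.mean())


def stat_cluster_geometry(points: np.ndarray, labels) -> StatClusterGeometry:
    """Cluster geometry in a 2-D statistics subspace.

    Radius is the mean of the per-axis standard deviations; the inter-cluster
    distance is the Euclidean centroid distance divided by the mean of the two
    radii, making it invariant to global rescaling of the space.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be n x 2 (a 2-D statistics subspace)")
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    centroids, radii = {}, {}
    for name in names:
        pts = points[labels == name]
        if len(pts) < 2:
            raise ValueError(f"cluster '{name}' has fewer than 2 points: radius undefined")
        mu, r = _cluster_stats(pts)
        centroids[name], radii[name] = tuple(mu), r
    distances = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = float(np.linalg.norm(np.subtract(centroids[a], centroids[b])))
            distances[(a, b)] = d / ((radii[a] + radii[b]) / 2.0)
    return StatClusterGeometry(names, centroids, radii, distances)


def sidak_level(alpha: float, n_comparisons: int) -> float:
    """Per-comparison confidence level under Sidak correction."""
    return (1.0 - alpha) ** (1.0 / n_comparisons)


def bootstrap_distance_test(
    points: np.ndarray,
    labels,
    n_boot: int = 1000,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    rng_seed: int = 0,
) -> dict:
    """Bootstrap CIs for normalized pair distances, with a permutation null.

    Points are resampled with replacement within each cluster; per-pair CIs
    are taken at the Sidak-adjusted level ``(1 - alpha)^(1/m)``.  A pair is
    flagged ``separated`` when its bootstrap CI lower bound exceeds the
    Sidak-level upper quantile of a label-permutation null of the same
    statistic (identical clusters are therefore never flagged).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    base = stat_cluster_geometry(points, labels)
    pairs = list(base.distances)
    m = n_comparisons if n_comparisons is not None else len(pairs)
    level = sidak_level(alpha, m)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    rng = np.random.default_rng(rng_seed)
    out = {}
    for a, b in pairs:
        pa, pb = points[labels == a], points[labels == b]
        boot = np.empty(n_boot)
        null = np.empty(n_boot)
        pooled = np.vstack([pa, pb])
        for i in range(n_boot):
            ra = pa[rng.integers(0, len(pa), len(pa))]
            rb = pb[rng.integers(0, len(pb), len(pb))]
            (mua, r_a), (mub, r_b) = _cluster_stats(ra), _cluster_stats(rb)
            boot[i] = np.linalg.norm(mua - mub) / ((r_a + r_b) / 2)
            perm = pooled[rng.permutation(len(pooled))]
            (mua, r_a), (mub, r_b) = (
                _cluster_stats(perm[: len(pa)]),
                _cluster_stats(perm[len(pa) :]),
            )
            null[i] = np.linalg.norm(mua - mub) / ((r_a + r_b) / 2)
        ci = (float(np.percentile(boot, lo_q)), float(np.percentile(boot, hi_q)))
        null_hi = float(np.percentile(null, 100 * level))
        out[(a, b)] = dict(
            distance=base.distances[(a, b)],
            ci=ci,
            ci_level=level,
            null_upper=null_hi,
            separated=bool(ci[0] > null_hi),
        )
    return out
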