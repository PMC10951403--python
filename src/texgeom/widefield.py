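"""Mesoscale (widefield) preprocessing and texture-selectivity analysis.

The processing chain is: per-pixel conversion to relative fluorescence
(dF/F, linear-trend normalized), hemodynamic correction by regressing the
low-passed calcium-independent (violet) channel out of the calcium-dependent
(blue) channel, trial splitting into a seven-axis tensor, peak-response and
pixelwise significance maps, retinotopic ROI carving, and standardized
texture-scramble discriminability (d') with a pre-stimulus null band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "HemoFit",
    "TrialTensor",
    "AreaROI",
    "channel_dff",
    "hemodynamic_correct",
    "split_trials",
    "peak_response_map",
    "pixel_significance_map",
    "roi_from_retinotopy",
    "area_modulated_fraction",
    "area_dprime",
    "dprime",
    "field_gradient_dprime",
]


def dprime(a: np.ndarray, b: np.ndarray, axis=None) -> np.ndarray:
    """Standardized mean difference: (mean_a - mean_b) / sqrt((var_a+var_b)/2).

    Population variances (ddof=0).  Raises on zero pooled variance.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = 0.5 * (a.var(axis=axis) + b.var(axis=axis))
    if np.any(pooled == 0):
        raise ZeroDivisionError("zero pooled variance: d' undefined")
    return (a.mean(axis=axis) - b.mean(axis=axis)) / np.sqrt(pooled)


def channel_dff(F: np.ndarray, intercept_tol: float = 1e-6):
    """Per-pixel dF/F = (F - (a*t + b)) / b from a linear trend fit.

    ``F`` has time on the first axis (frames, ...).  Pixels whose fitted
    intercept magnitude falls below ``intercept_tol`` times the series scale
    are masked to NaN and reported.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    T = F.shape[0]
    flat = F.reshape(T, -1)
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    slope = (tc @ flat) / (tc @ tc)
    intercept_mid = flat.mean(axis=0)  # value of the trend at t.mean()
    b = intercept_mid - slope * t.mean()  # intercept at t=0
    trend = t[:, None] * slope[None] + b[None]
    scale = np.maximum(np.abs(flat).max(axis=0), 1.0)
    bad = np.abs(b) < intercept_tol * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (flat - trend) / b[None]
    dff[:, bad] = np.nan
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pixels masked (near-zero dF/F intercept)")
    return dff.reshape(F.shape)


@dataclass
class HemoFit:
    """Per-pixel regression of low-passed violet dF/F onto blue dF/F."""

    c: np.ndarray
    d: np.ndarray
    cutoff_hz: float
    order: int


def hemodynamic_correct(
    blue_dff: np.ndarray,
    violet_dff: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = 5.0,
    order: int = 6,
):
    """Remove the calcium-independent component from the blue channel.

    The violet channel is low-pass filtered (Butterworth of the given order,
    applied forward-backward for zero phase), linearly fitted per pixel to the
    blue channel, and the fitted component subtracted::

        corrected = blue - (c * lowpass(violet) + d)

    Returns ``(corrected, HemoFit)``.
    """
    blue = np.asarray(blue_dff, float)
    violet = np.asarray(violet_dff, float)
    if blue.shape != violet.shape:
        raise ValueError("channel shapes differ")
    if cutoff_hz >= rate_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    sos = butter(order, cutoff_hz, fs=rate_hz, output="sos")
    vlp = sosfiltfilt(sos, violet, axis=0)
    if not np.all(np.isfinite(vlp)):
        n_bad = int((~np.isfinite(vlp)).any(axis=0).sum())
        raise FloatingPointError(f"low-pass filter unstable on {n_bad} pixels")
    T = blue.shape[0]
    bf, vf = blue.reshape(T, -1), vlp.reshape(T, -1)
    vm, bm = vf.mean(axis=0), bf.mean(axis=0)
    vc = vf - vm
    var_v = (vc**2).mean(axis=0)
    cov = (vc * (bf - bm)).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(var_v > 0, cov / np.where(var_v > 0, var_v, 1.0), 0.0)
    d = bm - c * vm
    corrected = bf - (c[None] * vf + d[None])
    shape = blue.shape[1:]
    return corrected.reshape(blue.shape), HemoFit(
        c=c.reshape(shape), d=d.reshape(shape), cutoff_hz=cutoff_hz, order=order
    )


@dataclass
class TrialTensor:
    """Trial-aligned responses.

    ``values`` is indexed ``[stim_class, family, exemplar, (rotation,) repeat,
    ...space..., frame]`` with frame 0 aligned to stimulus onset;
    ``time_ms`` gives each frame's time relative to onset.  ``blanks`` holds
    blank trials as ``[trial, ...space..., frame]``.
    """

    values: np.ndarray
    time_ms: np.ndarray
    classes: list
    families: list
    blanks: np.ndarray | None = None
    has_rotation_axis: bool = False
    meta: dict = field(default_factory=dict)

    def window_mask(self, window_ms) -> np.ndarray:
        return (self.time_ms >= window_ms[0]) & (self.time_ms <= window_ms[1])

    def repeat_averaged(self) -> np.ndarray:
        axis = 4 if self.has_rotation_axis else 3
        return self.values.mean(axis=axis)


def split_trials(
    movie: np.ndarray,
    schedule,
    rate_hz: float,
    window_ms: tuple[float, float] = (-500.0, 1000.0),
    with_rotation_axis: bool = False,
) -> TrialTensor:
    """Cut a continuous recording into an onset-aligned trial tensor.

    ``movie`` has time on the first axis (frames, ...space...).  Trials whose
    window would run off either end of the movie are dropped with a warning.
    The frame at time 0 is exactly the movie frame at the scheduled onset.
    """
    movie = np.asarray(movie)
    onsets = schedule.onset_frames(rate_hz)
    i0 = int(np.floor(window_ms[0] / 1000.0 * rate_hz))
    i1 = int(np.ceil(window_ms[1] / 1000.0 * rate_hz))
    n_frames_trial = i1 - i0 + 1
    time_ms = (np.arange(i0, i1 + 1)) / rate_hz * 1000.0

    tr = schedule.trials
    ok = (onsets + i0 >= 0) & (onsets + i1 < movie.shape[0])
    if not ok.all():
        warnings.warn(f"dropped {int((~ok).sum())} trials truncated at movie edges")

    classes = ["texture", "scramble"]
    families = sorted(tr.loc[~tr.is_blank, "family"].unique().tolist())
    stim = tr[~tr.is_blank]
    n_ex = int(stim.exemplar_id.max()) + 1
    rots = sorted(stim.rotation_deg.unique().tolist())
    n_rep = (
        stim.groupby(["stim_class", "family", "exemplar_id", "rotation_deg"])
        .size()
        .max()
    )
    space = movie.shape[1:]
    if with_rotation_axis:
        shape = (2, len(families), n_ex, len(rots), n_rep, *space, n_frames_trial)
    else:
        shape = (2, len(families), n_ex * len(rots), n_rep, *space, n_frames_trial)
    values = np.full(shape, np.nan, dtype=float)
    counts = {}
    blanks = []
    for i, row in enumerate(tr.itertuples(index=False)):
        if not ok[i]:
            continue
        seg = np.moveaxis(movie[onsets[i] + i0 : onsets[i] + i1 + 1], 0, -1)
        if row.is_blank:
            blanks.append(seg)
            continue
        ci = classes.index(row.stim_class)
        fi = families.index(row.family)
        ri = rots.index(row.rotation_deg)
        if with_rotation_axis:
            key = (ci, fi, row.exemplar_id, ri)
        else:
            key = (ci, fi, row.exemplar_id * len(rots) + ri)
        rep = counts.get(key, 0)
        counts[key] = rep + 1
        values[key + (rep,)] = seg
    return TrialTensor(
        values=values,
        time_ms=time_ms,
        classes=classes,
        families=families,
        blanks=np.array(blanks) if blanks else None,
        has_rotation_axis=with_rotation_axis,
        meta=dict(rate_hz=rate_hz, window_ms=tuple(window_ms), rotations=rots),
    )


def peak_response_map(tensor: TrialTensor, window_ms=(200.0, 400.0)) -> np.ndarray:
    """Mean over classes, families, exemplars, repeats and window frames."""
    m = tensor.window_mask(window_ms)
    vals = tensor.values[..., m]
    # average over everything except space
    space_ndim = vals.ndim - 5 - (1 if tensor.has_rotation_axis else 0)
    lead_axes = tuple(range(vals.ndim - space_ndim - 1))
    return vals.mean(axis=lead_axes + (vals.ndim - 1,))


def pixel_significance_map(
    tensor: TrialTensor,
    rng_seed: int = 0,
    post_window_ms=(200.0, 400.0),
    pre_window_ms=(-350.0, -100.0),
):
    """Paired t-test of texture-scramble differences, post vs pre stimulus.

    Repeat-averaged exemplar responses are differenced against a seeded
    random pairing of scramble exemplars within each family; the pixelwise
    difference distributions (pooled across families and exemplars) in the
    post-stimulus window are tested against the same construction in the
    pre-stimulus window with a two-sided paired t-test.

    Returns ``(p_map, pairing)``.
    """
    rng = np.random.default_rng(rng_seed)
    avg = tensor.repeat_averaged()  # [class, family, exemplar, ...space, frame]
    post = avg[..., tensor.window_mask(post_window_ms)].mean(axis=-1)
    pre = avg[..., tensor.window_mask(pre_window_ms)].mean(axis=-1)
    n_fam, n_ex = avg.shape[1], avg.shape[2]
    pairing = {f: rng.permutation(n_ex) for f in range(n_fam)}

    def _diffs(resp):
        out = []
        for f in range(n_fam):
            out.append(resp[0, f] - resp[1, f][pairing[f]])
        return np.concatenate(out, axis=0)  # [family*exemplar, ...space]

    d_post, d_pre = _diffs(post), _diffs(pre)
    res = sp_stats.ttest_rel(d_post, d_pre, axis=0)
    p = np.asarray(res.pvalue)
    p = np.where(np.isnan(p), 1.0, p)
    return p, pairing


@dataclass
class AreaROI:
    mask: np.ndarray
    label: str
    az_bounds: tuple
    el_bounds: tuple


def roi_from_retinotopy(
    azimuth: np.ndarray,
    elevation: np.ndarray,
    az_bounds: tuple[float, float] = (-10.0, 30.0),
    el_bounds: tuple[float, float] = (-30.0, 30.0),
    area_mask: np.ndarray | None = None,
    label: str = "",
) -> AreaROI:
    """Pixels whose retinotopic coordinates fall inside the given bounds,
    intersected with an area mask."""
    m = (
        (azimuth >= min(az_bounds)) & (azimuth <= max(az_bounds))
        & (elevation >= min(el_bounds)) & (elevation <= max(el_bounds))
    )
    if area_mask is not None:
        m = m & area_mask
    if not m.any():
        raise ValueError("empty ROI: retinotopic bounds do not intersect the area")
    return AreaROI(mask=m, label=label, az_bounds=tuple(az_bounds), el_bounds=tuple(el_bounds))


def area_modulated_fraction(p_map: np.ndarray, roi: AreaROI, alpha: float = 0.01) -> float:
    """Fraction of ROI pixels significantly modulated (p < alpha)."""
    return float((p_map[roi.mask] < alpha).mean())


def _class_exemplar_values(tensor: TrialTensor, roi_mask, window_ms):
    """Per-exemplar responses averaged over repeats, ROI pixels and window."""
    avg = tensor.repeat_averaged()  # [class, family, exemplar, H, W, frame]
    win = avg[..., tensor.window_mask(window_ms)].mean(axis=-1)
    vals = win[..., roi_mask].mean(axis=-1)  # [class, family, exemplar]
    return vals.reshape(2, -1)  # pooled exemplars across families


def area_dprime(
    tensor: TrialTensor,
    roi: AreaROI,
    window_ms=(200.0, 400.0),
    null_window_ms=(-300.0, 0.0),
    n_null: int = 200,
    rng_seed: int = 0,
) -> dict:
    """Texture-scramble d' of an area ROI with a pre-stimulus null band.

    Exemplar responses (pooled across families: 80 texture vs 80 scramble
    values at the default design) enter the standardized mean difference.
    The null distribution re-labels the pre-stimulus exemplar values at
    random; its 5th/95th percentiles are reported.
    """
    vals = _class_exemplar_values(tensor, roi.mask, window_ms)
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 exemplars per class")
    d = float(dprime(vals[0], vals[1]))
    pre = _class_exemplar_values(tensor, roi.mask, null_window_ms)
    pooled = np.concatenate([pre[0], pre[1]])
    n = len(pre[0])
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_null)
    for i in range(n_null):
        perm = rng.permutation(pooled)
        null[i] = dprime(perm[:n], perm[n:])
    return dict(
        dprime=d,
        null_dprime=float(dprime(pre[0], pre[1])),
        null_band=(float(np.percentile(null, 5)), float(np.percentile(null, 95))),
        n_exemplars=vals.shape[1],
    )


def field_gradient_dprime(
    dprime_map: np.ndarray,
    azimuth: np.ndarray,
    elevation: np.ndarray,
    area_mask: np.ndarray | None = None,
) -> dict:
    """Upper vs lower and left vs right visual-field d' comparisons.

    Quadrants follow the full-field mapping convention: upper = elevation in
    [0, +40] with azimuth in [-20, +20]; lower mirrors it; left/right swap the
    roles of the two maps.  Two-sided Welch t-tests over pixels.
    """
    base = np.ones_like(dprime_map, bool) if area_mask is None else area_mask

    def _sel(el_rng, az_rng):
        m = (
            base
            & (elevation >= el_rng[0]) & (elevation <= el_rng[1])
            & (azimuth >= az_rng[0]) & (azimuth <= az_rng[1])
        )
        return dprime_map[m]

    upper, lower = _sel((0, 40), (-20, 20)), _sel((-40, 0), (-20, 20))
    left, right = _sel((-20, 20), (-40, 0)), _sel((-20, 20), (0, 40))
    t_ud = sp_stats.ttest_ind(upper, lower, equal_var=False)
    t_lr = sp_stats.ttest_ind(left, right, equal_var=False)
    return dict(
        upper_mean=float(upper.mean()), lower_mean=float(lower.mean()),
        left_mean=float(left.mean()), right_mean=float(right.mean()),
        p_upper_lower=float(t_ud.pvalue), p_left_right=float(t_lr.pvalue),
    )
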