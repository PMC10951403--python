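"""Single-cell (two-photon) preprocessing, screening, d' metrics, and the
image-statistics encoding model with variance partitioning.

Traces are neuropil-corrected (``Fc = Fs - r * Fn``), baselined on the first
seconds of the recording, detrended and expressed as dF/F in percent.
Trial responses are frame-zero corrected (pre-stimulus mean subtracted) and
summarized in a response window.  Cells are screened with a stimulus-vs-blank
discriminability criterion, characterized with a texture-scramble d', and
modelled as a ridge-regularized linear readout of reduced image statistics
with cross-validated explained variance, permutation significance thresholds,
per-group weight sums, and unique (leave-one-group-out) explained variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend as _sp_detrend

from .widefield import dprime as _eq_dprime

__all__ = [
    "CellTraces",
    "CellResponseTable",
    "EncodingModelFit",
    "UniqueEVResult",
    "preprocess_traces",
    "frame_zero_tensor",
    "select_responsive",
    "cell_texscr_dprime",
    "response_table",
    "align_features",
    "ridge_weights",
    "fit_encoding_model",
    "permutation_ev_threshold",
    "group_weight_sums",
    "unique_ev",
]

DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 13)
FEATURE_GROUPS = ("marginal", "spectral", "linear_cc", "energy_cc")


@dataclass
class CellTraces:
    """Neuropil-corrected traces and their dF/F (%) representation."""

    dff_pct: np.ndarray  # cells x frames
    corrected: np.ndarray  # Fc = Fs - r * Fn
    baseline: np.ndarray  # F_mu per cell
    rate_hz: float
    r: float
    valid: np.ndarray  # cells with positive baseline


def preprocess_traces(
    soma: np.ndarray,
    neuropil: np.ndarray,
    rate_hz: float,
    r: float = 0.7,
    baseline_s: float = 5.0,
) -> CellTraces:
    """Neuropil-correct, baseline, detrend and scale to dF/F (%).

    ``Fc = Fs - r * Fn``; the baseline ``F_mu`` is the mean of ``Fc`` over the
    first ``baseline_s`` seconds (pre-stimulus); ``Fc`` is linearly detrended
    to zero mean and dF/F = 100 * Fd / F_mu.  Cells with non-positive
    baseline are masked (dF/F set to NaN) with a diagnostic warning.
    """
    soma = np.asarray(soma, float)
    neuropil = np.asarray(neuropil, float)
    if soma.shape != neuropil.shape:
        raise ValueError("soma and neuropil shapes differ")
    fc = soma - r * neuropil
    n_base = max(1, int(round(baseline_s * rate_hz)))
    fmu = fc[:, :n_base].mean(axis=1)
    valid = fmu > 0
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} cells masked (non-positive baseline)")
    fd = _sp_detrend(fc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = 100.0 * fd / fmu[:, None]
    dff[~valid] = np.nan
    return CellTraces(
        dff_pct=dff, corrected=fc, baseline=fmu, rate_hz=rate_hz, r=r, valid=valid
    )


@dataclass
class TrialResponses:
    """Frame-zero-corrected per-trial segments.

    ``stim`` is ``[trial, cell, frame]`` for stimulus trials with a metadata
    frame ``index`` (family, stim_class, exemplar_id, rotation_deg, repeat);
    ``blanks`` is ``[trial, cell, frame]``.
    """

    stim: np.ndarray
    index: pd.DataFrame
    blanks: np.ndarray
    time_ms: np.ndarray
    rate_hz: float

    def window_mask(self, window_ms) -> np.ndarray:
        return (self.time_ms >= window_ms[0]) & (self.time_ms <= window_ms[1])


def frame_zero_tensor(
    traces: CellTraces | np.ndarray,
    schedule,
    rate_hz: float | None = None,
    window_ms=(-500.0, 1000.0),
    pre_ms=(-500.0, 0.0),
) -> TrialResponses:
    """Cut dF/F into onset-aligned trials and subtract each trial's
    pre-stimulus mean ("frame-zero correction")."""
    if isinstance(traces, CellTraces):
        dff, rate = traces.dff_pct, traces.rate_hz
    else:
        dff = np.asarray(traces, float)
        if rate_hz is None:
            raise ValueError("rate_hz required for raw arrays")
        rate = rate_hz
    onsets = schedule.onset_frames(rate)
    i0 = int(np.floor(window_ms[0] / 1000.0 * rate))
    i1 = int(np.ceil(window_ms[1] / 1000.0 * rate))
    time_ms = np.arange(i0, i1 + 1) / rate * 1000.0
    # strictly pre-stimulus: the onset frame itself is excluded
    pre_mask = (time_ms >= pre_ms[0]) & (time_ms < pre_ms[1])
    tr = schedule.trials
    ok = (onsets + i0 >= 0) & (onsets + i1 < dff.shape[1])
    if not ok.all():
        warnings.warn(f"dropped {int((~ok).sum())} trials truncated at trace edges")
    stim_segs, rows, blank_segs = [], [], []
    rep_count: dict = {}
    for i, row in enumerate(tr.itertuples(index=False)):
        if not ok[i]:
            continue
        seg = dff[:, onsets[i] + i0 : onsets[i] + i1 + 1]
        seg = seg - seg[:, pre_mask].mean(axis=1, keepdims=True)
        if row.is_blank:
            blank_segs.append(seg)
        else:
            key = (row.family, row.stim_class, row.exemplar_id, row.rotation_deg)
            rep = rep_count.get(key, 0)
            rep_count[key] = rep + 1
            rows.append((*key, rep))
            stim_segs.append(seg)
    index = pd.DataFrame(
        rows, columns=["family", "stim_class", "exemplar_id", "rotation_deg", "repeat"]
    )
    return TrialResponses(
        stim=np.array(stim_segs),
        index=index,
        blanks=np.array(blank_segs),
        time_ms=time_ms,
        rate_hz=rate,
    )


def select_responsive(
    trials: TrialResponses,
    d_min: float = 1.0,
    dff_min_pct: float = 6.0,
    window_ms=(250.0, 500.0),
):
    """Stimulus-responsive screen: per-exemplar d'_stim vs blanks.

    For every cell and stimulus exemplar, responses in ``window_ms`` are
    averaged per trial; ``d'_stim = (mu_stim - mu_blank) / (sigma_stim +
    sigma_blank)`` across repeats.  A cell is kept iff its maximum d'_stim is
    >= ``d_min`` AND its maximum repeat-averaged response is >=
    ``dff_min_pct``.  Returns ``(mask, dprime_table)`` where the table is
    cells x stimuli (NaN where the denominator vanished).
    """
    m = trials.window_mask(window_ms)
    resp = trials.stim[..., m].mean(axis=-1)  # trial x cell
    blank = trials.blanks[..., m].mean(axis=-1)  # trial x cell
    if blank.shape[0] < 2:
        raise ValueError("need at least 2 blank trials")
    mu_b, sd_b = blank.mean(axis=0), blank.std(axis=0)
    keys = trials.index[["family", "stim_class", "exemplar_id", "rotation_deg"]]
    groups = keys.groupby(list(keys.columns), sort=True).indices
    n_cells = resp.shape[1]
    dp = np.full((n_cells, len(groups)), np.nan)
    mean_resp = np.full((n_cells, len(groups)), np.nan)
    for j, (key, idx) in enumerate(sorted(groups.items())):
        if len(idx) < 2:
            raise ValueError(f"exemplar {key} has fewer than 2 repeats")
        r = resp[idx]  # repeats x cells
        mu_s, sd_s = r.mean(axis=0), r.std(axis=0)
        denom = sd_s + sd_b
        zero = denom == 0
        if zero.any():
            warnings.warn(f"exemplar {key}: zero-variance denominator for {int(zero.sum())} cells")
        dp[:, j] = np.where(zero, np.nan, (mu_s - mu_b) / np.where(zero, 1.0, denom))
        mean_resp[:, j] = mu_s
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mask = (np.nanmax(dp, axis=1) >= d_min) & (np.nanmax(mean_resp, axis=1) >= dff_min_pct)
    return mask, dp


@dataclass
class CellResponseTable:
    """Cells x stimuli mean responses in the response window."""

    values: np.ndarray  # cells x stimuli
    stimuli: pd.DataFrame  # family, stim_class, exemplar_id, rotation_deg
    window_ms: tuple = (250.0, 500.0)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def response_table(trials: TrialResponses, window_ms=(250.0, 500.0)) -> CellResponseTable:
    """Average over repeats and the response window into a cells x stimuli table."""
    m = trials.window_mask(window_ms)
    resp = trials.stim[..., m].mean(axis=-1)  # trial x cell
    keys = trials.index[["family", "stim_class", "exemplar_id", "rotation_deg"]]
    groups = keys.groupby(list(keys.columns), sort=True).indices
    stim_rows, cols = [], []
    for key, idx in sorted(groups.items()):
        stim_rows.append(key)
        cols.append(resp[idx].mean(axis=0))
    return CellResponseTable(
        values=np.array(cols).T,
        stimuli=pd.DataFrame(
            stim_rows, columns=["family", "stim_class", "exemplar_id", "rotation_deg"]
        ),
        window_ms=tuple(window_ms),
    )


def cell_texscr_dprime(
    table: CellResponseTable, per_family: bool = False, pool_rotations: bool = True
):
    """Texture-scramble d' per cell: standardized mean difference across
    exemplar (and rotation) response values.

    Returns an array ``cells`` (pooled) or a DataFrame ``cells x families``.
    """
    is_tex = (table.stimuli.stim_class == "texture").to_numpy()
    if not pool_rotations:
        keep = (table.stimuli.rotation_deg == 0).to_numpy()
    else:
        keep = np.ones(len(table.stimuli), bool)
    if per_family:
        out = {}
        for fam in sorted(table.stimuli.family.unique()):
            f = (table.stimuli.family == fam).to_numpy() & keep
            out[fam] = _eq_dprime(
                table.values[:, f & is_tex], table.values[:, f & ~is_tex], axis=1
            )
        return pd.DataFrame(out)
    return _eq_dprime(table.values[:, keep & is_tex], table.values[:, keep & ~is_tex], axis=1)


# --------------------------------------------------------------------------
# encoding model
# --------------------------------------------------------------------------

def align_features(
    table: CellResponseTable, features: np.ndarray, stim_index: pd.DataFrame
) -> np.ndarray:
    """Reorder feature rows to match ``table.stimuli``.

    ``stim_index`` carries the family / stim_class / exemplar_id /
    rotation_deg keys of the feature rows (e.g. an image-set manifest).
    """
    key_cols = ["family", "stim_class", "exemplar_id", "rotation_deg"]
    lookup = {tuple(r): i for i, r in enumerate(stim_index[key_cols].to_numpy())}
    rows = [lookup[tuple(r)] for r in table.stimuli[key_cols].to_numpy()]
    return np.asarray(features, float)[rows]


def ridge_weights(X: np.ndarray, Y: np.ndarray, lam: float):
    """Closed-form ridge with intercept: ``w = (X'X + lam I)^-1 X'y`` on
    column-centered data.  ``Y`` may be (n,) or (n, cells)."""
    Xm, Ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - Xm, Y - Ym
    p = X.shape[1]
    W = np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ Yc)
    b = Ym - Xm @ W
    return W, b


def _stratified_folds(labels, n_folds: int, rng) -> list[np.ndarray]:
    """Fold assignment stratified over stimulus categories."""
    labels = np.asarray(labels)
    fold = np.empty(len(labels), int)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % n_folds
    return [np.flatnonzero(fold == f) for f in range(n_folds)]


@dataclass
class EncodingModelFit:
    """Per-cell ridge weights on reduced image statistics with CV metrics."""

    weights: np.ndarray  # cells x features
    intercepts: np.ndarray
    lambdas: np.ndarray  # chosen per cell
    cv_ev_pct: np.ndarray  # held-out explained variance, percent
    lambda_grid: np.ndarray
    folds: list
    group_blocks: dict = field(default_factory=dict)


def _cv_ev_matrix(X, Y, lambda_grid, folds):
    """Held-out EV (fraction) per (lambda, cell), averaged over folds.

    EV = 1 - SSE/SST on the held-out data, SST around the held-out mean.
    """
    n_lam, n_cells = len(lambda_grid), Y.shape[1]
    ev = np.zeros((n_lam, n_cells))
    for test in folds:
        train = np.setdiff1d(np.arange(X.shape[0]), test)
        Xtr, Ytr, Xte, Yte = X[train], Y[train], X[test], Y[test]
        sst = ((Yte - Yte.mean(axis=0)) ** 2).sum(axis=0)
        sst = np.where(sst > 0, sst, np.nan)
        for li, lam in enumerate(lambda_grid):
            W, b = ridge_weights(Xtr, Ytr, lam)
            sse = ((Yte - (Xte @ W + b)) ** 2).sum(axis=0)
            ev[li] += 1.0 - sse / sst
    return ev / len(folds)


def fit_encoding_model(
    table: CellResponseTable,
    features: np.ndarray,
    folds: int = 5,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    rng_seed: int = 0,
    group_blocks: dict | None = None,
) -> EncodingModelFit:
    """Ridge-regularized linear encoding of cell responses by image statistics.

    The regularization strength is selected per cell on the cross-validated
    explained variance over ``lambda_grid``; folds are stratified over
    stimulus categories and seeded.  Weights are refit on all stimuli at the
    selected lambda.  Negative held-out EV is reported as-is.
    """
    X = np.asarray(features, float)
    Y = table.values.T  # stimuli x cells
    if X.shape[0] != Y.shape[0]:
        raise ValueError("feature rows must match table stimuli")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("degenerate (rank-deficient) feature matrix")
    rng = np.random.default_rng(rng_seed)
    cats = (table.stimuli.family + "/" + table.stimuli.stim_class).to_numpy()
    fold_idx = _stratified_folds(cats, folds, rng)
    ev = _cv_ev_matrix(X, Y, np.asarray(lambda_grid), fold_idx)
    best = np.nanargmax(ev, axis=0)
    n_cells = Y.shape[1]
    weights = np.empty((n_cells, X.shape[1]))
    intercepts = np.empty(n_cells)
    lambdas = np.asarray(lambda_grid)[best]
    for lam in np.unique(best):
        cols = np.flatnonzero(best == lam)
        W, b = ridge_weights(X, Y[:, cols], float(np.asarray(lambda_grid)[lam]))
        weights[cols] = W.T
        intercepts[cols] = b
    cv_ev = 100.0 * ev[best, np.arange(n_cells)]
    return EncodingModelFit(
        weights=weights,
        intercepts=intercepts,
        lambdas=lambdas,
        cv_ev_pct=cv_ev,
        lambda_grid=np.asarray(lambda_grid),
        folds=fold_idx,
        group_blocks=group_blocks or {},
    )


def permutation_ev_threshold(
    table: CellResponseTable,
    features: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    folds: int = 5,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    rng_seed: int = 0,
    min_threshold_pct: float = 1.0,
) -> dict:
    """Permutation null for the encoding model's explained variance.

    Feature rows are re-assigned to randomly chosen stimuli (``n_perm``
    independent shuffles, pooled across cells); the ``1 - alpha`` quantile of
    the shuffled EV distribution is the significance threshold.  The pipeline
    inclusion threshold is the conservative ``max(threshold,
    min_threshold_pct)`` (default 1%).
    """
    X = np.asarray(features, float)
    Y = table.values.T
    rng = np.random.default_rng(rng_seed)
    cats = (table.stimuli.family + "/" + table.stimuli.stim_class).to_numpy()
    fold_idx = _stratified_folds(cats, folds, rng)
    lam = np.asarray(lambda_grid)
    null_ev = np.empty((n_perm, Y.shape[1]))
    for i in range(n_perm):
        Xs = X[rng.permutation(X.shape[0])]
        ev = _cv_ev_matrix(Xs, Y, lam, fold_idx)
        null_ev[i] = 100.0 * np.nanmax(ev, axis=0)
    thr = float(np.percentile(null_ev.ravel(), 100 * (1 - alpha)))
    return dict(
        threshold_pct=thr,
        inclusion_threshold_pct=max(thr, min_threshold_pct),
        null_ev_pct=null_ev,
        alpha=alpha,
    )


def group_weight_sums(
    fit: EncodingModelFit, group_blocks: dict | None = None
) -> pd.DataFrame:
    """Per-group sums of absolute weights, W_i = sum_j |w_ij| (cells x groups)."""
    blocks = group_blocks or fit.group_blocks
    if not blocks:
        raise ValueError("no group blocks recorded on the fit")
    return pd.DataFrame(
        {g: np.abs(fit.weights[:, sl]).sum(axis=1) for g, sl in blocks.items()}
    )


@dataclass
class UniqueEVResult:
    """Leave-one-group-out change in explained variance (percent of full EV)."""

    delta_ev_pct: pd.DataFrame  # included cells x groups
    full_ev_pct: np.ndarray
    cell_indices: np.ndarray


def unique_ev(
    table: CellResponseTable,
    features: np.ndarray,
    group_blocks: dict,
    min_full_ev_pct: float = 10.0,
    folds: int = 5,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    rng_seed: int = 0,
) -> UniqueEVResult:
    """Unique explained variance per statistics group.

    For cells whose full-model cross-validated EV is at least
    ``min_full_ev_pct``, four reduced models are fit, each omitting one
    group's columns; ``dEV_u = 100 * (EV_f - EV_i) / EV_f``.
    """
    full = fit_encoding_model(
        table, features, folds=folds, lambda_grid=lambda_grid, rng_seed=rng_seed
    )
    keep = np.flatnonzero(full.cv_ev_pct >= min_full_ev_pct)
    sub = CellResponseTable(table.values[keep], table.stimuli, table.window_ms)
    ev_f = full.cv_ev_pct[keep]
    out = {}
    for g, sl in group_blocks.items():
        cols = np.ones(features.shape[1], bool)
        cols[sl] = False
        red = fit_encoding_model(
            sub, features[:, cols], folds=folds, lambda_grid=lambda_grid, rng_seed=rng_seed
        )
        out[g] = 100.0 * (ev_f - red.cv_ev_pct) / ev_f
    return UniqueEVResult(
        delta_ev_pct=pd.DataFrame(out), full_ev_pct=ev_f, cell_indices=keep
    )
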