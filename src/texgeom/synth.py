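"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:

* procedural texture families whose higher-order (energy) correlations are
  controlled by an envelope-correlation strength ``kappa`` — at ``kappa=0``
  the images are Gaussian fields whose energy statistics match their own
  phase scrambles up to sampling error;
* full labelled image sets (textures + exact spectral scrambles, two
  rotations);
* fully randomized trial schedules for widefield and two-photon sessions;
* dual-channel widefield movies in which a shared band-limited hemodynamic
  artifact contaminates both channels;
* two-photon soma/neuropil traces generated from ground-truth linear weights
  on reduced image statistics, with neuropil contamination and slow drift;
* go/no-go behavioral logs from an equal-variance signal-detection observer.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stimuli import (
    ImageSet,
    StimulusImage,
    normalize_luminance_contrast,
    phase_scramble,
    rotate90,
)

__all__ = [
    "FamilyParams",
    "DEFAULT_FAMILIES",
    "TrialSchedule",
    "WidefieldTruth",
    "TwoPhotonTruth",
    "WidefieldSession",
    "TwoPhotonSession",
    "make_texture_family",
    "make_full_image_set",
    "make_trial_schedule",
    "simulate_widefield_session",
    "simulate_twophoton_session",
    "make_hemo_pair",
    "simulate_behavior_sessions",
]


# --------------------------------------------------------------------------
# texture families
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyParams:
    """Procedural texture family definition.

    ``kappa`` scales the shared multiplicative envelope, producing
    family-specific energy cross-correlations; ``sparsity`` < 1 builds the
    carrier from sparse impulses ("textons") instead of dense Gaussian noise,
    which adds the cross-scale phase alignment characteristic of edge-like
    texture elements; ``ori_bias_deg``/``ori_concentration`` shape the
    orientation spectrum; the carrier amplitude spectrum is log-Gaussian
    around ``sf_peak_cpd`` with ``sf_bandwidth_oct`` octaves of spread.
    """

    name: str
    kappa: float = 0.8
    ori_bias_deg: float | None = None
    ori_concentration: float = 1.0
    sf_peak_cpd: float = 0.12
    sf_bandwidth_oct: float = 0.75
    sparsity: float = 1.0  # fraction of active carrier impulses (1 = Gaussian)
    envelope_cutoff_frac: float = 0.25  # envelope cutoff as fraction of sf peak


# The four default families mirror the study conditions: distinct orientation
# content and envelope strengths, with "rocks" closest to a Gaussian field so
# its energy statistics sit nearest to its own scrambles.
DEFAULT_FAMILIES = (
    FamilyParams("scales", kappa=0.85, ori_bias_deg=0.0, ori_concentration=0.4,
                 sf_peak_cpd=0.12, sparsity=0.003),
    FamilyParams("rocks", kappa=0.10, ori_bias_deg=None, sf_peak_cpd=0.10, sparsity=1.0),
    FamilyParams("honeycomb", kappa=0.70, ori_bias_deg=60.0, ori_concentration=0.4,
                 sf_peak_cpd=0.11, sparsity=0.01),
    FamilyParams("plants", kappa=0.55, ori_bias_deg=120.0, ori_concentration=0.3,
                 sf_peak_cpd=0.09, sparsity=0.1),
)


def _filtered_noise(rng, n, amp_mask):
    noise = rng.standard_normal((n, n))
    x = np.fft.ifft2(np.fft.fft2(noise) * amp_mask).real
    return (x - x.mean()) / x.std()


def _carrier_mask(n: int, ppd: float, p: FamilyParams) -> np.ndarray:
    f = np.fft.fftfreq(n)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    r_cpd = np.hypot(fx, fy) * ppd
    theta = np.arctan2(fy, fx)
    with np.errstate(divide="ignore"):
        radial = np.exp(
            -(np.log2(np.maximum(r_cpd, 1e-9) / p.sf_peak_cpd) ** 2)
            / (2 * p.sf_bandwidth_oct**2)
        )
    radial[0, 0] = 0.0
    if p.ori_bias_deg is None:
        return radial
    ang = np.exp(p.ori_concentration * np.cos(2 * (theta - np.radians(p.ori_bias_deg))))
    return radial * ang


def make_texture_family(
    params: FamilyParams,
    n_exemplars: int,
    rng_seed: int,
    size: int = 256,
    pixels_per_degree: float | None = None,
) -> ImageSet:
    """Generate texture exemplars of one family (rotation 0, unscrambled).

    Exemplars are filtered-noise carriers multiplied by a shared smooth random
    envelope, ``exp(kappa * field)`` — a pointwise nonlinear transform of a
    Gaussian envelope field that couples the local energy of distant image
    regions; at ``kappa = 0`` the output is exactly a Gaussian field whose
    energy statistics match its own phase scrambles up to sampling error.
    """
    if not 0.0 <= params.kappa <= 1.0:
        raise ValueError("kappa must be in [0, 1]")
    ppd = pixels_per_degree if pixels_per_degree is not None else size / 100.0
    rng = np.random.default_rng(rng_seed)
    cmask = _carrier_mask(size, ppd, params)
    f = np.fft.fftfreq(size)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    r_cpd = np.hypot(fx, fy) * ppd
    env_mask = np.exp(-((r_cpd / (params.envelope_cutoff_frac * params.sf_peak_cpd)) ** 2))
    env_mask[0, 0] = 0.0
    env_field = _filtered_noise(rng, size, env_mask)
    envelope = np.exp(params.kappa * env_field)
    images = []
    for e in range(n_exemplars):
        src = rng.standard_normal((size, size))
        if params.sparsity < 1.0:
            src = src * (rng.random((size, size)) < params.sparsity)
        carrier = np.fft.ifft2(np.fft.fft2(src) * cmask).real
        carrier = (carrier - carrier.mean()) / carrier.std()
        x = carrier * envelope
        im = StimulusImage(
            pixels=x,
            family=params.name,
            stim_class="texture",
            exemplar_id=e,
            rotation_deg=0,
            pixels_per_degree=ppd,
        )
        images.append(normalize_luminance_contrast(im))
    return ImageSet(
        images,
        provenance=dict(
            generator="make_texture_family", seed=int(rng_seed), params=asdict(params)
        ),
    )


def make_full_image_set(
    families: tuple[FamilyParams, ...] = DEFAULT_FAMILIES,
    n_exemplars: int = 20,
    rng_seed: int = 0,
    size: int = 256,
    pixels_per_degree: float | None = None,
    rotations: tuple[int, ...] = (0, 90),
) -> ImageSet:
    """Textures + exact spectral scrambles for every family, at each rotation.

    With the defaults (4 families x 20 exemplars x {texture, scramble} x
    {0, 90} degrees) the set holds exactly 320 images, all normalized to mean
    0.5 / contrast 0.15.
    """
    seeds = np.random.SeedSequence(rng_seed).generate_state(2 * len(families) * n_exemplars)
    images = []
    si = 0
    for fi, fam in enumerate(families):
        tex = make_texture_family(
            fam, n_exemplars, int(seeds[si]) % 2**31, size=size,
            pixels_per_degree=pixels_per_degree,
        )
        si += 1
        for im in tex:
            scr = normalize_luminance_contrast(phase_scramble(im, int(seeds[si]) % 2**31))
            si += 1
            for base in (im, scr):
                images.append(base)
                if 90 in rotations:
                    images.append(rotate90(base))
    return ImageSet(
        images,
        provenance=dict(
            generator="make_full_image_set",
            seed=int(rng_seed),
            n_exemplars=n_exemplars,
            size=size,
            families=[f.name for f in families],
        ),
    )


# --------------------------------------------------------------------------
# trial schedules
# --------------------------------------------------------------------------

@dataclass
class TrialSchedule:
    """Fully randomized trial order with onset times.

    ``trials`` has one row per trial: family, stim_class, exemplar_id,
    rotation_deg (empty strings / -1 for blanks), is_blank, onset_s.
    """

    trials: pd.DataFrame
    stim_ms: float = 250.0
    iti_ms: float = 750.0
    lead_s: float = 6.0

    @property
    def n_stimulus_trials(self) -> int:
        return int((~self.trials.is_blank).sum())

    @property
    def n_blank_trials(self) -> int:
        return int(self.trials.is_blank.sum())

    @property
    def duration_s(self) -> float:
        period = (self.stim_ms + self.iti_ms) / 1000.0
        return self.lead_s + len(self.trials) * period + 2.0

    def onset_frames(self, rate_hz: float) -> np.ndarray:
        return np.round(self.trials.onset_s.to_numpy() * rate_hz).astype(int)


def make_trial_schedule(
    mode: str,
    rng_seed: int,
    families: tuple[str, ...] = ("scales", "rocks", "honeycomb", "plants"),
    n_exemplars: int = 20,
    n_repeats: int | None = None,
    n_blanks: int | None = None,
    rotations: tuple[int, ...] | None = None,
    stim_ms: float = 250.0,
    iti_ms: float = 750.0,
    lead_s: float = 6.0,
) -> TrialSchedule:
    """Randomized presentation order for a passive-viewing session.

    ``mode='widefield'``: 8 categories x 20 exemplars x 10 repeats = 1600
    stimulus trials + 200 blanks.  ``mode='twophoton'``: additionally two
    rotations and 8 repeats = 2560 stimulus trials + 160 blanks.
    """
    if mode == "widefield":
        n_repeats = 10 if n_repeats is None else n_repeats
        n_blanks = 200 if n_blanks is None else n_blanks
        rotations = (0,) if rotations is None else rotations
    elif mode == "twophoton":
        n_repeats = 8 if n_repeats is None else n_repeats
        n_blanks = 160 if n_blanks is None else n_blanks
        rotations = (0, 90) if rotations is None else rotations
    else:
        raise ValueError("mode must be 'widefield' or 'twophoton'")
    rows = []
    for fam in families:
        for cls in ("texture", "scramble"):
            for e in range(n_exemplars):
                for rot in rotations:
                    rows += [(fam, cls, e, rot, False)] * n_repeats
    rows += [("", "", -1, -1, True)] * n_blanks
    df = pd.DataFrame(
        rows, columns=["family", "stim_class", "exemplar_id", "rotation_deg", "is_blank"]
    )
    rng = np.random.default_rng(rng_seed)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    period = (stim_ms + iti_ms) / 1000.0
    df["onset_s"] = lead_s + np.arange(len(df)) * period
    return TrialSchedule(trials=df, stim_ms=stim_ms, iti_ms=iti_ms, lead_s=lead_s)


# --------------------------------------------------------------------------
# calcium kernel
# --------------------------------------------------------------------------

def calcium_kernel(rate_hz: float, rise_s: float = 0.05, decay_s: float = 0.5) -> np.ndarray:
    """Double-exponential indicator kernel, peak-normalized to 1."""
    t = np.arange(0, 5 * decay_s, 1.0 / rate_hz)
    k = (1 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


# --------------------------------------------------------------------------
# widefield sessions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WidefieldTruth:
    """Ground-truth parameters of a simulated dual-channel session.

    The LM area carries twice the texture-scramble modulation of V1
    (``tex_mod_lm / tex_mod_v1``), and within V1 the modulation grows with
    elevation (``upper_field_bias``).  ``d_true`` is 0 because per-channel
    detrending forces zero regression intercepts (see docs).
    """

    shape: tuple[int, int] = (64, 64)
    rate_hz: float = 20.0
    response_amp_pct: float = 2.0
    tex_mod_v1: float = 0.15
    tex_mod_lm: float = 0.30
    upper_field_bias: float = 0.5
    exemplar_jitter: float = 0.05
    c_true: float = 0.8
    d_true: float = 0.0
    artifact_amp_pct: float = 1.0
    artifact_cutoff_hz: float = 3.0
    noise_sd_pct: float = 0.2
    drift_frac: float = 0.05
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.5


@dataclass
class WidefieldSession:
    blue: np.ndarray  # frames x H x W raw fluorescence
    violet: np.ndarray
    rate_hz: float
    schedule: TrialSchedule
    azimuth: np.ndarray
    elevation: np.ndarray
    area_masks: dict
    truth: WidefieldTruth
    programmed: dict = field(default_factory=dict)


def _gaussian_blob(shape, center, sigma):
    yy, xx = np.indices(shape)
    return np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)))


def simulate_widefield_session(
    schedule: TrialSchedule,
    truth: WidefieldTruth = WidefieldTruth(),
    rng_seed: int = 0,
    images: ImageSet | None = None,
) -> WidefieldSession:
    """Dual-channel movie with calcium responses in two areas plus a shared
    hemodynamic artifact.

    blue = gain_map * (trial drive (x) calcium kernel) + c_true * artifact + noise
    violet =                         artifact                             + noise

    The artifact is band-limited below the pipeline's 5 Hz low-pass cutoff.
    ``images`` is accepted for interface symmetry; only the schedule's keys
    determine the programmed drive.
    """
    rng = np.random.default_rng(rng_seed)
    H, W = truth.shape
    rate = truth.rate_hz
    n_frames = int(np.ceil(schedule.duration_s * rate))
    t = np.arange(n_frames) / rate

    # retinotopy + area masks: V1 blob in the left half, LM in the right
    v1_center, lm_center = (H * 0.5, W * 0.30), (H * 0.5, W * 0.72)
    sigma = H * 0.14
    g_v1 = _gaussian_blob((H, W), v1_center, sigma)
    g_lm = _gaussian_blob((H, W), lm_center, sigma)
    masks = {"V1": g_v1 > 0.35, "LM": g_lm > 0.35}
    yy, xx = np.indices((H, W))
    # elevation ramps vertically (+40 top to -40 bottom); azimuth ramps
    # horizontally within each area's lobe
    elevation = 40.0 - 80.0 * yy / (H - 1)
    azimuth = np.where(
        xx < W / 2, -10 + 40 * xx / (W / 2 - 1), -10 + 40 * (xx - W / 2) / (W / 2 - 1)
    )

    # per-trial drives
    onsets = schedule.onset_frames(rate)
    tr = schedule.trials
    is_tex = (~tr.is_blank & (tr.stim_class == "texture")).to_numpy(float)
    is_stim = (~tr.is_blank).to_numpy(float)
    key_jitter = {}
    base_amp = np.empty(len(tr))
    for i, row in enumerate(tr.itertuples(index=False)):
        if row.is_blank:
            base_amp[i] = 0.0
            continue
        key = (row.family, row.stim_class, row.exemplar_id, row.rotation_deg)
        if key not in key_jitter:
            key_jitter[key] = rng.normal(0.0, truth.exemplar_jitter)
        base_amp[i] = 1.0 + key_jitter[key]

    kern = calcium_kernel(rate, truth.kernel_rise_s, truth.kernel_decay_s)

    def _drive(amps):
        d = np.zeros(n_frames)
        np.add.at(d, onsets, amps * is_stim)
        return np.convolve(d, kern)[:n_frames]

    base_drive = _drive(base_amp)
    tex_drive = _drive(base_amp * is_tex)

    # pixel maps: gain and texture-modulation (with V1 upper-field gradient)
    gain_map = truth.response_amp_pct * (g_v1 + g_lm)
    el_norm = np.clip(elevation / 40.0, -1, 1)
    texmod_map = truth.response_amp_pct * (
        truth.tex_mod_v1 * g_v1 * (1.0 + truth.upper_field_bias * el_norm)
        + truth.tex_mod_lm * g_lm
    )
    calcium = (
        base_drive[:, None, None] * gain_map[None]
        + tex_drive[:, None, None] * texmod_map[None]
    )

    # shared hemodynamic artifact, band-limited below 5 Hz
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, truth.artifact_cutoff_hz, fs=rate, output="sos")
    a_t = sosfiltfilt(sos, rng.standard_normal(n_frames))
    a_t = a_t / (a_t.std() or 1.0) * truth.artifact_amp_pct
    art_map = 0.5 + _gaussian_blob((H, W), (H * 0.45, W * 0.5), H * 0.3)
    artifact = a_t[:, None, None] * art_map[None]

    blue_dff = (
        calcium + truth.c_true * artifact + truth.d_true
        + rng.normal(0, truth.noise_sd_pct, calcium.shape)
    )
    violet_dff = artifact + rng.normal(0, truth.noise_sd_pct, calcium.shape)

    trend = 1.0 - truth.drift_frac * (t / t[-1])
    f0b, f0v = 1000.0, 800.0
    blue = (f0b * trend[:, None, None] * (1.0 + blue_dff / 100.0)).astype(np.float32)
    violet = (f0v * trend[:, None, None] * (1.0 + violet_dff / 100.0)).astype(np.float32)

    return WidefieldSession(
        blue=blue,
        violet=violet,
        rate_hz=rate,
        schedule=schedule,
        azimuth=azimuth,
        elevation=elevation,
        area_masks=masks,
        truth=truth,
        programmed=dict(
            gain_map=gain_map, texmod_map=texmod_map, artifact_t=a_t, artifact_map=art_map,
            base_drive=base_drive, tex_drive=tex_drive, seed=int(rng_seed),
        ),
    )


def make_hemo_pair(
    rng_seed: int = 0,
    n_frames: int = 6000,
    rate_hz: float = 20.0,
    c_true: float = 0.8,
    d_true: float = 0.1,
    signal_sd: float = 0.5,
    artifact_sd: float = 1.0,
    noise_sd: float = 0.02,
):
    """A single-pixel (blue, violet) dF/F pair with known (c, d).

    blue = signal + c_true * lowpass(violet) + d_true + noise.  Used to
    exercise the hemodynamic regression stage directly, where the intercept
    is recoverable (see docs on detrending and d).
    """
    from scipy.signal import butter, sosfiltfilt

    rng = np.random.default_rng(rng_seed)
    sos = butter(4, 3.0, fs=rate_hz, output="sos")
    violet = sosfiltfilt(sos, rng.standard_normal(n_frames))
    violet = violet / violet.std() * artifact_sd
    signal = rng.normal(0, signal_sd, n_frames)
    blue = signal + c_true * violet + d_true + rng.normal(0, noise_sd, n_frames)
    return blue, violet, dict(c_true=c_true, d_true=d_true, signal=signal, rate_hz=rate_hz)


# --------------------------------------------------------------------------
# two-photon sessions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPhotonTruth:
    """Ground truth for simulated soma/neuropil traces.

    Per-cell trial amplitude is ``max(0, w_true . x + baseline)`` on the
    reduced image statistics ``x``; the observed soma is contaminated with
    ``neuropil_r`` times the neuropil trace by construction, so neuropil
    correction with the same coefficient is exact in the noiseless case.
    """

    n_cells: int = 100
    silent_frac: float = 0.2
    rate_hz: float = 30.0
    within_family_scale: float = 1.0
    neuropil_r: float = 0.7
    baseline_amp_pct: float = 8.0
    weight_scale_pct: dict = field(
        default_factory=lambda: {
            "marginal": 1.0, "spectral": 1.5, "linear_cc": 1.5, "energy_cc": 4.0,
        }
    )
    trial_noise_pct: float = 2.0
    trace_noise_pct: float = 0.5
    neuropil_amp_pct: float = 3.0
    drift_frac_per_min: float = 0.01
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.5
    f0: float = 500.0


@dataclass
class TwoPhotonSession:
    soma: np.ndarray  # cells x frames, raw fluorescence
    neuropil: np.ndarray
    rate_hz: float
    schedule: TrialSchedule
    truth: TwoPhotonTruth
    w_true: np.ndarray  # cells x n_features (dF/F % per z-scored feature)
    baseline_true: np.ndarray
    features: np.ndarray  # n_stimuli x n_features
    stim_index: pd.DataFrame
    soma_true: np.ndarray | None = None


def simulate_twophoton_session(
    features: np.ndarray,
    stim_index: pd.DataFrame,
    schedule: TrialSchedule,
    truth: TwoPhotonTruth = TwoPhotonTruth(),
    rng_seed: int = 0,
    keep_true_soma: bool = False,
) -> TwoPhotonSession:
    """Soma + neuropil traces driven by linear weights on image statistics.

    ``features`` is the (n_stimuli x p) reduced-statistics design;
    ``stim_index`` must carry family / stim_class / exemplar_id / rotation_deg
    columns aligned with its rows.  A configurable fraction of cells is
    silent (zero weights and baseline).

    ``truth.within_family_scale`` scales the within-family components of the
    response: each stimulus's feature vector is shrunk toward its (family,
    class) mean before the weights are applied, and the trial-to-trial noise
    is scaled by the same factor.  Values below 1 therefore reduce
    within-family response dispersion while leaving family centroids — and,
    at a fixed seed, the cell weights — unchanged.  This is the dial for
    programming areas with more compact family representations.
    """
    rng = np.random.default_rng(rng_seed)
    features = np.asarray(features, float)
    if truth.within_family_scale != 1.0:
        features = features.copy()
        keys = stim_index[["family", "stim_class"]].agg("/".join, axis=1).to_numpy()
        for key in np.unique(keys):
            m = keys == key
            mu = features[m].mean(axis=0)
            features[m] = mu + truth.within_family_scale * (features[m] - mu)
    p = features.shape[1]
    n_cells = truth.n_cells
    rate = truth.rate_hz
    n_frames = int(np.ceil(schedule.duration_s * rate))

    # group-structured weights: last columns are the energy PCs by convention
    # of ReducedStats.features (2 cols per group, group order fixed)
    scales = np.concatenate(
        [np.full(2, truth.weight_scale_pct[g]) for g in
         ("marginal", "spectral", "linear_cc", "energy_cc")]
    )[:p] if p == 8 else np.full(p, 2.0)
    w = rng.normal(0, 1, (n_cells, p)) * scales
    baseline = np.abs(rng.normal(truth.baseline_amp_pct, 2.0, n_cells))
    silent = rng.random(n_cells) < truth.silent_frac
    w[silent] = 0.0
    baseline[silent] = 0.0

    # map schedule trials to stimulus rows
    key_cols = ["family", "stim_class", "exemplar_id", "rotation_deg"]
    stim_lookup = {tuple(r): i for i, r in enumerate(stim_index[key_cols].to_numpy())}
    tr = schedule.trials
    amp = np.zeros((n_cells, len(tr)))
    stim_amp = np.maximum(0.0, w @ features.T + baseline[:, None])  # cells x stimuli
    for i, row in enumerate(tr.itertuples(index=False)):
        if row.is_blank:
            continue
        j = stim_lookup[(row.family, row.stim_class, row.exemplar_id, row.rotation_deg)]
        amp[:, i] = stim_amp[:, j]
    amp += (
        rng.normal(0, truth.trial_noise_pct, amp.shape)
        * truth.within_family_scale
        * (amp > 0)
    )

    kern = calcium_kernel(rate, truth.kernel_rise_s, truth.kernel_decay_s)
    onsets = schedule.onset_frames(rate)
    dff = np.zeros((n_cells, n_frames))
    for c in range(n_cells):
        d = np.zeros(n_frames)
        np.add.at(d, onsets, amp[c])
        dff[c] = np.convolve(d, kern)[:n_frames]

    t_min = np.arange(n_frames) / rate / 60.0
    drift = 1.0 - truth.drift_frac_per_min * t_min
    soma_true = truth.f0 * drift[None] * (1.0 + dff / 100.0)
    soma_true += rng.normal(0, truth.trace_noise_pct / 100.0 * truth.f0, soma_true.shape)

    shared = rng.standard_normal(n_frames)
    from scipy.signal import butter, sosfiltfilt

    sos = butter(2, 1.0, fs=rate, output="sos")
    shared = sosfiltfilt(sos, shared)
    shared = shared / (shared.std() or 1.0)
    fn0 = 0.4 * truth.f0
    neuropil = fn0 * drift[None] * (
        1.0 + (truth.neuropil_amp_pct / 100.0) * shared[None]
        * (1.0 + 0.1 * rng.standard_normal((n_cells, 1)))
    )
    soma_obs = soma_true + truth.neuropil_r * neuropil

    return TwoPhotonSession(
        soma=soma_obs,
        neuropil=neuropil,
        rate_hz=rate,
        schedule=schedule,
        truth=truth,
        w_true=w,
        baseline_true=baseline,
        features=features,
        stim_index=stim_index.reset_index(drop=True),
        soma_true=soma_true if keep_true_soma else None,
    )


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def simulate_behavior_sessions(
    sensitivity: dict,
    n_sessions: int = 5,
    trials_per_session: int = 400,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Go/no-go logs from an unbiased equal-variance SDT observer.

    ``sensitivity`` maps family -> programmed d'.  On go trials the decision
    variable is N(d', 1), on no-go trials N(0, 1); the observer responds when
    it exceeds d'/2, giving hit/false-alarm rates that follow the
    equal-variance signal-detection model exactly.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for fam, d in sensitivity.items():
        for s in range(n_sessions):
            is_go = rng.random(trials_per_session) < 0.5
            dv = rng.standard_normal(trials_per_session) + d * is_go
            resp = dv > d / 2.0
            for g, r in zip(is_go, resp):
                rows.append((fam, s, "go" if g else "nogo", bool(r)))
    return pd.DataFrame(rows, columns=["family", "session", "stim_class", "response"])
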