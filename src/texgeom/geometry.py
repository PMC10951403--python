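"""Population embeddings, decoding, and representational-geometry metrics.

Population responses (cells x stimuli) are z-scored per cell and projected
into a PCA space of fixed dimensionality so that populations of different
sizes are comparable.  In that space the analyses are: binary texture-vs-
scramble decoding per family, 4-way texture-family decoding (L1 multinomial
logistic with cross-validated regularization), a shared two-area PCA space
with per-area projections, and cluster geometry (radii, centroid distances,
shrinkage-regularized Mahalanobis distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .psstats import _fix_pca_signs
from .twophoton import CellResponseTable

__all__ = [
    "Embedding",
    "NeuralClusterGeometry",
    "DecoderResult",
    "embed_population",
    "decode_texture_vs_scramble",
    "decode_families",
    "shared_embedding",
    "neural_cluster_geometry",
]


@dataclass
class Embedding:
    """Stimuli x components scores with the linear map that produced them."""

    points: np.ndarray
    loadings: np.ndarray  # components x cells
    cell_mean: np.ndarray
    cell_sd: np.ndarray
    center: np.ndarray  # PCA mean in z-scored space
    explained_variance_ratio: np.ndarray
    stimuli: pd.DataFrame
    area: str = ""
    area_projections: dict = field(default_factory=dict)


def _zscore_cells(values: np.ndarray):
    """Z-score each cell across stimuli; zero-variance cells are dropped."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1)
    keep = sd > 1e-12
    z = (values[keep] - mean[keep, None]) / sd[keep, None]
    return z.T, mean, sd, keep  # stimuli x cells


def embed_population(table: CellResponseTable, n_components: int = 20) -> Embedding:
    """Per-cell z-scoring followed by PCA over stimuli.

    Component signs follow the fixed convention (largest-magnitude loading
    positive), so the embedding is deterministic.
    """
    z, mean, sd, keep = _zscore_cells(table.values)
    ncomp = min(n_components, z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=ncomp, svd_solver="full")
    pts = pca.fit_transform(z)
    signs = _fix_pca_signs(pca)
    return Embedding(
        points=pts * signs,
        loadings=pca.components_,
        cell_mean=mean[keep],
        cell_sd=sd[keep],
        center=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        stimuli=table.stimuli,
    )


@dataclass
class DecoderResult:
    task: str
    accuracy: float
    fold_accuracies: np.ndarray
    chance: float
    n_components: int
    sweep: pd.DataFrame | None = None
    settings: dict = field(default_factory=dict)


def _cv_accuracy(X, y, clf, folds, rng_seed):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    return cross_val_score(clf, X, y, cv=skf, scoring="accuracy")


def decode_texture_vs_scramble(
    emb: Embedding,
    family: str,
    folds: int = 5,
    n_components: int | None = None,
    component_sweep: tuple[int, ...] | None = None,
    rng_seed: int = 0,
) -> DecoderResult:
    """Binary logistic decoding of texture vs scramble within one family."""
    m = (emb.stimuli.family == family).to_numpy()
    y = (emb.stimuli.stim_class[m] == "texture").to_numpy().astype(int)
    ncomp = n_components or emb.points.shape[1]
    X = emb.points[m][:, :ncomp]
    clf = LogisticRegression(max_iter=2000, tol=1e-6)
    scores = _cv_accuracy(X, y, clf, folds, rng_seed)
    sweep = None
    if component_sweep:
        rows = [
            (k, float(_cv_accuracy(emb.points[m][:, :k], y, clf, folds, rng_seed).mean()))
            for k in component_sweep
        ]
        sweep = pd.DataFrame(rows, columns=["n_components", "accuracy"])
    return DecoderResult(
        task=f"texture_vs_scramble/{family}",
        accuracy=float(scores.mean()),
        fold_accuracies=scores,
        chance=0.5,
        n_components=ncomp,
        sweep=sweep,
        settings=dict(folds=folds, rng_seed=rng_seed),
    )


def decode_families(
    emb: Embedding,
    folds: int = 5,
    n_components: int | None = None,
    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    component_sweep: tuple[int, ...] | None = None,
    rng_seed: int = 0,
) -> DecoderResult:
    """4-way texture-family decoding: multinomial logistic, L1 penalty,
    regularization by grid search on cross-validated accuracy."""
    m = (emb.stimuli.stim_class == "texture").to_numpy()
    y = emb.stimuli.family[m].to_numpy()
    ncomp = n_components or emb.points.shape[1]

    def _acc(X):
        best = -1.0, None
        for C in C_grid:
            clf = LogisticRegression(
                l1_ratio=1.0, solver="saga", C=C, max_iter=5000, tol=1e-4
            )
            sc = _cv_accuracy(X, y, clf, folds, rng_seed)
            if sc.mean() > best[0]:
                best = (float(sc.mean()), sc)
        return best

    acc, scores = _acc(emb.points[m][:, :ncomp])
    sweep = None
    if component_sweep:
        rows = [(k, _acc(emb.points[m][:, :k])[0]) for k in component_sweep]
        sweep = pd.DataFrame(rows, columns=["n_components", "accuracy"])
    return DecoderResult(
        task="texture_families",
        accuracy=acc,
        fold_accuracies=scores,
        chance=1.0 / len(np.unique(y)),
        n_components=ncomp,
        sweep=sweep,
        settings=dict(folds=folds, C_grid=C_grid, rng_seed=rng_seed),
    )


def shared_embedding(
    table_a: CellResponseTable,
    table_b: CellResponseTable,
    n_components: int = 16,
    labels: tuple[str, str] = ("A", "B"),
) -> Embedding:
    """PCA on the concatenated z-scored ensembles of two areas.

    Per-area projections are obtained by zeroing the other area's (centered)
    cells before applying the shared loadings; by linearity the two area
    projections sum exactly to the full projection.
    """
    if not table_a.stimuli[["family", "stim_class", "exemplar_id", "rotation_deg"]].equals(
        table_b.stimuli[["family", "stim_class", "exemplar_id", "rotation_deg"]]
    ):
        raise ValueError("the two tables must share the same stimulus rows")
    za, mean_a, sd_a, keep_a = _zscore_cells(table_a.values)
    zb, *_ = _zscore_cells(table_b.values)
    z = np.hstack([za, zb])
    ncomp = min(n_components, z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=ncomp, svd_solver="full")
    pts = pca.fit_transform(z)
    signs = _fix_pca_signs(pca)
    zc = z - pca.mean_
    na = za.shape[1]
    proj = {}
    for lab, sl in ((labels[0], slice(0, na)), (labels[1], slice(na, z.shape[1]))):
        masked = np.zeros_like(zc)
        masked[:, sl] = zc[:, sl]
        proj[lab] = masked @ pca.components_.T * signs
    return Embedding(
        points=pts * signs,
        loadings=pca.components_,
        cell_mean=np.concatenate([table_a.values.mean(axis=1), table_b.values.mean(axis=1)]),
        cell_sd=np.concatenate([table_a.values.std(axis=1), table_b.values.std(axis=1)]),
        center=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        stimuli=table_a.stimuli,
        area="+".join(labels),
        area_projections=proj,
    )


@dataclass
class NeuralClusterGeometry:
    """Radii, centroid distances and Mahalanobis distances per family pair."""

    labels: list
    centroids: dict
    radii: dict  # mean over components of the per-component SD
    centroid_distances: dict  # Euclidean, per pair
    mahalanobis: dict  # shrinkage-regularized pooled covariance, per pair
    shrinkage: dict  # fitted shrinkage intensity per pair


def neural_cluster_geometry(
    points: np.ndarray,
    labels,
    shrinkage: float | None = None,
) -> NeuralClusterGeometry:
    """Cluster geometry of family clouds in an embedding space.

    The radius generalizes the 2-D rule (sigma_x + sigma_y)/2 to the mean of
    per-component standard deviations.  The Mahalanobis distance for a pair
    uses the pooled within-pair covariance with Ledoit-Wolf shrinkage (a
    fixed ``shrinkage`` in [0, 1] may be supplied instead; the applied
    intensity is recorded).
    """
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    centroids, radii = {}, {}
    for name in names:
        pts = points[labels == name]
        if len(pts) < 2:
            raise ValueError(f"cluster '{name}' has fewer than 2 points")
        centroids[name] = pts.mean(axis=0)
        radii[name] = float(pts.std(axis=0).mean())
    dists, maha, shrunk = {}, {}, {}
    p = points.shape[1]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa, pb = points[labels == a], points[labels == b]
            delta = centroids[a] - centroids[b]
            dists[(a, b)] = float(np.linalg.norm(delta))
            centered = np.vstack([pa - centroids[a], pb - centroids[b]])
            if shrinkage is None:
                lw = LedoitWolf(assume_centered=True).fit(centered)
                cov, lam = lw.covariance_, float(lw.shrinkage_)
            else:
                emp = centered.T @ centered / len(centered)
                mu = np.trace(emp) / p
                cov = (1 - shrinkage) * emp + shrinkage * mu * np.eye(p)
                lam = float(shrinkage)
            maha[(a, b)] = float(np.sqrt(delta @ np.linalg.solve(cov, delta)))
            shrunk[(a, b)] = lam
    return NeuralClusterGeometry(
        labels=names,
        centroids=centroids,
        radii=radii,
        centroid_distances=dists,
        mahalanobis=maha,
        shrinkage=shrunk,
    )
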