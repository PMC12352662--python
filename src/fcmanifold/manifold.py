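"""Connectivity manifolds: affinity, PCA embedding, alignment, eccentricity.

A region's "connectivity profile" is its row of the centered covariance
matrix.  Rows are sparsified (top 10% of connections per row by signed
value), pairwise cosine similarity of the thresholded rows gives an
affinity matrix, and PCA of that affinity yields a low-dimensional
embedding (connectivity gradients).  Per-subject/epoch embeddings are
Procrustes-aligned (rotation/reflection only — no scaling, no
translation) to a group baseline template so coordinates are comparable
across epochs and subjects.  Manifold eccentricity is each region's
Euclidean distance from the origin of the aligned space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import orthogonal_procrustes


@dataclass
class ManifoldEmbedding:
    """Regions x d coordinates plus PCA bookkeeping."""

    coords: np.ndarray
    variance_explained: np.ndarray
    aligned: bool = False
    transform: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_regions(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def threshold_rows(S: np.ndarray, keep_fraction: float = 0.10,
                   by_abs: bool = False) -> np.ndarray:
    """Keep the top ``floor((R-1)*keep_fraction)`` off-diagonal entries per row.

    Ranking is by signed value (largest kept) by default, the convention
    of the connectivity-gradient literature; ``by_abs`` ranks by
    magnitude instead.  The diagonal is excluded and zeroed; everything
    else is set to zero.  The result is generally asymmetric; cosine
    similarity of its rows is symmetric regardless.
    """
    S = np.asarray(S, dtype=float)
    R = S.shape[0]
    if S.ndim != 2 or S.shape[1] != R:
        raise ValueError("input must be square")
    k = int(np.floor((R - 1) * keep_fraction))
    if k < 1:
        raise ValueError(
            f"keep_fraction {keep_fraction} keeps no connections for {R} regions"
        )
    W = np.abs(S) if by_abs else S.copy()
    np.fill_diagonal(W, -np.inf)
    # indices of the k largest entries per row
    order = np.argsort(-W, axis=1, kind="stable")
    mask = np.zeros_like(W, dtype=bool)
    rows = np.repeat(np.arange(R), k)
    mask[rows, order[:, :k].ravel()] = True
    out = np.where(mask, S, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def cosine_affinity(W: np.ndarray) -> np.ndarray:
    """Cosine similarity between all pairs of rows of ``W``."""
    W = np.asarray(W, dtype=float)
    norms = np.linalg.norm(W, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0)
        raise ValueError(f"zero-norm thresholded rows at regions {bad.tolist()}")
    A = (W @ W.T) / np.outer(norms, norms)
    A = np.clip(A, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    return 0.5 * (A + A.T)


def build_affinity(S: np.ndarray, keep_fraction: float = 0.10) -> np.ndarray:
    """Row-threshold a connectivity matrix and return its cosine affinity."""
    return cosine_affinity(threshold_rows(S, keep_fraction))


def pca_embed(A: np.ndarray, d: int = 3) -> ManifoldEmbedding:
    """PCA of the affinity matrix, rows as observations.

    Columns are mean-centered, the centered matrix is decomposed by SVD,
    and region coordinates are the projections onto the first ``d``
    components.  Sign convention: each component is flipped so its
    largest-magnitude loading is positive, making the embedding
    deterministic across platforms.
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("affinity contains non-finite values")
    Ac = A - A.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if d > rank:
        raise ValueError(f"requested d={d} exceeds rank {rank}")
    for k in range(d):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U[:, :d] * s[:d]
    total = float(np.sum(s**2))
    var = (s[:d] ** 2) / total if total > 0 else np.zeros(d)
    return ManifoldEmbedding(coords=coords, variance_explained=var, aligned=False)


def build_template_manifold(
    baseline_template_S: np.ndarray, d: int = 3, keep_fraction: float = 0.10
) -> ManifoldEmbedding:
    """Embed the group baseline connectivity matrix (the alignment target)."""
    emb = pca_embed(build_affinity(baseline_template_S, keep_fraction), d=d)
    emb.aligned = True  # the template defines the aligned frame
    return emb


def procrustes_align(
    source: ManifoldEmbedding,
    template: ManifoldEmbedding,
    allow_scaling: bool = False,
) -> ManifoldEmbedding:
    """Orthogonally align ``source`` coordinates to the template frame.

    Rotation and reflection only; no translation (PCA output is already
    column-centered) and, by default, no isotropic scaling — scaling
    would distort eccentricity comparisons across epochs.  A scaling
    variant is available for sensitivity analyses.
    """
    X = source.coords
    Y = template.coords
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: source {X.shape} vs template {Y.shape}")
    R, scale = orthogonal_procrustes(X, Y)
    if allow_scaling:
        denom = float(np.sum(X**2))
        factor = scale / denom if denom > 0 else 1.0
    else:
        factor = 1.0
    return ManifoldEmbedding(
        coords=factor * (X @ R),
        variance_explained=source.variance_explained.copy(),
        aligned=True,
        transform=R,
    )


def compute_eccentricity(emb: ManifoldEmbedding) -> np.ndarray:
    """Per-region Euclidean distance from the manifold origin [0, ..., 0]."""
    if not emb.aligned:
        raise ValueError("eccentricity requires an aligned embedding")
    return np.linalg.norm(emb.coords, axis=1)


def embed_covariance(
    S: np.ndarray,
    template: ManifoldEmbedding,
    d: int = 3,
    keep_fraction: float = 0.10,
    allow_scaling: bool = False,
) -> ManifoldEmbedding:
    """Affinity -> PCA -> Procrustes for one centered covariance matrix."""
    emb = pca_embed(build_affinity(S, keep_fraction), d=d)
    return procrustes_align(emb, template, allow_scaling=allow_scaling)


def graph_validation_metrics(
    W: np.ndarray, network_labels
) -> dict[str, np.ndarray]:
    """Weighted graph metrics on a row-thresholded connectivity matrix.

    Returns per-region node ``strength`` (row sum of weights),
    ``within_module_z`` (z-score of within-module strength among the
    module's regions; 0 for single-region or zero-variance modules), and
    ``participation`` coefficient ``1 - sum_m (k_im / k_i)^2``.
    """
    W = np.asarray(W, dtype=float)
    R = W.shape[0]
    labels = np.asarray(network_labels)
    if labels.shape[0] != R:
        raise ValueError("one network label per region required")
    Wo = W.copy()
    np.fill_diagonal(Wo, 0.0)
    strength = Wo.sum(axis=1)

    modules = np.unique(labels)
    # within-module strength of every region toward every module
    k_im = np.stack([Wo[:, labels == m].sum(axis=1) for m in modules], axis=1)

    within = np.zeros(R)
    for mi, m in enumerate(modules):
        members = labels == m
        km = k_im[members, mi]
        sd = km.std(ddof=0)
        if members.sum() > 1 and sd > 0:
            within[members] = (km - km.mean()) / sd
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(strength[:, None] != 0, k_im / strength[:, None], 0.0)
    participation = np.where(strength != 0, 1.0 - np.sum(frac**2, axis=1), 0.0)
    return {
        "strength": strength,
        "within_module_z": within,
        "participation": participation,
    }
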