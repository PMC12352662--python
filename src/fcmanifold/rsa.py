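"""Representational similarity analysis of whole-brain eccentricity.

The six task epochs are treated as conditions and regions as data
channels.  Each subject's 6x6 representational similarity matrix (RSM)
holds the Pearson correlation of whole-brain eccentricity between every
pair of epochs.  Four binary model RSMs code candidate structure (Hand,
Epoch, Learning, Time); each model is scored per subject by uncentered
cosine similarity between off-diagonal vectorizations, with uncertainty
from bootstrap resampling of subjects and a leave-one-out lower bound on
the noise ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import EPOCHS, EPOCH_HAND, EPOCH_STAGE, SCAN_ORDER
from .inference import fdr_bh

MODEL_NAMES = ("Hand", "Epoch", "Learning", "Time")

_IU = np.triu_indices(len(EPOCHS), k=1)


def _utri(rsm: np.ndarray) -> np.ndarray:
    """Upper-triangle (diagonal excluded) vectorization, row-major."""
    return np.asarray(rsm, dtype=float)[_IU]


def build_eccentricity_rsm(ecc_by_epoch: np.ndarray) -> np.ndarray:
    """6x6 Pearson-correlation RSM from a 6 x regions eccentricity panel.

    Rows follow the canonical epoch order.  A constant eccentricity
    vector has no defined correlation and is rejected.
    """
    E = np.asarray(ecc_by_epoch, dtype=float)
    if E.shape[0] != len(EPOCHS):
        raise ValueError(f"expected {len(EPOCHS)} epoch rows, got {E.shape[0]}")
    if np.any(E.std(axis=1) == 0):
        bad = np.flatnonzero(E.std(axis=1) == 0)
        raise ValueError(f"constant eccentricity vector for epochs {bad.tolist()}")
    rsm = np.corrcoef(E)
    np.fill_diagonal(rsm, 1.0)
    return rsm


def make_model_rsm(model: str, time_graded: bool = False) -> np.ndarray:
    """Binary 6x6 model RSM (1 = predicted similar, 0 = dissimilar).

    Hand: same hand.  Epoch: same task stage (Baseline/Early/Late).
    Learning: both Baseline or both non-Baseline.  Time: adjacent in
    scan (acquisition) order (``time_graded`` instead codes similarity
    decaying linearly with scan separation).  The diagonal is set to 1
    but is excluded from all scoring.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; valid: {MODEL_NAMES}")
    n = len(EPOCHS)
    M = np.zeros((n, n))
    scan_pos = {ep: i for i, ep in enumerate(SCAN_ORDER)}
    for i, a in enumerate(EPOCHS):
        for j, b in enumerate(EPOCHS):
            if model == "Hand":
                M[i, j] = float(EPOCH_HAND[a] == EPOCH_HAND[b])
            elif model == "Epoch":
                M[i, j] = float(EPOCH_STAGE[a] == EPOCH_STAGE[b])
            elif model == "Learning":
                M[i, j] = float(
                    (EPOCH_STAGE[a] == "Baseline") == (EPOCH_STAGE[b] == "Baseline")
                )
            elif time_graded:
                sep = abs(scan_pos[a] - scan_pos[b])
                M[i, j] = 1.0 - sep / (len(EPOCHS) - 1)
            else:  # Time, binary first-order adjacency
                M[i, j] = float(abs(scan_pos[a] - scan_pos[b]) == 1)
    np.fill_diagonal(M, 1.0)
    return M


def score_model(empirical: np.ndarray, model: np.ndarray,
                centered: bool = False) -> float:
    """Cosine similarity of the off-diagonal RSM vectorizations.

    Uncentered (raw) by default, matching the named method; ``centered``
    subtracts each vector's mean first (equivalent to Pearson r).
    """
    x = _utri(empirical)
    y = _utri(model)
    if centered:
        x = x - x.mean()
        y = y - y.mean()
    ny = np.linalg.norm(y)
    if ny == 0:
        raise ValueError("model RSM has zero off-diagonal norm")
    nx = np.linalg.norm(x)
    if nx == 0:
        raise ValueError("empirical RSM has zero off-diagonal norm")
    return float(np.dot(x, y) / (nx * ny))


def noise_ceiling_lower(subject_rsms: np.ndarray) -> float:
    """Leave-one-out lower bound on the noise ceiling.

    Mean over subjects of the cosine similarity between each subject's
    RSM and the average RSM of the remaining subjects.
    """
    rsms = np.asarray(subject_rsms, dtype=float)
    n = rsms.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    vals = []
    total = rsms.sum(axis=0)
    for i in range(n):
        rest = (total - rsms[i]) / (n - 1)
        vals.append(score_model(rsms[i], rest) if _utri(rest).any() else np.nan)
    return float(np.nanmean(vals))


@dataclass
class ModelScore:
    model: str
    per_subject: np.ndarray
    mean: float
    boot_mean: float
    boot_se: float
    p_vs_zero: float
    p_vs_ceiling: float


def bootstrap_scores(
    subject_rsms: np.ndarray,
    models: dict[str, np.ndarray] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    q: float = 0.05,
):
    """Bootstrap model scores over subjects.

    Resamples subjects with replacement; per resample the mean
    per-subject cosine score of each model.  One-sided p-values are the
    fraction of bootstrap means at or below zero (vs zero) or at or
    below the leave-one-out noise-ceiling bound (vs ceiling), with the
    +1/(n+1) correction.  Pairwise model differences are tested
    two-sidedly from the bootstrap difference distributions and
    BH-FDR-corrected at ``q``.

    Returns
    -------
    scores : dict model name -> :class:`ModelScore`
    pairwise : list of dicts (model_a, model_b, mean_diff, p, p_fdr, significant)
    """
    import warnings

    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; estimates will be unstable")
    rsms = np.asarray(subject_rsms, dtype=float)
    n = rsms.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if models is None:
        models = {name: make_model_rsm(name) for name in MODEL_NAMES}
    names = list(models)

    per_subject = np.array(
        [[score_model(rsms[s], models[m]) for m in names] for s in range(n)]
    )  # subjects x models
    ceiling = noise_ceiling_lower(rsms)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = per_subject[idx].mean(axis=1)  # n_boot x models

    scores: dict[str, ModelScore] = {}
    for k, name in enumerate(names):
        bm = boot_means[:, k]
        scores[name] = ModelScore(
            model=name,
            per_subject=per_subject[:, k],
            mean=float(per_subject[:, k].mean()),
            boot_mean=float(bm.mean()),
            boot_se=float(bm.std(ddof=1)),
            p_vs_zero=float((1 + np.sum(bm <= 0)) / (n_boot + 1)),
            p_vs_ceiling=float((1 + np.sum(bm <= ceiling)) / (n_boot + 1)),
        )

    pairwise = []
    pvals = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            diff = boot_means[:, a] - boot_means[:, b]
            p_lo = (1 + np.sum(diff <= 0)) / (n_boot + 1)
            p_hi = (1 + np.sum(diff >= 0)) / (n_boot + 1)
            p = min(1.0, 2.0 * min(p_lo, p_hi))
            pairwise.append(
                {
                    "model_a": names[a],
                    "model_b": names[b],
                    "mean_diff": float(diff.mean()),
                    "p": float(p),
                }
            )
            pvals.append(p)
    if pvals:
        reject, p_adj = fdr_bh(np.array(pvals), q=q)
        for row, r, pa in zip(pairwise, reject, p_adj):
            row["p_fdr"] = float(pa)
            row["significant"] = bool(r)
    return scores, pairwise, ceiling


def reexpression_test(
    ecc_panel: np.ndarray,
    region_subset,
    reference_epoch: str = "RH_Learn_Early",
    comparison_epochs: tuple[str, ...] = (
        "RH_Learn_Late",
        "LH_Transfer_Early",
        "LH_Transfer_Late",
    ),
):
    """Test whether the early-learning eccentricity pattern re-emerges.

    For each subject, correlates (Pearson, across ``region_subset``) the
    reference-epoch eccentricity pattern with each comparison epoch,
    then runs a one-way repeated-measures ANOVA over the comparison
    epochs and one-tailed paired t-tests for the directional hypotheses
    that the reference pattern is more similar to early transfer than to
    late learning and than to late transfer.

    Parameters
    ----------
    ecc_panel
        subjects x 6 epochs x regions eccentricity array.

    Returns
    -------
    dict with per-subject similarities (subjects x comparisons), the
    rmANOVA F/p, and the one-tailed contrasts.
    """
    from .inference import paired_contrast, rm_anova_1way

    E = np.asarray(ecc_panel, dtype=float)
    subset = np.asarray(region_subset)
    if subset.dtype == bool:
        subset = np.flatnonzero(subset)
    if subset.size < 3:
        raise ValueError("region_subset must contain at least 3 regions")
    epoch_idx = {ep: i for i, ep in enumerate(EPOCHS)}
    ref = E[:, epoch_idx[reference_epoch]][:, subset]
    sims = np.empty((E.shape[0], len(comparison_epochs)))
    for c, ep in enumerate(comparison_epochs):
        comp = E[:, epoch_idx[ep]][:, subset]
        for s in range(E.shape[0]):
            sims[s, c] = stats.pearsonr(ref[s], comp[s])[0]

    F, p_anova, df1, df2 = rm_anova_1way(sims)
    contrasts = {}
    ce = list(comparison_epochs)
    if "LH_Transfer_Early" in ce:
        i_early = ce.index("LH_Transfer_Early")
        for other in ("RH_Learn_Late", "LH_Transfer_Late"):
            if other in ce:
                t, p = paired_contrast(
                    sims[:, i_early], sims[:, ce.index(other)], sided="one-greater"
                )
                contrasts[f"LH_Transfer_Early>{other}"] = {"t": t, "p": p}
    return {
        "similarities": sims,
        "comparison_epochs": ce,
        "anova": {"F": F, "p": p_anova, "df": (df1, df2)},
        "contrasts": contrasts,
    }
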