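"""Epoch splicing, shrinkage covariance estimation, Riemannian centering.

The pipeline estimates one functional-connectivity matrix per subject and
task epoch with the Ledoit-Wolf shrinkage estimator, then removes the
dominant subject-specific covariance "fingerprint" by tangent-space
centering: every epoch matrix ``S_ij`` is log-mapped at its subject's
geometric mean ``Sbar_i``, parallel-transported to the grand geometric
mean ``Sbar_gm`` with ``G = Sbar_gm^{1/2} Sbar_i^{-1/2}`` (``T_ij^c =
G T_ij G^T``), and exp-mapped back onto the SPD cone.  After centering,
every subject's six epoch matrices share ``Sbar_gm`` as their geometric
mean, so the residual variation reflects epoch (task) effects rather than
who the subject is.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.covariance import LedoitWolf

from . import spd
from .design import EPOCHS, SCAN_EPOCHS


def z_score(ts: np.ndarray) -> np.ndarray:
    """Z-score each column (region) of a volumes x regions matrix.

    Uses the population standard deviation (ddof=0), so the plain sample
    covariance of the result has unit diagonal.  Constant columns are
    rejected: a region with zero variance carries no signal and breaks
    downstream covariance estimation.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be 2-D (volumes x regions)")
    sd = ts.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant region time series at columns {bad.tolist()}")
    return (ts - ts.mean(axis=0)) / sd


def splice_epochs(
    scans: dict[str, np.ndarray],
    discard_lead: int = 6,
    epoch_len: int = 96,
) -> dict[str, np.ndarray]:
    """Cut scan-level time series into the six fixed task epochs.

    Each scan first drops its leading ``discard_lead`` volumes (scanner
    equilibration).  Baseline scans then contribute their first
    ``epoch_len`` volumes; Learning/Transfer scans contribute their first
    ``epoch_len`` (Early) and their last ``epoch_len`` (Late) volumes.

    Parameters
    ----------
    scans
        Mapping of scan label (``LH_Baseline``, ``RH_Baseline``,
        ``RH_Learning``, ``LH_Transfer``) to volumes x regions arrays.

    Returns
    -------
    dict
        Epoch label -> volumes x regions array, in canonical epoch order.
    """
    out: dict[str, np.ndarray] = {}
    for scan_label, epochs in SCAN_EPOCHS.items():
        if scan_label not in scans:
            raise ValueError(f"missing scan '{scan_label}'")
        ts = np.asarray(scans[scan_label], dtype=float)
        n_needed = discard_lead + epoch_len * len(epochs)
        if ts.shape[0] < n_needed:
            raise ValueError(
                f"scan '{scan_label}' too short: {ts.shape[0]} volumes, "
                f"needs >= {n_needed} (discard {discard_lead} + "
                f"{len(epochs)} x {epoch_len})"
            )
        body = ts[discard_lead:]
        if len(epochs) == 1:
            out[epochs[0]] = body[:epoch_len]
        else:
            out[epochs[0]] = body[:epoch_len]
            out[epochs[1]] = body[-epoch_len:]
    return {ep: out[ep] for ep in EPOCHS}


def estimate_covariance(epoch_ts: np.ndarray, assume_z_scored: bool = False) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance of a volumes x regions epoch.

    The estimate is the convex combination
    ``(1 - alpha) * sample_cov + alpha * mean_variance * I`` with the
    analytic shrinkage intensity ``alpha``; it is SPD even with fewer
    volumes than regions.  Input is z-scored per region first (unless
    ``assume_z_scored``), matching the pipeline convention.
    """
    ts = np.asarray(epoch_ts, dtype=float)
    if ts.shape[0] < 2:
        raise ValueError("need at least 2 volumes to estimate covariance")
    if not assume_z_scored:
        ts = z_score(ts)
    else:
        if np.any(ts.std(axis=0, ddof=0) == 0):
            raise ValueError("constant region time series")
    lw = LedoitWolf(assume_centered=False).fit(ts)
    C = 0.5 * (lw.covariance_ + lw.covariance_.T)
    if not (0.0 <= lw.shrinkage_ <= 1.0):  # pragma: no cover - estimator contract
        raise RuntimeError(f"shrinkage intensity {lw.shrinkage_} outside [0, 1]")
    return C


def subject_mean(epoch_covs: dict[str, np.ndarray], tol: float = 1e-10,
                 max_iter: int = 50) -> np.ndarray:
    """Geometric mean of one subject's six epoch covariances."""
    missing = [ep for ep in EPOCHS if ep not in epoch_covs]
    if missing:
        raise ValueError(f"subject is missing epochs: {missing}")
    return spd.geometric_mean([epoch_covs[ep] for ep in EPOCHS], tol=tol,
                              max_iter=max_iter)


def center_covariances(
    covs: dict[tuple, np.ndarray],
    grand_mean: str = "subject_means",
    tol: float = 1e-10,
    max_iter: int = 50,
):
    """Riemannian-center all (subject, epoch) covariances onto a grand mean.

    Parameters
    ----------
    covs
        Mapping ``(subject_id, epoch_label) -> SPD matrix``; every subject
        must have all six epochs.
    grand_mean
        ``"subject_means"`` (default): Karcher mean of the per-subject
        means, weighting every subject equally. ``"all"``: Karcher mean
        over all subject-epoch matrices pooled.

    Returns
    -------
    centered : dict with the same keys
    gm : grand-mean SPD matrix
    subject_means : dict subject_id -> per-subject geometric mean
    """
    subjects = sorted({k[0] for k in covs})
    per_subject: dict = {}
    for s in subjects:
        epoch_covs = {ep: covs[(s, ep)] for ep in EPOCHS if (s, ep) in covs}
        if len(epoch_covs) != len(EPOCHS):
            missing = [ep for ep in EPOCHS if (s, ep) not in covs]
            raise ValueError(f"subject {s!r} missing epochs {missing}")
        per_subject[s] = spd.geometric_mean(
            [epoch_covs[ep] for ep in EPOCHS], tol=tol, max_iter=max_iter
        )
    if grand_mean == "subject_means":
        gm = spd.geometric_mean(list(per_subject.values()), tol=tol, max_iter=max_iter)
    elif grand_mean == "all":
        gm = spd.geometric_mean(
            [covs[(s, ep)] for s in subjects for ep in EPOCHS],
            tol=tol, max_iter=max_iter,
        )
    else:
        raise ValueError("grand_mean must be 'subject_means' or 'all'")

    gm_sqrt = spd.sqrtm(gm)
    centered: dict[tuple, np.ndarray] = {}
    for s in subjects:
        Si = per_subject[s]
        G = gm_sqrt @ spd.invsqrtm(Si)
        for ep in EPOCHS:
            T = spd.tangent_log(covs[(s, ep)], Si)
            Tc = G @ T @ G.T
            centered[(s, ep)] = spd.tangent_exp(0.5 * (Tc + Tc.T), gm)
    return centered, gm, per_subject


def baseline_template(
    centered: dict[tuple, np.ndarray], tol: float = 1e-10, max_iter: int = 50
) -> np.ndarray:
    """Group baseline connectivity matrix for the template manifold.

    Within each subject, the Left and Right Baseline centered matrices are
    averaged arithmetically; the template is the geometric mean of those
    per-subject averages.
    """
    subjects = sorted({k[0] for k in centered})
    per_subject = []
    for s in subjects:
        avg = 0.5 * (centered[(s, "LH_Baseline")] + centered[(s, "RH_Baseline")])
        per_subject.append(spd.eigenvalue_floor(avg, spd.EIG_CLIP))
    return spd.geometric_mean(per_subject, tol=tol, max_iter=max_iter)
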