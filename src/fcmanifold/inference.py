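"""Region-wise and network-wise statistics for eccentricity maps.

Mass-univariate 3x2 repeated-measures ANOVA (Task Stage x Hand) across
regions with pooled BH-FDR correction, post-hoc paired contrasts,
seed-connectivity contrast maps, brain-behavior correlations, and
spatially constrained null models via the Vasa spin-permutation
procedure on spherical parcel centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .design import EPOCHS, EPOCH_HAND, EPOCH_STAGE, HANDS, STAGES

# column order of the (hand, stage) cells within the canonical epoch axis
_CELL_INDEX = {
    (EPOCH_HAND[ep], EPOCH_STAGE[ep]): i for i, ep in enumerate(EPOCHS)
}


def _panel_to_cells(ecc_panel: np.ndarray) -> np.ndarray:
    """Reshape subjects x 6 x regions into subjects x hand(2) x stage(3) x regions."""
    E = np.asarray(ecc_panel, dtype=float)
    if E.ndim == 2:
        E = E[:, :, None]
    if E.shape[1] != len(EPOCHS):
        raise ValueError(f"expected {len(EPOCHS)} epochs on axis 1")
    out = np.empty((E.shape[0], len(HANDS), len(STAGES), E.shape[2]))
    for hi, h in enumerate(HANDS):
        for si, st in enumerate(STAGES):
            out[:, hi, si] = E[:, _CELL_INDEX[(h, st)]]
    return out


def rm_anova_2way(ecc_panel: np.ndarray) -> dict[str, np.ndarray]:
    """Two-way fully within-subject ANOVA (Hand x Stage), vectorized over regions.

    Classical sum-of-squares partition with subject-by-effect error
    terms: ``F_effect = MS_effect / MS_effect-by-subject``.  No
    sphericity correction is applied by default.

    Parameters
    ----------
    ecc_panel
        subjects x 6 epochs x regions (or subjects x 6 for one region).

    Returns
    -------
    dict with arrays ``F_hand, p_hand, F_stage, p_stage, F_inter,
    p_inter`` (one entry per region) and the degrees of freedom ``df``.
    """
    Y = _panel_to_cells(ecc_panel)  # n x 2 x 3 x R
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells: rmANOVA requires complete data")
    n, A, B, R = Y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = Y.mean(axis=(0, 1, 2))
    m_s = Y.mean(axis=(1, 2))            # n x R
    m_a = Y.mean(axis=(0, 2))            # A x R
    m_b = Y.mean(axis=(0, 1))            # B x R
    m_ab = Y.mean(axis=0)                # A x B x R
    m_sa = Y.mean(axis=2)                # n x A x R
    m_sb = Y.mean(axis=1)                # n x B x R

    ss_a = n * B * np.sum((m_a - grand) ** 2, axis=0)
    ss_b = n * A * np.sum((m_b - grand) ** 2, axis=0)
    ss_ab = n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2, axis=(0, 1)
    )
    ss_as = B * np.sum(
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2, axis=(0, 1)
    )
    ss_bs = A * np.sum(
        (m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2, axis=(0, 1)
    )
    resid = (
        Y
        - m_ab[None]
        - m_sa[:, :, None]
        - m_sb[:, None]
        + m_a[None, :, None]
        + m_b[None, None]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2, axis=(0, 1, 2))

    df_a, df_b, df_ab = A - 1, B - 1, (A - 1) * (B - 1)
    df_as, df_bs, df_abs = df_a * (n - 1), df_b * (n - 1), df_ab * (n - 1)

    # effect sums of squares at roundoff scale are treated as exactly zero
    total_ss = np.sum((Y - grand) ** 2, axis=(0, 1, 2))
    eps = 1e-12 * (total_ss + np.finfo(float).tiny)

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_eff / df_eff) / (ss_err / df_err)
        F = np.where(np.isfinite(F) & (ss_eff > eps), F, 0.0)
        p = stats.f.sf(F, df_eff, df_err)
        return F, p

    F_hand, p_hand = f_and_p(ss_a, df_a, ss_as, df_as)
    F_stage, p_stage = f_and_p(ss_b, df_b, ss_bs, df_bs)
    F_inter, p_inter = f_and_p(ss_ab, df_ab, ss_abs, df_abs)
    return {
        "F_hand": F_hand, "p_hand": p_hand,
        "F_stage": F_stage, "p_stage": p_stage,
        "F_inter": F_inter, "p_inter": p_inter,
        "df": {
            "hand": (df_a, df_as),
            "stage": (df_b, df_bs),
            "interaction": (df_ab, df_abs),
        },
    }


def rm_anova_1way(data: np.ndarray):
    """One-way repeated-measures ANOVA on a subjects x conditions array."""
    Y = np.asarray(data, dtype=float)
    n, k = Y.shape
    grand = Y.mean()
    m_c = Y.mean(axis=0)
    m_s = Y.mean(axis=1)
    ss_c = n * np.sum((m_c - grand) ** 2)
    ss_err = np.sum((Y - m_c[None] - m_s[:, None] + grand) ** 2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_c / df1) / (ss_err / df2)
    F = float(F) if np.isfinite(F) else 0.0
    return F, float(stats.f.sf(F, df1, df2)), df1, df2


def anova_map(ecc_panel: np.ndarray, q: float = 0.05, pool: str = "pooled"):
    """Region-wise 3x2 rmANOVA with FDR over regions x 3 effects.

    ``pool="pooled"`` (default) corrects one BH pass over the pooled
    vector of all three effects across regions; ``"per-effect"``
    corrects each effect separately.
    """
    res = rm_anova_2way(ecc_panel)
    R = res["F_hand"].shape[0]
    p_all = np.concatenate([res["p_hand"], res["p_stage"], res["p_inter"]])
    if pool == "pooled":
        reject, p_adj = fdr_bh(p_all, q=q)
        res["q_hand"], res["q_stage"], res["q_inter"] = (
            p_adj[:R], p_adj[R:2 * R], p_adj[2 * R:]
        )
        res["sig_hand"], res["sig_stage"], res["sig_inter"] = (
            reject[:R], reject[R:2 * R], reject[2 * R:]
        )
    elif pool == "per-effect":
        for eff, key in (("hand", "p_hand"), ("stage", "p_stage"), ("inter", "p_inter")):
            reject, p_adj = fdr_bh(res[key], q=q)
            res[f"q_{eff}"] = p_adj
            res[f"sig_{eff}"] = reject
    else:
        raise ValueError("pool must be 'pooled' or 'per-effect'")
    return res


def fdr_bh(p_values: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values); empty input round-trips
    to empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def paired_contrast(a: np.ndarray, b: np.ndarray, sided: str = "two"):
    """Paired t-test on condition difference a - b.

    ``sided``: ``"two"``, ``"one-greater"`` (H1: a > b), or
    ``"one-less"`` (H1: a < b).  Zero-variance differences with zero
    mean return (0.0, nan) flagged by the nan p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    alternative = {"two": "two-sided", "one-greater": "greater", "one-less": "less"}[
        sided
    ]
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d.mean(), 0):
            return 0.0, float("nan")
        return float(np.inf * np.sign(d.mean())), 0.0
    t, p = stats.ttest_rel(a, b, alternative=alternative)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# seed connectivity contrasts

_GROUPINGS = {
    "EarlyVsBaseline": (("RH_Learn_Early", "LH_Transfer_Early"),
                        ("LH_Baseline", "RH_Baseline")),
    "LateVsEarly": (("RH_Learn_Late", "LH_Transfer_Late"),
                    ("RH_Learn_Early", "LH_Transfer_Early")),
}


def seed_contrast(
    centered_covs: dict[tuple, np.ndarray],
    seed_region: int,
    grouping: str,
    network_labels,
    seed_hemisphere: str | None = None,
):
    """Paired-t contrast of seed connectivity maps between epoch groups.

    Per subject, the seed region's row of the centered covariance is
    averaged within each epoch group; a region-wise paired t-test
    between the two group maps follows (positive t = first-named group
    larger).  ``ContraVsIpsi`` groups epochs by the hand contralateral /
    ipsilateral to ``seed_hemisphere``.  The seed's self-connection is
    excluded (NaN in the map).  Also returns the mean t per network.
    """
    subjects = sorted({k[0] for k in centered_covs})
    labels = np.asarray(network_labels)

    if grouping == "ContraVsIpsi":
        if seed_hemisphere not in ("L", "R"):
            raise ValueError("ContraVsIpsi requires seed_hemisphere 'L' or 'R'")
        contra_hand = "R" if seed_hemisphere == "L" else "L"
        g1 = tuple(ep for ep in EPOCHS if EPOCH_HAND[ep] == contra_hand)
        g2 = tuple(ep for ep in EPOCHS if EPOCH_HAND[ep] != contra_hand)
    elif grouping in _GROUPINGS:
        g1, g2 = _GROUPINGS[grouping]
    else:
        raise ValueError(
            f"unknown grouping {grouping!r}; valid: "
            f"{('ContraVsIpsi',) + tuple(_GROUPINGS)}"
        )

    def group_map(s, eps):
        return np.mean([centered_covs[(s, ep)][seed_region] for ep in eps], axis=0)

    A = np.array([group_map(s, g1) for s in subjects])
    B = np.array([group_map(s, g2) for s in subjects])
    R = A.shape[1]
    t_map = np.full(R, np.nan)
    p_map = np.full(R, np.nan)
    for r in range(R):
        if r == seed_region:
            continue
        t_map[r], p_map[r] = paired_contrast(A[:, r], B[:, r], sided="two")

    networks = np.unique(labels)
    net_t = {
        str(m): float(np.nanmean(t_map[labels == m])) for m in networks
    }
    return {"t": t_map, "p": p_map, "network_mean_t": net_t,
            "groups": (g1, g2), "seed_region": int(seed_region)}


# ---------------------------------------------------------------------------
# brain-behavior correlation

def ecc_behavior_correlation(
    delta_ecc: np.ndarray, behavior: np.ndarray, q: float = 0.05
):
    """Across-subject Pearson correlation of eccentricity change vs behavior.

    ``delta_ecc`` is subjects x regions (e.g., Early minus Baseline);
    ``behavior`` one scalar per subject.  Missing behavioral values are
    dropped pairwise; regions with fewer than 4 complete pairs or zero
    variance are flagged missing (NaN r).  Region-wise p-values are
    BH-FDR corrected at ``q``.
    """
    D = np.asarray(delta_ecc, dtype=float)
    b = np.asarray(behavior, dtype=float)
    if D.shape[0] != b.shape[0]:
        raise ValueError("subject dimension mismatch")
    R = D.shape[1]
    r = np.full(R, np.nan)
    p = np.full(R, np.nan)
    for j in range(R):
        mask = np.isfinite(D[:, j]) & np.isfinite(b)
        if mask.sum() < 4:
            continue
        x, y = D[mask, j], b[mask]
        if x.std() == 0 or y.std() == 0:
            continue
        r[j], p[j] = stats.pearsonr(x, y)
    valid = np.isfinite(p)
    sig = np.zeros(R, dtype=bool)
    p_adj = np.full(R, np.nan)
    if valid.any():
        rej, adj = fdr_bh(p[valid], q=q)
        sig[valid] = rej
        p_adj[valid] = adj
    return {"r": r, "p": p, "q": p_adj, "significant": sig}


# ---------------------------------------------------------------------------
# spin test

@dataclass
class SpinNull:
    observed: float
    null: np.ndarray
    p: float
    n_perm: int


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation in SO(3) via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    return Q


def _greedy_assign(D: np.ndarray) -> np.ndarray:
    """Match original regions (rows) to rotated regions (cols).

    Greedy without replacement by ascending distance; ties break on the
    smallest flat (row-major) index, i.e. by region index.  Returns
    ``assign`` with ``assign[row] = col``.
    """
    n = D.shape[0]
    D = D.copy()
    assign = np.full(n, -1, dtype=int)
    for _ in range(n):
        flat = np.argmin(D)
        i, j = divmod(int(flat), n)
        assign[i] = j
        D[i, :] = np.inf
        D[:, j] = np.inf
    return assign


def spin_permutations(
    sphere_xyz: np.ndarray,
    hemisphere,
    n_perm: int = 1000,
    seed: int = 0,
    with_replacement: bool = False,
) -> np.ndarray:
    """Vasa-style spatial permutations of region indices.

    Each permutation draws one random 3D rotation, applies it to the
    left hemisphere's unit-sphere centroids and its x-mirrored version
    to the right hemisphere, then reassigns every region the index of
    the nearest rotated region without replacement (greedy by ascending
    distance).  Hemispheres are matched independently, so unequal sizes
    are fine.

    ``with_replacement`` switches to plain nearest-rotated-neighbor
    assignment (duplicates allowed), the simpler non-Vasa variant.

    Returns an ``n_perm x n_regions`` integer array ``perm`` where
    ``values[perm[k]]`` is the k-th null re-arrangement.
    """
    xyz = np.asarray(sphere_xyz, dtype=float)
    hemi = np.asarray(hemisphere)
    if xyz.shape[0] != hemi.shape[0] or xyz.shape[1] != 3:
        raise ValueError("sphere_xyz must be regions x 3 with matching hemisphere")
    rng = np.random.default_rng(seed)
    mirror = np.diag([-1.0, 1.0, 1.0])
    perms = np.empty((n_perm, xyz.shape[0]), dtype=int)
    idx_by_hemi = {h: np.flatnonzero(hemi == h) for h in np.unique(hemi)}
    for k in range(n_perm):
        Q = _random_rotation(rng)
        for h, idx in idx_by_hemi.items():
            rot = Q if h == "L" else mirror @ Q @ mirror
            rotated = xyz[idx] @ rot.T
            D = cdist(xyz[idx], rotated)
            assign = (np.argmin(D, axis=1) if with_replacement
                      else _greedy_assign(D))
            perms[k, idx] = idx[assign]
    return perms


def spin_null(
    region_values: np.ndarray,
    sphere_xyz: np.ndarray,
    hemisphere,
    statistic_fn,
    n_perm: int = 1000,
    seed: int = 0,
    sided: str = "two",
    perms: np.ndarray | None = None,
) -> SpinNull:
    """Spatial-permutation p-value for a statistic of a region map.

    ``statistic_fn`` maps a region-value vector to a scalar.  The null
    distribution re-evaluates it on spin-permuted values; the p-value
    uses the +1 correction, so it lies in ``[1/(n_perm+1), 1]``.
    """
    v = np.asarray(region_values, dtype=float)
    observed = float(statistic_fn(v))
    if perms is None:
        perms = spin_permutations(sphere_xyz, hemisphere, n_perm=n_perm, seed=seed)
    else:
        n_perm = perms.shape[0]
    null = np.array([statistic_fn(v[perm]) for perm in perms])
    if sided == "two":
        count = np.sum(np.abs(null) >= abs(observed))
    elif sided == "greater":
        count = np.sum(null >= observed)
    elif sided == "less":
        count = np.sum(null <= observed)
    else:
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    p = float((1 + count) / (n_perm + 1))
    return SpinNull(observed=observed, null=null, p=p, n_perm=n_perm)


def network_ecc_behavior(
    delta_ecc: np.ndarray,
    behavior: np.ndarray,
    network_labels,
    hemisphere,
    sphere_xyz: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    q: float = 0.05,
):
    """Network-level eccentricity-change vs behavior correlation with spin nulls.

    Networks are hemisphere-specific (label = hemisphere:network).  Per
    network, member regions' delta eccentricity is averaged per subject
    and correlated with the behavioral scalar.  The null rotates the
    region-to-value assignment (one shared set of spin permutations for
    all networks) and recomputes each network's correlation; p-values
    are BH-FDR corrected across networks.
    """
    D = np.asarray(delta_ecc, dtype=float)
    b = np.asarray(behavior, dtype=float)
    labels = np.asarray(network_labels)
    hemi = np.asarray(hemisphere)
    mask = np.isfinite(b)
    D, b = D[mask], b[mask]
    if b.size < 4:
        raise ValueError("need at least 4 subjects with behavior")

    net_keys = [f"{h}:{m}" for h, m in zip(hemi, labels)]
    uniq = sorted(set(net_keys))
    members = {nk: np.array([i for i, k in enumerate(net_keys) if k == nk])
               for nk in uniq}
    empty = [nk for nk, idx in members.items() if idx.size == 0]
    for nk in empty:  # pragma: no cover - construction makes this impossible
        warnings.warn(f"network {nk} has no regions; skipped")
        del members[nk]

    perms = spin_permutations(sphere_xyz, hemi, n_perm=n_perm, seed=seed)

    def net_corr(values: np.ndarray) -> dict[str, float]:
        # values: subjects x regions (possibly permuted along regions)
        out = {}
        for nk, idx in members.items():
            x = values[:, idx].mean(axis=1)
            if x.std() == 0 or b.std() == 0:
                out[nk] = np.nan
            else:
                out[nk] = stats.pearsonr(x, b)[0]
        return out

    observed = net_corr(D)
    null = {nk: np.empty(n_perm) for nk in members}
    for k in range(n_perm):
        permuted = net_corr(D[:, perms[k]])
        for nk in members:
            null[nk][k] = permuted[nk]

    results = {}
    pvals, order = [], []
    for nk in members:
        r = observed[nk]
        nl = null[nk]
        ok = np.isfinite(nl)
        p = float((1 + np.sum(np.abs(nl[ok]) >= abs(r))) / (ok.sum() + 1))
        results[nk] = {"r": float(r), "p_spin": p, "null": nl}
        pvals.append(p)
        order.append(nk)
    rej, adj = fdr_bh(np.array(pvals), q=q)
    for nk, rj, pa in zip(order, rej, adj):
        results[nk]["q"] = float(pa)
        results[nk]["significant"] = bool(rj)
    return results
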