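"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a multi-subject task-fMRI study at desk scale:
zero-mean multivariate-Gaussian region time series whose covariance per
subject and epoch is

    C_ij = base + subject_i fingerprint
           + hand_modulation(j)  * sensorimotor-block component
           + learning_modulation(j) * transmodal-coupling component
           + diagonal noise,

forced SPD by an eigenvalue floor.  The base covariance combines
network-block structure with a dominant low-dimensional gradient (a
rank-two component graded along the network ordering), mirroring the
hierarchical unimodal-to-transmodal organization of cortical FC; this
graded spectrum is what makes the low-dimensional manifold embedding
stable.  Subject fingerprints are strong symmetric low-rank updates,
fixed across epochs, reproducing the subject-level clustering that
dominates uncentered FC.  The hand modulation (+1 for epochs performed
with the hand contralateral to the designated left-hemisphere
sensorimotor block, -1 otherwise) scales the sensorimotor block's
internal covariance; the learning modulation (0 at Baseline, 1 at
Early, 0.5 at Late) scales the transmodal block's coupling with the
rest of the brain — a connectivity-profile reorganization, deliberately
re-applied at early transfer, the structure the re-expression analysis
probes.

Parcel metadata places regions on the unit sphere with networks in
concentrated spatial caps (spatial autocorrelation for the spin test)
and unequal network sizes (graded affinity spectrum).  Behavioral
trials implement a 45 degree clockwise visuomotor rotation with
subject-varying explicit strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import EPOCHS, EPOCH_HAND, EPOCH_STAGE
from .spd import eigenvalue_floor

NETWORK_NAMES = (
    "SomMot", "Visual", "DorsAttn", "SalVentAttn", "Limbic", "Control",
    "Default", "Subcortex", "Cerebellum",
)

#: learning modulation per epoch: zero at Baseline, full at Early,
#: half at Late (partial washout / consolidation)
LEARNING_MODULATION = {
    ep: {"Baseline": 0.0, "Early": 1.0, "Late": 0.5}[EPOCH_STAGE[ep]]
    for ep in EPOCHS
}


def _learning_level(epoch: str, late: float = 0.5) -> float:
    """Learning modulation: 0 at Baseline, 1 at Early, ``late`` at Late."""
    return {"Baseline": 0.0, "Early": 1.0, "Late": late}[EPOCH_STAGE[epoch]]


@dataclass
class SyntheticDesign:
    """Cohort dimensions and planted effect sizes.

    Defaults are the desk-scale study conditions: 12 subjects, 60
    regions, 96 volumes per epoch (the imaging epoch length).
    ``subject_effect_sd`` is the Frobenius scale of the per-subject
    covariance fingerprint; the default makes subject identity the
    dominant source of FC variance, as in real cohorts.
    ``hand_effect_size`` scales the sensorimotor block's internal
    covariance swing (+/-), ``learning_effect_size`` the transmodal
    block's coupling change with the rest of the brain; both are
    moderate fractions of the base covariance entries.
    """

    n_subjects: int = 12
    n_regions: int = 60
    n_volumes_per_epoch: int = 96
    epochs: tuple[str, ...] = EPOCHS
    subject_effect_sd: float = 8.0
    hand_effect_size: float = 0.3
    learning_effect_size: float = 0.15
    noise_sd: float = 0.25
    learning_weight_spread: tuple = (0.6, 1.4)
    late_modulation: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if tuple(self.epochs) != EPOCHS:
            raise ValueError(f"epochs must be the fixed 6-epoch order {EPOCHS}")
        if self.n_volumes_per_epoch < self.n_regions:
            warnings.warn(
                "fewer volumes than regions: sample covariance is rank-"
                "deficient (Ledoit-Wolf shrinkage remains valid)"
            )


@dataclass
class SyntheticDataset:
    """Generated cohort: time series, ground-truth covariances, metadata."""

    design: SyntheticDesign
    metadata: pd.DataFrame
    timeseries: dict = field(repr=False, default_factory=dict)
    true_covariances: dict = field(repr=False, default_factory=dict)

    @property
    def subjects(self) -> list[int]:
        return sorted({k[0] for k in self.timeseries})


def _network_sizes(per_hemi: int, n_networks: int) -> np.ndarray:
    """Unequal per-hemisphere network sizes.

    The first (sensorimotor) network is kept small and the remaining
    networks decrease in size; unequal blocks give the affinity matrix
    a graded eigenvalue spectrum, so the leading manifold components
    are well separated and stable under sampling noise.
    """
    first = max(2, round(per_hemi / 6))
    w = np.linspace(1.5, 0.7, n_networks - 1)
    rest = np.maximum(2, np.round((per_hemi - first) * w / w.sum()).astype(int))
    while first + rest.sum() > per_hemi:
        rest[np.argmax(rest)] -= 1
    while first + rest.sum() < per_hemi:
        rest[np.argmin(rest)] += 1
    return np.concatenate([[first], rest])


def generate_parcel_metadata(
    n_regions: int, n_networks: int, seed: int, cap_sd: float = 0.22
) -> pd.DataFrame:
    """Parcel metadata table with spatially clustered networks.

    Regions split equally between hemispheres.  Each network gets a
    random cap center per hemisphere (right hemisphere mirrored in x)
    and member centroids are drawn by perturbing the center with
    isotropic Gaussian noise of scale ``cap_sd`` and re-normalizing —
    a von-Mises-Fisher-like concentration that yields contiguous
    spherical caps and hence realistic spatial autocorrelation.

    The first network's left-hemisphere regions form the designated
    ``sensorimotor`` block; the last network (both hemispheres) forms
    the ``transmodal`` block.
    """
    if n_regions % 2 != 0:
        raise ValueError("n_regions must be even (split across hemispheres)")
    if n_networks < 3:
        raise ValueError("need at least 3 networks")
    rng = np.random.default_rng(seed)
    per_hemi = n_regions // 2
    sizes = _network_sizes(per_hemi, n_networks)
    names = [
        NETWORK_NAMES[i % len(NETWORK_NAMES)]
        + ("" if i < len(NETWORK_NAMES) else f"_{i // len(NETWORK_NAMES)}")
        for i in range(n_networks)
    ]
    centers = rng.standard_normal((n_networks, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)

    rows = []
    region_id = 0
    for hemi in ("L", "R"):
        for ni in range(n_networks):
            for _ in range(sizes[ni]):
                c = centers[ni] if hemi == "L" else centers[ni] * np.array([-1, 1, 1])
                v = c + cap_sd * rng.standard_normal(3)
                v /= np.linalg.norm(v)
                if ni == 0 and hemi == "L":
                    role = "sensorimotor"
                elif ni == n_networks - 1:
                    role = "transmodal"
                else:
                    role = "other"
                rows.append({
                    "region_id": region_id, "hemisphere": hemi,
                    "network": names[ni], "x": v[0], "y": v[1], "z": v[2],
                    "block_role": role,
                })
                region_id += 1
    return pd.DataFrame(rows)


def _base_covariance(
    metadata: pd.DataFrame,
    within: float = 0.30,
    between: float = 0.08,
    gradient1: float = 0.30,
    gradient2: float = 0.15,
) -> np.ndarray:
    """Shared baseline network structure with a dominant FC gradient.

    Network blocks (``within`` on-block, ``between`` off-block) plus a
    rank-two graded component: networks are ordered along a principal
    gradient (linear loading) with a secondary quadratic gradient, so
    covariance between networks decays with their separation along the
    hierarchy and the spectrum of the matrix is strongly graded.
    Unit diagonal.
    """
    nets = metadata["network"].to_numpy()
    uniq = list(dict.fromkeys(nets))
    pos = np.array([uniq.index(n) for n in nets], dtype=float)
    pos /= max(len(uniq) - 1, 1)
    g1 = 2.0 * pos - 1.0
    g2 = 4.0 * (pos - 0.5) ** 2 - 1.0
    same = nets[:, None] == nets[None, :]
    C = (np.where(same, within, between)
         + gradient1 * np.outer(g1, g1) + gradient2 * np.outer(g2, g2))
    np.fill_diagonal(C, 1.0)
    return C


def _block_indicator(metadata: pd.DataFrame, role: str) -> np.ndarray:
    u = (metadata["block_role"] == role).to_numpy(dtype=float)
    if u.sum() == 0:
        raise ValueError(f"metadata has no regions with block_role={role!r}")
    return u


def hand_modulation_sign(epoch: str, sensorimotor_hemisphere: str = "L") -> float:
    """+1 for epochs using the hand contralateral to the block's hemisphere."""
    contra_hand = "R" if sensorimotor_hemisphere == "L" else "L"
    return 1.0 if EPOCH_HAND[epoch] == contra_hand else -1.0


def generate_subject_dataset(
    design: SyntheticDesign, metadata: pd.DataFrame, fingerprint_rank: int = 6
) -> SyntheticDataset:
    """Sample per-subject, per-epoch region time series.

    The subject fingerprint is a symmetric rank-``fingerprint_rank``
    update with Gaussian weights, normalized so its expected Frobenius
    norm equals ``design.subject_effect_sd``; the hand component is the
    sensorimotor block's internal covariance (indicator outer product),
    the learning component the symmetric coupling of the transmodal
    block with all remaining regions.  Ground-truth ``C_ij`` for every
    cell is recorded.  Identical seeds give bitwise-identical output.
    """
    if len(metadata) != design.n_regions:
        raise ValueError(
            f"metadata has {len(metadata)} regions, design expects "
            f"{design.n_regions}"
        )
    rng = np.random.default_rng(design.seed)
    R = design.n_regions
    base = _base_covariance(metadata)
    sm_u = _block_indicator(metadata, "sensorimotor")
    tm_u = _block_indicator(metadata, "transmodal")
    sm_M = np.outer(sm_u, sm_u)
    # heterogeneous (but fixed) per-region weights give the learning effect a
    # reproducible spatial profile within the block, so its re-expression at
    # transfer is detectable as pattern similarity, not just a mean shift
    lo, hi = design.learning_weight_spread
    tm_w = tm_u.copy()
    tm_w[tm_u > 0] = np.linspace(lo, hi, int(tm_u.sum()))
    tm_M = np.outer(tm_w, 1.0 - tm_u) + np.outer(1.0 - tm_u, tm_w)

    ds = SyntheticDataset(design=design, metadata=metadata)
    for s in range(design.n_subjects):
        P = np.zeros((R, R))
        for _ in range(fingerprint_rank):
            v = rng.standard_normal(R)
            v /= np.linalg.norm(v)
            P += rng.standard_normal() * np.outer(v, v)
        P *= design.subject_effect_sd / np.sqrt(fingerprint_rank)
        for ep in EPOCHS:
            C = (
                base
                + P
                + design.hand_effect_size * hand_modulation_sign(ep) * sm_M
                + design.learning_effect_size * _learning_level(ep, design.late_modulation) * tm_M
                + design.noise_sd**2 * np.eye(R)
            )
            C = eigenvalue_floor(C, 1e-6)
            if np.linalg.eigvalsh(C)[0] <= 0:  # pragma: no cover
                raise RuntimeError("constructed covariance is not SPD")
            L = np.linalg.cholesky(C)
            ts = rng.standard_normal((design.n_volumes_per_epoch, R)) @ L.T
            ds.timeseries[(s, ep)] = ts
            ds.true_covariances[(s, ep)] = C
    return ds


def reexpression_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """Study conditions for the pattern re-expression scenario.

    A stronger, more spatially heterogeneous learning coupling
    (effect 0.2, per-region weights spread 0.2-1.8) with a weaker late
    re-expression level (0.25 of the early modulation), so the
    early-learning eccentricity pattern is distinctive enough — and
    sufficiently attenuated at late transfer — for its re-emergence at
    early transfer to be detectable as pattern similarity across
    subjects.  Pattern correlation is scale-invariant, so early/late
    discrimination requires a real contrast in how strongly the pattern
    is expressed relative to noise, not merely a scaled-down copy.
    """
    kw = dict(learning_effect_size=0.2, learning_weight_spread=(0.2, 1.8),
              late_modulation=0.25, seed=seed)
    kw.update(overrides)
    return SyntheticDesign(**kw)


# ---------------------------------------------------------------------------
# eccentricity panels with planted representational structure

def generate_eccentricity_panel(
    n_subjects: int,
    n_regions: int,
    structure: str = "Hand",
    effect: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Simulate subjects x 6 epochs x regions eccentricity maps directly.

    A shared regional baseline profile is modulated by a spatial
    pattern whose epoch weighting follows one of the binary RSA model
    structures (``Hand``, ``Epoch``, ``Learning``, ``Time``) or carries
    no epoch structure at all (``null``).  Useful for exercising the
    RSA stage without the full covariance pipeline.
    """
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(n_regions) + 3.0
    pattern = rng.standard_normal(n_regions)
    if structure == "null":
        weights = np.zeros(len(EPOCHS))
    elif structure == "Hand":
        weights = np.array([1.0 if EPOCH_HAND[ep] == "L" else -1.0 for ep in EPOCHS])
    elif structure == "Epoch":
        stage_w = {"Baseline": -1.0, "Early": 1.0, "Late": 0.0}
        weights = np.array([stage_w[EPOCH_STAGE[ep]] for ep in EPOCHS])
    elif structure == "Learning":
        weights = np.array(
            [-1.0 if EPOCH_STAGE[ep] == "Baseline" else 1.0 for ep in EPOCHS]
        )
    elif structure == "Time":
        weights = np.linspace(-1.0, 1.0, len(EPOCHS))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    panel = np.empty((n_subjects, len(EPOCHS), n_regions))
    for s in range(n_subjects):
        for j in range(len(EPOCHS)):
            panel[s, j] = (
                base
                + effect * weights[j] * pattern
                + noise_sd * rng.standard_normal(n_regions)
            )
    return np.abs(panel)


# ---------------------------------------------------------------------------
# behavioral trials

TARGET_ANGLES = np.arange(0, 360, 45)

SCAN_N_TRIALS = {
    "LH_Baseline": 64, "RH_Baseline": 64, "RH_Learning": 160,
    "Report": 16, "LH_Transfer": 80,
}


def generate_behavioral_trials(
    n_subjects: int,
    strategy_sd: float = 12.0,
    seed: int = 0,
    rotation: float = 45.0,
    decay_tau: float = 30.0,
    residual_error: float = 4.0,
    motor_noise_sd: float = 3.5,
    transfer_carryover: float = 0.8,
    flag_rates: dict | None = None,
    strategy_override: float | None = None,
) -> pd.DataFrame:
    """Simulate the visuomotor-rotation behavioral session for a cohort.

    Each subject draws an explicit re-aiming strategy magnitude
    ``s_i`` in [0, 45] degrees (truncated normal around half the
    rotation with SD ``strategy_sd``, or forced by
    ``strategy_override``).  Baseline errors are small motor noise.
    Learning errors start at ``rotation - s_i`` (the strategy
    compensates immediately) and decay exponentially with time constant
    ``decay_tau`` trials toward ``residual_error``.  Transfer errors
    start near ``rotation - transfer_carryover * s_i`` — carried
    strategy drives intermanual transfer — plus a share of the residual
    late-learning error, and decay likewise.  Report angles are
    ``s_i`` plus noise.  Clockwise errors are negative (counter-
    clockwise-positive convention).  A small fraction of trials carries
    early-start / timeout / cursor-jump flags and sub-floor reaction
    times.
    """
    if strategy_sd < 0:
        raise ValueError("strategy_sd must be >= 0")
    rates = {"early_start": 0.04, "timeout": 0.05, "cursor_jump": 0.02,
             "fast_rt": 0.01}
    if flag_rates:
        rates.update(flag_rates)
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        if strategy_override is not None:
            s_i = float(strategy_override)
        else:
            s_i = float(np.clip(
                rotation / 2 + strategy_sd * rng.standard_normal(), 0.0, rotation
            ))
        final_learning = residual_error
        for scan, n_trials in SCAN_N_TRIALS.items():
            # pseudorandomized targets in 8-trial bins
            targets = np.concatenate([
                rng.permutation(TARGET_ANGLES)
                for _ in range(int(np.ceil(n_trials / 8)))
            ])[:n_trials]
            t_idx = np.arange(1, n_trials + 1)
            noise = motor_noise_sd * rng.standard_normal(n_trials)
            if scan in ("LH_Baseline", "RH_Baseline"):
                err = noise
            elif scan in ("RH_Learning", "Report"):
                start = max(rotation - s_i - residual_error, 0.0)
                err = -(start * np.exp(-(t_idx - 1) / decay_tau)
                        + residual_error) + noise
            else:  # LH_Transfer
                start = max(
                    rotation - transfer_carryover * s_i
                    + 0.5 * final_learning - residual_error, 0.0)
                err = -(start * np.exp(-(t_idx - 1) / decay_tau)
                        + residual_error) + noise
            err = np.mod(err + 180.0, 360.0) - 180.0
            endpoint = np.mod(targets + err, 360.0)
            report = np.full(n_trials, np.nan)
            if scan == "Report":
                report = np.mod(
                    targets + s_i + 2.0 * rng.standard_normal(n_trials), 360.0
                )
            rt = rng.lognormal(np.log(350.0), 0.25, n_trials)
            fast = rng.random(n_trials) < rates["fast_rt"]
            rt[fast] = rng.uniform(30.0, 90.0, fast.sum())
            mt = rng.lognormal(np.log(450.0), 0.25, n_trials)
            for k in range(n_trials):
                rows.append({
                    "subject_id": s, "scan_label": scan, "trial_index": int(t_idx[k]),
                    "target_angle": float(targets[k]),
                    "endpoint_angle": float(endpoint[k]),
                    "reaction_time": float(rt[k]), "movement_time": float(mt[k]),
                    "early_start": bool(rng.random() < rates["early_start"]),
                    "timeout": bool(rng.random() < rates["timeout"]),
                    "cursor_jump": bool(rng.random() < rates["cursor_jump"]),
                    "report_angle": float(report[k]) if np.isfinite(report[k])
                                    else np.nan,
                })
    return pd.DataFrame(rows)
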