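"""End-to-end orchestration: synthetic cohort -> eccentricity -> statistics.

``eccentricity_pipeline`` is the analysis backbone used by the tests
and the CLI: Ledoit-Wolf covariance per subject/epoch, Riemannian
centering, baseline template manifold, Procrustes-aligned embeddings,
and the subjects x epochs x regions eccentricity panel.
``run_pipeline`` wraps it with config handling, serialization, and a
run manifest; completed stages are skipped on rerun when the config
hash matches.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import connectivity as conn
from . import inference, io, manifold, rsa
from .design import EPOCHS
from .synth import SyntheticDesign, generate_behavioral_trials, \
    generate_parcel_metadata, generate_subject_dataset


def estimate_all_covariances(timeseries: dict) -> dict:
    """Ledoit-Wolf covariance for every (subject, epoch) time series."""
    return {key: conn.estimate_covariance(ts) for key, ts in timeseries.items()}


def eccentricity_pipeline(
    timeseries: dict,
    d: int = 3,
    keep_fraction: float = 0.10,
    grand_mean: str = "subject_means",
    return_intermediates: bool = False,
):
    """Covariance -> centering -> template -> aligned manifolds -> eccentricity.

    Parameters
    ----------
    timeseries
        Mapping (subject, epoch) -> volumes x regions array; every
        subject needs all six epochs.

    Returns
    -------
    panel : subjects x 6 x regions eccentricity array (canonical epoch
        order; subjects sorted)
    subjects : sorted subject ids
    extras : dict with centered covariances, grand mean, template
        embedding (only if ``return_intermediates``)
    """
    covs = estimate_all_covariances(timeseries)
    centered, gm, subj_means = conn.center_covariances(covs, grand_mean=grand_mean)
    template_S = conn.baseline_template(centered)
    template = manifold.build_template_manifold(template_S, d=d,
                                                keep_fraction=keep_fraction)
    subjects = sorted({k[0] for k in centered})
    R = template.n_regions
    panel = np.empty((len(subjects), len(EPOCHS), R))
    for si, s in enumerate(subjects):
        for ei, ep in enumerate(EPOCHS):
            emb = manifold.embed_covariance(
                centered[(s, ep)], template, d=d, keep_fraction=keep_fraction
            )
            panel[si, ei] = manifold.compute_eccentricity(emb)
    if return_intermediates:
        return panel, subjects, {
            "covariances": covs, "centered": centered, "grand_mean": gm,
            "subject_means": subj_means, "template_S": template_S,
            "template": template,
        }
    return panel, subjects


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "fcmanifold_run"
    synthetic: bool = True
    null: bool = False  # zero all planted effects
    n_subjects: int = 12
    n_regions: int = 60
    n_networks: int = 6
    n_volumes_per_epoch: int = 96
    subject_effect_sd: float = 8.0
    hand_effect_size: float = 0.3
    learning_effect_size: float = 0.15
    noise_sd: float = 0.25
    strategy_sd: float = 12.0
    d: int = 3
    keep_fraction: float = 0.10
    grand_mean: str = "subject_means"
    q: float = 0.05
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0
    rt_floor: float = 100.0
    extreme_quantile: float = 0.0005
    # external inputs (used when synthetic=False)
    timeseries_dir: str | None = None
    metadata_path: str | None = None
    trials_path: str | None = None

    def validate(self) -> None:
        if self.n_regions % 2:
            raise ValueError("n_regions must be even")
        if not self.synthetic:
            for name in ("timeseries_dir", "metadata_path", "trials_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"missing input for {name}: {p!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_done(manifest: dict, stage: str, cfg_hash: str) -> bool:
    return manifest.get("stages", {}).get(stage, {}).get("config_hash") == cfg_hash


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute behavior -> connectivity -> manifold -> rsa -> inference.

    Writes every stage's outputs plus ``manifest.json`` (config, hash,
    seeds, stage records) into ``config.out_dir``.  On rerun with an
    unchanged config, stages whose outputs already exist are skipped.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest_path = out / "manifest.json"
    manifest = {"config": asdict(config), "config_hash": cfg_hash, "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash:
            manifest = old

    def record(stage, **info):
        manifest.setdefault("stages", {})[stage] = {
            "config_hash": cfg_hash, **info
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    # ---- inputs -----------------------------------------------------------
    resume_inputs = (config.synthetic
                     and _stage_done(manifest, "synth", cfg_hash)
                     and (out / "metadata.tsv").exists()
                     and (out / "trials.tsv").exists())
    resume_panel = (_stage_done(manifest, "manifold", cfg_hash)
                    and (out / "eccentricity.tsv").exists())
    if config.synthetic:
        hand = 0.0 if config.null else config.hand_effect_size
        learn = 0.0 if config.null else config.learning_effect_size
        design = SyntheticDesign(
            n_subjects=config.n_subjects, n_regions=config.n_regions,
            n_volumes_per_epoch=config.n_volumes_per_epoch,
            subject_effect_sd=config.subject_effect_sd,
            hand_effect_size=hand, learning_effect_size=learn,
            noise_sd=config.noise_sd, seed=config.seed,
        )
        metadata = generate_parcel_metadata(
            config.n_regions, config.n_networks, seed=config.seed
        )
        if resume_inputs and resume_panel:
            metadata = io.read_metadata(out / "metadata.tsv")
            trials = io.read_trials(out / "trials.tsv")
            timeseries = None  # manifold stage resumes from disk
        else:
            dataset = generate_subject_dataset(design, metadata)
            timeseries = dataset.timeseries
            trials = generate_behavioral_trials(
                config.n_subjects, strategy_sd=config.strategy_sd,
                seed=config.seed + 1,
            )
            io.write_metadata(out / "metadata.tsv", metadata)
            io.write_trials(out / "trials.tsv", trials)
            record("synth", n_subjects=config.n_subjects, seed=config.seed)
    else:
        metadata = io.read_metadata(config.metadata_path)
        trials = io.read_trials(config.trials_path)
        raw = io.read_cell_matrices(config.timeseries_dir, "ts")
        if not raw:
            raise ValueError(
                f"no time-series tables found in {config.timeseries_dir!r}"
            )
        timeseries = raw

    # ---- behavior ---------------------------------------------------------
    filtered, report = beh.filter_trials(
        trials, rt_floor=config.rt_floor,
        extreme_quantile=config.extreme_quantile,
    )
    summary = beh.behavior_summary(filtered)
    summary.to_csv(out / "behavior_summary.tsv", sep="\t",
                   float_format=io.FLOAT_FMT)
    (out / "behavior_exclusions.json").write_text(json.dumps(report, indent=2))
    record("behavior", retained=report["retained"], total=report["total"])

    # ---- connectivity + manifold ------------------------------------------
    if resume_panel and timeseries is None:
        panel, subjects = io.read_ecc_panel(out / "eccentricity.tsv")
    else:
        panel, subjects, extras = eccentricity_pipeline(
            timeseries, d=config.d, keep_fraction=config.keep_fraction,
            grand_mean=config.grand_mean, return_intermediates=True,
        )
        io.write_cell_matrices(out / "centered", extras["centered"], "cov")
        io.write_matrix(out / "grand_mean.tsv", extras["grand_mean"])
        io.write_matrix(out / "template_cov.tsv", extras["template_S"])
        io.write_ecc_panel(out / "eccentricity.tsv", panel, subjects)
        record("connectivity", n_cells=len(extras["centered"]))
        record("manifold", d=config.d,
               variance_explained=[float(v) for v in
                                   extras["template"].variance_explained])

    # ---- rsa --------------------------------------------------------------
    rsms = np.stack([rsa.build_eccentricity_rsm(panel[i]) for i in
                     range(panel.shape[0])])
    scores, pairwise, ceiling = rsa.bootstrap_scores(
        rsms, n_boot=config.n_boot, seed=config.seed + 2, q=config.q
    )
    rsa_rows = [
        {"model": m, "mean": sc.mean, "boot_se": sc.boot_se,
         "p_vs_zero": sc.p_vs_zero, "p_vs_ceiling": sc.p_vs_ceiling}
        for m, sc in scores.items()
    ]
    pd.DataFrame(rsa_rows).to_csv(out / "rsa_scores.tsv", sep="\t", index=False)
    pd.DataFrame(pairwise).to_csv(out / "rsa_pairwise.tsv", sep="\t", index=False)
    record("rsa", noise_ceiling=float(ceiling))

    # ---- inference --------------------------------------------------------
    res = inference.anova_map(panel, q=config.q)
    region_ids = metadata["region_id"].to_numpy()
    anova_df = pd.DataFrame({
        "region_id": region_ids,
        "F_hand": res["F_hand"], "p_hand": res["p_hand"], "q_hand": res["q_hand"],
        "sig_hand": res["sig_hand"],
        "F_stage": res["F_stage"], "p_stage": res["p_stage"],
        "q_stage": res["q_stage"], "sig_stage": res["sig_stage"],
        "F_inter": res["F_inter"], "p_inter": res["p_inter"],
        "q_inter": res["q_inter"], "sig_inter": res["sig_inter"],
    })
    anova_df.to_csv(out / "anova.tsv", sep="\t", index=False)

    # brain-behavior: eccentricity change (RH learning early - RH baseline)
    # vs early learning error
    e_idx = {ep: i for i, ep in enumerate(EPOCHS)}
    delta = panel[:, e_idx["RH_Learn_Early"]] - panel[:, e_idx["RH_Baseline"]]
    behav = summary["early_learning_error"].reindex(subjects).to_numpy()
    n_complete = int(np.isfinite(behav).sum())
    if n_complete >= 4:
        corr = inference.ecc_behavior_correlation(delta, behav, q=config.q)
        pd.DataFrame({
            "region_id": region_ids, "r": corr["r"], "p": corr["p"],
            "q": corr["q"], "significant": corr["significant"],
        }).to_csv(out / "behavior_correlation.tsv", sep="\t", index=False)
        net = inference.network_ecc_behavior(
            delta, behav, metadata["network"], metadata["hemisphere"],
            metadata[["x", "y", "z"]].to_numpy(),
            n_perm=config.n_perm, seed=config.seed + 3, q=config.q,
        )
        pd.DataFrame([
            {"network": nk, "r": v["r"], "p_spin": v["p_spin"], "q": v["q"],
             "significant": v["significant"]} for nk, v in net.items()
        ]).to_csv(out / "network_behavior.tsv", sep="\t", index=False)
    else:
        warnings.warn("fewer than 4 subjects with behavior; correlation skipped")
    record("inference",
           n_sig_hand=int(res["sig_hand"].sum()),
           n_sig_stage=int(res["sig_stage"].sum()),
           n_sig_inter=int(res["sig_inter"].sum()))
    return out
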