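"""Delimited-table serialization for all pipeline artifacts.

Everything is plain TSV with headers so runs are inspectable and
round-trip bit-identically: parcel metadata, per-subject/epoch time
series and covariance matrices, trial tables, eccentricity panels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import EPOCHS

FLOAT_FMT = "%.17g"  # full double precision for exact round trips


def write_matrix(path, M: np.ndarray) -> None:
    np.savetxt(path, np.asarray(M, dtype=float), delimiter="\t", fmt=FLOAT_FMT)


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_metadata(path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_trials(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"early_start": bool, "timeout": bool, "cursor_jump": bool},
    )


def _cell_name(subject, epoch: str) -> str:
    return f"sub-{subject:02d}_epoch-{epoch}" if isinstance(subject, (int, np.integer)) \
        else f"sub-{subject}_epoch-{epoch}"


def write_cell_matrices(directory, matrices: dict, prefix: str) -> None:
    """Write a (subject, epoch)-keyed dict of matrices, one TSV per cell."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (s, ep), M in matrices.items():
        write_matrix(directory / f"{prefix}_{_cell_name(s, ep)}.tsv", M)


def read_cell_matrices(directory, prefix: str) -> dict:
    """Read back matrices written by :func:`write_cell_matrices`."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob(f"{prefix}_sub-*_epoch-*.tsv")):
        stem = path.stem[len(prefix) + 1:]
        sub_part, epoch_part = stem.split("_epoch-")
        subject = sub_part[len("sub-"):]
        try:
            subject = int(subject)
        except ValueError:
            pass
        out[(subject, epoch_part)] = read_matrix(path)
    return out


def write_ecc_panel(path, panel: np.ndarray, subjects=None) -> None:
    """Eccentricity panel (subjects x 6 x regions) as a long TSV."""
    panel = np.asarray(panel, dtype=float)
    n, e, r = panel.shape
    if subjects is None:
        subjects = list(range(n))
    rows = []
    for si, s in enumerate(subjects):
        for ei, ep in enumerate(EPOCHS):
            for ri in range(r):
                rows.append((s, ep, ri, panel[si, ei, ri]))
    pd.DataFrame(
        rows, columns=["subject_id", "epoch", "region_id", "eccentricity"]
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ecc_panel(path):
    """Inverse of :func:`write_ecc_panel`; returns (panel, subjects)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    subjects = sorted(df["subject_id"].unique())
    regions = sorted(df["region_id"].unique())
    panel = np.full((len(subjects), len(EPOCHS), len(regions)), np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    e_idx = {e: i for i, e in enumerate(EPOCHS)}
    r_idx = {r: i for i, r in enumerate(regions)}
    panel[
        df["subject_id"].map(s_idx), df["epoch"].map(e_idx),
        df["region_id"].map(r_idx),
    ] = df["eccentricity"]
    return panel, subjects
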