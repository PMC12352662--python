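"""Task-design constants shared across the pipeline.

The experiment comprises six equal-length task epochs in a fixed order.
Each epoch is characterized by the hand used (Left/Right) and the task
stage (Baseline / Early / Late), forming a complete 3x2 within-subject
design. Scan order (the order epochs were acquired) differs from the
(hand, stage) factorial layout and matters only for the "Time" RSA model.
"""

from __future__ import annotations

#: Canonical epoch order used everywhere (rows/cols of RSMs, axis 1 of
#: eccentricity panels).
EPOCHS: tuple[str, ...] = (
    "LH_Baseline",
    "RH_Baseline",
    "RH_Learn_Early",
    "RH_Learn_Late",
    "LH_Transfer_Early",
    "LH_Transfer_Late",
)

EPOCH_INDEX: dict[str, int] = {name: i for i, name in enumerate(EPOCHS)}

#: Hand used in each epoch.
EPOCH_HAND: dict[str, str] = {
    "LH_Baseline": "L",
    "RH_Baseline": "R",
    "RH_Learn_Early": "R",
    "RH_Learn_Late": "R",
    "LH_Transfer_Early": "L",
    "LH_Transfer_Late": "L",
}

#: Task stage of each epoch.
EPOCH_STAGE: dict[str, str] = {
    "LH_Baseline": "Baseline",
    "RH_Baseline": "Baseline",
    "RH_Learn_Early": "Early",
    "RH_Learn_Late": "Late",
    "LH_Transfer_Early": "Early",
    "LH_Transfer_Late": "Late",
}

#: Epoch order as acquired in the scanner (baselines, then right-hand
#: learning, then left-hand transfer).  Used by the "Time" RSA model.
SCAN_ORDER: tuple[str, ...] = (
    "LH_Baseline",
    "RH_Baseline",
    "RH_Learn_Early",
    "RH_Learn_Late",
    "LH_Transfer_Early",
    "LH_Transfer_Late",
)

#: Scans (acquisition runs) and the epochs they contribute after splicing.
SCAN_EPOCHS: dict[str, tuple[str, ...]] = {
    "LH_Baseline": ("LH_Baseline",),
    "RH_Baseline": ("RH_Baseline",),
    "RH_Learning": ("RH_Learn_Early", "RH_Learn_Late"),
    "LH_Transfer": ("LH_Transfer_Early", "LH_Transfer_Late"),
}

HANDS: tuple[str, ...] = ("L", "R")
STAGES: tuple[str, ...] = ("Baseline", "Early", "Late")
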