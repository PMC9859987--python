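"""Patient-reported symptom scores (PCSI) and responder dichotomization.

Symptoms are rated on Likert scales of 1-4 or 1-5 (higher = more severe) at
baseline, weekly on-treatment visits and post-treatment follow-up.  A patient
is a *responder* for a symptom when its level at the follow-up timepoint
(default 12 months post-RT) increased by at least 2 levels over baseline;
improvements and +1 changes are non-responders.  Patients missing either
timepoint are excluded, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PCSIRecord",
    "ResponderLabel",
    "dichotomize",
    "cohort_labels",
    "BASELINE",
    "FOLLOWUP_12M",
]

BASELINE = "baseline"
FOLLOWUP_12M = "12m"
DEFAULT_THRESHOLD = 2

#: default symptom -> organ mapping (urinary u* -> bladder, rectal r* -> bowel)
SYMPTOM_ORGAN_MAP = {"u2": "bladder", "r1": "rectum"}


@dataclass(frozen=True)
class PCSIRecord:
    """One Likert rating of one symptom for one patient at one timepoint."""

    patient_id: str
    symptom_id: str
    timepoint: str
    level: int
    scale_max: int = 4

    def __post_init__(self) -> None:
        if not 1 <= int(self.level) <= int(self.scale_max):
            raise ValueError(
                f"level {self.level} outside 1..{self.scale_max} for "
                f"{self.patient_id}/{self.symptom_id}@{self.timepoint}"
            )


@dataclass(frozen=True)
class ResponderLabel:
    """Dichotomized symptom change: responder iff delta >= threshold."""

    patient_id: str
    symptom_id: str
    responder: bool
    delta: int


def dichotomize(
    baseline: int,
    followup: int,
    *,
    threshold: int = DEFAULT_THRESHOLD,
    scale_max: int = 5,
    patient_id: str = "",
    symptom_id: str = "",
) -> ResponderLabel:
    """Classify one (baseline, follow-up) level pair.

    Responder when ``followup - baseline >= threshold`` (default 2 levels, a
    clinically meaningful worsening); decreases never qualify.
    """
    for name, lvl in (("baseline", baseline), ("followup", followup)):
        if lvl is None:
            raise ValueError(f"{name} level is missing; label withheld")
        if not 1 <= int(lvl) <= int(scale_max):
            raise ValueError(f"{name} level {lvl} outside the 1..{scale_max} scale")
    delta = int(followup) - int(baseline)
    return ResponderLabel(
        patient_id=patient_id,
        symptom_id=symptom_id,
        responder=delta >= threshold,
        delta=delta,
    )


def cohort_labels(
    records,
    symptom_id: str,
    followup_timepoint: str = FOLLOWUP_12M,
    *,
    baseline_timepoint: str = BASELINE,
    threshold: int = DEFAULT_THRESHOLD,
) -> tuple[list[ResponderLabel], list[str]]:
    """Per-patient responder labels for one symptom.

    ``records`` is an iterable of :class:`PCSIRecord` or a DataFrame with
    columns patient_id, symptom_id, timepoint, level (and optionally
    scale_max).  Returns ``(labels, incomplete_patient_ids)`` where the second
    list names patients lacking the baseline or follow-up rating.  Duplicate
    (patient, symptom, timepoint) rows raise.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in records],
                "symptom_id": [r.symptom_id for r in records],
                "timepoint": [r.timepoint for r in records],
                "level": [r.level for r in records],
                "scale_max": [r.scale_max for r in records],
            }
        )
    if "scale_max" not in df.columns:
        df["scale_max"] = 5
    key = ["patient_id", "symptom_id", "timepoint"]
    dup = df.duplicated(subset=key)
    if dup.any():
        rows = df.loc[dup, key].to_records(index=False).tolist()
        raise ValueError(f"duplicate PCSI rows: {rows}")
    sub = df[df["symptom_id"] == symptom_id]
    base = sub[sub["timepoint"] == baseline_timepoint].set_index("patient_id")
    fup = sub[sub["timepoint"] == followup_timepoint].set_index("patient_id")
    patients = sorted(set(sub["patient_id"]))
    labels: list[ResponderLabel] = []
    incomplete: list[str] = []
    for pid in patients:
        if pid not in base.index or pid not in fup.index:
            incomplete.append(pid)
            continue
        scale_max = int(max(base.at[pid, "scale_max"], fup.at[pid, "scale_max"]))
        labels.append(
            dichotomize(
                int(base.at[pid, "level"]),
                int(fup.at[pid, "level"]),
                threshold=threshold,
                scale_max=scale_max,
                patient_id=pid,
                symptom_id=symptom_id,
            )
        )
    return labels, incomplete
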