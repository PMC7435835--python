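"""Per-recording OSA screening from per-minute predictions.

The apnea-hypopnea index of a recording is estimated from the per-minute
calls as AHI = 60*N/L events/hour, where L is the number of 1-minute
segments and N the number predicted apneic.  A recording with AHI >= 5
(inclusive, per the AASM definition) is called OSA.  Cohort summaries
report recording-level sensitivity/specificity/accuracy (OSA positive) and
the Pearson correlation of estimated against reference AHI — both against
the PSG-derived value and, where available, against the AHI implied by the
per-minute annotations, since the literature conflates the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .evaluate import ConfusionMatrix, metrics

__all__ = [
    "OSA_THRESHOLD", "RecordingDiagnosis", "CohortSummary",
    "estimate_ahi", "classify_recording", "diagnose_recording",
    "cohort_summary",
]

OSA_THRESHOLD = 5.0  # events/hour; inclusive


def estimate_ahi(L: int, N_apnea: int) -> float:
    """Estimated AHI = 60*N/L events per hour."""
    if L < 1:
        raise ValueError("recording must contain at least one minute")
    if not 0 <= N_apnea <= L:
        raise ValueError(f"apnea-minute count {N_apnea} outside [0, {L}]")
    return 60.0 * N_apnea / L


def classify_recording(ahi: float, threshold: float = OSA_THRESHOLD) -> str:
    """'OSA' if ahi >= threshold (inclusive), else 'non-OSA'."""
    if ahi < 0:
        raise ValueError(f"AHI cannot be negative, got {ahi}")
    return "OSA" if ahi >= threshold else "non-OSA"


@dataclass
class RecordingDiagnosis:
    """Screening result for one recording."""

    record_id: str
    L: int
    N_apnea: int
    estimated_ahi: float
    osa_call: str
    reference_ahi: Optional[float] = None


def diagnose_recording(record_id: str, predicted_labels: Sequence[str],
                       reference_ahi: Optional[float] = None,
                       threshold: float = OSA_THRESHOLD) -> RecordingDiagnosis:
    """Turn per-minute predicted labels into a recording-level call."""
    L = len(predicted_labels)
    n_a = sum(1 for p in predicted_labels if p == "A")
    ahi = estimate_ahi(L, n_a)
    return RecordingDiagnosis(record_id, L, n_a, ahi,
                              classify_recording(ahi, threshold),
                              reference_ahi)


@dataclass
class CohortSummary:
    """Recording-level screening performance over a cohort."""

    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    r_reference: float
    r_annotation: Optional[float]
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def cohort_summary(diagnoses: Sequence[RecordingDiagnosis],
                   truth: Sequence[dict],
                   threshold: float = OSA_THRESHOLD) -> CohortSummary:
    """Score recording-level calls against reference truth.

    ``truth`` holds one mapping per recording with keys ``record_id``,
    ``reference_ahi`` (the PSG-style value defining true OSA status) and
    optionally ``annotation_ahi`` (the value implied by per-minute
    annotations).  Records are matched by id; a mismatch is an error.
    """
    truth_by_id = {t["record_id"]: t for t in truth}
    if set(truth_by_id) != {d.record_id for d in diagnoses}:
        missing = {d.record_id for d in diagnoses} ^ set(truth_by_id)
        raise ValueError(f"record ids do not match between diagnoses and "
                         f"truth: {sorted(missing)}")

    rows = []
    for d in diagnoses:
        t = truth_by_id[d.record_id]
        ref = float(t["reference_ahi"])
        rows.append({
            "record_id": d.record_id,
            "L": d.L,
            "N_apnea": d.N_apnea,
            "estimated_ahi": d.estimated_ahi,
            "reference_ahi": ref,
            "annotation_ahi": t.get("annotation_ahi"),
            "call": d.osa_call,
            "truth": classify_recording(ref, threshold),
        })
    table = pd.DataFrame(rows)

    # recording-level confusion, OSA positive (reuse the minute-level
    # machinery with A=OSA)
    to_sym = {"OSA": "A", "non-OSA": "N"}
    from .evaluate import confusion as _confusion
    cm = _confusion([to_sym[r["truth"]] for r in rows],
                    [to_sym[r["call"]] for r in rows])
    m = metrics(cm)

    est = table["estimated_ahi"].to_numpy()
    r_ref = float(stats.pearsonr(est, table["reference_ahi"].to_numpy())[0])
    r_ann = None
    if table["annotation_ahi"].notna().all():
        r_ann = float(stats.pearsonr(
            est, table["annotation_ahi"].astype(float).to_numpy())[0])

    return CohortSummary(cm, m["accuracy"], m["sensitivity"],
                         m["specificity"], r_ref, r_ann, table)
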