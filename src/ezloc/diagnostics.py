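"""Confusion-matrix diagnostics of single features against the EZ.

Each scored feature (the six lesion features plus the largest-area
designation, which is treated as a seventh binary feature here) is taken
as a flag for "this ROI is the EZ" and scored against the EZ label —
pooled over all seizure-free patients' ROIs, or separately per patient
with a fixed denominator of 22 ROIs.

PPV and FDR are complements among flagged ROIs; when a feature flags
nothing (tp + fp = 0) both are reported as absent (NaN), never coerced
to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import AlignmentError, EmptyCohortError
from .core_data import ALL_FEATURES, CohortTable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def ppv(self) -> float:
        """Percent of flagged ROIs that are EZ; NaN when nothing flagged."""
        flagged = self.tp + self.fp
        return 100.0 * self.tp / flagged if flagged else float("nan")

    @property
    def fdr(self) -> float:
        """Percent of flagged ROIs that are not EZ; NaN when nothing flagged."""
        flagged = self.tp + self.fp
        return 100.0 * self.fp / flagged if flagged else float("nan")


def confusion_counts(flagged, ez) -> ConfusionCounts:
    """Cell counts of a binary flag vector against the EZ label vector."""
    f = np.asarray(flagged, dtype=bool)
    e = np.asarray(ez, dtype=bool)
    if f.shape != e.shape:
        raise AlignmentError(f"length mismatch: {f.shape} vs {e.shape}")
    return ConfusionCounts(
        tp=int((f & e).sum()),
        fp=int((f & ~e).sum()),
        tn=int((~f & ~e).sum()),
        fn=int((~f & e).sum()),
    )


def feature_diagnostics(
    cohort: CohortTable, rater_id: str, scope: str = "pooled"
) -> pd.DataFrame:
    """Accuracy, PPV and FDR of each feature as an EZ flag.

    ``scope='pooled'`` pools every seizure-free patient's ROIs into one
    confusion matrix per feature; ``scope='per_patient'`` returns a
    long-format frame with one row per (patient, feature) and a
    denominator of exactly 22.

    Percentages are returned at full precision; round at report time.
    """
    if scope not in ("pooled", "per_patient"):
        raise ValueError(f"unknown scope {scope!r}")
    sf = cohort.seizure_free()
    if sf.n_patients == 0:
        raise EmptyCohortError("no seizure-free patients in cohort")
    frame = sf.rater_frame(rater_id)

    rows = []
    if scope == "pooled":
        ez = frame["ez"].to_numpy(bool)
        for f in ALL_FEATURES:
            c = confusion_counts(frame[f.value].to_numpy(bool), ez)
            rows.append(
                {
                    "feature": f.value,
                    "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                    "n": c.total,
                    "accuracy": c.accuracy, "ppv": c.ppv, "fdr": c.fdr,
                }
            )
    else:
        for pat, grp in frame.groupby("patient_id", sort=True):
            ez = grp["ez"].to_numpy(bool)
            for f in ALL_FEATURES:
                c = confusion_counts(grp[f.value].to_numpy(bool), ez)
                rows.append(
                    {
                        "patient_id": pat,
                        "feature": f.value,
                        "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                        "n": c.total,
                        "accuracy": c.accuracy, "ppv": c.ppv, "fdr": c.fdr,
                    }
                )
    return pd.DataFrame(rows)
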