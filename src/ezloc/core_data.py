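"""Canonical data model for rater-scored ROI grids.

The scoring unit is a cortical region of interest (ROI): 11 predefined
regions per hemisphere, 22 per patient.  Each rater scores every ROI for
six binary dysplastic features (tubers, cysts, calcifications, increased
cortical thickness, gray-white matter blurring, transmantle sign) and
additionally designates, per patient, the single ROI containing the
largest FCD-affected area.  The epileptogenic zone (EZ) is a study-level
per-ROI label — the resected area in patients who remained seizure-free —
identical across raters.

Cohorts are stored as flat tables keyed by (patient, rater, roi); row
order never influences a result.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from ._errors import CohortValidationError, DuplicationError, SchemaError


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Region(str, enum.Enum):
    FRONTAL_MESIAL = "frontal_mesial"
    FRONTAL_LATERAL = "frontal_lateral"
    FRONTAL_POLAR = "frontal_polar"
    FRONTAL_BASAL = "frontal_basal"
    FRONTAL_CENTRAL = "frontal_central"
    TEMPORAL_MESIAL = "temporal_mesial"
    TEMPORAL_LATERAL = "temporal_lateral"
    PARIETAL_MESIAL = "parietal_mesial"
    PARIETAL_LATERAL = "parietal_lateral"
    OCCIPITAL_MESIAL = "occipital_mesial"
    OCCIPITAL_LATERAL = "occipital_lateral"


@dataclass(frozen=True, order=True)
class RoiId:
    """One of the 22 canonical cortical regions (hemisphere x 11 subregions)."""

    hemisphere: Hemisphere
    region: Region

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.hemisphere.value}/{self.region.value}"


#: All 22 ROIs in canonical (hemisphere, region) order.
ALL_ROIS: tuple[RoiId, ...] = tuple(
    RoiId(h, r) for h in Hemisphere for r in Region
)
N_ROIS_PER_PATIENT = len(ALL_ROIS)
assert N_ROIS_PER_PATIENT == 22


class FeatureName(str, enum.Enum):
    TUBER = "tuber"
    CYST = "cyst"
    CALCIFICATION = "calcification"
    INCREASED_THICKNESS = "increased_thickness"
    GWM_BLURRING = "gwm_blurring"
    TRANSMANTLE_SIGN = "transmantle_sign"
    LARGEST_FCD_AREA = "largest_fcd_area"


#: The six freely combinable per-ROI lesion features.
LESION_FEATURES: tuple[FeatureName, ...] = (
    FeatureName.TUBER,
    FeatureName.CYST,
    FeatureName.CALCIFICATION,
    FeatureName.INCREASED_THICKNESS,
    FeatureName.GWM_BLURRING,
    FeatureName.TRANSMANTLE_SIGN,
)

#: FCD-like features that drive the largest-affected-area designation.
FCD_FEATURES: tuple[FeatureName, ...] = (
    FeatureName.INCREASED_THICKNESS,
    FeatureName.GWM_BLURRING,
    FeatureName.TRANSMANTLE_SIGN,
)

#: All seven scored features (six lesion features + largest-area flag).
ALL_FEATURES: tuple[FeatureName, ...] = LESION_FEATURES + (
    FeatureName.LARGEST_FCD_AREA,
)

FEATURE_COLUMNS = [f.value for f in ALL_FEATURES]
LESION_COLUMNS = [f.value for f in LESION_FEATURES]
FCD_COLUMNS = [f.value for f in FCD_FEATURES]

#: Cohort file schema, in canonical column order.
COHORT_COLUMNS = (
    ["patient_id", "rater_id", "hemisphere", "region"]
    + FEATURE_COLUMNS
    + ["ez", "seizure_free"]
)
_BINARY_COLUMNS = FEATURE_COLUMNS + ["ez", "seizure_free"]
_SORT_KEYS = ["patient_id", "rater_id", "hemisphere", "region"]


def percentage(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, rounded half away from zero.

    The zero-denominator case returns 0.0 so that empty cohorts summarize
    cleanly.
    """
    if denominator == 0:
        return 0.0
    q = (Decimal(100) * Decimal(int(numerator)) / Decimal(int(denominator)))
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RoiObservation:
    """One rater's binary feature vector and EZ label for one patient ROI."""

    patient_id: str
    rater_id: str
    roi: RoiId
    features: Mapping[FeatureName, bool]
    ez: bool
    seizure_free: bool = True

    def __post_init__(self) -> None:
        missing = [f for f in ALL_FEATURES if f not in self.features]
        if missing:
            raise CohortValidationError(
                f"observation {self.patient_id}/{self.rater_id}/{self.roi}: "
                f"missing feature values {[m.value for m in missing]}"
            )


def count_abnormalities(
    obs: RoiObservation,
    include_largest_area: bool = False,
    exclude_calcifications: bool = False,
) -> int:
    """Number of abnormalities present in one ROI observation.

    Counts the six lesion features, optionally adding the largest-area
    designation and optionally dropping calcifications (the three derived
    abnormality-count variants used in the agreement analysis).
    """
    feats = list(LESION_FEATURES)
    if exclude_calcifications:
        feats.remove(FeatureName.CALCIFICATION)
    if include_largest_area:
        feats.append(FeatureName.LARGEST_FCD_AREA)
    return sum(bool(obs.features[f]) for f in feats)


def abnormality_count_column(
    frame: pd.DataFrame,
    include_largest_area: bool = False,
    exclude_calcifications: bool = False,
) -> np.ndarray:
    """Vectorized :func:`count_abnormalities` over a cohort frame."""
    cols = list(LESION_COLUMNS)
    if exclude_calcifications:
        cols.remove(FeatureName.CALCIFICATION.value)
    if include_largest_area:
        cols.append(FeatureName.LARGEST_FCD_AREA.value)
    return frame[cols].to_numpy(dtype=int).sum(axis=1)


class CohortTable:
    """A validated patient x rater x ROI grid.

    Construct via :meth:`from_frame`, :func:`parse_cohort` or the synthetic
    generator.  The underlying frame is canonically sorted, so two cohorts
    built from the same observations in any row order compare equal.
    """

    def __init__(self, frame: pd.DataFrame, _validated: bool = False):
        if not _validated:
            frame = _validate_frame(frame)
        self._frame = frame

    # ---------------------------------------------------------------- basic

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTable":
        return cls(frame)

    @property
    def frame(self) -> pd.DataFrame:
        """Canonical copy of the underlying table."""
        return self._frame.copy()

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(self._frame["patient_id"].unique())

    @property
    def raters(self) -> tuple[str, ...]:
        return tuple(sorted(self._frame["rater_id"].unique()))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_meta(self) -> dict[str, dict[str, bool]]:
        g = self._frame.groupby("patient_id", sort=True)["seizure_free"].first()
        return {p: {"seizure_free": bool(v)} for p, v in g.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortTable({self.n_patients} patients, "
            f"{len(self.raters)} raters, {len(self._frame)} rows)"
        )

    # -------------------------------------------------------------- subsets

    def rater_frame(self, rater_id: str) -> pd.DataFrame:
        """All rows for one rater, canonically sorted by (patient, roi)."""
        if rater_id not in self.raters:
            raise KeyError(f"unknown rater {rater_id!r}; known: {self.raters}")
        sub = self._frame[self._frame["rater_id"] == rater_id]
        return sub.reset_index(drop=True)

    def subset_patients(self, patient_ids) -> "CohortTable":
        keep = set(patient_ids)
        unknown = keep - set(self.patients)
        if unknown:
            raise KeyError(f"unknown patients {sorted(unknown)}")
        sub = self._frame[self._frame["patient_id"].isin(keep)]
        return CohortTable(sub.reset_index(drop=True), _validated=True)

    def seizure_free(self) -> "CohortTable":
        """Subcohort of seizure-free patients (the EZ-referenced analyses
        are restricted to these by contract)."""
        keep = [p for p, m in self.patient_meta.items() if m["seizure_free"]]
        sub = self._frame[self._frame["patient_id"].isin(keep)]
        return CohortTable(sub.reset_index(drop=True), _validated=True)

    # ------------------------------------------------------------ iteration

    def observations(self) -> Iterator[RoiObservation]:
        for row in self._frame.itertuples(index=False):
            yield RoiObservation(
                patient_id=row.patient_id,
                rater_id=row.rater_id,
                roi=RoiId(Hemisphere(row.hemisphere), Region(row.region)),
                features={f: bool(getattr(row, f.value)) for f in ALL_FEATURES},
                ez=bool(row.ez),
                seizure_free=bool(row.seizure_free),
            )


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a raw cohort frame."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = frame[COHORT_COLUMNS].copy()

    df["patient_id"] = df["patient_id"].astype(str)
    df["rater_id"] = df["rater_id"].astype(str)

    valid_hemi = {h.value for h in Hemisphere}
    valid_region = {r.value for r in Region}
    bad_h = set(df["hemisphere"].astype(str)) - valid_hemi
    if bad_h:
        raise SchemaError(f"unknown hemisphere token(s): {sorted(bad_h)}")
    bad_r = set(df["region"].astype(str)) - valid_region
    if bad_r:
        raise SchemaError(f"unknown region token(s): {sorted(bad_r)}")
    df["hemisphere"] = df["hemisphere"].astype(str)
    df["region"] = df["region"].astype(str)

    for col in _BINARY_COLUMNS:
        vals = df[col]
        if vals.dtype == bool:
            df[col] = vals
            continue
        as_str = vals.astype(str).str.strip()
        ok = as_str.isin(["0", "1"])
        if not ok.all():
            idx = int(np.flatnonzero(~ok.to_numpy())[0])
            raise SchemaError(
                f"column {col!r}: non-binary value {vals.iloc[idx]!r} "
                f"at row {idx} (only 0/1 accepted)"
            )
        df[col] = as_str == "1"

    df = df.sort_values(_SORT_KEYS, kind="mergesort").reset_index(drop=True)

    dup = df.duplicated(subset=["patient_id", "rater_id", "hemisphere", "region"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise DuplicationError(
            "duplicate (patient, rater, roi) key: "
            f"({row.patient_id}, {row.rater_id}, {row.hemisphere}/{row.region})"
        )

    # completeness: every (patient, rater) covers all 22 ROIs
    for (pat, rat), grp in df.groupby(["patient_id", "rater_id"], sort=False):
        if len(grp) != N_ROIS_PER_PATIENT:
            raise CohortValidationError(
                f"patient {pat!r}, rater {rat!r}: "
                f"{len(grp)} of {N_ROIS_PER_PATIENT} ROIs present"
            )
        n_largest = int(grp[FeatureName.LARGEST_FCD_AREA.value].sum())
        any_fcd = bool(grp[FCD_COLUMNS].to_numpy().any())
        if n_largest > 1:
            raise CohortValidationError(
                f"patient {pat!r}, rater {rat!r}: {n_largest} ROIs flagged as "
                "largest FCD-affected area (at most one allowed)"
            )
        if any_fcd and n_largest != 1:
            raise CohortValidationError(
                f"patient {pat!r}, rater {rat!r}: FCD-like features present "
                "but no largest FCD-affected area designated"
            )

    # study-level labels must not vary across raters
    for col, key in (("ez", ["patient_id", "hemisphere", "region"]),
                     ("seizure_free", ["patient_id"])):
        var = df.groupby(key, sort=False)[col].nunique()
        if (var > 1).any():
            bad = var[var > 1].index[0]
            raise CohortValidationError(
                f"label {col!r} differs across raters for {bad}"
            )

    # every seizure-free patient has a non-empty EZ
    sf = df[df["seizure_free"]]
    if not sf.empty:
        ez_per_patient = sf.groupby("patient_id", sort=False)["ez"].any()
        if not ez_per_patient.all():
            bad = ez_per_patient[~ez_per_patient].index[0]
            raise CohortValidationError(
                f"seizure-free patient {bad!r} has no EZ-labelled ROI"
            )

    return df


def parse_cohort(path) -> CohortTable:
    """Read and validate a cohort CSV (UTF-8, header row, 0/1 binaries)."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    return CohortTable.from_frame(raw)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV that round-trips through :func:`parse_cohort`."""
    df = cohort.frame
    for col in _BINARY_COLUMNS:
        df[col] = df[col].astype(int)
    df.to_csv(path, index=False)


# --------------------------------------------------------------- summaries


@dataclass(frozen=True)
class FeaturePrevalence:
    patients_positive: int
    patients_total: int
    rois_positive: int
    rois_total: int

    @property
    def patient_pct(self) -> float:
        return percentage(self.patients_positive, self.patients_total)

    @property
    def roi_pct(self) -> float:
        return percentage(self.rois_positive, self.rois_total)


@dataclass(frozen=True)
class PrevalenceSummary:
    """Whole-cohort descriptive summary for one rater.

    Per lesion feature: how many patients have it anywhere and how many
    ROIs carry it; plus the histogram of per-ROI abnormality multiplicity
    (0-6, counting the six lesion features only).
    """

    features: Mapping[FeatureName, FeaturePrevalence]
    histogram: Mapping[int, int]
    patients_total: int
    rois_total: int

    @property
    def rois_abnormal(self) -> int:
        """ROIs carrying at least one lesion feature."""
        return sum(v for k, v in self.histogram.items() if k > 0)

    def multiplicity_pct(self, k: int, of: str = "abnormal") -> float:
        """Percentage of ROIs with exactly *k* abnormalities.

        ``of='abnormal'`` uses abnormal ROIs as the denominator (the
        convention of the narrative summary); ``of='all'`` uses all ROIs.
        """
        denom = self.rois_abnormal if of == "abnormal" else self.rois_total
        return percentage(self.histogram.get(k, 0), denom)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, p in self.features.items():
            rows.append(
                {
                    "feature": f.value,
                    "patients_positive": p.patients_positive,
                    "patients_total": p.patients_total,
                    "patient_pct": p.patient_pct,
                    "rois_positive": p.rois_positive,
                    "rois_total": p.rois_total,
                    "roi_pct": p.roi_pct,
                }
            )
        return pd.DataFrame(rows)


def summarize_prevalence(cohort: CohortTable, rater_id: str) -> PrevalenceSummary:
    """Table-style whole-cohort summary of one rater's scores."""
    df = cohort.rater_frame(rater_id)
    patients_total = df["patient_id"].nunique()
    rois_total = len(df)

    features: dict[FeatureName, FeaturePrevalence] = {}
    for f in LESION_FEATURES:
        col = df[f.value]
        features[f] = FeaturePrevalence(
            patients_positive=int(df.loc[col, "patient_id"].nunique()),
            patients_total=patients_total,
            rois_positive=int(col.sum()),
            rois_total=rois_total,
        )

    counts = abnormality_count_column(df)
    hist = {k: int((counts == k).sum()) for k in range(len(LESION_FEATURES) + 1)}
    return PrevalenceSummary(
        features=features,
        histogram=hist,
        patients_total=patients_total,
        rois_total=rois_total,
    )
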