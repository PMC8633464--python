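"""Synthetic rater-scored cohorts with the structure the analysis assumes.

The study data are two radiologists' score sheets over 22 cortical ROIs
per patient; those sheets are not public, so this module generates
cohorts with the same statistical skeleton:

* baseline per-ROI Bernoulli prevalence for each of the six lesion
  features, calibrated to the whole-cohort ROI prevalences of a
  28-patient TSC surgical series (tubers ~30%, GWM blurring ~18%,
  transmantle sign ~11%, increased thickness ~5%, calcifications ~2%,
  cysts ~2%);
* an epileptogenic zone of 1-4 ROIs per patient in which feature odds
  are multiplied by per-feature odds ratios (odds, not risk, so
  probabilities stay in [0, 1]); default ratios reproduce the observed
  sign pattern of feature-EZ association — all features enriched except
  cysts (odds ratio 1);
* two raters who flip each latent feature independently with
  per-rater false-positive/false-negative rates, giving imperfect but
  calibrated agreement;
* the largest-FCD-area designation assigned per (patient, rater) to the
  ROI with the most observed FCD-like features, ties broken by a seeded
  draw;
* optionally, a planted k-of-S rule that separates EZ from non-EZ ROIs
  exactly, for recovery tests of the rule search.

EZ ROIs are sampled uniformly without spatial adjacency: real resections
are contiguous, but no downstream statistic here sees geometry.
Features are independent across ROIs and across features given EZ
status.  Identical config + seed gives a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from ._errors import ConfigError, PlantingError
from .core_data import (
    ALL_ROIS,
    COHORT_COLUMNS,
    FCD_FEATURES,
    LESION_FEATURES,
    N_ROIS_PER_PATIENT,
    CohortTable,
    FeatureName,
)
from .rule_search import Rule

_LESION_NAMES = [f.value for f in LESION_FEATURES]
_FCD_IDX = [LESION_FEATURES.index(f) for f in FCD_FEATURES]

#: Baseline (non-EZ) per-ROI prevalences; together with the default odds
#: ratios and EZ sizes these imply pooled ROI prevalences close to the
#: published whole-cohort column (see docs/methods.md).
DEFAULT_BASELINE_PREV: dict[str, float] = {
    "tuber": 0.28,
    "cyst": 0.018,
    "calcification": 0.012,
    "increased_thickness": 0.04,
    "gwm_blurring": 0.16,
    "transmantle_sign": 0.09,
}

#: EZ odds multipliers; cysts deliberately unenriched.
DEFAULT_EZ_ODDS_RATIO: dict[str, float] = {
    "tuber": 3.0,
    "cyst": 1.0,
    "calcification": 25.0,
    "increased_thickness": 15.0,
    "gwm_blurring": 4.0,
    "transmantle_sign": 8.0,
}

#: Distribution of EZ extent over 1-4 ROIs, mirroring a resection mix of
#: mostly focal, some lobar, few multilobar procedures.
DEFAULT_EZ_SIZE_DIST: tuple[float, float, float, float] = (
    0.64, 0.18, 0.11, 0.07,
)

DEFAULT_RATER_FLIP: dict[str, dict[str, float]] = {
    "R1": {"fp_rate": 0.02, "fn_rate": 0.10},
    "R2": {"fp_rate": 0.03, "fn_rate": 0.20},
}

#: Fraction of patients seizure-free after surgery (15 of 28).
DEFAULT_P_SEIZURE_FREE = 15 / 28


class RaterNoise(BaseModel):
    fp_rate: float = Field(ge=0.0, le=1.0)
    fn_rate: float = Field(ge=0.0, le=1.0)


class PlantedRuleConfig(BaseModel):
    features: list[str]
    threshold: int
    #: exempt the rule's features from rater noise so the planted
    #: separation survives observation exactly
    guarantee: bool = False

    def to_rule(self) -> Rule:
        return Rule(frozenset(FeatureName(f) for f in self.features),
                    self.threshold)


class SimulationConfig(BaseModel):
    """All knobs of the generator; defaults are the study-like conditions."""

    n_patients: int = Field(default=28, ge=1)
    seed: int = 0
    baseline_prev: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_BASELINE_PREV)
    )
    ez_odds_ratio: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EZ_ODDS_RATIO)
    )
    ez_size_dist: tuple[float, float, float, float] = DEFAULT_EZ_SIZE_DIST
    rater_flip: dict[str, RaterNoise] = Field(
        default_factory=lambda: {
            k: RaterNoise(**v) for k, v in DEFAULT_RATER_FLIP.items()
        }
    )
    p_seizure_free: float = Field(default=DEFAULT_P_SEIZURE_FREE, ge=0.0, le=1.0)
    planted_rule: PlantedRuleConfig | None = None

    @field_validator("baseline_prev", "ez_odds_ratio")
    @classmethod
    def _check_feature_keys(cls, v: dict[str, float], info):
        if set(v) != set(_LESION_NAMES):
            raise ValueError(
                f"{info.field_name} must have exactly the keys {_LESION_NAMES}"
            )
        return v

    @model_validator(mode="after")
    def _check_values(self):
        for name, p in self.baseline_prev.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"baseline_prev[{name}]={p} outside [0, 1]")
        for name, r in self.ez_odds_ratio.items():
            if r <= 0:
                raise ValueError(f"ez_odds_ratio[{name}]={r} must be > 0")
        if abs(sum(self.ez_size_dist) - 1.0) > 1e-9:
            raise ValueError("ez_size_dist must sum to 1")
        if any(p < 0 for p in self.ez_size_dist):
            raise ValueError("ez_size_dist entries must be >= 0")
        if not self.rater_flip:
            raise ValueError("at least one rater is required")
        return self

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        import json

        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        try:
            return cls(**raw)
        except Exception as exc:  # pydantic ValidationError and friends
            raise ConfigError(f"invalid simulation config: {exc}") from exc


TRUTH_COLUMNS = (
    ["patient_id", "hemisphere", "region"]
    + _LESION_NAMES
    + ["latent_ez", "ez", "seizure_free"]
)


@dataclass
class SimulationResult:
    """Observed cohort plus the latent ground truth it was drawn from."""

    cohort: CohortTable
    truth: pd.DataFrame
    config: SimulationConfig


def adjusted_prevalence(p0: float, odds_ratio: float) -> float:
    """Prevalence after multiplying the odds of ``p0`` by ``odds_ratio``."""
    if p0 <= 0.0:
        return 0.0
    if p0 >= 1.0:
        return 1.0
    odds = odds_ratio * p0 / (1.0 - p0)
    return odds / (1.0 + odds)


def _apply_planted_rule(
    latent: np.ndarray, target: np.ndarray, rule: Rule
) -> np.ndarray:
    """Edit latent features in place of a copy so that rows with
    ``target`` True satisfy the rule and the rest do not.

    Only features in the rule's subset are touched, and only as many as
    needed per row.
    """
    if FeatureName.LARGEST_FCD_AREA in rule.features:
        raise PlantingError(
            "cannot plant the largest-area designation: it is derived "
            "per patient, not a free per-ROI feature"
        )
    idx = sorted(LESION_FEATURES.index(f) for f in rule.features)
    t = rule.threshold
    out = latent.copy()
    sub = out[:, idx]
    present = sub.sum(axis=1)
    for row in np.flatnonzero(target & (present < t)):
        need = t - int(sub[row].sum())
        for j in range(len(idx)):
            if need == 0:
                break
            if not sub[row, j]:
                sub[row, j] = True
                need -= 1
    for row in np.flatnonzero(~target & (present >= t)):
        drop = int(sub[row].sum()) - (t - 1)
        for j in range(len(idx)):
            if drop == 0:
                break
            if sub[row, j]:
                sub[row, j] = False
                drop -= 1
    out[:, idx] = sub
    return out


def _assign_largest_area(
    observed: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One largest-area flag per patient at the ROI with the most
    observed FCD-like features; none when a patient shows none.

    ``observed`` has shape (n_patients, 22, 6).
    """
    n_pat = observed.shape[0]
    flags = np.zeros((n_pat, N_ROIS_PER_PATIENT), dtype=bool)
    fcd_counts = observed[:, :, _FCD_IDX].sum(axis=2)
    for i in range(n_pat):
        m = fcd_counts[i].max()
        if m == 0:
            continue
        candidates = np.flatnonzero(fcd_counts[i] == m)
        pick = candidates[0] if len(candidates) == 1 else rng.choice(candidates)
        flags[i, pick] = True
    return flags


def generate_cohort(config: SimulationConfig) -> SimulationResult:
    """Draw a cohort: latent truth, rater observations, validated table.

    Draw order is fixed, so a given (config, seed) is bit-reproducible:
    seizure-freedom, EZ sizes, EZ locations, latent features (in
    canonical feature order), then per-rater flips and largest-area
    tie-breaks in rater-name order.
    """
    n = config.n_patients
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(n)))
    patient_ids = [f"P{i + 1:0{width}d}" for i in range(n)]

    seizure_free = rng.random(n) < config.p_seizure_free
    ez_sizes = rng.choice(
        np.arange(1, 5), size=n, p=np.asarray(config.ez_size_dist, float)
    )
    latent_ez = np.zeros((n, N_ROIS_PER_PATIENT), dtype=bool)
    for i in range(n):
        rois = rng.choice(N_ROIS_PER_PATIENT, size=int(ez_sizes[i]),
                          replace=False)
        latent_ez[i, rois] = True

    latent = np.zeros((n, N_ROIS_PER_PATIENT, len(LESION_FEATURES)),
                      dtype=bool)
    for j, feat in enumerate(LESION_FEATURES):
        p0 = config.baseline_prev[feat.value]
        p1 = adjusted_prevalence(p0, config.ez_odds_ratio[feat.value])
        pmat = np.where(latent_ez, p1, p0)
        latent[:, :, j] = rng.random((n, N_ROIS_PER_PATIENT)) < pmat

    # the observable EZ label exists only where the operational definition
    # applies: resected and seizure-free
    ez = latent_ez & seizure_free[:, None]

    exempt_idx: list[int] = []
    if config.planted_rule is not None:
        rule = config.planted_rule.to_rule()
        flat = latent.reshape(-1, len(LESION_FEATURES))
        flat = _apply_planted_rule(flat, ez.reshape(-1), rule)
        latent = flat.reshape(latent.shape)
        if config.planted_rule.guarantee:
            exempt_idx = sorted(
                LESION_FEATURES.index(f) for f in rule.features
            )

    frames = []
    hemis = [r.hemisphere.value for r in ALL_ROIS]
    regions = [r.region.value for r in ALL_ROIS]
    for rater_id in sorted(config.rater_flip):
        noise = config.rater_flip[rater_id]
        flip_p = np.where(latent, noise.fn_rate, noise.fp_rate)
        flips = rng.random(latent.shape) < flip_p
        if exempt_idx:
            flips[:, :, exempt_idx] = False
        observed = latent ^ flips
        largest = _assign_largest_area(observed, rng)

        df = pd.DataFrame(
            {
                "patient_id": np.repeat(patient_ids, N_ROIS_PER_PATIENT),
                "rater_id": rater_id,
                "hemisphere": hemis * n,
                "region": regions * n,
            }
        )
        for j, feat in enumerate(LESION_FEATURES):
            df[feat.value] = observed[:, :, j].reshape(-1)
        df[FeatureName.LARGEST_FCD_AREA.value] = largest.reshape(-1)
        df["ez"] = ez.reshape(-1)
        df["seizure_free"] = np.repeat(seizure_free, N_ROIS_PER_PATIENT)
        frames.append(df)

    cohort = CohortTable.from_frame(
        pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]
    )

    truth = pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids, N_ROIS_PER_PATIENT),
            "hemisphere": hemis * n,
            "region": regions * n,
        }
    )
    for j, feat in enumerate(LESION_FEATURES):
        truth[feat.value] = latent[:, :, j].reshape(-1)
    truth["latent_ez"] = latent_ez.reshape(-1)
    truth["ez"] = ez.reshape(-1)
    truth["seizure_free"] = np.repeat(seizure_free, N_ROIS_PER_PATIENT)

    return SimulationResult(cohort=cohort, truth=truth, config=config)


def plant_rule(
    result: SimulationResult, rule: Rule, guarantee: bool = False
) -> SimulationResult:
    """Regenerate a cohort from its own config with ``rule`` planted.

    Latent draws reuse the config's seed, so the returned cohort differs
    from ``result`` only by the minimal feature edits that make every EZ
    ROI satisfy the rule and every non-EZ ROI fail it (plus re-drawn
    rater noise and largest-area tie-breaks downstream of the edits).
    With ``guarantee=True`` the rule's features are exempted from rater
    noise, so the separation also holds in every rater's observed scores.
    """
    cfg = result.config.model_copy(
        update={
            "planted_rule": PlantedRuleConfig(
                features=[f.value for f in rule.sorted_features],
                threshold=rule.threshold,
                guarantee=guarantee,
            )
        }
    )
    return generate_cohort(cfg)


# ----------------------------------------------------- printed-count builds


def cohort_from_feature_counts(
    roi_counts: dict[str, int],
    patient_counts: dict[str, int],
    n_patients: int = 28,
    n_seizure_free: int = 15,
    rater_id: str = "R1",
) -> CohortTable:
    """Deterministic single-rater cohort matching per-feature counts.

    Builds a valid 22-ROI grid in which feature ``f`` appears in exactly
    ``patient_counts[f]`` patients and ``roi_counts[f]`` ROIs — the shape
    of a published whole-cohort summary table — so the descriptive
    summary machinery can be exercised against printed counts.  Feature
    placements are independent; multiplicity structure is arbitrary.
    """
    for f in _LESION_NAMES:
        pc, rc = patient_counts[f], roi_counts[f]
        if not 0 <= pc <= n_patients:
            raise ConfigError(f"{f}: patient count {pc} outside 0..{n_patients}")
        if not pc <= rc <= pc * N_ROIS_PER_PATIENT:
            raise ConfigError(
                f"{f}: ROI count {rc} infeasible for {pc} patients"
            )

    mat = {
        f: np.zeros((n_patients, N_ROIS_PER_PATIENT), dtype=bool)
        for f in _LESION_NAMES
    }
    for f in _LESION_NAMES:
        pc, rc = patient_counts[f], roi_counts[f]
        if pc == 0:
            continue
        per_patient = np.zeros(n_patients, dtype=int)
        per_patient[:pc] = 1
        extra = rc - pc
        i = 0
        while extra > 0:
            if per_patient[i % pc] < N_ROIS_PER_PATIENT:
                per_patient[i % pc] += 1
                extra -= 1
            i += 1
        for p in range(pc):
            mat[f][p, : per_patient[p]] = True

    return _single_rater_cohort(mat, n_patients, n_seizure_free, rater_id)


def cohort_from_multiplicity_histogram(
    histogram: dict[int, int],
    n_patients: int = 28,
    n_seizure_free: int = 15,
    rater_id: str = "R1",
) -> CohortTable:
    """Deterministic cohort whose abnormality-multiplicity histogram
    matches ``histogram`` (mapping 0-6 -> ROI count; must total
    22 x n_patients).

    Which features make up a k-abnormality ROI is arbitrary (the first k
    in canonical order), since the multiplicity summary is blind to
    identity.
    """
    total = sum(histogram.values())
    if total != n_patients * N_ROIS_PER_PATIENT:
        raise ConfigError(
            f"histogram totals {total}, expected "
            f"{n_patients * N_ROIS_PER_PATIENT}"
        )
    # round-robin the k-abnormality ROIs across patients' free slots
    mat = {
        f: np.zeros((n_patients, N_ROIS_PER_PATIENT), dtype=bool)
        for f in _LESION_NAMES
    }
    next_slot = np.zeros(n_patients, dtype=int)
    p = 0
    for k in sorted(histogram, reverse=True):
        if k == 0:
            continue
        for _ in range(histogram[k]):
            tries = 0
            while next_slot[p] >= N_ROIS_PER_PATIENT:
                p = (p + 1) % n_patients
                tries += 1
                if tries > n_patients:
                    raise ConfigError("histogram does not fit the grid")
            slot = next_slot[p]
            for f in _LESION_NAMES[:k]:
                mat[f][p, slot] = True
            next_slot[p] += 1
            p = (p + 1) % n_patients
    return _single_rater_cohort(mat, n_patients, n_seizure_free, rater_id)


def _single_rater_cohort(
    mat: dict[str, np.ndarray],
    n_patients: int,
    n_seizure_free: int,
    rater_id: str,
) -> CohortTable:
    width = max(3, len(str(n_patients)))
    patient_ids = [f"P{i + 1:0{width}d}" for i in range(n_patients)]
    seizure_free = np.zeros(n_patients, dtype=bool)
    seizure_free[:n_seizure_free] = True
    ez = np.zeros((n_patients, N_ROIS_PER_PATIENT), dtype=bool)
    ez[:n_seizure_free, 0] = True  # EZ at the first ROI of each SF patient

    fcd_any = np.zeros((n_patients, N_ROIS_PER_PATIENT), dtype=int)
    for f in FCD_FEATURES:
        fcd_any += mat[f.value].astype(int)
    largest = np.zeros((n_patients, N_ROIS_PER_PATIENT), dtype=bool)
    for i in range(n_patients):
        if fcd_any[i].max() > 0:
            largest[i, int(np.argmax(fcd_any[i]))] = True

    hemis = [r.hemisphere.value for r in ALL_ROIS]
    regions = [r.region.value for r in ALL_ROIS]
    df = pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids, N_ROIS_PER_PATIENT),
            "rater_id": rater_id,
            "hemisphere": hemis * n_patients,
            "region": regions * n_patients,
        }
    )
    for f in _LESION_NAMES:
        df[f] = mat[f].reshape(-1)
    df[FeatureName.LARGEST_FCD_AREA.value] = largest.reshape(-1)
    df["ez"] = ez.reshape(-1)
    df["seizure_free"] = np.repeat(seizure_free, N_ROIS_PER_PATIENT)
    return CohortTable.from_frame(df[COHORT_COLUMNS])
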