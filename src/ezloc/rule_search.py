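"""Brute-force search over "at least t of feature subset S" rules.

A rule flags an ROI when at least ``threshold`` of its ``features`` are
present.  A rule is *perfect* for a patient when it flags at least one of
the patient's 22 ROIs and every flagged ROI lies in the EZ — i.e. the
rule points at the EZ with 100% within-patient positive predictive value.
The search enumerates every subset of the feature pool with every
admissible threshold (448 rules for the full 7-feature pool) and ranks
rules by the number of patients for which they are perfect.

Among the top-scoring rules a reduced *frontier* is reported: rules whose
flagging behaviour is exactly reproduced by a rule over a strict subset
of their features are dropped as redundant descriptions of the same
classifier.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._errors import ConfigError, EmptyCohortError
from .core_data import ALL_FEATURES, CohortTable, FeatureName, RoiObservation


@dataclass(frozen=True)
class Rule:
    """A feature subset with a presence threshold."""

    features: frozenset[FeatureName]
    threshold: int

    def __post_init__(self) -> None:
        feats = frozenset(FeatureName(f) for f in self.features)
        object.__setattr__(self, "features", feats)
        if not feats:
            raise ConfigError("rule needs at least one feature")
        if not 1 <= self.threshold <= len(feats):
            raise ConfigError(
                f"threshold {self.threshold} outside 1..{len(feats)}"
            )

    @property
    def sorted_features(self) -> tuple[FeatureName, ...]:
        order = {f: i for i, f in enumerate(ALL_FEATURES)}
        return tuple(sorted(self.features, key=order.__getitem__))

    def label(self) -> str:
        names = ", ".join(f.value for f in self.sorted_features)
        return f"at least {self.threshold} of {{{names}}}"


@dataclass(frozen=True)
class PatientRuleStats:
    n_flagged: int
    tp: int
    fp: int
    perfect: bool


@dataclass(frozen=True)
class RuleEvaluation:
    rule: Rule
    per_patient: Mapping[str, PatientRuleStats]
    n_perfect: int
    n_patients: int
    total_tp: int  # EZ ROIs flagged, reported but never optimized

    def __post_init__(self) -> None:
        assert 0 <= self.n_perfect <= self.n_patients


def apply_rule(rule: Rule, obs: RoiObservation) -> bool:
    """True iff at least ``rule.threshold`` of the rule's features are
    present in the observation."""
    return sum(bool(obs.features[f]) for f in rule.features) >= rule.threshold


# ------------------------------------------------------------- vectorized


def _design(cohort: CohortTable, rater_id: str):
    """Boolean feature matrix, EZ vector and patient codes for the
    seizure-free subcohort of one rater, in canonical order."""
    sf = cohort.seizure_free()
    if sf.n_patients == 0:
        raise EmptyCohortError("no seizure-free patients in cohort")
    frame = sf.rater_frame(rater_id)
    X = frame[[f.value for f in ALL_FEATURES]].to_numpy(bool)
    ez = frame["ez"].to_numpy(bool)
    codes, patients = pd.factorize(frame["patient_id"], sort=True)
    return X, ez, codes, [str(p) for p in patients]


def _evaluate(
    flags: np.ndarray,
    ez: np.ndarray,
    codes: np.ndarray,
    patients: list[str],
    require_unique: bool,
) -> tuple[dict[str, PatientRuleStats], int, int]:
    n_pat = len(patients)
    nf = np.bincount(codes, weights=flags, minlength=n_pat).astype(int)
    tp = np.bincount(codes, weights=flags & ez, minlength=n_pat).astype(int)
    fp = nf - tp
    if require_unique:
        perfect = (nf == 1) & (fp == 0)
    else:
        perfect = (nf >= 1) & (fp == 0)
    per_patient = {
        patients[i]: PatientRuleStats(
            n_flagged=int(nf[i]), tp=int(tp[i]), fp=int(fp[i]),
            perfect=bool(perfect[i]),
        )
        for i in range(n_pat)
    }
    return per_patient, int(perfect.sum()), int(tp.sum())


def _rule_flags(X: np.ndarray, rule: Rule) -> np.ndarray:
    idx = [ALL_FEATURES.index(f) for f in rule.features]
    return X[:, idx].sum(axis=1) >= rule.threshold


def evaluate_rule(
    rule: Rule,
    cohort: CohortTable,
    rater_id: str,
    require_unique: bool = False,
) -> RuleEvaluation:
    """Score one rule over every seizure-free patient's 22 ROIs.

    ``require_unique=True`` tightens "perfect" from "at least one ROI
    flagged, none outside the EZ" to "exactly one ROI flagged and it is
    in the EZ".
    """
    X, ez, codes, patients = _design(cohort, rater_id)
    flags = _rule_flags(X, rule)
    per_patient, n_perfect, total_tp = _evaluate(
        flags, ez, codes, patients, require_unique
    )
    return RuleEvaluation(
        rule=rule,
        per_patient=per_patient,
        n_perfect=n_perfect,
        n_patients=len(patients),
        total_tp=total_tp,
    )


# ----------------------------------------------------------------- search


def enumerate_rules(
    feature_pool: Iterable[FeatureName],
) -> list[Rule]:
    """Every (subset, threshold) pair over the pool, in canonical order."""
    order = {f: i for i, f in enumerate(ALL_FEATURES)}
    pool = sorted({FeatureName(f) for f in feature_pool}, key=order.__getitem__)
    if not pool:
        raise ConfigError("feature pool is empty")
    rules = []
    for k in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, k):
            for t in range(1, k + 1):
                rules.append(Rule(frozenset(combo), t))
    return rules


@dataclass
class SearchResult:
    """All rule evaluations, ranked, plus the non-dominated frontier."""

    evaluations: list[RuleEvaluation]
    frontier: list[RuleEvaluation]
    n_patients: int
    signatures: dict[Rule, bytes] = field(repr=False, default_factory=dict)

    @property
    def n_rules(self) -> int:
        return len(self.evaluations)

    @property
    def best_n_perfect(self) -> int:
        return self.evaluations[0].n_perfect if self.evaluations else 0

    def to_frame(self) -> pd.DataFrame:
        frontier_rules = {e.rule for e in self.frontier}
        rows = []
        for e in self.evaluations:
            rows.append(
                {
                    "features": "+".join(
                        f.value for f in e.rule.sorted_features
                    ),
                    "threshold": e.rule.threshold,
                    "n_perfect": e.n_perfect,
                    "n_patients": e.n_patients,
                    "total_tp": e.total_tp,
                    "frontier_flag": e.rule in frontier_rules,
                }
            )
        return pd.DataFrame(rows)

    def per_patient_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.evaluations:
            feats = "+".join(f.value for f in e.rule.sorted_features)
            for pat, s in e.per_patient.items():
                rows.append(
                    {
                        "features": feats,
                        "threshold": e.rule.threshold,
                        "patient_id": pat,
                        "n_flagged": s.n_flagged,
                        "tp": s.tp,
                        "fp": s.fp,
                        "perfect": s.perfect,
                    }
                )
        return pd.DataFrame(rows)


def _rank_key(e: RuleEvaluation):
    # most perfect patients first, then parsimony (smaller S), then
    # specificity (larger t), then canonical feature order for stability
    return (
        -e.n_perfect,
        len(e.rule.features),
        -e.rule.threshold,
        tuple(f.value for f in e.rule.sorted_features),
    )


def search_rules(
    cohort: CohortTable,
    rater_id: str,
    feature_pool: Iterable[FeatureName] | None = None,
    require_unique: bool = False,
) -> SearchResult:
    """Exhaustive evaluation of every k-of-S rule over the pool.

    Returns all evaluations ranked by (n_perfect desc, |S| asc, t desc)
    and the frontier: among rules attaining the maximum n_perfect, those
    whose exact flag set is not reproduced by a rule over a strict subset
    of their features.
    """
    if feature_pool is None:
        feature_pool = ALL_FEATURES
    rules = enumerate_rules(feature_pool)
    X, ez, codes, patients = _design(cohort, rater_id)

    evaluations: list[RuleEvaluation] = []
    signatures: dict[Rule, bytes] = {}
    for rule in rules:
        flags = _rule_flags(X, rule)
        per_patient, n_perfect, total_tp = _evaluate(
            flags, ez, codes, patients, require_unique
        )
        evaluations.append(
            RuleEvaluation(
                rule=rule,
                per_patient=per_patient,
                n_perfect=n_perfect,
                n_patients=len(patients),
                total_tp=total_tp,
            )
        )
        signatures[rule] = np.packbits(flags).tobytes()

    evaluations.sort(key=_rank_key)
    best = evaluations[0].n_perfect
    top = [e for e in evaluations if e.n_perfect == best]
    frontier = [
        e
        for e in top
        if not any(
            other.rule.features < e.rule.features
            and signatures[other.rule] == signatures[e.rule]
            for other in top
        )
    ]
    return SearchResult(
        evaluations=evaluations,
        frontier=frontier,
        n_patients=len(patients),
        signatures=signatures,
    )
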