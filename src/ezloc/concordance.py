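"""Inter-rater agreement and feature-EZ association statistics.

Two statistics carry the analysis: Cohen's kappa for chance-corrected
agreement between the two raters, and Kendall's tau-b for the association
between a feature's presence across ROIs and the EZ label (and between the
two raters' scores).  For paired binary data tau-b reduces to the phi
coefficient of the 2x2 table, which is what makes it usable on heavily
tied region grids where tau-a would be degenerate.

ROIs from all seizure-free patients are pooled into one vector of length
22 x n_patients; within-patient clustering is deliberately ignored, which
mirrors the pooled design this analysis reproduces and is a known
statistical caveat.

P-values come either from a normal approximation or from seeded label
permutations (default 10,000 shuffles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import AlignmentError, EmptyCohortError, UndefinedMetricError
from .core_data import (
    ALL_FEATURES,
    CohortTable,
    abnormality_count_column,
)

_EPS = 1e-12

#: Derived abnormality-count rows included alongside the seven features.
COUNT_VARIANTS: dict[str, dict[str, bool]] = {
    "n_abnormalities": {},
    "n_abnormalities_incl_largest": {"include_largest_area": True},
    "n_abnormalities_excl_calcifications": {"exclude_calcifications": True},
}


@dataclass(frozen=True)
class MetricResult:
    """A point estimate with its provenance.

    ``table`` is the (a, b, c, d) cell counts — a = both positive,
    b = x only, c = y only, d = both negative — when both inputs are
    binary, else ``None``.
    """

    estimate: float
    p_value: float | None
    method: str
    n: int
    table: tuple[int, int, int, int] | None = None


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 1:
        raise ValueError("expected a 1-D vector")
    return a


def _binary_table(x: np.ndarray, y: np.ndarray):
    """(a, b, c, d) if both vectors are 0/1-valued, else None."""
    if set(np.unique(x)) <= {0, 1} and set(np.unique(y)) <= {0, 1}:
        xb = x.astype(bool)
        yb = y.astype(bool)
        a = int((xb & yb).sum())
        b = int((xb & ~yb).sum())
        c = int((~xb & yb).sum())
        d = int((~xb & ~yb).sum())
        return a, b, c, d
    return None


def _check_lengths(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise AlignmentError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("need at least 2 paired observations")


# ------------------------------------------------------------------ kappa


def cohens_kappa(
    x,
    y,
    method: str = "asymptotic",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> MetricResult:
    """Cohen's kappa between two categorical rating vectors.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    proportion and p_e the chance agreement implied by the marginals.
    Works for binary features and for the small-integer abnormality
    counts alike.

    The asymptotic p-value tests kappa = 0 with the standard
    large-sample null variance; the permutation p-value shuffles one
    rater's labels (p_e is marginal-invariant, so only p_o is
    recomputed per shuffle).

    Raises :class:`UndefinedMetricError` when chance agreement is 1
    (both raters constant with equal marginals), where kappa has no value.
    """
    x = _as_array(x)
    y = _as_array(y)
    _check_lengths(x, y)
    n = len(x)

    cats = np.unique(np.concatenate([x, y]))
    xi = np.searchsorted(cats, x)
    yi = np.searchsorted(cats, y)
    k = len(cats)
    conf = np.bincount(xi * k + yi, minlength=k * k).reshape(k, k)
    p_row = conf.sum(axis=1) / n
    p_col = conf.sum(axis=0) / n
    p_o = np.trace(conf) / n
    p_e = float(p_row @ p_col)
    if p_e >= 1.0 - _EPS:
        raise UndefinedMetricError(
            "Cohen's kappa undefined: chance agreement is 1 "
            "(both raters constant)"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    if method == "asymptotic":
        # Fleiss large-sample variance under H0: kappa = 0
        s = float(np.sum(p_row * p_col * (p_row + p_col)))
        var0 = (p_e + p_e**2 - s) / (n * (1.0 - p_e) ** 2)
        if var0 <= 0:
            p_value = 1.0
        else:
            z = kappa / np.sqrt(var0)
            p_value = float(2.0 * stats.norm.sf(abs(z)))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(yi, (n_perm, 1)), axis=1)
        p_o_perm = (perms == xi).mean(axis=1)
        kappa_perm = (p_o_perm - p_e) / (1.0 - p_e)
        exceed = int((np.abs(kappa_perm) >= abs(kappa) - _EPS).sum())
        p_value = (1 + exceed) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p-value method {method!r}")

    return MetricResult(
        estimate=float(kappa),
        p_value=p_value,
        method=method,
        n=n,
        table=_binary_table(x, y),
    )


# ------------------------------------------------------------------ tau-b


def _phi_from_a(a, n, m1, k1) -> np.ndarray:
    """phi coefficient as a function of the (1,1) cell, margins fixed."""
    denom = np.sqrt(float(m1) * (n - m1) * k1 * (n - k1))
    return (np.asarray(a, dtype=np.int64) * n - m1 * k1) / denom


def kendall_tau_b(
    x,
    y,
    method: str = "permutation",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> MetricResult:
    """Kendall's tau-b (tie-corrected) between two vectors.

    For paired binary data tau-b equals the phi coefficient
    (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) of the 2x2 table.  Either
    vector being constant leaves the statistic undefined
    (:class:`UndefinedMetricError`).

    P-values: ``permutation`` (default) shuffles the second vector with a
    seeded generator and reports the two-sided rank of |tau|;
    ``asymptotic`` uses the normal approximation.
    """
    x = _as_array(x).astype(float)
    y = _as_array(y).astype(float)
    _check_lengths(x, y)
    n = len(x)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedMetricError(
            "Kendall tau undefined for a constant vector"
        )

    tau, p_asym = stats.kendalltau(x, y, variant="b")
    tau = float(tau)
    table = _binary_table(x, y)

    if method == "asymptotic":
        p_value = float(p_asym)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        if table is not None:
            # binary fast path: under permutation only the (1,1) cell moves
            m1 = int(x.sum())
            k1 = int(y.sum())
            perms = rng.permuted(
                np.tile(y.astype(np.int8), (n_perm, 1)), axis=1
            )
            a_perm = perms @ x.astype(np.int64)
            tau_perm = _phi_from_a(a_perm, n, m1, k1)
        else:
            tau_perm = np.empty(n_perm)
            yp = y.copy()
            for i in range(n_perm):
                rng.shuffle(yp)
                tau_perm[i] = stats.kendalltau(x, yp, variant="b").statistic
        exceed = int((np.abs(tau_perm) >= abs(tau) - _EPS).sum())
        p_value = (1 + exceed) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p-value method {method!r}")

    return MetricResult(
        estimate=tau, p_value=p_value, method=method, n=n, table=table
    )


# ----------------------------------------------------------------- tables


def _aligned_rater_frames(cohort: CohortTable, rater_a: str, rater_b: str):
    fa = cohort.rater_frame(rater_a)
    fb = cohort.rater_frame(rater_b)
    keys_a = list(zip(fa["patient_id"], fa["hemisphere"], fa["region"]))
    keys_b = list(zip(fb["patient_id"], fb["hemisphere"], fb["region"]))
    if keys_a != keys_b:
        raise AlignmentError(
            f"raters {rater_a!r} and {rater_b!r} do not cover identical "
            "(patient, roi) keys"
        )
    return fa, fb


def _metric_row(x, y, which: str, method, n_perm, seed) -> dict:
    """One table row; degenerate metrics become NaN with a marker."""
    row: dict = {}
    try:
        if which == "kappa":
            r = cohens_kappa(x, y, method=method, n_perm=n_perm, seed=seed)
        else:
            r = kendall_tau_b(x, y, method=method, n_perm=n_perm, seed=seed)
        row[which] = r.estimate
        row[f"{which}_p"] = r.p_value
        row[f"{which}_undefined"] = False
    except UndefinedMetricError:
        row[which] = np.nan
        row[f"{which}_p"] = np.nan
        row[f"{which}_undefined"] = True
    return row


def _variant_columns(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {
        f.value: frame[f.value].to_numpy(int) for f in ALL_FEATURES
    }
    for name, kw in COUNT_VARIANTS.items():
        cols[name] = abnormality_count_column(frame, **kw)
    return cols


def feature_agreement_table(
    cohort: CohortTable,
    rater_a: str,
    rater_b: str,
    method: str = "permutation",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-feature inter-rater kappa and tau-b, pooled over all ROIs.

    Rows: the seven scored features plus the three derived
    abnormality-count variants.  Constant or degenerate rows are reported
    as NaN with ``*_undefined`` markers rather than silently coded.
    """
    fa, fb = _aligned_rater_frames(cohort, rater_a, rater_b)
    cols_a = _variant_columns(fa)
    cols_b = _variant_columns(fb)

    seeds = np.random.SeedSequence(seed).generate_state(2 * len(cols_a))
    rows = []
    for i, name in enumerate(cols_a):
        x, y = cols_a[name], cols_b[name]
        row = {"feature": name, "n": len(x)}
        row.update(_metric_row(x, y, "kappa", method, n_perm,
                               int(seeds[2 * i]) % 2**31))
        row.update(_metric_row(x, y, "tau", method, n_perm,
                               int(seeds[2 * i + 1]) % 2**31))
        rows.append(row)
    return pd.DataFrame(rows)


def feature_ez_association(
    cohort: CohortTable,
    rater_id: str,
    method: str = "permutation",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Kendall tau-b of each feature against the EZ label.

    Pools the 22 ROIs of every seizure-free patient into one vector per
    feature (and per derived abnormality count) and correlates it with
    the per-ROI EZ indicator.
    """
    sf = cohort.seizure_free()
    if sf.n_patients == 0:
        raise EmptyCohortError("no seizure-free patients in cohort")
    frame = sf.rater_frame(rater_id)
    ez = frame["ez"].to_numpy(int)
    cols = _variant_columns(frame)

    seeds = np.random.SeedSequence(seed).generate_state(len(cols))
    rows = []
    for i, name in enumerate(cols):
        row = {"feature": name, "n": len(ez)}
        row.update(_metric_row(cols[name], ez, "tau", method, n_perm,
                               int(seeds[i]) % 2**31))
        rows.append(row)
    return pd.DataFrame(rows)
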