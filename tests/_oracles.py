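"""Independent oracles used by the test suite.

Everything here is deliberately naive — pure-Python loops, pair counting,
closed forms — and shares no code path with the package implementation
it checks.
"""

from itertools import combinations
from math import sqrt

from ezloc.core_data import ALL_FEATURES


def phi_from_table(a: int, b: int, c: int, d: int) -> float:
    """Phi coefficient of a 2x2 table; None if a margin is degenerate."""
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return None
    return (a * d - b * c) / sqrt(denom)


def tau_b_by_pair_counting(x, y) -> float:
    """Kendall tau-b by exhaustive concordant/discordant pair counting."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return None
    return (concordant - discordant) / denom


def kappa_by_hand(x, y) -> float:
    """Cohen's kappa from first principles on two categorical lists."""
    n = len(x)
    cats = sorted(set(x) | set(y))
    p_o = sum(1 for a, b in zip(x, y) if a == b) / n
    p_e = sum(
        (sum(1 for v in x if v == c) / n) * (sum(1 for v in y if v == c) / n)
        for c in cats
    )
    if p_e == 1:
        return None
    return (p_o - p_e) / (1 - p_e)


def expected_kappa_under_flips(p, fp_a, fn_a, fp_b, fn_b) -> float:
    """Closed-form expected kappa between two raters who independently
    flip a shared Bernoulli(p) latent feature with the given
    false-positive / false-negative rates."""
    p11 = p * (1 - fn_a) * (1 - fn_b) + (1 - p) * fp_a * fp_b
    q_a = p * (1 - fn_a) + (1 - p) * fp_a
    q_b = p * (1 - fn_b) + (1 - p) * fp_b
    p00 = 1 - q_a - q_b + p11
    p_o = p11 + p00
    p_e = q_a * q_b + (1 - q_a) * (1 - q_b)
    return (p_o - p_e) / (1 - p_e)


def naive_rule_search(cohort, rater_id, feature_pool=None):
    """Double-loop enumeration of every k-of-S rule over the pool.

    Returns {(frozenset(S), t): (n_perfect, {patient: (n_flagged, tp, fp)})}
    computed with per-observation Python loops on the seizure-free
    subcohort.
    """
    if feature_pool is None:
        feature_pool = list(ALL_FEATURES)
    by_patient = {}
    for obs in cohort.seizure_free().observations():
        if obs.rater_id != rater_id:
            continue
        by_patient.setdefault(obs.patient_id, []).append(obs)

    results = {}
    pool = list(feature_pool)
    for k in range(1, len(pool) + 1):
        for subset in combinations(pool, k):
            for t in range(1, k + 1):
                n_perfect = 0
                detail = {}
                for pat, obs_list in by_patient.items():
                    flagged = [
                        o
                        for o in obs_list
                        if sum(bool(o.features[f]) for f in subset) >= t
                    ]
                    tp = sum(1 for o in flagged if o.ez)
                    fp = len(flagged) - tp
                    if len(flagged) >= 1 and fp == 0:
                        n_perfect += 1
                    detail[pat] = (len(flagged), tp, fp)
                results[(frozenset(subset), t)] = (n_perfect, detail)
    return results
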