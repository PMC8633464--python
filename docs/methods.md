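# Methods

## The analysis

The scoring unit is one of 22 cortical ROIs (11 per hemisphere: frontal
mesial/lateral/polar/basal/central, temporal mesial/lateral, parietal
mesial/lateral, occipital mesial/lateral). Each rater records, per ROI,
the presence of six binary dysplastic features — tuber, cyst,
calcification, increased cortical thickness, GWM junction blurring,
transmantle sign — and designates per patient the single ROI with the
largest FCD-affected area. The epileptogenic zone (EZ) is a per-ROI
study label, identical across raters: the resected area in patients who
remained seizure-free at two-year follow-up. Patients who are not
seizure-free may appear in a cohort file but are excluded from every
EZ-referenced computation, because an incomplete resection leaves their
true EZ unknown.

Analysis stages:

1. **Descriptive summary** — per-feature patient-level and ROI-level
   counts and percentages, and the histogram of per-ROI abnormality
   multiplicity (0–6 lesion features).
2. **Agreement** — Cohen's kappa and Kendall's tau-b between the two
   raters per feature, and for three derived abnormality counts (plain,
   including the largest-area flag, excluding calcifications).
3. **Association** — tau-b between each feature and the EZ label,
   pooling the 22 ROIs of every seizure-free patient into one vector.
4. **Diagnostics** — accuracy, PPV and FDR of each feature as an EZ
   flag, pooled and per patient (denominator exactly 22).
5. **Rule search** — exhaustive evaluation of all "at least *t* of
   subset *S*" rules, maximizing the number of patients for whom the
   rule flags ≥1 ROI with zero false positives.

## Statistical choices

**Tau variant.** Binary region grids are almost entirely ties, so tau-a
is degenerate; tau-b (tie-corrected) is used, which on paired binary
data equals the phi coefficient of the 2×2 table. The estimate and the
asymptotic p-value come from `scipy.stats.kendalltau(variant="b")`.

**Kappa.** Computed directly from the confusion matrix (the formula is
two lines and needs custom degenerate handling); when chance agreement
is 1 — both raters constant — the statistic is undefined and the
package raises/flags rather than returning a number. The implementation
is cross-checked against `statsmodels` in the test suite. For the
abnormality counts, kappa treats each count value as a category
(unweighted agreement).

**P-values.** Default: permutation with 10,000 seeded label shuffles,
two-sided by |statistic|; a normal approximation is available by flag.
For binary vectors the permutation fast path exploits that, with
margins fixed, both kappa and phi are functions of the single (1,1)
cell, so 10,000 shuffles cost one matrix product. For the count-valued
rows kappa permutations recompute only the observed agreement (chance
agreement is marginal-invariant); tau permutations fall back to a loop.
Known limitation: the asymptotic and permutation p-values agree closely
only when expected cell counts are adequate (balanced margins); for
rare features (ROI prevalence ~2%, expected cells below ~10) the normal
approximation can differ from the exact conditional p-value by ~0.05–
0.1. The permutation method is the default for exactly this reason.

**Pooling caveat.** Association and pooled diagnostics concatenate
ROIs across patients (e.g. 330 = 22 × 15) and ignore within-patient
clustering, matching the pooled design this package reproduces.
P-values are therefore anti-conservative to an unquantified degree; the
per-patient diagnostics avoid the issue.

**Undefined PPV/FDR.** When a feature flags no ROI for a patient,
PPV and FDR are reported as absent (NaN), never coerced to 0% or 100% —
coding them silently would bias per-patient summaries.

**Rounding.** Reported percentages use one decimal, rounded half away
from zero, implemented in exact decimal arithmetic. Counts are always
authoritative; a printed percentage inconsistent with its own counts is
never reproduced.

## The rule search

A rule (S, t) flags an ROI when at least t of the features in S are
present (1 ≤ t ≤ |S| ≤ 7; the largest-area designation participates as
a seventh binary feature). "Perfect for a patient" defaults to: at
least one flagged ROI and every flagged ROI inside the EZ — the weakest
reading of "identifies at least one ROI correctly with 100% PPV" when
the EZ spans several ROIs. A stricter variant (exactly one flagged ROI)
is exposed as `require_unique`. The search is exhaustive —
Σ_k C(|pool|,k)·k rules, 448 for the full pool — so no optimization
heuristics are involved; an independently coded naive enumerator in the
test suite checks every per-patient count.

Ties between rules with equal perfect-patient counts are broken toward
smaller feature sets, then larger thresholds (parsimony, then
specificity), then canonical feature order, which makes rankings
invariant to row and patient order. Among the top-scoring rules the
*frontier* drops any rule whose exact flag set is reproduced by a rule
over a strict subset of its features: the two describe the same
classifier and the smaller is kept. Cysts remain in the default pool:
excluding a feature because it shows no EZ association would bake the
expected answer into the search; exclusion is a flag.

Total EZ coverage (summed true positives) is reported but never
optimized; the objective is the perfect-patient count alone.

## The synthetic generator

`SimulationConfig` defaults define the study-like conditions used
throughout the tests:

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 28 | surgical cohort size |
| `p_seizure_free` | 15/28 | observed two-year seizure-freedom rate |
| `baseline_prev` | tuber .28, GWM blurring .16, transmantle .09, thickness .04, cyst .018, calcification .012 | chosen so the implied EZ/non-EZ mixture reproduces the whole-cohort ROI prevalences (~30%, 18%, 11%, 5.5%, 1.8%, 2.1%) |
| `ez_odds_ratio` | calcification 25, thickness 15, transmantle 8, GWM 4, tuber 3, cyst 1 | free parameters (no per-feature EZ prevalences are published); chosen once to reproduce the qualitative association pattern — every feature enriched in the EZ except cysts — not as published values |
| `ez_size_dist` | (.64, .18, .11, .07) over 1–4 ROIs | mirrors the resection mix (mostly focal, some lobar, few multilobar) |
| `rater_flip` | R1 fp .02 / fn .10; R2 fp .03 / fn .20 | per-feature, per-ROI independent flips giving fair-to-substantial kappa for the common features; agreement targets are reached by calibrating flip rates, never by specifying kappa directly |

Generation order is fixed (seizure-freedom, EZ sizes, EZ locations,
latent features in canonical order, then per-rater flips and
largest-area tie-breaks in rater order), so a (config, seed) pair is
bit-reproducible. EZ enrichment is parameterized as an odds ratio so
probabilities never leave [0, 1]. The observable `ez` column is set
only for seizure-free patients; the latent enrichment region of every
patient is recorded in the ground-truth frame as `latent_ez`.

The largest-area flag is assigned per (patient, rater) to the ROI with
the most observed FCD-like features (thickness, GWM blurring,
transmantle sign), ties broken by a seeded draw, and omitted when a
patient shows none — which keeps the designation consistent with each
rater's own scores.

**Planting.** `plant_rule` regenerates the cohort from its own seed
with minimal latent edits so that every EZ ROI satisfies the rule and
no non-EZ ROI does; only features in S are touched, in canonical order.
Rater noise is re-applied afterwards, so planted separations degrade
realistically; `guarantee=True` exempts the rule's features from noise
when an exact observed-level separation is needed. The largest-area
designation cannot be planted: it is derived per patient from the
FCD-feature counts, not a free per-ROI bit, and requesting it raises an
error.

**What the generator does not emulate.** No spatial contiguity of the
EZ or of lesions; no feature co-occurrence beyond shared EZ status (no
published co-occurrence structure exists to calibrate one); no
per-feature rater error rates; no MRI signal. Passing tests therefore
demonstrate correctness of the statistical machinery under these
idealized conditions, not fidelity to any real patient population.

**Printed-count builders.** Two deterministic constructors rebuild
cohorts from published summary numbers — per-feature patient/ROI counts,
or the abnormality-multiplicity histogram — for exercising the summary
arithmetic against printed tables. Feature placements are arbitrary
within the stated counts; these cohorts are synthetic reconstructions,
not the study data. (The per-feature counts and the histogram cannot
both be matched by one cohort: the histogram implies 422 feature
instances, the per-feature counts 420, so each builder matches its own
table only.)

## Problem sizes and numerical details

The test suite runs cohorts of 1–300 patients; Monte-Carlo checks use
4,400–6,600 ROI draws with 3-standard-error bands, closed-form kappa
calibration uses 10 seeds × 200 patients, and the search cross-check
uses 50 random 10-patient cohorts. The tau-b/phi equivalence is
verified exhaustively over every 2×2 table with n ≤ 12. The acceptance
script's stochastic stages (planted-rule recovery, default-condition
search) derive all randomness from the single `--seed` argument via a
`SeedSequence` splitter; every reported quantity is recomputed at run
time.
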