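# Methods

## Scope and shape

`neosep` is an analysis project: the computational steps live in the
library (`src/neosep/`), the numbered drivers under `analysis/` narrate one
pass over a synthetic cohort, and the test suite holds every contract to
independent oracles. The package analyses *derived* per-sample feature
tables (flow-derived immune parameters, plasma analyte concentrations,
clinical metadata); it deliberately does not touch raw cytometry files,
gating, single-cell count matrices or the negative-binomial differential
expression test whose output tables the `degsets` module consumes.

## The synthetic cohort generator

The generator (`neosep.simulate.generate_cohort`) emulates the statistical
structure of a prospective neonatal-unit cohort so that every downstream
stage is testable without access to patient data.

**Sampling design.** 19 babies, gestational age drawn uniformly on 23–29
completed weeks. Routine draws follow a weekly schedule (7 ± 2-day jitter;
routine-draw count per baby ~N(7, 2.5) clipped to 2–14). Suspected-sepsis
episodes add a draw at onset, so the realized per-baby total has median ≈9
— matching the study's figure, which counts both weekly and on-suspicion
draws. Episode onsets are Poisson per baby (sepsis 2.4, ruled-out
suspicion 2.0, NEC 0.08), placed uniformly in the baby's observation
window with ≥10-day separation; infeasible onsets are dropped. These rates
reproduce the study's scale: ~32 deduplicated sepsis samples from 19
babies and a 48-h evaluation set of roughly 30 sepsis vs 20–25 ruled-out
samples. Samples within 5 days after onset share the episode id (the
"repeat samples from one episode" that deduplication removes).

**Immune parameters.** 105 parameters, log-normal baselines (flow counts,
frequencies and MFIs are positive and right-skewed — log-normality also
makes log2 fold changes well-defined). On the log2 scale each value is
`base_p + u_{b,p} + slope_p·min(day, plateau) − effect·w(day) + ε`, where
`u_{b,p} ~ N(0, 0.3²)` is a per-baby random intercept (the study gives no
within-baby correlation structure; a random intercept per trait is our
choice and matches the mixed model used for confounder adjustment),
`ε` is multiplicative assay noise (log-normal, CV 20%; no noise model is
given), and `w` is the episode recovery weight below. Ten signature
parameters (named for the traits they emulate: CD4/CD8/total T-cell
counts, T-cell/mDC/pDC frequencies, mDC counts, HLA-DR MFI on DC and
classical/intermediate monocytes) carry the sepsis effect, default 1.0
log2 (a 2-fold acute suppression).

**Episode kinetics.** `w(day) = clip(1 − (day − onset)/rebound, 0, 1)`
with `rebound = 7` days: full suppression at onset, linear log-scale
recovery, exactly baseline at onset+7. Plasma amphiregulin multiplies by
`mult^w` (default 4-fold at sepsis/NEC onset; 1.3-fold for ruled-out
suspicion, a mild inflammatory bump). CRP spikes above 10 mg/L in 75% of
sepsis/NEC episodes (the cited "low or undetectable in one quarter"
fraction) and stays at its 1–5 mg/L baseline otherwise. IL-6 and IL-10
spike with sepsis; CXCL8, TNF-α and IFN-γ are null analytes.

**Developmental trend.** The signature parameters rise with postnatal age
at 0.03 log2/day before plateauing. The plateau defaults to day 21 rather
than day 30: with 15-day analysis brackets, a ramp running to day 30
leaves bracket 2 (days 16–30) mid-ramp and creates a real bracket-2-vs-3
difference, contradicting the observation the trend is meant to emulate —
that only the first bracket transition differs. Saturating inside bracket
2 reproduces that observation; the plateau day is configurable.

**Amphiregulin baseline calibration.** Log-normal with median exactly
19 pg/mL; a single log-SD σ = ln(27.9/14)/(2·z₀.₇₅) ≈ 0.511 is fitted to
the IQR *width*, so each quartile lands within ~4% of its target (13.5 and
26.8 vs 14 and 27.9) — a one-parameter scale family cannot hit both
quartiles exactly while keeping the median exact.

**Ground truth.** Every cohort is accompanied by a JSON sidecar naming the
true-effect parameters and every injected episode (onset, kind, whether
CRP was elevated), enabling the recovery tests.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no gestational-age dependence of immune traits,
no drift in assay calibration, no informative missingness (QC dropout is
random at 2%), no organism-specific effect profiles, no correlation
between analytes beyond the shared episode kinetics, and episode timing
independent of immune state. Recovery results on this generator
demonstrate that the pipeline detects the planted structure at the study's
size and noise level, not that the biological signature is real.

## Classification

A precedence rule table: NEC (Bell II/III) > MCS > ClinSep > NSC > Stable.
A positive CoNS culture without supporting clinical evidence is treated as
a contaminant, i.e. as an effectively negative culture for the later
rules. "Contemporaneous" is resolved by the data producer: each sample of
an episode carries the episode-level culture and antibiotic metadata, so
the classifier is a total function over structured flags; a suspected
sample matching neither ClinSep (≥3 of the 13 clinical criteria and a
≥5-day course) nor NSC (stopped within 72 h) is a classification error,
never silently categorized. Episode deduplication keeps the earliest
sample per episode id; QC missingness is pairwise (per parameter per
test), never listwise.

## Statistics

* **Effect size:** log2 ratio of group medians (robust, median-centric);
  when a median is zero, a pseudocount of half the smallest positive
  observed value is added to both numerator and denominator.
* **Mann–Whitney:** exact enumeration when n₁+n₂ ≤ 20 without ties,
  otherwise tie-corrected normal approximation (scipy). Verified against
  full enumeration over all C(n₁+n₂, n₁) labelings for totals ≤ 12.
* **BH adjustment:** statsmodels step-up implementation, verified against
  a direct step-up oracle; applied within each analysis family (one
  volcano screen, one bracket grid) separately. Not-evaluable tests (NaN)
  pass through without counting toward the number of hypotheses.
* **Paired Wilcoxon:** zero differences dropped (classic convention); for
  ≤25 non-zero differences the exact two-sided p is computed by dynamic
  programming over signed rank sums on doubled average ranks — exact even
  with tied absolute differences, where scipy's exact method does not
  apply; beyond that, a tie-corrected normal approximation. Verified
  against enumeration of all 2ⁿ sign assignments for n ≤ 12.
* **Kruskal–Wallis/Dunn:** scipy omnibus; Dunn's pairwise z-tests on
  pooled mean ranks with tie-corrected variance, Bonferroni-adjusted over
  the k(k−1)/2 comparisons (the classic Dunn correction).
* **Mixed model:** statsmodels `MixedLM`, REML, random intercept per baby,
  sepsis indicator plus sex, birthweight Z, postnatal day and gestational
  age as fixed effects; traits log2-transformed so the sepsis coefficient
  is a log2 fold change. Non-convergence is reported in the result dict.
  The contract is the model formula; the optimizer is delegated.
* **ROC/Youden:** candidate thresholds are the unique observed values with
  strict ">" positivity (matching the printed rule); Youden ties break
  toward the lowest threshold, maximizing sensitivity, because the test's
  purpose is ruling sepsis *out*. Verified against exhaustive search.
* **Confusion metrics:** exact rational arithmetic (`fractions.Fraction`),
  presentation rounding to 2 decimals half-away-from-zero. A missing
  analyte makes a sample not-evaluable — excluded from the 2×2 with a
  count, never silently negative.
* **Back-solving printed accuracy figures**
  (`solve_confusion_from_printed`): integer search over TP and TN matching
  the rounded printed sensitivity and NPV; where rounding admits several
  tables, the one whose unrounded metrics are closest to the printed
  values is chosen (this uniquely selects TP=32/FN=1/TN=16/FP=12 from
  sens 0.97, NPV 0.94 with 33 positives and 28 negatives).

## Pairing

Triplet matching is a deterministic function of postnatal days: for each
deduplicated sepsis episode, the nearest same-baby sample before and after
within 14 days (the stated gaps are "approximately one week" each side;
14 days is the permissive bound). Equidistant (same-day) candidates break
to input order and are logged; a sample may serve several episodes, or be
itself another episode's sepsis sample — both are flagged rather than
forbidden, since the design does not forbid them. Incomplete triplets
contribute to whichever pairwise comparisons they support. The
"sepsis-transient" call requires both acute comparisons significant and
pre-vs-post not; on cohorts with a strong developmental ramp, pre-vs-post
can genuinely differ across an episode (age drift), which is reported as
such rather than suppressed.

## Problem sizes

Simulation-based checks use 50 seeded cohorts for signature recovery and
null screens, 60 mixed-model fits for the type-I-error check, 10⁵ draws
for plasma calibration, and enumeration oracles up to totals of 12 (rank
tests) and 10³ points (Youden). These sizes give Monte-Carlo error well
inside the asserted tolerances while keeping the whole suite fast.

## Known limitations

* The generator's clinical metadata are internally consistent by
  construction; the classifier's contradiction handling is exercised only
  by constructed fixtures.
* Dunn's correction is Bonferroni (the classic form); some software uses
  Holm or BH variants and will give smaller adjusted p-values.
* The ROC uses the empirical thresholds only; no smoothing or confidence
  bands, and no binomial CIs on sensitivity/specificity (offered nowhere
  downstream).
* Prevalence re-projection assumes sensitivity and specificity transport
  across populations — the usual, and strong, assumption.
* The per-baby characteristics table packaged with the study constants
  could not be transcribed column-exactly for the assay-membership flags;
  the flow-cohort flag is a reconstruction whose cohort-level summaries
  (median gestational age, range) match the printed ones.
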