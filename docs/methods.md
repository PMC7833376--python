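# Methods

## Model

The sentinel-node positivity probability of a clinically node-negative
patient is modelled as

    L = 1 − exp(−Q · ∏ᵢ gᵢ · D^Z),

a multiplicative exponential law in the primary-tumor diameter `D` (mm).
The model descends from a tumor-cell dissemination picture: the exponent
argument is an effective "seeding intensity" proportional to tumor bulk
(`D^Z`, with `Z = 1` for nodal involvement) and modulated multiplicatively by
each prognostic factor. Its assumptions are strong and worth stating:

* **Multiplicative separability.** Factor effects combine as a product of
  per-level multipliers; no interactions.
* **Diameter is the only continuous driver.** All other covariates act
  through discrete level multipliers.
* **Missingness is neutral.** An unobserved factor contributes `g = 1`.
  This is what makes the model usable on records with ~60% missing grading,
  but it also means the "unknown" stratum is implicitly assumed to behave
  like the calibration population average.
* **Scale gauge.** `(Q, g)` is identified only up to a common rescaling:
  multiplying `Q` by `c` and dividing any product of multipliers by `c`
  leaves `L` unchanged patient-wise only if applied to a shared factor, but
  population-wise the overall scale of the `g`s trades off against `Q`
  exactly. The calibration below resolves this gauge.

Probabilities are strictly inside `[0, 1)` for finite parameters. Exponent
arguments above 700 — where `1 − exp(−x)` would silently round to 1 in
double precision — raise `ModelOverflowError` rather than saturate.

## Two-phase calibration

**Phase 1** solves for `Q` on the full training cohort, all `g = 1`:

    mean over cohort of [1 − exp(−Q · D^Z)] = observed positive fraction.

The left side is continuous and strictly increasing in `Q` from 0 toward 1,
so the root is unique; prevalence 0 or 1 has no finite root and raises.

**Phase 2** fixes `Q` and solves the same moment equation per factor level
on that level's sub-sample (size `W`), yielding the level's `g`. Each level
is fitted independently against the phase-1 baseline — multipliers of other
factors stay at 1 — so each `g` measures the marginal association of its
level, not a jointly adjusted effect. No joint refinement is performed, and
`Q` is not re-normalized after phase 2; consequently the population-mean
prediction of the *final* parameter set is not constrained to equal the
prevalence (it typically differs slightly). This is a deliberate fidelity
choice, not an oversight; a jointly calibrated variant would be a different
estimator.

Numerics: each root is bracketed by geometric expansion (factor 8, at most
200 steps) and polished by Brent's method; the residual of the rate equation
at the root must be below 1e−10 or the solver errors out. Fitting is fully
deterministic.

Degenerate strata: an observed rate of exactly 0 or 1 admits no finite root;
the multiplier is clamped to 1e−6 or 1e6 and flagged in the fit report.
Strata smaller than `min_stratum` (default 5) are left at `g = 1` with a
warning — with decade age bins, the extreme bins routinely hold 0–3 patients
and a "fitted" multiplier there would be noise. Both choices surface in the
`FitReport` rather than silently vanishing.

## Evaluation protocol

* **Scores to decisions.** The classification rule is `score ≥ t`. The
  operating threshold is the Youden cut-point: the observed score
  maximizing `J(t) = sensitivity + specificity − 1`, ties broken toward
  higher sensitivity (a missed positive node is the costly error in this
  application), then toward the smaller threshold.
* **AUC** is the area under the empirical ROC curve (equivalently the
  Mann–Whitney statistic with half-weight ties), computed via
  scikit-learn; the test suite cross-checks it against explicit pair
  enumeration.
* **Hold-out validation** is a simple (not class-stratified) random split
  with training size `⌈0.8·n⌉` — 795 of 993. The threshold selected on the
  training scores is transferred unchanged to the test set.
* **Repeated cross-validation**: `n_rounds` (default 100) independent
  rounds of class-stratified k-fold (default 10) partitioning; per round,
  every record is scored once by a model fitted on the other folds, the
  pooled out-of-fold scores give one AUC/accuracy/sensitivity/specificity
  quadruple at that round's pooled Youden threshold, and rounds are
  summarized by median and quartiles (numpy linear interpolation). Pooling
  within a round, rather than averaging per-fold metrics, avoids selecting
  thresholds on ~80-record folds where they are unstable. Round seeds are
  `base_seed + round_index`.
* **Subgroup reports** recompute sensitivity/specificity at the *fixed*
  upstream threshold within clinically conventional strata (tumor-size
  category, age ≤45 / 46–60 / >60, grade, St. Gallen molecular subtype).
  Undefined metrics (no positives, or no negatives, in a stratum) are
  reported as NA, never as 0.

St. Gallen surrogate subtypes are assigned as: hormone-receptor positive
(ER+ or PR+) and HER2− and Ki67-low → Luminal A; hormone-receptor positive
and (HER2+ or Ki67-high) → Luminal B; ER−/PR− and HER2+ → HER2-positive;
ER−/PR− and HER2− → triple-negative; HER2 unknown → unknown. Ki67 is
dichotomized at 20%.

## Synthetic cohorts

The generator draws covariates **independently** from the study
population's published marginals (counts/993): decade age distribution,
histology (72.3% ductal, 6.4% lobular, 21.2% unknown), ER 87.8%+,
PR 76.4%+, Ki67 33.1% high, HER2 11.8%+ (0.6% unknown), grading
10.7/17.7/11.6% G1–G3 with 60.0% unknown. Diameter is log-normal truncated
to (0, 120] mm with location and scale solved exactly from the two category
constraints P(D ≤ 20) = 0.7533 and P(D ≤ 50) = 0.9859 (median ≈ 13.2 mm,
σ_log ≈ 0.61). Node status is Bernoulli with probability given by the risk
model under known ground-truth parameters.

The default ground truth uses the base factor scheme with multipliers whose
*directions* mirror the published within-level positivity gradients (risk
peaking in the 41–50 age band, higher for lobular histology and graded
tumors, lower for receptor-negative disease); their magnitudes are a design
choice. `Q` is then calibrated semi-analytically — exact enumeration over
all factor-level combinations times 256-node Gauss–Legendre quadrature over
the truncated diameter law — so the expected prevalence equals 208/993.
Unknowns are missing-completely-at-random.

What the generator does **not** emulate: correlations among prognostic
factors (grade×Ki67, subtype×age, size×grade all correlate in real
cohorts), informative missingness (ungraded tumors are unlikely to be a
random subset), measurement error in diameter, and any deviation of nature
from the model's own functional form. Passing tests therefore demonstrate
that the software correctly implements and inverts the stated model under
its stated population structure — they say nothing about how well the model
fits real patients, which is precisely the scientific question such a
validation study asks of real data.

A deterministic companion, `reference_cohort()`, reconstructs the published
**per-factor** counts exactly (993 patients, 208 positive; every level's
total and positive count matches the study table). Its joint distribution
is artificial — factors are assigned independently within the positive and
negative groups — so it supports marginal summary arithmetic and sizing
checks, nothing more.

## Parameter recovery and the calibration gauge

Because of the scale gauge, "recovering the true `(Q, g)`" is well-posed
only when the truth sits in the gauge the calibration itself selects: the
one where neutral multipliers reproduce the overall prevalence (the phase-1
identity). The recovery tests therefore keep the true multiplier *ratios*
fixed and apply one common scale, solved so the truth is a fixed point of
the calibration map; with 20,000 simulated patients the refit then lands
within ~1–3% on `Q` and within ~2–7% on each multiplier across seeds. A
truth outside that gauge is systematically "mis-recovered" by the common
scale factor at any sample size — a property of the estimator, not a bug.

## Problem sizes and defaults

| Quantity | Default | Why |
|---|---|---|
| Cohort size `n` | 993 | the study population size |
| Split fraction | 0.8 (ceil) | 795/198, the study's hold-out composition |
| CV rounds × folds | 100 × 10 | the study protocol; tests and the acceptance script use 2–20 rounds, which already stabilize the medians at this cohort size |
| `Z` | 1 | fixed for nodal involvement |
| Rate-equation tolerance | 1e−10 absolute | far below sampling noise; cheap |
| `min_stratum` | 5 | decade-bin tails are smaller than any meaningful calibration sample |
| Clamp bounds | [1e−6, 1e6] | finite stand-ins for the non-existent roots of rate-0/1 strata |

## Known limitations

* Phase-2 multipliers are marginal, not mutually adjusted; correlated
  factors (e.g. grade and Ki67) will share credit in a way the model cannot
  disentangle.
* No uncertainty quantification on `Q` or the `g`s (no standard errors or
  intervals); the repeated-CV quartiles quantify performance variability,
  not parameter variability.
* The clamped multipliers of degenerate strata can push scored exponents
  past the overflow guard on extreme patients; the error is raised, by
  design, rather than a probability of 1.0 being reported.
* The original web calculator's own parameter values are not published, so
  its predictions cannot be reproduced or compared here.
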