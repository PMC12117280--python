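# Methods

This note documents the models, algorithms, and design choices behind
`memiselect`, in enough detail to judge what a passing test suite does —
and does not — establish.

## Synthetic trial generator

**Randomization.** Arms are assigned by permuted blocks with sizes drawn
uniformly with replacement from {2, 4, 6}. Every complete block is
balanced, so the cumulative arm imbalance never exceeds half the largest
block (≤ 3); at n=191 the realized split is always 96/95 in one order or
the other.

**Predictor marginals.** The 17 baseline predictors mix continuous,
binary, and categorical variables. Sample-frame quantities follow the
reported demographics of the motivating trial (age 21.84 ± 3.37,
gender 78.0% female / 21.5% male / 0.5% other, ethnicity 86.4% Chinese /
2.1% Malay / 6.3% Indian / 5.2% other, education 75.9% junior college,
5.24% psychotropic medication, 15.71% prior psychotherapy). The remaining
continuous instruments (treatment credibility/expectancy, symptom
severities, ACS, DERS, FFMQ, PCQ, SCS) use means/SDs typical of
treatment-seeking socially anxious young adults on each scale; these were
chosen once and are configuration, not fitted values. Variables with a
hard floor (age ≥ 18, symptom scales ≥ 0, screener-eligible
social-anxiety severity ≥ 20) are drawn as `floor + Gamma(k, θ)` with
k, θ solved from the target mean/SD — right-skewed, bounded, and exact in
the first two moments, which is what the moment-recovery tests check.
Predictors are drawn independently; real psychopathology scales are
correlated, and that is one stated limit of what the recovery tests show
(see Limitations).

**Outcome model.** Remission at each time point follows
`logit P = a_t + x'β + arm·(τ_t + x'γ)` with x standardized (continuous:
(x−μ)/σ; binary and level indicators: centred and scaled by
√(p(1−p))). Defaults: main effects β = {sad −0.8, depression −0.3,
mindfulness +0.4}; planted moderators γ = {mindfulness +1.5, GAD
severity +1.5, sad severity −1.5} on the log-odds scale per SD. The
intercept a_t is solved by Monte-Carlo root finding (100k draws on a
fixed internal stream) so the marginal remission rate matches the
configured base rates — 18% posttreatment and 26% at follow-up, the
midpoints of the trial's reported arm-specific rates.

**Arm balancing.** With a nonlinear link, symmetric moderators do *not*
leave the arms' mean remission rates equal: E[σ(a + x'β + x'γ)] drifts
above E[σ(a + x'β)] in the lower tail. The generator therefore also
solves the arm offset τ_t so that both arms' expected rates equal the
base rate (`balance_arms=True`, the default), emulating a trial whose
average between-arm effect is null while moderators redistribute who
benefits — the pattern the motivating trial reports. This matters
downstream: with unequal arm means, forest shrinkage toward each arm's
base rate biases every estimated ITE in one direction and degrades sign
recovery even at large n. Setting `balance_arms=False` restores the raw
`arm_effect` semantics. A side effect of balancing is a right-skewed ITE
distribution (median slightly negative, fat positive tail), which makes
the optimization label naturally imbalanced (~25–40% positive) — the
situation SMOTE is meant for.

**Severity back-fill.** The SPDQ score is generated after the binary
remission draw as `cutoff − (|N(0, 4)| + 0.01)` for remitters and
`cutoff + |N(0, 9)|` for non-remitters (cutoff 12.13, floored at 0). Only
the side of the cutoff is meaningful; the magnitudes are cosmetic.

**Missingness.** Exactly `round(rate × cells)` cells of the analysis
matrix — the 17 predictors plus the posttreatment severity column, 18
columns in all — are masked, uniformly at random by default (MCAR), so a
191-row trial at rate 0.10 masks exactly 344 of 3438 cells. An MAR mode
tilts cell selection toward rows with higher observed GAD severity for
robustness experiments. Arm and participant id are never maskable. The
follow-up severity column is left unmasked by default; per-time-point
analyses each see one outcome column, and the 18-column bookkeeping is
the convention used throughout.

**Engagement.** Prompt completion (0–70) is beta-binomial with mean 85%
and SD 17%, matching the reported engagement summaries; it is emitted for
descriptive statistics only and feeds no model.

## Trial statistics

Remission is severity **strictly below 12.13**. The 2×2 chi-square is
the uncorrected Pearson closed form `N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]`
with a 1-df upper-tail p; within-group pre-vs-post change is treated as
two independent proportions (baseline remission 0 of n by eligibility).
No Yates correction and no McNemar: that combination is what reproduces
all six published-style statistics exactly when counts are reconstructed
as `round(pct × n)`. Welch's t accepts raw vectors or summary
statistics; with the reported engagement summaries the Welch df
reproduces (≈186.4 vs printed 186.52) while the t statistic from rounded
summaries differs in sign at the second decimal (+0.08 vs printed
−0.06) — a rounding artifact we report rather than force.

## Fold-aware preprocessing

**Fold plans.** Repeated stratified k-fold (scikit-learn), one derived
seed per repeat; per-fold sizes differ by ≤ 1 and per-fold positive
counts differ by ≤ 1.

**Imputation.** Chained random-forest imputation in the missForest
style: initialize missing cells at the training mean/mode, then sweep
incomplete columns in order of increasing missingness, regressing or
classifying each on all others, until the total change in imputed values
stops decreasing or `max_iter` is reached (the change criterion is the
operation's contract; out-of-bag stopping is a known alternative we did
not adopt). The fitted state freezes the final sweep's forests, the
initial-fill values, and the number of refinement passes; held-out rows
are imputed by replaying that frozen procedure, so transforming new data
can never alter fitted state (asserted bitwise in tests). Observed cells
are never modified. Standardization statistics are computed from the
frozen-state imputation of the training rows themselves, so the training
partition transforms to exactly mean 0 / SD 1. Defaults inside the
cross-validation loops are deliberately light (1 sweep, 25–30 trees):
with ~10% missingness and weakly coupled predictors, further sweeps
change imputed values marginally while multiplying cost across the
hundreds of fold-level refits; `rf_impute_fit` itself defaults to
`max_iter=10` for standalone use.

**Encoding.** Categorical predictors with > 2 registered levels expand
to one indicator per level (full one-hot; the redundancy is harmless to
tree and kernel learners and keeps group attribution simple); two-level
predictors become a single 0/1 indicator. Levels unseen in training
encode as all-zero with a warning. The singleton "other" gender level is
collapsed into the majority level by default (configurable) because a
one-participant level cannot survive stratified folding.

**SMOTE.** The rebalancer first undersamples the majority class to the
midpoint of the two class counts, then adds synthetic minority points —
uniform convex combinations of a minority point and one of its k=5
nearest minority neighbours (Euclidean, post-standardization) — until
`minority = round(target_ratio × majority)` holds exactly. Balanced
input passes through untouched. Synthetic rows carry a provenance flag,
and the nested loop only ever rebalances training partitions (inner
rebalancing happens inside each inner-training split), so evaluation
rows can never contain synthetic points.

## T-learner

Per arm, the remission outcome at the chosen time point is modelled with
a 500-tree random forest. Same-arm probabilities are k-fold cross-fitted
(default 10, clamped to the rarer outcome count) with preprocessing
refitted inside each cross-fit training split; the counterfactual arm's
probability comes from the full other-arm model, which never contains
the participant by construction. Rows with a missing outcome are
excluded from training but still receive both predictions. Per-arm seeds
are derived from the arm's participant-id *set*, which makes the
estimator exactly antisymmetric under arm relabelling (tested).
ITE = p̂₁ − p̂₀; the optimization label is strict (`p̂₁ > p̂₀`, ties 0).
The learner is pluggable behind a fit/predict-probability contract; no
SMOTE and no screening are applied inside the T-learner.

`recovery_report` scores estimated ITEs against the generator's latent
truth: sign agreement is `mean((ITÊ>0) == (ITE>0))` (well-defined under
the no-moderation null, where it sits at chance) plus a Spearman rank
correlation.

## Screening

Elastic-net-penalized logistic regression (mixing parameter fixed at
0.5, strength tuned on an inner-CV deviance grid, saga solver) ranks the
original predictors by the maximum absolute coefficient over each
predictor's indicator block — so a categorical predictor enters or
leaves the top-k as a unit — and keeps the top k (default 10). Ties,
including the fully shrunk all-zero fit, break by the canonical
17-predictor registry order. Screening runs inside each outer training
fold only; the reported "final" predictor set is the modal top-k across
folds, ties broken by mean importance. Applying the screen once to the
full dataset would be leakage, and the per-fold variant is the one
implemented.

## Nested evaluation

For each repeat × outer fold: fit preprocessing on the outer-training
partition; screen (optional); run the inner grid search (AUC criterion,
SMOTE refitted inside each inner-training split; grid points ranked with
150-tree forests for speed and the winner refitted at 500 trees); refit
the winner with SMOTE on the full outer-training partition; score the
untouched outer-test partition once. Grids: RF variables-per-split
∈ {⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋}; SVM cost ∈ {0.25, 1, 4, 16} × kernel width
∈ {1/(2p), 1/p, 2/p}; the logistic reference is untuned. SVM scores are
a logistic squash of the decision value — monotone, so rank metrics are
unaffected and 0.5 corresponds to the margin. The classification
threshold for confusion-matrix metrics is 0.5.

AUC is the Mann–Whitney form (ties half); AUPRC is step-function average
precision; both are cross-checked against brute-force pair counting and
scikit-learn in tests. Metrics aggregate as means over all repeat × fold
evaluations; the AUC CI is the 2.5/97.5 percentile across repeat-level
means. DeLong's test (fast placement-value covariance estimate) compares
each learner against the logistic reference on per-case scores averaged
across repeats, since the test requires paired case-level scores; it is
validated against a paired permutation oracle. The point-biserial
calibration effect is d = 2r/√(1−r²) with degenerate inputs flagged.

**Leakage sentinel.** Every fold artifact stores a hash of the fitted
model taken immediately after fitting and again after evaluation;
`leakage_sentinel_ok` asserts the two are identical for every fold, i.e.
evaluation touched no trained parameter.

**A caveat the null test makes precise.** The optimization label is
itself a *function of the predictors* — the sign of a difference of two
fitted surfaces. Under a zero-moderation generator, those surfaces are
pure noise, yet a downstream classifier can still learn the (noise)
function and score far above 0.5 against the T-learner label while every
leakage control passes (the `tlearner_label_null_auc` diagnostic in
`scripts/acceptance.py` measures this directly). High AUC against
counterfactual labels therefore certifies that the label is *learnable*,
not that real moderation exists; evidence for moderation must come from
ground-truth recovery (synthetic data) or external validation. The null
calibration accordingly uses a label with no predictor signal — the
remission outcome under the zero-weight generator — and checks the mean
outer AUC against a chance band whose width counts only the `n_outer`
disjoint test partitions as independent evaluations (repeats reuse the
same rows and add no independent information); per-fold null variance is
`(n₁+n₀+1)/(12 n₁ n₀)`.

## Kernel SHAP

Coalitions are formed at the level of the original predictors: all
indicator columns of a categorical predictor switch in or out together,
so the attribution is already the predictor-level sum and is invariant
to indicator column order. Coalition values average the model over the
background sample with coalition features taken from the explained
instance. When `2^p − 2` interior coalitions fit the budget they are
enumerated exactly with Shapley-kernel weights; otherwise coalitions are
sampled from the kernel's size distribution. The weighted least-squares
solve enforces `base + Σφ = f(x)` exactly (the additivity gap is
reported), with a 1e-10 ridge guarding sampled designs. For a linear
model with the full enumeration this reproduces the closed form
`φⱼ = wⱼ(xⱼ − mean background)` to numerical precision.

Ranking uses mean |φ| over the explained instances, ties broken by
registry order. Direction is the sign of the Spearman correlation
between predictor value and attribution (beeswarm plots show the same
relationship visually but are not machine-checkable); for categoricals
the "value" is the registry level code, which makes direction
order-dependent and is reported as such. A consistency check flags
predictors whose direction flips between the posttreatment and follow-up
models. Defaults for pipeline runs: 100-row stratified background,
100 explained instances, 512 sampled coalitions; attribution standard
error shrinks monotonically with the coalition budget (tested).

## Orchestration and problem sizes

`run_experiment` chains generate/load → trial statistics → T-learner →
nested CV (initial 17-predictor and final top-10 configurations) → SHAP,
writing CSV/JSON/SVG artifacts and a sha256 manifest; every stage's seed
derives deterministically from the master seed, and identical configs
produce byte-identical bundles. The packaged validation runs use
deliberately modest sizes chosen as the package's own defaults — n=400
trials with 10 outer folds × 3 repeats for the signal-recovery chain,
n=200 for the null calibration, n=1000–2000 for moderator and ITE
recovery, 20 generator seeds for the SHAP recovery rate — sizes at which
the planted effects are comfortably identifiable while a full run stays
in the minutes range on a single CPU.

## Limitations

- Predictors are generated independently; correlated batteries could
  make screening and SHAP attributions less stable than the recovery
  tests suggest.
- The generator plants moderation on the log-odds scale with a balanced
  average effect; it does not simulate dropout, EMA time series, or
  measurement error in the instruments.
- Direction labels for multi-level categorical predictors depend on the
  registry's level coding.
- The T-learner caveat above applies to any analysis that classifies
  counterfactual labels, including the original design this package
  re-implements: discrimination metrics against such labels cannot by
  themselves establish real treatment-effect heterogeneity.
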