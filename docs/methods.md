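# Methods

`eftrial` implements the quantitative machinery of a two-arm randomized
trial comparing episodic future thinking (EFT) against control episodic
thinking (CET) in adults with alcohol use disorder: estimation of delay
discounting and behavioral-economic demand at five laboratory sessions,
aggregation of a ~35-day remote drinking-monitoring period split into three
phases (7-day baseline, then two monitoring phases of about two weeks each),
breathalyzer/self-report concordance, covariate-adaptive randomization, and
model selection for submission adherence. A synthetic-cohort generator
replaces the trial's raw data, so every estimator can be validated against
known generating parameters.

## Delay discounting

The adjusting-amount task presents, at each of seven delays
(1 day, 2 weeks, 1 month, 3 months, 1 year, 5 years, 25 years — converted to
1/14/30/90/365/1825/9125 days by convention), six binary choices between a
smaller-sooner amount and a constant $1000 larger-later amount. Trial 1
offers SS = A/2; after trial *t* the SS moves by A/2^(t+1), down after an SS
choice and up after an LL choice. The indifference point is defined as the
amount that would be offered on trial 7, which makes the procedure an exact
binary search with resolution A/2^7 = $7.8125 and renders the always-SS
(7.8125) and always-LL (992.1875) paths symmetric about A/2.

Indifference points V(D) are fit with the hyperbolic model V = A/(1 + kD) by
least squares on the indifference points themselves (not on log V and not
trial-wise), the dominant convention for this task; the estimation method is
recorded in the fit metadata. The SSE is minimized over ln k ∈
[ln 1e−10, ln 1e3] by a 600-point grid followed by bounded scalar
refinement; the objective is one-dimensional and smooth in ln k, so this is
globally reliable (a 10^6-point grid oracle in the tests confirms dominance).
Degenerate curves (all V = A, all V = 0) return the boundary optimum with
`boundary_flag` set instead of raising, since flat responders are real data.

Systematicity screening uses the two standard criteria with thresholds of
20% of A (any rise between adjacent delays above 0.2·A fails criterion 1)
and 10% of A (a first-to-last drop below 0.1·A fails criterion 2). The
thresholds are arguments with these defaults. Flagged curves are never
dropped; downstream tables carry the flags.

Quantization limits identifiability: titrated points sit within one
resolution step of the true curve, so the recovery tests bound
|ln k̂ − ln k| by the numerically computed interval of rates whose curves
stay within (√7+1)·resolution of the truth at every delay, rather than by an
arbitrary constant.

## Behavioral-economic demand

The purchase task asks how many standard drinks would be bought at 13
ascending prices from $0 to $80/drink (the interior default price list is a
package choice and travels with the data file). Quantities above 50 at any
price are capped to 50 and flagged; capping is idempotent.

Observed metrics: intensity = quantity at price 0; Omax = max over prices of
price×quantity; Pmax = the lowest price attaining Omax (ties broken toward
the lower price; the all-zero curve gives Omax 0 at Pmax 0).

Fitted demand uses the exponentiated equation
Q(C) = Q0·10^{k(e^{−αQ0C} − 1)}, fit on the raw consumption scale so zero
quantities stay in the likelihood — the form is defined at Q = 0 and C = 0,
and Q(0) = Q0 exactly. The span k is not free: it is fixed per dataset at
log10(max pooled consumption) − log10(min pooled nonzero consumption) + 0.5,
the convention of the standard demand-analysis toolchain, and shared across
all fits in the dataset (also exposed as a parameter). (Q0, α) are estimated
by bounded nonlinear least squares (Q0 ∈ (0, 2×cap], α ∈ [1e−8, 10]) with
five deterministic α starts (1e−4 … 1); a fit is marked nonconverged when
the optimizer fails, every response is zero, or α lands on a bound, and
nonconverged fits are excluded from downstream summaries with a logged
count, never silently.

A derived `fitted_pmax` reports the price at which the fitted expenditure
curve C·Q̂(C) has point elasticity −1, obtained by solving
u·e^{−u} = 1/(k·ln10) for u = αQ0C on (0, 1) with a bracketing root finder.
When k·ln10 ≤ e the expenditure curve has no interior maximum (the
exponentiated form plateaus at Q0·10^{−k}, so expenditure eventually grows
linearly in price) and a bounded grid maximization on [0, 10×Pmax_obs + 1]
is used instead. Doubling α exactly halves this price, a scale property the
tests verify.

## Consumption aggregation and eligibility

Daily reports are aggregated per participant-phase. Two denominators are
computed and labeled, never mixed: `drinks_per_day` divides total reported
drinks by total *calendar* days of the phase (the figure-style convention,
which understates drinking when submissions are missing), and
`drinks_per_reported_day` divides by reported days only.
`drinks_per_drinking_day` divides by days with at least one reported drink
and is undefined (never zero-filled) when there are none. Missing reports
count toward calendar days only. Phase lengths are taken from the data, not
assumed fixed.

Baseline eligibility after the 7-day baseline phase requires: reports on at
least 5 of 7 days, drinking on at least 4 days, and harmful drinking —
at least 4 days of 4+ drinks, or an average above 4 drinks per drinking day.
All failed clauses are returned as reasons. Note that this rule is *not*
monotone in drinks: adding a single drink to an abstinent day creates a new
light drinking day and can pull the drinks/drinking-day average below the
threshold; the property tests assert monotonicity only for additions to
existing drinking days.

The model-frame export keeps one row per participant-day with the outcome
left missing where unreported, joined with group and the adjustment
covariates (age, sex, education, income, AUDIT score), ready for external
mixed-model fitting — the (G)LMM inference itself is intentionally out of
scope.

## Breath/self-report concordance

A day's breath status is the peak (highest) of its up-to-three BrAC samples
against a 0.02% threshold: ≥ threshold is positive, below is negative, no
samples is missing. Report status is none (an explicit 0), one-or-more, or
missing. The 3×3 cross-tabulation preserves the missing row/column; the
association test uses only days with both a breath classification and a
report. The Fisher exact odds ratio is the conditional maximum-likelihood
estimate under the noncentral hypergeometric model (via
`scipy.stats.contingency.odds_ratio`), which on the published matrix's
non-missing cells ((184, 519), (18, 844)) gives 16.60 — the sample
cross-product ratio would give 16.62. The two-sided p-value sums the null
hypergeometric probabilities of tables no more probable than the observed
one; the tests verify both against a from-scratch enumeration oracle on
every 2×2 table with total ≤ 40 (one representative per symmetry orbit).
Days with a report but only pre-drinking negative samples are classified as
given; no correction is attempted, since that discordance is a property of
the measurement process.

The ROC AUC of peak BrAC for discriminating drinking days is the tie-aware
rank statistic P(peak_drink > peak_none) + ½P(tie), pooled across
participants (a within-participant average is a defensible alternative; the
pooled version matches the association analysis above).

## Randomization

Sequential minimization: each candidate is assigned to the group that
minimizes Σ over the two balancing covariates (square-root drinks/day and
baseline ln k) of the absolute standardized mean difference — standardized
by the pooled SD of already-allocated participants and skipped while that SD
is undefined — plus 0.5·|n_EFT − n_CET|, with probability 0.8 (the biased
coin), and to the other group otherwise; exact ties use a fair coin, so the
first allocation is 50/50 and the marginal ratio stays 1:1. Bias, size
penalty, and seed are configurable. The cited trials do not publish their
exact imbalance metric or bias; these defaults are declared package choices
that reproduce the stated goals (probability adjustment, two-covariate
balance, even allocation) with a transparent, testable rule.

## Adherence model selection

Missing-submission indicators (drink-count reports; breath samples with a
within-day slot term) are modeled by plain maximum-likelihood logistic
regression. The candidate space is every subset of the main effects (group,
phase, age, sex, ethnicity, race, education, income, and — for breath —
time of submission) crossed with every hierarchy-respecting subset of the
allowed interactions (group×phase; for breath also time×phase, time×group),
intercept-only included: 320 models for the drink-count outcome. Categorical
predictors are dummy-coded against the first level; the parameter count
includes the intercept. Each model's BIC is −2·loglik + p·ln(n); separated
or nonconverged fits are excluded with a recorded warning and the search
continues. Participant random effects are not included — the selection is a
fixed-effects screen, as in the source design.

## Synthetic cohort

The generator emulates the study conditions: 32 participants per group by
default; latent ln k ~ Normal(−5.0, 2.5²) (the observed baseline scale);
baseline drinking rates Gamma with mean 5.5 drinks/day and shape 6.25
(CV 0.4, matching the observed dispersion); latent demand Q0 and α
log-normal around 10 drinks and 0.003 with log-SD 0.3 and 0.5; purchase
responses from the exponentiated equation (span 2.0) with multiplicative
10^N(0, 0.1) noise, rounding, and the 50 cap; choices from a softmax on the
two options' hyperbolic values with temperature $20 (temperature 0 recovers
the deterministic value maximizer used by the oracle tests). Daily drink
counts are Poisson(participant rate × group-phase factor) — matching the
Poisson outcome models the design calls for — with default factors EFT
(1, 0.75, 0.55) and CET (1, 0.85, 1), i.e. a sustained EFT reduction and a
transient CET dip. Breath samples decay across the day's three slots
(factors 1/0.6/0.3) around brac_per_drink = 0.012%/drink with 0.004%
additive noise truncated at zero, plus two realism mechanisms: a 35% chance
that a drinking day's samples all precede drinking (the dominant source of
negative-breath/positive-report discordance) and a 2% per-sample heavy-tail
contamination (occasional unexplained positives). Missingness is Bernoulli
per submission with probability expit(phase log-odds + participant
propensity), default log-odds (−2.2, −1.8, −1.2) rising across phases and
propensity SD 0.3.

One master seed fans out through `SeedSequence.spawn` to per-participant
substreams, so identical configs give byte-identical files and enlarging a
cohort never reshuffles earlier participants.

What the generator does **not** emulate: within-person day-to-day
autocorrelation of drinking (days are conditionally independent given the
participant rate), session effects on the latent parameters (ln k and α are
constant across the five sessions), realistic alcohol pharmacokinetics,
dropout (completion filtering is tested by constructing dropouts directly),
and any EFT effect on discounting or demand. Passing recovery tests
therefore demonstrates estimator correctness under the stated generating
model, not robustness to serial dependence, reactivity, or informative
missingness.

## Pipeline, filtering, and reproducibility

`run_pipeline` executes simulate/load → discounting → demand → consumption →
concordance → adherence selection, writes each interface CSV plus a single
`report.json`, and logs every exclusion count. Curves are reconstructed from
the recorded trial-level choices with an integrity check that replays the
titration rule against the stored SS amounts. `complete_case_filter` keeps
participants with all five sessions; the intention-to-treat mode keeps
everyone who started the intervention (completed S2), masks sessions after
the last completed one, and truncates daily records at the last day with any
submission. Reports embed the seed, a SHA-256 hash of the configuration and
the package version; reruns with the same seed are byte-identical.

Problem sizes in the test and acceptance runs — cohorts of 12–100
participants for unit recovery, 64 (the trial's randomized n) for the
end-to-end pattern check, 50 noiseless responders for discounting recovery,
and the ≤ 40-total exhaustive Fisher enumeration — were chosen as the
smallest sizes at which the Monte-Carlo error bands in the assertions are
meaningful.
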