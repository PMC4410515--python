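# Methods

## The update rules

Let {H_1, …, H_n} be a finite set of mutually exclusive, jointly exhaustive
hypotheses with credences Pr_t1(H_i), and let E be evidence with
per-hypothesis likelihoods Pr(E | H_i), Pr_t1(E) = Σ_i Pr_t1(H_i) Pr(E | H_i) > 0.

Bayesian conditioning sets

    Pr_t2(H_i) = Pr_t1(H_i) Pr(E | H_i) / Σ_j Pr_t1(H_j) Pr(E | H_j).

Probabilistic abduction adds an explanatory bonus ℰ_i ≥ 0 to each numerator
before renormalising:

    Pr_t2(H_i) = (Pr_t1(H_i) Pr(E | H_i) + ℰ_i) / Σ_j (Pr_t1(H_j) Pr(E | H_j) + ℰ_j).

The bonus schema is deliberately open-ended; this package instantiates the
simplest version: a flat constant c (default 0.1) awarded to the *unique*
hypothesis that best explains E under a pluggable explanatory-power measure,
and nothing to anyone on a tie. With c = 0 the two rules perform the same
floating-point operations, so they agree bit for bit — the Bayesian rule is
the exact zero-bonus special case, which the test suite checks on 10⁴
randomized partitions. Ties award no bonus because any other convention
breaks the permutation symmetry of the partition.

Only finite partitions are supported; general proposition algebras and
updating on uncertain evidence (Jeffrey conditioning) are out of scope.

## Measures of explanatory power

All measures share the neutral-point convention: independence of H and E
scores 0. Implemented: the simple difference Pr(E|H) − Pr(E); Popper's ratio
(Pr(E|H) − Pr(E)) / (Pr(E|H) + Pr(E)); Good's log-ratio ln(Pr(E|H)/Pr(E));
the L_α rescalings of Good's measure,

    L_α(x) = 1 − exp(−x²/(2α²))  for x ≥ 0,  odd reflection for x < 0,

with named presets G1 = L_0.5, G2 = L_1, G3 = L_2; and the
Schupbach–Sprenger posterior ratio (Pr(H|E) − Pr(H|¬E)) / (Pr(H|E) + Pr(H|¬E)).
All but raw Good have range [−1, 1]. L_α is strictly increasing and odd with
limits ±1; in double precision it saturates at ±1 once x²/(2α²) exceeds
about 36, which the property tests acknowledge. Good's measure at
Pr(E|H) = 0 returns a −∞ sentinel by default (L_α maps it to −1, keeping the
rescaled family total); a strict mode raises instead. The simple measure is
implemented for completeness but not used in any default pipeline.

Model-based scoring assembles the conditionals from a hypothesis space:
Pr(H|E) by Bayes's theorem and Pr(H|¬E) = Pr(H)(1 − Pr(E|H))/(1 − Pr(E)).
Probability-sum checks use an absolute tolerance of 1e−9 (double-precision
accumulation over ≤ 40 terms); best-explainer ties use 1e−12.

## The two-urn experiment

Urn A holds 30 black and 10 white balls, urn B 15 black and 25 white; a fair
coin selects the urn and 10 balls are drawn without replacement. The
objective posterior O_k = Pr(H_A | first k draws) starts at 0.5 and is
computed from ordered-sequence likelihoods (products of remaining-count
ratios). Order cancels in the posterior, so this is equivalent to
hypergeometric count likelihoods; exchangeability is tested by permuting
sequences. Explanatory-power scores are computed per step against the
*cumulative* evidence — the draws so far, from the selection priors — which
matches how judgments "in light of the draws so far" are elicited. A
latest-draw-only mode exists for sensitivity analysis. The scalar functions
are the readable reference path; a vectorised batch path produces identical
numbers (cross-checked at 1e−12) for simulation studies.

## Synthetic participants

The original 26-participant interview data are unavailable, so analyses run
on synthetic datasets that emulate the study design: 26 participants × 10
draws, each trial freshly simulated, with credence

    S = β₀ + β_O·O + β_A·A + β_B·B + ε,   ε ~ Normal(0, σ²),

truncated to [0, 1] by resampling ε. Defaults: β = (0.33, 0.40, 0.24, −0.13)
(the published estimates for the best computed-score model), scores under
G3 = L_2, σ = 0.08. Resampling rather than clipping avoids boundary point
masses that would bias the OLS analysis; the realised truncation rate
(typically 1–3%) is logged and a warning fires at ≥ 5%. With these defaults
the generating model's realised R² averages ≈ 0.89, slightly above the
0.84–0.86 band of the published fits — the synthetic data are cleaner than
interview data, since the only noise is the homoscedastic Gaussian term.
Judged explanatory goodness is emulated as computed score + Normal(0, sd²)
noise clipped to [−1, 1], sd defaulting to 0.05: the study this emulates
found computed degrees to track judgments closely, and no published value
pins the judgment noise down. Participant-level random intercepts are off by
default (the analysis pools observations) but available.

What passing tests show: the pipeline recovers known coefficients, selects
the generating model, and is calibrated under the null *for data generated
by this homoscedastic, pooled, linear process*. Real interview data would
add heteroscedasticity across draw steps, participant effects, and response
instrument artifacts that the generator deliberately omits, so the recovery
results validate the machinery, not the original study's conclusions.

## Model comparison

Models are compared with k = number of regression coefficients (intercept
included) + 1 for the noise variance, LL = maximised Gaussian log-likelihood
at the ML variance RSS/n, and AIC = 2k − 2LL. This is the convention under
which the published comparison table reproduces from its own columns (its
Bayes-only row: k = 3, LL = 202.39, AIC = −398.77 ≈ 6 − 404.78). REML or
unbiased-variance conventions do not. Nested models are tested by LR with
chi-squared reference; non-nested pairs by Vuong's z (basic statistic,
population-variance denominator, no Schwarz correction by default since the
compared score models share k; a corrected mode exists) and Clarke's exact
two-sided binomial sign test with zeros dropped. Standardized β z-scores
predictors and response; raw coefficients are fitted (whether the original
analysis pre-standardized judged scores is unknowable from the published
tables, so both B and β are reported). No multiple-testing correction is
applied across pairwise tests, matching the unadjusted published p values.

## Normative simulation

A coin's heads probability is one of {0, 0.1, …, 1}; the agent starts
uniform and updates per toss (likelihood Pr(heads | p) = p). The abductive
bonus goes to the bias hypothesis maximising the likelihood of the *whole
toss record so far* — the grid point nearest the running heads frequency, up
to binomial-likelihood tie-breaks. Scoring bestness on the latest toss alone
is implemented but degenerate: any likelihood-monotone measure then always
crowns an extreme bias (1 on heads, 0 on tails), and the flat bonus keeps
resurrecting refuted extremes, capping the credence in the true hypothesis
below high thresholds; a test documents this. Convergence is measured as the
first toss at which the true hypothesis's credence strictly exceeds θ = 0.9
(configurable; the threshold comparison is strict), censored runs are
excluded from mean times with the censor count reported, and inaccuracy is
the Brier score Σ_i (cred_i − 1{i = true})². Default problem sizes — 1000
replications of 500 tosses, true bias 0.7 — give stable Monte-Carlo
estimates; with c = 0.1 abduction typically reaches θ in ~60–70 tosses
against ~170 for Bayes, at the price of a slightly worse final Brier score,
so neither rule dominates across epistemic goals. No published value fixes
the grid, prior, or c for the cited convergence results; these defaults are
this package's choices.

## Published reference statistics

`reference_tables.py` stores the printed summary statistics of the original
analysis (model-comparison table, best-model coefficients, judged-model AIC).
Since the raw data are gone, those numbers enter only as inputs to
arithmetic-consistency checks: the LR column reproduces exactly from the LL
column for four of the five score models (the G3 row prints 52.06 where its
LL entries imply 52.04 — inside accumulated printed rounding), the ΔAIC
column follows from the AIC column to one unit in the last place, and every
AIC obeys 2k − 2LL within ±0.02.

## Known limitations

- The bonus schema is the flat-constant instantiation only; graded bonuses
  (scaling with the margin of explanatory bestness) are not implemented.
- The generator assumes homoscedastic noise and pooled observations.
- Vuong/Clarke variants in the original analysis are not documented beyond
  the authors' names; the variants here are the standard textbook forms.
- The coin-simulation conclusions are Monte-Carlo, not analytic.
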