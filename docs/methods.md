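# Methods

## The measurement model

Responses are dichotomous (0 = unfavourable, 1 = favourable) answers of N
persons to J questionnaire items. The Rasch model puts person n's latent
trait θ_n and item j's difficulty δ_j on one logit scale:

    P(X_nj = 1 | θ_n) = exp(θ_n − δ_j) / (1 + exp(θ_n − δ_j)).

The latent trait is treated as a random effect, Θ ~ N(μ, σ²), so the sample
is exchangeable with its population. Marginal maximum likelihood (MML)
integrates each person's likelihood contribution over this normal density;
with incomplete data the contribution is the product over that person's
*observed* items only, which is the likelihood-based "available case"
treatment of missingness. One identifiability constraint is required; the
default fixes μ = 0 and leaves all J difficulties free, with Σδ = 0 / free μ
available as an alternative. The location contrast ν = mean(δ) − μ is
invariant to this choice and is the quantity whose bias signals a global
over- or under-estimation of difficulty (equivalently, under- or
over-estimation of the latent trait).

Assumptions inherited from the model: unidimensionality, local independence
given θ, and monotonicity of the item response functions.

## Simulating informative non-response

Each person carries, besides θ_n, a non-response propensity ξ_n; the pair is
bivariate standard normal with correlation ρ ≤ 0 (low trait level goes with
more skipping). A complete matrix is drawn from the Rasch model, then each
cell is deleted independently with probability

    π_nj = clip( π · (1 + 0.4 ξ_n) + w · 0.4 π · δ_j , 0.01, 1 ),

where π is the target per-item missingness rate, w ∈ {0, 1} switches on a
link between non-response and item difficulty, and 1% is a hard floor. The
probability is centred on π: with ρ = 0, w = 0 the mechanism is MCAR, with
w = 1 it acquires a MAR component (harder items skipped more), and with
ρ ≠ 0 it is MNAR. The linear-clip form and its 0.4π person slope were
calibrated so that the expected number of persons with 3+ missing responses
out of 5 matches the reference counts (about 6 / 37 / 97 persons per 500 at
π = 10/20/30%); the item slope 0.4π preserves the mean rate because the
default difficulties sum to zero. A closed-form oracle for the ineligible
count (Gauss–Hermite integration of a Poisson-binomial tail over ξ) is part
of the study module and shows the count does not depend on ρ, because only
the marginal law of ξ enters.

The generator emulates: item-level informative non-response driven by one
latent propensity, at rates and informativity levels spanning MCAR to
strongly MNAR. It does not emulate: longitudinal dropout, covariate-driven
(external-variable) MAR, polytomous items, or clustered/multi-scale
questionnaires — conclusions from passing tests carry to real data only
within those limits.

## Strategies for handling the missing cells

Sixteen strategies are implemented. NOIMP (analyse all observed responses;
the MML fit and the pairwise scalability coefficient need no imputation) and
LD (drop any person with a missing response) do not impute. The fourteen
imputation methods fill cells only for persons observing a strict majority
of items (> J/2, i.e. at least 3 of 5) — the common 50% scoring rule;
ineligible persons keep their observed responses. Observed cells are never
altered. Deterministic fills round the method's probability half-up
(0.5 → 1), matching the rounding of the reference implementations'
platform; randomized variants (-R) draw Bernoulli(p).

* WORST: every eligible missing cell ← 0.
* PMS(-R): person's observed positive rate S_n / |O_n|.
* IMS(-R): item's observed positive rate R_j / |M_j|; an item with no
  observed responses stays missing.
* CIM(-R): item rate rescaled by the person's relative level,
  q_nj = (S_n / Σ_{k∈O_n} p_k) · p_j, clipped to [0, 1].
* ICS: copy the person's response to the donor item — the item most
  correlated (signed pairwise Pearson over joint observers, ties to the
  lowest index) with the target; missing donors leave the cell missing.
* LOG(-R): forward stepwise logistic regression of the target item on the
  other items (likelihood-ratio entry at α = 0.05, candidate models fitted
  on rows complete for the candidate set); cells whose selected covariates
  are missing stay missing. Perfect separation falls back to a weakly
  L2-regularized fit.
* MOK: items sorted easiest→hardest by observed positive counts (stable);
  per missing cell the five Guttman-consistency rules fire in order —
  (a) observed positive at a harder position → 1; (b) observed negative at
  an easier position → 0; (c) negatives at easier positions at least as
  numerous as positives there → 0; (d) negatives at harder positions no
  more numerous than positives there → 1; (e) Bernoulli with the item's
  observed positive proportion.
* RAS(-R): fit the Rasch model on the observed data, fill from
  p_nj = expit(θ̂_n − δ̂_j). Person estimates default to EAP (posterior mean
  under the fitted N(0, σ̂²)); WLE and interior-ML are switches. The EAP
  default is deliberate: un-shrunk person estimates make deterministic fills
  track the person's observed score too hard, which inflates the estimated
  latent variance far beyond what this family of methods produces in
  reference results.
* RAI: iterate deterministic RAS — refit on the completed matrix,
  re-impute the originally missing cells — until two passes agree, capped
  at 10 passes.

Each randomized method consumes its own child random stream, so the set of
methods run never changes any single method's draws.

## Estimation numerics

The marginal likelihood uses non-adaptive Gauss–Hermite quadrature, 30 nodes
by default (the J = 5 log-likelihood changes by < 1e−6 per person between
orders 30 and 60). Persons are grouped by their (observed-set, response)
pattern — at most 3^J patterns — so the per-fit cost is independent of N
beyond the grouping pass. Optimization is L-BFGS-B on (δ, log σ) with an
analytic gradient; convergence is declared on a gradient sup-norm below
1e−5 (the optimizer's line search can give up with the optimum already in
hand, so the status flag alone is not trusted). Starting values are
δ⁰_j = −logit(observed item rate), log σ⁰ = 0. An item with no observed 0s
or no observed 1s has a divergent difficulty and raises an error naming the
item.

Person estimation: Warm's weighted likelihood estimator (WLE) solves the
penalized score equation per pattern and stays finite at extreme scores;
its standard error is I(θ̂)^{−1/2} with I the observed-item test
information. Interior ML omits the penalty and is undefined (nan) at
extreme scores. EAP returns the posterior mean and SD under the fitted
latent normal (60-node quadrature). Persons with no observed responses get
nan and are excluded from person-level indices.

## Validation indices

**Loevinger's H** is computed by the pairwise technique: for each item pair,
the covariance and its maximum given the marginals, min(p_j, p_k) − p_j p_k,
are computed on the persons observing both items; H is the ratio of the two
sums over all pairs (the Mokken-scale "ratio of sums" aggregation).
Degenerate pairs (fewer than 2 joint observers, or an item constant in the
joint subsample) are dropped from both sums with a warning.

**Q1** tests fit on the fully observed rows: within each non-extreme score
group r = 1..J−1, the observed item-positive counts are compared with
N_r · P(X_j = 1 | R = r), the score-conditional probabilities obtained from
elementary symmetric functions of exp(−δ̂) — these are θ-free by
sufficiency of the score. The statistic is referred to chi-square with
df = (J−1)² (df shrinks by J−1 per empty score group). The classical
(J−1)/J small-sample multiplier is available but off by default: at the
study design (N = 500, J = 5) the uncorrected statistic holds the nominal
5% type-I error while the multiplied one rejects at about 1%. Q1 is
restricted to complete rows because score groups are undefined otherwise;
after imputation the still-missing (ineligible) rows are simply not part of
the test.

**PSI** (person separation index) is reported in the model-variance form

    PSI = σ̂² / (σ̂² + mean(se_n²)),

the fitted latent variance against the average squared standard error of
the person estimates — a signal-to-total ratio in the spirit of classical
reliability. The empirical separation form (V − mean se²)/V with V the
variance of the person estimates is available when no model variance is
supplied. The model form is the default because its response to imputation
(inflation under person-mean filling, deflation under item-mean filling)
matches the reference behaviour of the index, whereas the empirical form is
dominated by the large standard errors of sparsely observed persons and
moves the opposite way.

## The bias protocol

One replication = one complete dataset + one missingness mask; every
strategy sees the same incomplete matrix. H and PSI biases are paired
differences against the same replication's complete-data values, averaged
over replications (Monte-Carlo SE = SD/√L). ν and σ² biases compare the
replication-averaged estimate to the generating truths (0 and 1). The
difficulty-dispersion bias is the across-item population variance (divisor
J) of the replication-averaged difficulty estimates minus the generating
value 0.5. The Q1 row is the percent of replications rejecting at 5%, with
a Wald 95% CI (Clopper–Pearson is a config switch away in spirit — the
Wald form is what the negligibility rule uses).

Negligibility thresholds: |bias| < 0.05 (H, PSI), < 0.1 (ν), < 0.2
(Var δ); mean σ̂² inside [0.71, 1.37] — the central 95% interval of
complete-data estimates at this design, which the test suite re-derives;
Q1 negligible when its CI contains 5%.

Replication failures (non-convergent fit, undefined index) are recorded as
missing for that method and replication; aggregates report the effective L.

## Problem sizes and reproducibility

The study design is N = 500, J = 5, δ = (−1, −0.5, 0, 0.5, 1), μ = 0,
σ² = 1, over the grid π ∈ {0.1, 0.2, 0.3} × ρ ∈ {0, −0.4, −0.9} ×
w ∈ {0, 1}. The test suite and the acceptance script use 1000 replications
for quantities that need no model fitting (ineligible counts, H bias, the
complete-data σ̂² interval) and 200 replications where every replication
carries one or more MML fits; with pattern-grouped fits (a few milliseconds
each) a full 16-method condition runs in well under a minute. A master seed
spawns one child stream per replication × stage (latents, responses, mask,
one per randomized method), making every number bit-reproducible from the
config alone.

## Known limitations

* The missingness mechanism is a calibrated reconstruction: its linear-clip
  form matches the reference ineligible-person counts, but quantities that
  are sensitive to the exact distribution of per-person missingness rates
  (e.g. the latent-variance bias of PMS at π = 20%) can sit a few percent
  away from reference values even when the neighbouring rates match.
* Deterministic Rasch imputation (RAS) with any correct person point
  estimate *widens* the apparent spread of item difficulties here; some
  legacy implementations report a *narrowing* instead, consistent with
  evaluating the fill probability under an item-easiness sign convention.
  The magnitude is comparable; the sign is not. The package keeps the
  difficulty convention of the fitted model throughout.
* The Q1 variant was chosen by type-I-error calibration at the study
  design; at very different N or J the (J−1)/J-multiplied form may be the
  better-calibrated one.
* PSI's exact historical formula varies across software lineages; both
  implemented forms are documented above and selectable.
* No multiple imputation, hot-deck, response-function or two-way
  imputation; no polytomous items; no CML estimation; no group-comparison
  power analysis.
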