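# Methods

## Model

Symptom endorsement vectors x ∈ {0,1}^p are modelled by a pairwise binary
Markov random field (Ising model in its {0,1} parameterization):

    P(x) = Z⁻¹ exp( Σ_j τ_j x_j + Σ_{j<k} β_jk x_j x_k ).

τ_j is the threshold of symptom j — its log-odds of endorsement when no
neighbour is endorsed; β_jk is the conditional association between j and k
given all other symptoms.  The {0,1} domain (rather than ±1) is used
throughout because the data are presence/absence indicators and because it
makes the nodewise conditionals ordinary logistic regressions:

    P(x_j = 1 | x_−j) = logistic( τ_j + Σ_k β_jk x_k ).

This identity is the package's primary correctness oracle: an unpenalized
nodewise logistic regression fitted to all 2^p states weighted by the exact
model probabilities must return (τ_j, β_j·) exactly, and the test suite
checks this to 1e-4 for p ≤ 4.

## Estimation (eLasso)

For each node j an l1-penalized logistic regression of column j on the
remaining p−1 columns is fitted along a penalty path of `n_lambda = 100`
log-spaced values from λ_max (the smallest penalty at which every slope is
zero, computed from the data as max_k |n⁻¹ Σ_i x_ik (x_ij − x̄_j)|; the path
starts a factor 1+1e-6 above it so the intercept-only model is always on
the path despite round-off at the KKT boundary) down to `0.01·λ_max`.  The
intercept is never penalized.  The penalty is selected by

    EBIC(λ) = −2 ℓ̂(λ) + J log n + 2 γ J log(p−1),

where ℓ̂ is the log-likelihood of the penalized coefficients evaluated
without the penalty, J counts nonzero slopes (the intercept is not
counted), and γ defaults to 0.25.  Ties break toward the sparser
(larger-λ) model.  The two directed estimates of each edge are combined by
the AND rule (default: both nonzero, weight = mean of the two) or the OR
rule (either nonzero; a structural zero still enters the mean).  Thresholds
τ_j are the selected intercepts.  Estimation is fully deterministic.

Numerical details:

* Optimizer: IRLS with an inner cyclic coordinate descent on the weighted
  least-squares subproblem (the glmnet scheme), relative tolerance 1e-7,
  at most 10,000 outer iterations; both are exposed in `ElassoConfig`.
* Because predictors are binary, the n×(p−1) design is collapsed exactly to
  its unique rows (≤ 2^(p−1), i.e. ≤ 256 for the 9-symptom instrument) with
  success/total counts, so fit time does not grow with n.  This is a
  likelihood-preserving reformulation, not an approximation.
* Perfect separation at small penalties: coefficients are capped at |40|;
  a path point that hits the cap is excluded from EBIC selection, with a
  warning.
* A constant column has no finite estimate; the default is a hard error,
  and `on_constant="drop"` instead zeroes its row/column and records a
  capped threshold (±40) — note dropping changes the effective p in the
  EBIC of nothing already fitted, since the node simply does not enter the
  nodewise regressions.
* No predictor standardization: all predictors are 0/1 indicators on a
  common scale, so the penalty is already comparable across coefficients.

The solver is cross-checked in the tests against statsmodels GLM (λ = 0,
agreement 1e-7) and against scikit-learn's liblinear at λ > 0 by comparing
penalized objective values (ours must not be worse), keeping those
libraries strictly in the oracle role.

## Descriptive comparison of prevalences

Stratum prevalences are compared with the continuity-corrected (Yates)
chi-square on the 2×2 table, statistic
N·(max(|ad−bc|−N/2, 0))²/((a+b)(c+d)(a+c)(b+d)), 1 df.  The survey
literature this mirrors labels the procedure a "Z-test" but prints
chi-square-scale values that match the corrected statistic, not the
uncorrected one (which equals the squared pooled z); both are available,
Yates is the default.  Display percents round half-up to integers.
Significance markers: `*` p < 0.05, `**` p < 0.001.  No multiplicity
adjustment is applied across the nine symptoms, matching the reporting
convention of the tables this reproduces.

## Centrality

* strength(j) = Σ_k |β_jk| — sign-blind.
* Distances use edge length 1/|β_jk| and weighted shortest paths.  A
  verbal definition by "number of edges crossed" would suggest unweighted
  hops; the weighted convention is the field standard for symptom networks
  and is the default here, with `weighted=False` available.  This is a
  documented divergence.
* closeness(j) = 1/Σ_k d(j,k), and 0 if any d(j,k) = ∞ (so one isolated
  node zeroes closeness for the whole network — the convention is strict
  by design and visible in sparse estimates).  The inverse-total-distance
  form is used, not the (p−1)-averaged variant; with z-scored display the
  two differ only by a constant factor.
* betweenness: fractional shortest-path counts over unordered pairs
  (Brandes accumulation via networkx), which equals exhaustive path
  enumeration — asserted to 1e-9 on seeded random graphs with p ≤ 6.
* z-scores standardize across the p nodes with the population SD; zero SD
  yields all-zero z-scores with a warning.
* The shared layout is a seeded Fruchterman–Reingold embedding of the
  pooled network, rescaled to the unit square and reused unchanged for
  every stratum rendering; an edgeless reference falls back to a
  deterministic circle.

## Stability

The case-dropping bootstrap draws, for each drop proportion q in
{0.05, …, 0.70} (step 0.05) and replicate b ≤ B (default 1000), a uniform
subsample of ⌈(1−q)n⌉ rows without replacement — "loss of subjects", not
resampling — refits the network, and records the Pearson correlation (or
Spearman by config) of the subsample's vectorized upper-triangle edge
weights, thresholds τ, and node strengths with the full-sample values.
CS(cor = 0.7) is the largest q at which ≥95% of the valid replicates
correlate ≥0.7; labels: ≥0.2 reasonable, ≥0.5 excellent.  The "intercept"
stability reported in this literature is interpreted as the τ vector, the
only intercept-like quantity in the model.  A replicate whose refit fails,
or whose statistic vector has zero variance on either side (e.g. an empty
subsample network), is recorded as NaN and excluded from the valid count —
the same NA convention as the reference R tooling; note this can flatter CS
when many subsample networks come out empty, which is why the failure count
is reported alongside.

## Synthetic data

`enumerate_distribution` computes exact state probabilities for p ≤ 20
(state s has node 0 as least significant bit); `sample(method="exact")`
draws i.i.d. states from it; `sample(method="gibbs")` runs single-site
sweeps with burn-in 1000 sweeps and thinning 10 (conservative for p = 9).
`calibrate_thresholds` solves marginals(τ; β) = targets by damped
fixed-point iteration on the logit scale (closed form logit(target) when
β = 0), to 1e-6.

`emulate_study(seed)` is the stated test-bed world: two gender-specific
ground-truth models whose thresholds are calibrated so the exact marginals
equal the published per-stratum prevalences of the emulated survey
(women n = 288: DM 0.45, LI 0.27, AW 0.23, SD 0.36, PAR 0.14, FE 0.34,
FW 0.24, C 0.23, SU 0.19; men n = 267: 0.20, 0.14, 0.10, 0.16, 0.10,
0.13, 0.11, 0.10, 0.07), with planted sparse couplings qualitatively
echoing the reported structures — a depressed-mood hub (DM–FE 1.2, DM–PAR
0.9, DM–SD 0.9, plus SD–SU, LI–FE, PAR–C at 0.6) for women; FE tied to
SU/LI/AW (1.2) and SD tied to PAR/DM/FW (1.2/0.9/0.9) for men.  Coupling
magnitudes were chosen once as typical of estimated symptom networks
(conditional log-odds ratios of 0.6–1.2) and are not tuned.  Two models
rather than four: the four published strata overlap pairwise (every
respondent is in one gender and one age stratum), so calibrating four
independent models to all four margins simultaneously is over-constrained;
age-group labels are instead assigned by seeded permutation within gender
at fixed totals 296/259 (154 of the women and 142 of the men in the
younger group, the proportional split).  Consequences: gender-stratum
marginals match their published targets in expectation, age-stratum
marginals only approximately (mixtures of the two gender models), and the
age-stratified networks are mixture artifacts — useful for pipeline
plumbing, not for inference benchmarks.

What the generator does not emulate: item-level missingness, interviewer
effects, age-by-symptom interactions, or the unpublished coupling weights
of the real survey.  A green estimator test on this world therefore
establishes support/weight recovery under a correctly specified sparse
Ising model at the stated n — not agreement with the survey's unpublished
network, which would require the raw respondent-level data.

## Known limitations

* Binary data only; no Gaussian/polychoric variants, no ordinal scales.
* The AND/OR rule and γ apply globally; no per-node overrides.
* CS is reported on the grid actually examined; a model stable beyond 70%
  case drop is truncated at 0.7 by construction.
* Closeness of a disconnected network is all zeros by the strict
  convention; use the distance matrix directly if per-component closeness
  is wanted.
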