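# Methods

## The index

The Composite Coverage Index is a weighted mean of eight binary
intervention indicators over the maternal–child care continuum. Written
with per-component weights in sixteenths it is

| component | weight | defined for |
|---|---|---|
| FPS — family-planning need satisfied | 4/16 | all women 15–49 |
| SBA — skilled birth attendance | 2/16 | all |
| ANCS — ≥1 antenatal visit, qualified provider | 2/16 | all |
| DTC3 — 3 pentavalent/DTC doses | 2/16 | all |
| MSL — measles dose | 1/16 | all |
| BCG — BCG dose | 1/16 | all |
| ORT — oral rehydration | 2/16 | children with a diarrhoea episode |
| CPNM — care-seeking for cough/pneumonia | 2/16 | children with a cough episode |

so that the four care domains (family planning; maternal/newborn care;
immunisation; care of the sick child) each contribute one quarter. The
weights are held as exact rationals and sum to 1; with all eight
components observed, 16·CCI is an integer. A record is *optimal* when
CCI ≥ 0.50 — the threshold is inclusive — and *partial* otherwise.
Classification is always per record on the un-aggregated score; survey
weights enter only at estimation time.

**Not-applicable components.** ORT and CPNM exist only for children with
the relevant illness episode. The default `na_policy="renormalise"` drops
the missing component and rescales the remaining weights to sum to one;
`impute_zero`, `impute_one` and `drop_record` are available and every
scored output carries a `renormalised` flag. Renormalisation was chosen
as the default because it makes no assumption about the unobserved
behaviour, and because the choice is surfaced rather than hidden: when no
component is missing all four policies coincide (tested as a property).

## Design-based estimation

All variances use first-order Taylor linearisation with the
with-replacement PSU approximation: the covariance of an estimator with
per-record influence contributions `u_i` is the between-PSU variance of
the PSU totals of `u` within strata, summed over strata with the
`n_h/(n_h−1)` factor. No finite-population corrections and no replicate
weights. Strata with a single PSU raise an error by default; an explicit
`single_psu="center"` option centres the lonely PSU at the grand mean
(silent variance underestimation being worse than a crash). All
estimators are ratio-type, so every estimate, SE, statistic and p-value
is invariant to rescaling the weights (tested).

Proportions get logit-scale 95% CIs (back-transformed, hence inside
[0,1]) and a design effect relative to `p(1−p)/(n−1)`.

**Rao–Scott corrected chi-square.** The Pearson X² is computed on the
weighted cell proportions scaled to the unweighted n, then corrected by
the second-order (Satterthwaite) procedure: eigenvalues of the
generalised design-effect matrix over the (R−1)(C−1) interaction
contrasts give the corrected statistic and fractional df. Two
implementation details matter:

- the SRS reference covariance used in the design-effect matrix carries
  the same `n/(n−1)` with-replacement factor as the Taylor estimator, so
  under equal-weight element sampling the corrected statistic equals the
  Pearson X² *exactly* (not just asymptotically);
- the correction is computed on the subspace where the null covariance of
  the contrasts is non-degenerate; tables with empty cells that kill all
  contrast variance fall back, flagged, to the uncorrected reference.

The printed p-value is the F form (statistic/df against F(df, df·(#PSU −
#strata))), matching common survey-software behaviour; the chi-square
version is reported alongside. Under a clustered null (two independent
binary variables, each with cluster-level random effects of SD 0.8, 30
clusters × 15) the measured type-I error at α = 0.05 over 1,000
replicates is ≈ 0.04–0.06 (recomputed by the test suite and the
reproduction script).

**Design-based rank-sum test.** The outcome is replaced by pooled
weighted mid-ranks scaled to (0,1]; the test is a Wald test of the
difference in design-weighted mean rank score between the two groups,
with linearised variance and a t reference on the design df. Under
equal-weight element sampling its z agrees with the classical
normal-approximation Wilcoxon z to within a few percent (tested at
n = 200/group).

## Survey-weighted logistic regression

Point estimates maximise the weighted log-likelihood (pseudo-MLE) by
Newton/IRLS with step-halving; convergence is declared on a parameter
step below 1e-10 or a relative likelihood change below 1e-10 — the latter
matters under quasi-separation, where the fit is returned with a
`separation` warning once |β| exceeds 15. Covariances are the
design-based sandwich A⁻¹BA⁻¹ with B the between-PSU covariance of the
score totals. Categorical terms use reference-level dummy coding;
complete-case rows are used per fitted model with the dropped count
recorded.

**AIC.** Under a pseudo-likelihood the AIC is not uniquely defined; here
weights are normalised to mean 1 inside the AIC so it scales with n, not
Σw, making model comparison invariant to the weight scale (tested).
Backward elimination drops one whole term (categorical block) per step —
the removal with the lowest AIC — and stops when no removal lowers it;
exact ties (within 1e-9) resolve to the term earliest in the
specification, so the trail is deterministic.

**Hosmer–Lemeshow.** Records sorted by fitted probability are cut into
g = 10 groups of near-equal *weighted* size, never splitting a block of
tied fitted probabilities; the statistic is Σ(O−E)²/(W·p̄(1−p̄)) with
df = g−2. Under a correctly specified model the rejection rate at 5% is
≈ 0.04–0.06 over 500 replicates (recomputed at run time).

## Spatial statistics

Spatial weights come from a symmetric region adjacency list;
row-standardisation is the default style (binary available). Global
Moran's I uses the cross-product form with E[I] = −1/(n−1); local Moran
I_i = (z_i/m₂)·Σ_j w_ij z_j, whose row-standardised mean equals the
global I (asserted to 1e-10). With only 8 regions the analytic normal
p is unreliable, so permutation inference is primary: full relabelling
for the global test (two-sided count of |I_perm| ≥ |I_obs|, pseudo-p
(m+1)/(M+1); exact enumeration available for n ≤ 8) and conditional
permutation (unit fixed, the others permuted into neighbour positions)
for the local tests. Quadrants are assigned purely from the signs of the
centred value and its lag; significance is a separate flag.

The Guinea adjacency fixture encodes the first-order borders of the 8
administrative regions (Conakry's only neighbour is Kindia, which
surrounds the peninsula).

## Classification tree

Breiman-style binary Gini CART with case weights: numeric/ordinal splits
at midpoints, categorical splits via the order-by-weighted-class-rate
shortcut (exact for a binary response). Stopping: `max_depth`,
`min_node_weight` (weighted), and `min_improvement` on the Gini decrease,
which plays the role a significance stop plays in conditional-inference
trees. No pruning by default. Survey structure enters only through the
case weights. The tree's candidate variables are wired to the stepwise
selection's output in the pipeline, so the profile reflects the final
regression model.

## Synthetic survey generator

The generator emulates the features of a two-stage national household
survey that the analysis actually relies on:

- **Strata and clusters** — 8 regions × urban/rural = 16 strata, each
  with `clusters_per_stratum` clusters (default 25) whose household
  counts vary uniformly over 0.6–1.4 × `households_per_cluster`
  (default 125), giving a finite population of ≈50,000 eligible pairs.
- **Wealth confounding** — a latent wealth index with a regional shift
  (capital high, highlands low; strength `wealth_region_sd`) plus an
  urban shift, binned into population quintiles. This deliberately
  builds the wealth×region confounding that the equity analysis is
  about.
- **Covariates** — education (mother, partner), media access
  (newspaper/radio/TV), work, marital status, planned pregnancy, ANC ≥ 4
  visits, child age/sex, drawn from logistic/ordinal models on wealth
  and residence with marginals in the range typical of West African
  DHS rounds.
- **Components** — each of the eight indicators is Bernoulli with
  logistic probability on (intercept, centred wealth quintile, ANC ≥ 4,
  urban, any maternal education, planned pregnancy, radio); the default
  coefficient vectors give wealth and ANC the largest effects. Diarrhoea
  and cough episodes occur at rates 0.25 and 0.30 (typical two-week
  under-five prevalences); ORT/CPNM are defined only for those records.
- **Sampling** — first stage systematic PPS on a randomly ordered
  cluster list (the standard DHS device), second stage systematic
  households; weights are inverse inclusion probabilities, exactly 1 in
  the census case and self-weighting within stratum otherwise.
  Certainty clusters are handled by clamping the first-stage probability
  at 1.

The ground truth (true coefficient vectors, per-region and marginal
optimal proportions computed exhaustively over the generated population)
is emitted alongside, and identical (config, seed) reproduce identical
populations, truths and samples byte for byte.

**What the generator does not emulate:** household rosters beyond the
analysed fields, non-response and calibration adjustments to weights,
child mortality (only eligible records are emitted), within-household
correlation beyond the cluster effect, and measurement/recall error in
vaccination status. Passing tests therefore demonstrate the correctness
and calibration of the estimators under the assumed design, not the
substantive national estimates, which require the restricted microdata.

## Problem sizes and numerical choices

The validation studies run at sizes chosen to give stable Monte-Carlo
estimates in seconds: 1,000 replicates for the Rao–Scott null, 500 for
Hosmer–Lemeshow and CI coverage, 20 seeds × ~5,000 records for
coefficient recovery, 200 replicate draws for the Horvitz–Thompson
check. Tolerances: exact identities at 1e-8–1e-12; oracle equivalence of
the logistic fit at 1e-6; recovery within 3 design SE. Ties in ranks are
mid-ranked; ties in stepwise AIC and tree splits resolve to the earliest
candidate; all permutation tests take explicit seeds and reproduce
exactly.

Known limitations: no replicate-weight variance, no finite-population
corrections, no multilevel models or interaction search, Wald-only
inference in the regression tables, and the spatial analysis treats
region-level proportions as fixed values (their sampling error is
reported but not propagated into the Moran inference).
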