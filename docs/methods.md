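# Methods

`pvsignal` implements nine statistical detectors for signals of
disproportionate reporting (SDRs) in spontaneous-reporting count data whose
adverse-event (AE) terms sit in a two-level WHO-ART-style hierarchy
(system-organ classes, SOC, containing preferred terms, PT), together with a
synthetic-data generator and an evaluation harness that measures type I
error, power, sensitivity and positive predictive value (PPV) across
simulated replicates.

## Data model

Reports are tabulated as an I x J matrix of counts `n_ij` (AE term i, drug
j) at one hierarchy level.  Every detector consumes the 2x2 table of one
(AE, drug) pair — `n_ij`, the AE margin `n_i.`, the drug margin `n_.j`, the
grand total `n_..` — and the expected count under row-column independence
`E_ij = n_i. n_.j / n_..`.  Margins are always recomputed from cells.
Undefined estimates (zero cells where a statistic or its variance does not
exist) are carried explicitly and never signal.

## Detectors

**ROR** (reporting odds ratio) and **PRR** (proportional reporting ratio)
are the classical frequentist disproportionality measures with
normal-approximation intervals on the log scale:

    ROR = n_ij (n_.. - n_i. - n_.j + n_ij) / ((n_i. - n_ij)(n_.j - n_ij))
    var log ROR = 1/n_ij + 1/(n_i. - n_ij) + 1/(n_.j - n_ij) + 1/(n_.. - n_i. - n_.j + n_ij)

    PRR = (n_ij / n_i.) / ((n_.j - n_ij) / (n_.. - n_i.))
    var log PRR = 1/n_ij - 1/n_i. + 1/(n_.j - n_ij) - 1/(n_.. - n_i.)

A pair is flagged when the 95% CI lower bound `exp(log point - z sd)`
exceeds the cutoff (standard cutoff 2).  For rare AEs the two coincide.

**IC** (information component) is `log2(n_ij / E_ij)` with variance
`(1/ln2)^2 (1/n_ij + 1/n_i. + 1/n_.j)`; the interval is additive on the IC
scale (`IC ± z sd`) and the standard rule is lower bound > log2(2) = 1.
Exponentiating a log of the IC, as sometimes printed, is the identity where
defined and undefined for IC <= 0, so the additive form is used.

**LRT** (likelihood-ratio-test scan over AEs for one fixed drug): for each
AE with observed excess (`n_ij/n_i. > (n_.j - n_ij)/(n_.. - n_i.)`),

    llr_i = n_ij ln(n_ij / E_ij) + (n_.j - n_ij) ln((n_.j - n_ij) / (n_.j - E_ij)),

zero otherwise; the test statistic is the maximum over AEs.  Inference is
Monte Carlo: null replicates redistribute the drug total as
`Multinomial(n_.j, n_i./n_..)`, each scored by its own maximum, and
`p = R/(n_mc + 1)` with R the rank of the observed statistic (ties count
against it).  Individual AEs receive rank p-values against the same null
maximum distribution, which controls the family-wise error; the minimum over
AEs is the global p-value.  Default `n_mc = 9999`.

**GPS** (gamma-Poisson shrinker): `n_ij | λ_ij ~ Poisson(λ_ij E_ij)` with a
five-parameter mixture-gamma prior
`λ ~ w Gamma(α1, β1) + (1-w) Gamma(α2, β2)` fit by maximum marginal
likelihood over *all* cells of the matrix (each cell's marginal is a mixture
of negative binomials `NB(α_k, E/(E+β_k))`).  The optimiser works on
unconstrained transforms (log shapes/rates, logit weight) with an analytic
gradient, L-BFGS-B bounded to ±30 on the transformed scale (so degenerate
point-mass priors are representable but finite), from the DuMouchel-style
start (0.2, 0.1, 2, 4, 1/3) plus 4 jittered restarts; convergence tolerance
1e-8 on the objective.  The decision statistic EB05 is the 5th percentile of
the conjugate posterior mixture
`w* Gamma(α1+n, β1+E) + (1-w*) Gamma(α2+n, β2+E)`, obtained by bracketed
root finding on the posterior CDF (|CDF(EB05) - 0.05| < 1e-8); the standard
rule is EB05 > 2.  On data simulated under the exact global null the
marginal likelihood is maximised by a near-point-mass prior at λ = 1, which
makes EB05 ≈ 1 for every cell; rejection rates at a cutoff of exactly 1 are
therefore an artifact of optimiser stopping rules, while cutoffs ≥ 1.5 are
stable.

**BCPNN**: beta-binomial model for the joint and marginal reporting
probabilities (all prior beta parameters 1 except
`β_ij = γ - 1, γ = (n_.. + 2)^2 / ((n_i. + 1)(n_.j + 1))`), delta-method
posterior mean and variance of the IC:

    E[IC]   = log2[(n_ij + 1)(n_.. + 2)^2 / ((n_.. + γ)(n_i. + 1)(n_.j + 1))]
    Var[IC] = (1/ln2)^2 [ (n_.. - n_ij + γ - 1)/((n_ij + 1)(1 + n_.. + γ))
              + (n_.. - n_i. + 1)/((n_i. + 1)(n_.. + 3))
              + (n_.. - n_.j + 1)/((n_.j + 1)(n_.. + 3)) ]

with rule `E[IC] - z sqrt(Var[IC]) > log2(2)`.  The `(n_.. + 2)^2` term is
forced by the stated beta posterior means; a delta-method check against
direct posterior sampling is part of the test suite.

**new IC**: conjugate `Gamma(0.5, 0.5)` prior on λ, posterior
`Gamma(n_ij + 0.5, E_ij + 0.5)`, posterior mean of log2 λ approximated by
`log2((n_ij + 0.5)/(E_ij + 0.5))`, exact gamma quantiles for the credible
interval.  A literal rule "2.5% quantile > 0" is vacuous for a gamma
posterior, so the decision threshold on the 2.5% quantile is configurable
with default 1 (i.e. the lower limit of log2 λ above 0).

**sB** (simplified Bayes): single `Gamma(α, α)` prior (mean 1, variance
1/α; defaults α ∈ {0.5, 0.01, 0.0001}, 0.5 used throughout), posterior
`Gamma(α + n_ij, α + E_ij)`, and the moment-based bound
`mean - 1.645 sd > 2`.  With α = 0.5 the posterior is identical to new IC's;
the two methods differ only in interval construction (moment bound versus
exact quantile), which we keep as printed rather than unifying.

**Tree scan**: simple cuts only — every PT leaf, and every SOC with all its
leaves.  With `c_i` the leaf count for the target drug and `x_i` its count
over all drugs (totals C, X), a cut G scores
`LR(G) = c_G ln(c_G/x_G) + (C - c_G) ln((C - c_G)/(X - x_G))` when its rate
exceeds the rest of the tree, and is excluded otherwise (the reported value
is the raw form above; subtracting the null constant `C ln(C/X)` would shift
all cuts equally and cannot change rankings or p-values).  Inference
conditions on C: null replicates are `Multinomial(C, x_i/X)` over leaves,
each replicate scored by its own maximum over the same cuts; the global
p-value is the rank `R/(n_mc + 1)` and secondary cuts get rank p-values
against the same null maximum distribution.  Ties for the most likely cut go
to the smallest node identifier.  All computations are canonicalised to the
tree's leaf order, so results are invariant to the order in which leaf data
are supplied.

## Two-level evaluation

Every method except the tree scan is run twice — on the PT-level table and
on the SOC-aggregated table — and the detection sets are merged; the tree
scan covers both levels in one pass.  A detection is a (level, term) pair;
a PT and its parent SOC count separately.

Truth labelling for simulated data: planted signals live on PT cells.  By
default a SOC containing at least one true PT is also a true signal
(`pt_and_parent_soc`), so SOC detections induced by genuine PT signals score
as true positives; `pt_only` is available.  Across replicates the harness
reports type I error (share of datasets with ≥ 1 false positive), power
(share with ≥ 1 detection), and sensitivity/PPV averaged over the S datasets
with at least one detection (undefined, reported as NaN, when S = 0).

## Synthetic data generator

One replicate at total report count `n_..`:

1. AE margins (I = 300 by default) and drug margins (J = 500) are each drawn
   `Multinomial(n_.., u/Σu)` with independent `Uniform(0, 1)` weights,
   giving skewed, realistic term/drug totals.
2. PTs are assigned uniformly at random to SOCs (30 by default, matching the
   order of magnitude of SOC counts in real WHO-ART extracts), every SOC
   keeping at least one PT.
3. One target drug j* is chosen uniformly; `⌊signal_ratio · I⌋` PT cells are
   selected as true signals with relative reporting rates
   `rr_i ~ Uniform(rr_low, rr_high)` (1 elsewhere), and the target column is
   `Multinomial(n_.j*, p)` with `p_i = rr_i r0 n_i./n_..` and the baseline
   `r0 = 1/Σ_i rr_i n_i./n_..` derived from the normalisation constraint.
   In the rare event a cell probability leaves [0, 1] the signal set is
   resampled (at most 100 times).
4. In `full_matrix` mode (required by GPS) every other column is filled
   under the null, `Multinomial(n_.j, n_i./n_..)`, and all margins are
   recomputed from realised cells so the 2x2 identities hold exactly; in
   column-only mode the generated margins are used directly.

Replicates are seeded by a `(base seed, replicate index)` seed sequence:
independent streams, bitwise reproducible, parallel-safe.  With
`signal_ratio = 0` the generator reduces exactly to the global null.

What the generator does *not* emulate: report-level covariates and
duplicated reports, real margin distributions (margins come from uniform
weights, not an empirical database), correlated drugs (all non-target
columns are null and independent), multi-parent terms, and time.  Passing
benchmarks here therefore demonstrate correctness of the statistics and
their calibration under this stylised model, not performance on any real
reporting database.

## Numerical choices

- Normal quantiles: two-sided `z_{1-α/2}` from the requested confidence
  (default 0.95); sB uses the printed constant 1.645.
- Monte Carlo ranks count ties against the observed statistic
  (conservative), and `p = R/(n_mc + 1)` is never 0.
- GPS fit excludes structurally empty cells (E = 0, which are
  parameter-free) and errors if such a cell holds a count.
- EB05 bracket: [0, max of component 99.9% quantiles], doubled until it
  covers, then Brent's method at ~1e-14 tolerance.
- Degenerate tree cuts (whole tree, empty leaves) are excluded by the
  excess indicator sentinel (-inf), and a dataset with no admissible cut has
  p-value 1 by construction.

## Replication scales

The packaged benchmark scripts use the study conditions
(`n_.. = 300,000`, I = 300, J = 500, 30 SOCs): 1000 replicates for the
closed-form detectors and the Monte Carlo detectors (999 null replicates per
test), and 300 full-matrix replicates for GPS, whose five-parameter refit on
every 300 x 500 replicate dominates the compute; these sizes keep the full
reproduction to roughly ten minutes on one CPU while leaving Monte Carlo
standard errors of at most ~0.03 on any reported rate.

## Known limitations

- The ROR/PRR decision rule is the documented CI-lower-bound rule; reference
  benchmark rows whose behaviour matches a point-estimate rule will not be
  reproduced by it (the CI rule flags far fewer small-count cells).
- GPS operating characteristics at an EB05 cutoff of exactly 1 are not
  stable under the null (see the boundary discussion above).
- Sensitivity/PPV depend on how SOC-level detections are scored; both
  conventions are implemented and the default is stated above.
- The LRT's secondary signals use rank p-values against the null maximum;
  false-discovery-rate ordering of secondary signals is out of scope, as are
  extended scans over arbitrary AE groups, zero-inflated variants, and
  sequential (SPRT-style) monitoring.
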