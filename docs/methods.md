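# Methods

## Scope and model

qsarkit models the potency of small-molecule inhibitors as a linear function
of standardized molecular descriptors, y = β₀ + Σⱼ βⱼxⱼ, with y = pIC50 =
−log10(IC50 in mol/L). The package assumes descriptors are supplied as a
numeric table (descriptor *computation* from structures is out of scope) and
that the series is small (tens of compounds), which drives every design
choice below: heavy regularization through subset selection, honest
resampling-based validation, and explicit applicability-domain reporting.

## Preprocessing

Order: drop columns with any missing value (at ingestion) → drop
zero-variance columns → remove one member of every descriptor pair with
|Pearson r| > 0.95 → keep the top 50 columns by variance → standardize the
survivors on the training rows → stratified 70/30 split.

Two choices here were genuinely open:

- **Variance ranking scale.** After unit-variance scaling every column ties,
  so the top-k step ranks *pre-standardization* variances and the
  standardization statistics are re-estimated on the surviving columns.
- **Correlation-filter tie-break.** The scan is greedy in column order and
  keeps the earlier member of an offending pair, so the output is invariant
  to appending a duplicate of a retained column.

Sample statistics use the n−1 denominator throughout. Stratification bins a
continuous response into 5 quantile bins; per-bin training counts follow the
largest-remainder rule so the total is exactly round(0.7·n) (ties favour
earlier bins), and membership within bins is sampled with a seeded
generator. Scaling parameters serialize to JSON so screening runs reuse the
training statistics bit-exactly.

## Feature selection

The GA is an elitist generational algorithm on binary masks: tournament
selection (size 2), uniform crossover (rate 0.9), per-bit mutation at rate
1/p, one elite, population 50, at most 50 generations, stopping after 10
generations without best-fitness improvement. Fitness is R²_adj − k/n; empty,
oversized (n − k − 1 < 1) or rank-deficient masks score −∞. Elitism makes the
best-fitness trace non-decreasing; fitness evaluations are memoized within a
run. All operator settings are configurable — the stopping rule and the
fitness are the protocol-fixed parts.

The "no improvement for 10" stopping rule is read as 10 *generations* (the
alternative reading, 10 independent restarts, would multiply cost without
changing the optimum the suite checks against).

Stepwise selection is bidirectional from the intercept-only model on the
Gaussian concentrated-likelihood AIC, n·ln(RSS/n) + 2(k+1); the BIC refit
uses the same search restricted to a prior pool with penalty ln(n)(k+1).
Additive constants cancel in comparisons. VIF screening iteratively removes
the column with the largest 1/(1−R²ⱼ) until all are ≤ 10 (the conventional
cutoff); infinite VIFs (exact collinearity) are removed first, ties resolve
to the later column.

## Models

OLS is solved by least squares on the intercept-augmented design; rank
deficiency is an error naming the dependent columns (pivoted QR). The
residual SD uses n − p − 1. PLS wraps a standard implementation with
`scale=False` (input is already standardized), choosing the component count
by 10-fold CV RMSE; at full rank its training predictions coincide with OLS,
which the suite asserts. Tree baselines (random forest with 500 trees;
gradient boosting with depth 6, learning rate 0.1, 200 rounds) are adapters
over established libraries and inform comparisons only.

The built-in reference equation (`published_kras_model()`) is a pure
constant. Its training scaling vector is not available, so predictions are
only meaningful on inputs the caller has standardized; this is deliberate
and documented rather than silently approximated.

## Validation battery

- **Repeated k-fold CV** (default 10×5): the complete fit specification —
  including any feature selection declared inside it — is re-run on each
  fold's training rows, so selection bias cannot leak into fold scores.
  Fold R² is computed about the fold's observed mean (the training-mean
  convention is selectable). Summaries are the mean and empirical 2.5/97.5%
  quantiles; on ~62-compound series the quantile range spans several tenths
  of an R² unit, which is a property of the regime, not a defect.
- **Y-randomization** (default B = 50): empirical p with the +1 correction,
  so p ≥ 1/(B+1) always; a strong real signal attains that floor.
- **Leave-cluster-out** (default k = 4 k-means clusters on standardized
  descriptors): emulates prediction on a novel chemical neighbourhood.
  Held-out clusters with fewer than 3 points are flagged unstable — an R²
  over 2 points is degenerate (it is ±1 or undefined) — rather than
  suppressed.
- **Split conformal** (default α = 0.1, 80/20 proper-train/calibration,
  calibration size m = ⌈0.2n⌉): q̂ is the ⌈(m+1)(1−α)⌉-th smallest absolute
  calibration residual; if that rank exceeds m the interval is honestly
  infinite (with a warning) instead of clipped. The score is the absolute
  residual, giving constant-width intervals and a single reportable width.

## Applicability domain

Mahalanobis D² uses the training mean and sample covariance of the *model's*
descriptor subset (a full-space override is available); the default cutoff
is the analytic χ²(0.95, p) quantile, with a fixed-cutoff mode (e.g. 15.0)
for reproducing screening flags computed under a rounded threshold. A
near-singular covariance falls back to a small ridge (1e−8 of the mean
diagonal, logged). Williams leverage uses the intercept-augmented training
projector, h* = 3(p+1)/n, and standardized residuals (training residual SD,
n − p − 1) within ±3. Strata with fewer than 3 points report counts only.

## Screening

Queries are standardized with the stored training statistics, predicted,
optionally wrapped in conformal intervals, and flagged against the
Mahalanobis domain. The hit rule is a strict inequality (pIC50 > 8.0).
Outside-domain compounds keep their predictions but are labelled
extrapolations; the "reliable hits" are hits ∩ inside-domain.

## Synthetic data

The generator emulates the statistical structure of a small congeneric
series: Gaussian descriptors with latent-factor block correlation (within-
family shells, ρ = 0.6), a configurable number of near-duplicate columns
(|r| ≈ 0.99) to exercise the redundancy filters, heterogeneous raw scales
and locations so standardization is a real step, and a sparse linear signal
on 8 of ~50 descriptors with Gaussian noise. Defaults: 62 compounds, noise
SD 0.88 — chosen so that with reference-magnitude coefficients (Σβ² ≈ 2.0)
the population R² is near 0.72, a realistic fit level for such series —
activity centred at 6.7, giving pIC50 values spanning roughly 5–9.3.

`reference_study_fixture` names its 8 informative descriptors after the
reference equation (TASA, RDFE14, grav, RDFE19, PNSA3, RDFM11, RDFP9,
RDFV14) with the published coefficient magnitudes and signs. These are drawn
independently of each other — they represent unrelated descriptor families
(surface partitions, gravitational index, differently weighted RDF shells)
— while block correlation applies to the noise shells. Query sets mix
in-domain draws (from the training mean and covariance) with points shifted
8 training-SDs along random directions, with ground-truth labels.

What the generator does *not* emulate: real RDF/CPSA descriptor marginals
are bounded and skewed rather than Gaussian (a log-normal toggle exists);
real activity noise is heteroscedastic across assay batches; and real
descriptor redundancy is richer than pairwise near-duplication. Passing
tests therefore demonstrate correctness of the algorithms under the stated
statistical assumptions, not predictive validity on any particular assay.

## Numerical choices and degenerate inputs

- IC50 must be positive and finite; unparseable rows are dropped with a log,
  duplicated ids are an error. Duplicate structures collapse to the median
  pIC50 (robust, order-independent); the duplicate key is the canonical
  SMILES when parseable, else the raw string.
- Least-squares fits guard RSS ≥ 1e−300 inside logs; information criteria of
  rank-deficient designs are +∞.
- The GA guarantees at least one active bit per initial chromosome;
  degenerate masks are handled by the −∞ sentinel, not exceptions.
- KMeans clustering retries once with the next seed before raising on an
  empty cluster.
- CSV round-trips use 17-significant-digit output and round-trip float
  parsing, so descriptor matrices survive write→read bit-exactly.

## Problem sizes used by the test suite

The suite exercises the stochastic claims at sizes chosen to make the
Monte-Carlo error small relative to each assertion's margin: 20 seeded GA
replicates against exhaustive search at p = 10; 500 conformal
meta-replicates of a 62-train/50-test series; 10 000 in-distribution queries
against the χ² boundary (±1.5% tolerance around the nominal 5%); 200
Y-randomization meta-replicates under pure noise; 10 fixture seeds for
coefficient-sign recovery. These run in well under a minute each.

## Known limitations

- The reference equation cannot be applied to raw descriptor values without
  the (unpublished) original training scaling; it serves as a fixed,
  verifiable constant and a template for user-fitted models.
- Constant-width conformal intervals ignore heteroscedasticity; a
  studentized score would be the natural extension.
- Mahalanobis and leverage domains are ellipsoidal; multi-modal chemistry
  (disjoint scaffold clusters) can sit "inside" between modes. The
  leave-cluster-out battery is the mitigation.
- With ~62 compounds, stepwise/AIC-style selection admits occasional noise
  descriptors by construction (per-candidate admission probability ≈ 0.157);
  the GA's k/n penalty is slightly more conservative but not immune. The
  Y-randomization and repeated-CV reports are the intended guard.
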