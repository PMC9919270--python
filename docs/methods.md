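# Methods

`leafspec` estimates leaf chlorophyll content (LCC, μg·cm⁻²) from leaf-level
hyperspectral reflectance.  The chain is: edge trimming → Savitzky–Golay
smoothing → a sweep of Grünwald–Letnikov fractional-order derivatives →
band-wise Pearson screening → VCPA-GA hybrid wavelength selection with PLS
cross-validation fitness → a five-learner regression comparison scored by
R², MAE, RMSE and RPIQ.  This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Fractional-order derivatives

On a unit (1 nm) wavelength grid the order-`v` Grünwald–Letnikov derivative
of a spectrum `f` at band `x` is

    d^v f(x) ≈ Σ_{k=0}^{m} w_k f(x−k),   w_0 = 1,   w_k = w_{k−1}(k−1−v)/k,

with the weights equal to the alternating generalised binomial coefficients
`(−1)^k C(v,k)`.  `v = 0` is the identity, `v = 1` and `v = 2` the backward
first and second differences; fractional orders interpolate between
baseline preservation and noise-amplifying differencing.  Choices:

- **Weights by multiplicative recursion**, not Γ-function evaluation: the
  recursion is exact and overflow-free for any memory length; the Γ form is
  retained only as an independent test oracle.
- **Memory `m`**: all bands to the left of the evaluation point, matching
  the series expanded back to the start of the spectrum.  Bands with fewer
  than 2 history points are flagged invalid in a mask rather than
  zero-padded — zero-padding would fabricate derivative values at the blue
  edge.  Configurable truncation is available (`FODConfig.memory`).
- **Unit grid only**: the printed series assumes step 1; non-unit grids
  raise an error telling the caller to resample, rather than silently
  rescaling.
- Derivatives are computed by direct summation on small problems and FFT
  convolution above 10⁶ band-terms; the switchover keeps small fixtures
  exact to machine precision.
- Default sweep: orders 0, 0.2, …, 2.0 (11 orders).

Savitzky–Golay smoothing precedes derivation.  The emulated campaign does
not state the filter parameters; defaults are a 9-band window with a
degree-2 polynomial (a common choice for 1-nm leaf spectra), edges handled
by one-sided polynomial fits, both configurable.  Edge trimming keeps
400–2400 nm inclusive (2001 bands of a 350–2500 nm instrument range).

## Correlation screening

Per band, product-moment correlation of the derivative against LCC;
significance is two-sided at level α (default 0.01) via the t-transform
`r_crit = t_{1−α/2,n−2}/√(n−2+t²)`.  At n = 293 this gives r_crit ≈ 0.1502.
No multiple-testing correction is applied per band, matching common
chemometric usage of this screen (a Bonferroni-corrected threshold can be
obtained by passing a smaller α); the screen is descriptive, not
inferential — selection is done by VCPA-GA, not by the screen.  Constant
and mask-invalid bands yield NaN and are never counted.  Ties in |r| break
to the lower wavelength.

## VCPA-GA wavelength selection

Selection runs in the 400–900 nm window (501 bands), where pigments drive
reflectance.  The samples are first split once into a calibration set
(193 of 293, proportionally scaled for other n) and an independent test
set; **selection never sees the test rows**, which are used exactly once to
compute the final RMSEP.

**Shrinkage (VCPA).**  An exponentially decreasing schedule
`r_i = p₀·e^(−k·i)` (k fixed by requiring `r_L = ω`) prescribes the number
of surviving bands at each of L iterations.  Each iteration draws K binary
inclusion vectors (Bernoulli 0.5, rows with < 2 bands redrawn), scores each
subset by the minimum 5-fold PLS RMSECV over 1–10 latent variables, and
retains the `r_i` bands with the highest appearance frequency among the top
10 % of subsets.  Full-scale defaults L = 50, K = 1000 follow the
originating VCPA formulation; ω = 100.

**Refinement (GA).**  Binary chromosomes over the ω survivors; tournament
selection (size 2), single-point crossover (rate 0.5), bit-flip mutation
(rate 0.01), elitism of 1, all-zero chromosomes repaired to a random single
inclusion.  Fitness is the negated PLS RMSECV under folds fixed per run, so
fitness is deterministic and memoised; elitism makes the best RMSECV
nonincreasing across generations.  GA hyperparameters are not dictated by
the emulated design; defaults (population 30, 100 generations) are
declared in `SelectionConfig` and echoed in run manifests.

The whole (shrink → GA) procedure is replicated (default 50×); the
replication with the lowest calibration RMSECV defines the reported subset
(the aggregation rule was an open choice; the per-band selection-frequency
table across replications is retained so other rules can be applied post
hoc).  Reported per order: Nvar, the optimal latent-variable count Nlvs,
RMSEC, RMSECV, RMSEP.

A plain-VCPA mode (`vcpa_select`) shrinks to ≤ 14 survivors and finishes
with an exhaustive best-subset enumeration, for comparison with the hybrid.

**PLS implementation.**  PLS1 (NIPALS, column/response centred on the
training part of each fold only) is implemented in-package and jitted with
numba, because selection evaluates ~10⁵ small candidate subsets per run and
per-call overhead dominates with general-purpose libraries.  The
implementation is verified in the test suite against
`sklearn.cross_decomposition.PLSRegression` fold by fold to 1e-10.
Latent-variable count is chosen as the RMSECV argmin over 1–10, ties to
fewer components.  CV folds are stratified on the response (fold labels
shuffled within consecutive y-rank blocks) and fixed per replication seed,
which stabilises RMSECV comparisons across candidate subsets.

## Regression evaluation

Samples are split once into train/test/validation parts (187/59/47 at
n = 293, proportional otherwise).  Five learners run on each order's
selected bands: ridge regression (α = 1), random forest (500 trees),
XGBoost (depth 6, η = 0.1, 200 rounds), RBF-kernel SVR (C = 10,
γ = 'scale'), and Gaussian-process regression (RBF + white kernel,
marginal-likelihood optimised).  Hyperparameters are fixed, library-typical
values declared in `learners.DEFAULT_HYPER` — no tuning is performed, so
differences between learners reflect their inductive biases at sensible
settings, not search effort.  Inputs are mean-centred with training means
only.

Metrics follow the standard definitions: R² = 1 − SSE/SST, MAE,
RMSE = √(SSE/n), and RPIQ = (Q3 − Q1)/RMSE.  RPIQ quartiles are the
linear-interpolation quartiles of the observed values of the evaluated
split (the estimator and the quartile source were open choices; using the
validation split's own quartiles makes RPIQ·RMSE = IQR an exact internal
identity).  Degenerate cases return NaN sentinels: R² when SST = 0, RPIQ
when RMSE = 0.

## Synthetic data generator

The generator emulates the statistical structure of a leaf-level field
campaign: n = 293 samples with LCC uniform on 12.44–73.95 μg·cm⁻²
(truncated-normal optional), spectra on the 350–2500 nm, 1-nm grid.  The
spectrum model is phenomenological — a near-infrared plateau, Gaussian
chlorophyll valleys at 450/670 nm whose depth grows linearly with LCC, a
Gaussian green-peak modulation at 550 nm that shrinks with LCC, a logistic
red edge whose centre shifts from 700 nm by +15 nm per 70 μg·cm⁻², fixed
water valleys at 1450/1950 nm, i.i.d. additive Gaussian band noise
(sd 0.005 reflectance; the emulated campaign publishes no noise model), and
clipping to [0, 1].  Every monotone LCC dependence is therefore analytic
and directly testable: reflectance at 550 nm strictly decreases with LCC,
the red-edge inflection moves to longer wavelengths, water valleys are
LCC-independent.  SPAD readings are simulated by exactly inverting the
exponential calibration Cab = 6.34299·e^(0.04379·SPAD) − 6.10629, with
optional meter noise (off by default).

What the generator does **not** emulate: radiative-transfer physics
(PROSPECT-class models), correlated/heteroscedastic instrument noise,
water/dry-matter covariation with pigments, scattering differences between
leaves, or canopy effects.  Consequently, passing tests demonstrate that
the pipeline's operators are correct and that the selection and evaluation
machinery recovers known structure under realistic dimensionality and
noise — they do not certify accuracy on any particular field dataset.

For selection benchmarks with an unambiguous ground truth the package also
provides a planted-band design (`make_planted_bands`): an i.i.d. standard
normal band matrix with a response depending on exactly 6 of 501 bands plus
Gaussian noise (sd 0.5).  Smooth leaf spectra make exact band identity
unidentifiable (neighbouring bands are near-collinear), so recovery is
benchmarked on the planted design where it is well defined.

## Problem sizes in tests and the acceptance script

Full-scale selection settings (L = 50, K = 1000, 50 replications,
100-generation GA) are the library defaults.  The test suite and
`scripts/acceptance.py` exercise the identical code paths at smoke scale —
typically L = 8–20, K = 100–200, 2–5 replications, GA populations of
16–20 over 10–20 generations — chosen as the smallest settings at which
the strategy's behaviour (planted-band recovery, null safety, end-to-end
accuracy) is stable across seeds.  All stage seeds derive from one master
seed, and identical configuration reproduces byte-identical reports.

## Known limitations

- The EDF internals (L, K, inclusion probability, top fraction) and the GA
  hyperparameters are conventions of the originating methods, not
  quantities the emulated study publishes; all are exposed in
  `SelectionConfig`.
- RMSEC ≤ RMSECV is not asserted anywhere: with small Nvar the calibration
  refit can be worse than a lucky fold split.
- The reported subset comes from a single best replication; with strongly
  collinear bands the per-replication subsets vary, and the frequency table
  is the more faithful summary of what is stable.
- The selection calibration/test split and the regression
  train/test/validation split are drawn independently, so a sample may be
  in selection-calibration and regression-validation; the selection RMSEP
  is honest, but the regression-grid metrics inherit whatever optimism
  follows from selecting bands on (a superset of) the training samples.
  The emulated design has the same property and does not state the overlap
  rule, so this risk is documented rather than silently "fixed".
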