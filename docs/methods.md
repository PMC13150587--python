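# Methods

This note records the models, numerical choices and limitations behind
`enzopt`, in the spirit of a statistics package's model documentation.
Everything quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what the code
reproduces.

## Design construction and unit coding

A 3-factor Box–Behnken design is the 12 edge midpoints of the factor
cube (all ±1 pairs over each factor pair, third factor at its center)
plus `center_points` replicated centers; generation order is
deterministic (factor pairs lexicographic, signs (−,−),(−,+),(+,−),(+,+),
centers last).  Only the 3-factor design is supported; other sizes raise
rather than extrapolate.

Coded↔actual conversion is **piecewise linear about the center level**,
not a single affine map.  The bundled experiment's binding-time levels
(6, 16, 24 h) are not equidistant, yet 16 h is the labelled center; a
single affine map would either move the center or mislabel the extremes.
The piecewise map reproduces the labelled levels exactly and is
invertible on [low, high], at the price of a kink at the center.  A
consequence worth knowing: the 10-term quadratic model space in actual
units is *not* the same function space as the 10-term model in
piecewise-coded units (actual-unit interactions acquire coded c·c²
components), so fit statistics agree between unit systems only for
affine recodings.  The property suite asserts invariance under affine
recoding and deliberately not under the piecewise coding.

## Response-surface fit and ANOVA

The full second-order polynomial (10 terms) is fitted by OLS **in actual
units**; the bundled experiment's published equation is uncoded and its
prediction column is reproduced from it.  ANOVA uses adjusted
(drop-term) sums of squares for every term and group: SS(T) =
SSE(model without T) − SSE(full).  These are computed from the
normal-equations coefficient covariance (β_g' C_gg⁻¹ β_g with
C = (X'X)⁻¹), and the tests verify them against literal refit-without-term
oracles.  Sequential SS is not implemented — for this class of design
the published group SS are only consistent with the adjusted convention.

Residual error is split into pure error (within sets of runs with
exactly equal factor levels; replicate detection is exact equality, no
tolerance) and lack-of-fit (the remainder); F(LOF) = MS(LOF)/MS(PE),
all other F ratios use the residual MS.  With no replicated runs the
lack-of-fit rows are absent rather than zero.  PRESS uses the standard
leverage shortcut Σ(eᵢ/(1−hᵢᵢ))²; a leverage of 1 raises an explicit
error rather than returning an unusable number.

One parameterization caveat, documented rather than hidden: the bundled
experiment's published per-term ANOVA rows for the three *linear* terms
derive from a symmetric affine coding of the time factor and are not
reproducible from the uncoded fit (the square and interaction rows are
identical either way, as is every overall statistic).  The package
reports uncoded adjusted SS throughout.

The constrained optimum is found by deterministic multi-start L-BFGS-B
(8 box vertices + box center + the clipped unconstrained stationary
point; `ftol` 1e−14), tie-broken first-found at 1e−8 relative tolerance.
For a quadratic over a box this recovers the global optimum; the test
suite cross-checks random surfaces against dense-grid enumeration.
Stationary points are classified by the Hessian's eigenvalue signs;
optima touching the box are classified "boundary" with per-factor flags.

## Augmentation

The augmentation reproduces a resampling-plus-noise scheme for
replicated design data: draw `target_n` observations uniformly with
replacement from the source observations, then add independent
Uniform(−w, w) noise.  The half-width rule is `w = √3·IQR/1.349`
per run (quartiles by linear interpolation): IQR/1.349 is the
normal-consistent robust SD, and the √3 factor makes the uniform
noise's SD equal it.  The published description of this procedure
("uniform noise described using the interquartile range to the standard
deviation of the replicates") does not pin down a unique rule, so the
raw-IQR half-width and a pooled spread estimate are provided as options
and the rule used is recorded in the output provenance.  Noise is
injected before splitting.

The default 80:20 split is sample-level, mirroring the described
procedure; because augmented samples sharing a source observation land
on both sides, test metrics on such a split read optimistic.  The split
records a leakage warning in its metadata, and a `group` mode (whole
runs assigned to one side) is provided for honest generalization
estimates.

## Regression benchmark

Three families, features = the three actual-unit factor levels:

| family | estimator | defaults |
|---|---|---|
| `svr-rbf` | SVR, RBF kernel, standardized features | grid C∈{1,10,100}, γ∈{½,1,2}×scale, ε∈{0.01,0.1,1}×sd(y); 5-fold seeded CV |
| `gpr-se` | GP regression, standardized features | const×RBF + white kernel, length-scale init 1.0, 5 restarts, y normalized |
| `rfr` | random forest, raw features | 100 trees, unlimited depth, bootstrap |

Every default is overridable per family and echoed into the result
provenance.  Kernel methods standardize features (scaler fitted on the
training split only); trees are scale-free and use raw features.  The
GPR's predictive SD is available from the underlying estimator but is
not used for optimization — no acquisition logic is implemented.

Skill metrics are R² and RMSE per split plus Taylor-diagram statistics
(population-SD convention; centered RMSE obeys the law-of-cosines
identity, asserted to 1e−9).  Model optima are located by dense grid
search (default 101³; ties to the lowest lexicographic coordinates),
since tree and kernel surfaces are non-smooth or expensive to
differentiate and ~10⁶ evaluations is desk-scale.

## Enzyme metrics

Deactivation is modeled as single-exponential (first-order), fitted by
unweighted least squares on (t, ln A): slope = −k_d, t½ = ln 2/k_d
(exactly — the identity is asserted on every fit), SF = t½,imm/t½,free.
Non-positive activities are excluded with a warning (their log is
undefined); fewer than 3 usable points is an error; a non-decaying
series yields k_d = 0 with an infinite-half-life flag rather than a
negative rate.  On noise-free exponential data the log-linear slope
equals the nonlinear least-squares rate (cross-checked in tests).

IE is reported as (value, "mg/g"): with V in mL, concentrations in
mg/mL and support mass in g, the natural unit is mg per g of beads, and
the unit tag is explicit because g/g conventions also circulate.
Storage-stability and reusability series are summarized as percentages
of their reference point (cycle 1 ≡ 100%); no kinetic model is fitted
to 3-point weekly series.

## Synthetic data

`simulate_bbd_dataset` draws replicate responses from a known quadratic
truth surface plus i.i.d. Gaussian noise.  Defaults are the bundled
experiment's setting: the published coefficient vector as truth, 3
replicates per run, and noise SD 37.3 U g⁻¹ = √1393, the square root of
that experiment's pure-error mean square — i.e. the replicate
variability actually observed at its center point, taken as a global
default because per-run dispersions are not published.  Replicate noise
is Gaussian even though augmentation injects uniform noise: the
generator models lab replicate error; the augmenter reproduces a
described procedure.  Negative draws are floored at 0 and counted in
`attrs["floored"]` (this slightly biases low-mean runs upward; at the
default setting the lowest run mean is ~2.6 SD above zero, so the
effect is ≲0.1 U g⁻¹).

What the generator does **not** emulate: run-to-run heteroscedasticity,
assay drift, systematic lack-of-fit beyond the quadratic, and any
dependence between replicates.  Passing recovery tests therefore show
the pipeline is correct and well-calibrated *under its own assumptions*,
not that a real immobilization campaign would behave this way.

Two calibration facts from the recovery studies (seeded, reproduced in
the test suite): each of the ten coefficients falls within 3 estimated
SE of truth in ≥95% of simulated refits, and the refit optimum puts the
cross-linker and time factors at their true lower bounds in ≈99% of
simulations — but the chitosan coordinate of the optimum scatters with
q90 ≈ 0.25 about its true value at this noise level, so point estimates
of a ridge-like optimum coordinate from a single 15-run campaign carry
real uncertainty.

A related honesty note on the ML benchmark: with replicate noise at the
center-point-derived 37.3 U g⁻¹, the augmented test responses carry
irreducible noise that caps *any* predictor's test R² at ≈0.93 (median
over seeds; the truth surface itself scores no better).  Published
benchmarks of this design reporting R² ≈ 0.985 imply substantially
smaller replicate dispersion than the center replicates suggest.  The
acceptance suite records this as a known-red expectation rather than
tuning the generator toward it.

## Problem sizes and determinism

Default analysis sizes: 15-run design, 45-observation replicate sets,
750 augmented samples, 600/150 split, 101³ optimum grids (41³ in the
multi-seed acceptance sweep, which resolves the optimum envelope 12×
over), 200–500 simulated datasets in recovery studies, 20-seed ML
sweeps.  All randomness flows through `numpy.random.default_rng`; the
CLI fans one master seed out to per-stage seeds via `SeedSequence`, and
identical seeds give bit-identical datasets, splits and reports (file
outputs are written atomically with SHA-256 digests in a manifest).

## Known limitations

* Only 3-factor Box–Behnken designs; no CCD/Plackett–Burman, no
  randomization or blocking fields.
* Single-response optimization; no desirability functions or Box–Cox.
* No neural/boosting families in the benchmark; no Bayesian
  hyperparameter search.
* The sample-level split mirrors the published procedure but leaks
  augmented siblings across the boundary (see above); use `group` mode
  when an unbiased generalization estimate matters.
* Deactivation fitting is single-phase first-order; multi-phase decay
  is out of scope.
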