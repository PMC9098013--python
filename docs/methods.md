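# Methods

This note documents the models and numerical choices behind `ridgenet`,
module by module, including the places where the design was genuinely
open and what the synthetic benchmark does and does not establish.

## Ridge data model and preprocessing (`ridge_io`)

A *ridge* is one tracked NMR feature: a chemical-shift trace and an
intensity trace on an experiment's time grid (hours, strictly increasing,
≥ 4 points). Missing cells are NaN, never zero — gaps arise when tracking
loses a peak, typically near a local baseline shift, and zero-filling
would fabricate intensity.

**Gap filling** copies the value of the nearest observed time point, ties
to the earlier point. The alternative (linear interpolation) was rejected
because leading/trailing gaps would need extrapolation; a fill mask is
retained so downstream stages can discount filled cells.

**Cross-experiment matching** pairs features of different experiments
greedily by ascending |Δ mean ppm|, never beyond 0.01 ppm for unannotated
features, each feature used at most once per experiment pair; annotated
features pair only within the same compound name (drift tolerated, since
the name, not the shift, identifies them — individual multiplet
components stay distinct through the closest-pair rule). Accepted pairs
are closed transitively. Greedy matching (not optimal assignment) is
deterministic and matches the closest-pairs semantics; ties break by
lower ppm, then lexicographic id.

**Dual-channel normalization**: the ¹³C-HSQC channel is scaled onto the
¹H channel through the pyruvate methyl signal — per time point,
f(t) = Σ(4 proton multiplet components)/HSQC peak, averaged over time
points where the peaks exceed their 10 % intensity quantile (the
low-signal tail makes the ratio unstable). Labeled/unlabeled comparison
scaling divides by the unlabeled compound's maximum, then standardizes
within each (experiment, labeling) stratum; zero-variance ridges are
flagged and excluded from variance-sensitive stages rather than failing
the pipeline.

## Penalized smoothing (`fda_smooth`)

Objective: `F(c) = ‖y − Bc‖² + λ c'Rc` with B the order-6 B-spline design
(knot at every sampling point) and R the Gram matrix of third
derivatives. Order 6 is the minimal order for which D³ of the spline is
non-degenerate (piecewise quadratic), needed because the penalty acts on
D³ so that D¹ — the rate — is itself smooth. R is assembled exactly by
3-point Gauss–Legendre quadrature per inter-knot interval (integrand is
quartic). The normal equations are solved by Cholesky; the system is
positive definite for λ > 0 because the only curves both interpolating
zero data and having zero roughness are the zero quadratic.

GCV(λ) = n·SSE/(n − df)², df = tr[B(B'B+λR)⁻¹B'] (Craven–Wahba). λ is
searched on 33 log-spaced values in [10⁻⁴, 10⁴]; ties resolve toward the
larger (smoother) λ, where "tie" includes all fits with GCV below
10⁻¹²·var(y) — noiseless polynomial data interpolates at every λ and the
remaining differences are float noise. No extrapolation outside the data
domain. Per-feature fixed-λ overrides are available (`lam=` arguments and
the `smooth --lam` CLI flag) for features whose GCV choice undersmooths.

## Functional PCA (`fpca`)

Curves are standardized (mean 0, sample sd 1 over their own time points),
smoothed, evaluated on a dense grid (4× the sampling density), and the
sample covariance of the evaluations is symmetrized with trapezoid
quadrature weights W: the eigenproblem of W^½CW^½ yields eigenfunctions
orthonormal in L², eigenvalues equal to score variances, and scores
s_ik = ∫(x_i − mean)ξ_k dt. The dense-grid route (rather than a
basis-coefficient metric) was chosen because it is directly checkable
against a brute-force weighted PCA; the agreement tolerance is ~2 % on
eigenvalues at 4× density.

Signs are fixed so each eigenfunction has a non-negative projection onto
the increasing linear trend: produced metabolites then score positive on
a "rising" component, consumed ones negative, and results are
reproducible across platforms. Retained components default to the
smallest K reaching 99 % cumulative variance. Pooled cross-condition FPCA
rescales each experiment's time axis to [0, 1] (experiment durations
differ); absolute-hours pooling is available by resampling externally.

## Correlation network (`corr_network`)

Features matched across all experiments are concatenated in sorted
experiment order (raw gap-filled intensities — rank correlation is robust
and smoothing would only launder the ranks). Spearman ρ with average-rank
ties; the largest 10 % of signed pairs become edges ("largest"
interpreted as signed, not |ρ|: multiplet components of one compound
co-vary positively; absolute-value ranking is a flag away). MCL runs on
the non-negative edge weights (negative retained correlations clipped to
0 for the transition matrix only): self-loops at each node's maximum
incident weight, column normalization, expansion (power 2), inflation
(entrywise power = granularity 5, default), pruning below 10⁻⁸, declared
converged when the iterate is idempotent within 10⁻⁸ (hard cap 200
iterations). Clusters are read off attractor rows and merged on overlap;
the result is a partition, deterministic for a fixed node order and
invariant to input order up to relabeling. Cluster reports count members
by annotation status (annotated / consistent-but-overlapped /
unannotated) and propagate a unanimous compound name.

## Kinetic network inference (`kinetic_network`)

The model class links a target's rate to feature levels:
dX_T/dt ≈ β₀ + Σ β_m·term_m, each term a single feature or a pairwise
product, at most two terms. The target's *own* level is allowed as a term
(mass-action consumption makes dX_T/dt depend on X_T; without a self-term
every candidate model is misspecified and discrimination between true and
false covariates collapses — we measured this directly on the benchmark).
Self-terms never produce edges.

**Scoring.** For every held-out environment, the model is fitted by OLS
on the pooled remaining environments' (smoothed derivative ~ smoothed
term values) samples, the fitted rate is integrated along the held-out
grid from the observed initial value (the rate does not depend on the
integrated state, so integration is cumulative quadrature on a 4×-refined
grid), and the mean squared error against the held-out smoothed
trajectory is normalized by the target's variance in that environment.
Lower is better; zero means the integrated model reproduces the held-out
trajectory. Near-zero variance targets (relative variance below 10⁻¹²)
are scored on absolute error.

**Variable significance.** Each environment ranks the models by its own
score; the top q = max(5, ⌈0.05·N⌉) of every ranking are inspected, and a
covariate's evidence is its containment count averaged over environments
— a covariate must sit near the top of *every* condition's ranking, not
dominate one. The averaged count x̄ of a covariate appearing in K of the
N models is tested against the single-ranking hypergeometric null
P[X ≥ x̄] (linearly interpolated between bracketing integers); since the
per-environment rankings share one pooled fit, this calibration is
deliberately conservative, and its false-positive rate falls as rankings
concentrate with added conditions. Rank
statistics are blind to score magnitudes, so one decisively dominant
model — the typical signature of a noiseless identifiable system — is
promoted separately: if the best model containing the covariate beats the
best model without it tenfold in every environment, the covariate is
significant (reported p = 1/N). Covariates with p < 0.05 become
undirected edges (no multiple-testing correction — deliberately liberal,
consistent with treating the network as exploratory). A classical
rank-sum comparison of containing vs non-containing model scores is
available (`ranking="ranksum"`), but bulk-rank tests are diluted by junk
partner terms and miss single-model evidence, which is why the count
statistic is the default.

**Clustering and bootstrap.** Communities by greedy modularity
maximization on the unweighted topology (deterministic, labels by
smallest member). The bootstrap resamples, per feature independently, a
complete replicate curve per environment (breaking cross-feature
replicate pairing by design), re-infers and re-clusters B = 100 times;
edge support is the containment fraction (supported at ≥ 40 %) and the
cocluster frequency matrix records how often two features share a
community.

## Benchmark simulator (`benchmark_sim`)

Ground truth graphs: n = 100 nodes, planted clusters 40/20/20, every pair
connected with probability 0.015 and same-cluster pairs additionally with
0.15 (union of draws). Each edge becomes a reaction (direction uniform,
reversible with probability 0.3, rate k ~ U(0,1)) or, with probability
0.2, a regulation: one endpoint multiplies the rate of a random reaction
incident to the other by X_r^α, α ∈ {−1, +1}; 20 % of single-reactant
reactions are merged pairwise into two-reactant reactions. The
reaction/regulation split, reversibility and merge fraction are not
dictated by the biology being emulated and are configurable; defaults are
recorded in the truth file. Concentrations are floored at 10⁻⁶ inside
rate evaluation (an α = −1 regulator at zero would blow up) and clipped
at 0 on output.

Trajectories are integrated with LSODA on the grid 0…5 step 0.2 under
per-condition U(0,1) initial values. Observation effects mirror NMR data:
per compound, N_S ~ U{1..5} redundant signals with U(0.3, 3) multipliers;
per replicate and time point, Gaussian noise with sd 0.02·σ(X) + 10⁻⁷
(σ(X) per feature per condition); exactly ⌊n/2⌋ compounds observable.
Structure (graph, kinetics, signals, mask) and per-condition initial
values come from separate seeded streams, so the condition sets are
nested (the first two of eight conditions equal a two-condition run) and
condition-count sweeps are paired on identical systems. Synthetic
chemical shifts place signal j of compound c at 10(c+1)/n + 0.001·j ppm,
exercising the feature-matching logic deterministically.

What the generator does *not* emulate: peak overlap and baseline
artifacts, pH-driven chemical-shift drift, missing cells, heteroscedastic
NMR noise, and Michaelis–Menten-type saturation. Passing benchmark
properties therefore shows the inference machinery recovers mass-action
dependency structure under noise, redundancy and partial observation —
not that it is robust to every artifact of real spectra.

## Evaluation (`evaluation`)

Edges are scored at the compound level (signal edges collapsed through
the signal map; two signals of one compound never form an edge):
precision = N_tp/N_pp (undefined when nothing is predicted), recall =
N_tp/N_cp with N_cp the true edges whose *both* endpoints are observable
— an edge touching a hidden compound is unrecoverable in principle and
is excluded from the denominator. Clusters are scored at the signal
level: for each planted cluster, the estimated cluster with the largest
overlap (ties: larger cluster, then smaller id) gives the match ratio
R = N_overlap/N_cluster. The random baseline re-draws groups of the
observed estimated-cluster sizes uniformly among observed signals
(Monte Carlo, seeded; for one group of size g the closed form is m/M).

## Problem sizes

The default test and acceptance runs use the reduced benchmark scale:
30-node networks with clusters 12/6/6, five networks per condition level,
condition counts {2, 4, 8}, three replicates — the package's standard
demonstration configuration; the full 100-node, 59-network study is a
single flag away (`ridgenet evaluate --nodes 100 --clusters 40,20,20`).

## Known limitations

- Edge significance is deliberately uncorrected for multiple testing.
- At small benchmark scales the number of recoverable true edges per
  network is in the single digits, so mean recall across condition counts
  carries substantial Monte-Carlo noise: the nominal 5 % false-positive
  budget at two conditions includes occasional lucky true pairs that a
  correctly calibrated test sheds as conditions are added, which can make
  recall dip before genuine power accumulates. Precision trends and
  cluster recovery are much more stable at this scale.
- The kinetic score assumes shared kinetics across conditions; regime
  changes (e.g., a pathway switching off) violate it.
- GCV occasionally undersmooths short noisy series; fixed-λ overrides
  exist but no automatic per-feature rule.
- The correlation-network cluster count is sensitive to the MCL dialect
  (self-loop weighting, pruning); ours is documented above.
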