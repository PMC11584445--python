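# Methods

## The microfailure process

The package models damage accumulation in a quasi-statically loaded bone
specimen as a counting process N(ε) indexed by tensile strain ε rather
than time: strain is what the loading rig controls and what digital image
correlation measures, and the physics of microcracking is driven by
deformation, not by the clock. Between the (k−1)-th and k-th microfailure
the strain increment is exponential,

    Δε_k ~ Exp(λ_k),     λ_k = λ α^(−k+1),   0 < α < 1,   λ > 0,

the exponential being the unique memoryless choice: between events the
material has a constant hazard per unit strain. Each microfailure
embrittles the material, which the geometric rate law encodes as a constant
multiplicative jump of the hazard; the per-event log-growth β = −ln α is
the deterioration rate. Two structural consequences are load-bearing for
everything downstream:

- **NBUE monotonicity.** E(Δε_k) = α^(k−1)/λ is strictly decreasing:
  expected quiet intervals shrink as damage accumulates.
- **Explosiveness.** The expected increments form a geometric series, so
  the event count diverges at the finite random strain
  ε_∞ = Σ_k Δε_k with E(ε_∞) = μ_∞ = 1/((1−α)λ) and
  Var(ε_∞) = 1/(λ²(1−α²)). The observed failure strain ε_max of a specimen
  is one realization of (approximately) ε_∞.

The doubly stochastic reading — the rate itself is a random process through
its dependence on the event count — is what motivates the "coxplosive"
name used in this field for this class of explosive Cox-type processes.

### Segment expectations and an index subtlety

The expected strain between events i and j (0 ≤ i < j ≤ ∞) is implemented
in the telescoping form

    μ_(i,j) = (α^i − α^j) / ((1−α) λ),

which is additive over abutting segments and satisfies μ_(0,∞) = μ_∞
exactly. An alternative convention with α^(j+1) in place of α^j circulates
in some formulations of this model; it is not self-consistent (it breaks
additivity and only telescopes to μ_∞ from i = 0), so it is provided only
as `mu_convention="shifted"` for comparison and is never the default.

### Simulation

`simulate` draws all increments in one vectorized pass
(Δε_k = E_k/λ_k with E_k ~ Exp(1)), which is distributionally identical to
the sequential scheme, and truncates at `max_events` (default 2000) or at
the first increment below `min_increment` (default 1e−12 strain, i.e. the
numerical explosion asymptote); the stop reason is recorded. The
sub-threshold draw is kept so the final cumulative strain sits at the
asymptote and at least one event always exists.

## Parameter estimation

Per specimen, (α, λ) minimize the expectation-matching penalty

    Φ(α,λ) = [μ_∞ − Σ_i Δε*_i]² + Σ_{k=1}^{n−1} [μ_(k,k+1) − (ε*_{k+1} − ε*_k)]²,

with the empirical increments measured from zero strain by default, so
Σ_i Δε*_i telescopes to the observed maximum strain ε*_n (configurable to
measure from the first event instead). The gap sum runs to n−1: a term for
the gap after the last observed event would reference an unobserved event.

**Optimization.** For fixed α every model term is linear in t = 1/λ, so Φ
is an exact quadratic in t with closed-form minimizer
t*(α) = (A S + Σ c_k g_k)/(A² + Σ c_k²), A = 1/(1−α). The fit therefore
profiles λ out analytically and searches only α: a dense grid (default 128
points on [1e−4, 1−1e−4]) brackets the profile minimum, bounded Brent
refinement polishes the best grid minima (default 3), and the result is
additionally guarded to be no worse than the grid optimum or a
moment-matching initializer (λ₀ = 1/Δε*_1, α₀ = 1 − 1/(λ₀ ε*_n)). The
procedure is deterministic, costs ~1 ms per specimen, and cannot be beaten
by a generic 2-D search of the same objective since the λ direction is
solved exactly.

**Statistical properties worth knowing.** The penalty is a least-squares
match of *absolute* expected increments, so its information content
saturates: beyond roughly 1/(1−α) events the increments (and their model
expectations) are vanishingly small and contribute nothing. Moreover the
first penalty term effectively equates μ̂_∞ with the single realized total
strain, whose coefficient of variation is √((1−α)/(1+α)) — about 26 % at
α = 0.85 — independent of the event count. Consequently per-fit dispersion
of λ̂ has an irreducible floor of that order and does **not** shrink as
events accumulate; only the *median over replicate fits* is a stable
recovery diagnostic (median α̂ within ~0.01, median λ̂ within ~10 % at
α = 0.85, λ = 100). The test suite asserts recovery in that median sense;
the one red test in `tests/test_acceptance.py` documents the absence of
error decay with event count rather than an implementation defect. A
direct corollary: the fitted E(ε_∞) is nearly identical to the observed
ε_max by construction, which is why their correlation across a cohort is
extreme.

**Pareto energies.** AE signal energies above the minimum energy E_m follow
P(E′ ≤ E) = 1 − (E_m/E)^ν. The tail exponent uses the Hill/ML closed form
ν̂ = n_tail / Σ ln(E_i/E_m) over energies strictly above E_m; energies at or
below the threshold are residual or friction-related and are excluded. E_m
is chosen per specimen, by default as the 5th percentile of the filtered
energies (a fixed user value is available); because Pareto exceedances over
any higher threshold are again Pareto with the same exponent, ν̂ is
insensitive to this choice. ν̂ ≤ 1 (infinite-mean regime) is legal but
flagged. A least-squares fit of the empirical log-survival curve is
available (`method="lsq"`) for comparison with graphical/spreadsheet
distribution fits, but the MLE is the default since it dominates it
statistically.

**Friction filtering.** Guard-sensor events and energies below a floor are
removed before fitting. The friction floor and the Pareto threshold are
conceptually one knob (friction events are "energy-distinguishable"), so
when a fixed E_m is configured it is also applied as the friction floor;
with the quantile method the guard channels do the work and the Pareto cut
handles the rest. No numeric threshold is hard-coded.

## The synthetic cohort generator

The generator emulates the *statistical structure* of a bending-test
cohort, not its biomechanics. Per cohort:

- Age ~ N(50.9, 10.9²) truncated to [26, 62] years and BMI ~ N(32.6, 6.2²)
  truncated to [24.2, 42.7] kg/m², independent (as in the study cohort),
  sampled by rejection (acceptance probability ≈ 0.8).
- A latent "inveteration" factor z = (z_age + z_bmi)/√2 + N(0, 0.05²)
  drives every specimen parameter: logit α = 3.6 + 0.4 z + N(0, 0.05²),
  ln λ = 7.0 + 1.1 z + N(0, 0.1²), ν = 1.9 − 0.6 z + N(0, 0.05²) floored
  at 1.05. A single factor (rather than separate age and BMI effects) is
  deliberate: the analysis stage is supposed to find one dominant
  principal component, so the generator encodes exactly one axis.
- Event strains: the explosive cascade is simulated to its numerical
  asymptote and then thinned to the events a detector can resolve — an
  event must lie at least `strain_resolution` (default 1e−6 strain) beyond
  the previously detected one. Near the asymptote gaps vanish, so detection
  terminates naturally; this is what bounds N_AE (typically 40–600 here)
  and makes ε_max sit within one resolution step of the realized ε_∞.
  Thinning, rather than stopping at the first small increment, matters: a
  single unluckily small early gap is a missed event, not the end of the
  recording.
- Energies: i.i.d. Pareto(ν, E_m = 1) on the central channel; Poisson-many
  (mean 8) friction artifacts with energies uniform on (0.05, 0.8)·E_m are
  merged in on the guard channels at strains uniform over the loading range.

**Calibration.** The linkage defaults were fixed by a one-time Monte-Carlo
grid study and then frozen. Two findings shaped them. First, fitted α̂
carries the irreducible estimation noise described above, so the cohort
mean α must be high (≈ 0.97, where the total-strain CV is small) for the
fitted parameters to reflect the latent factor. Second, the PCA consumes
*linear* correlations, so the log-scale spread of λ (and hence of ε_max)
must stay moderate — large lognormal skew destroys Pearson correlations
that the rank correlations retain. With the frozen defaults, cohorts of
n = 200 reproduce the expected eight-way correlation sign pattern
(α–age +, α–BMI +, λ–BMI +, ν–age −, ν–BMI −, N_AE–age +, ε_max–BMI −,
α–λ +) essentially always, give PC₁ variance fractions around 0.63, and
give Pearson r ≈ 0.96 between the true E(ε_∞) and the realized ε_max.

**What passing tests do and do not show.** The generator shares its event
model with the estimator, so parameter-recovery results are
within-model statements; they say nothing about misspecification (e.g.
non-geometric rate growth, strain-rate effects, sensor dead time,
localized multi-crack interactions), and the cohort-level results concern
sign patterns and factor dominance, not the correlation magnitudes of any
real cohort, which depend on the real biological spread.

## Cohort statistics

- **Spearman matrix** over (α, λ, ν, N_AE, ε_max, age, BMI) with average
  ranks for ties and two-sided p-values: t-approximation for n ≥ 10, exact
  rank-permutation enumeration below (a 15-specimen cohort uses the
  approximation; both are available). Constant columns yield NaN, never a
  silent zero. Incomplete specimens are dropped with a log message before
  analysis.
- **PCA** by eigendecomposition of the covariance of z-scored variables
  (the seven magnitudes carry incommensurate units, so correlation-matrix
  PCA is the defensible default; raw-covariance PCA is available by flag
  and errors on zero-variance columns). Components are ordered by
  descending variance with a deterministic sign convention (largest-
  magnitude loading positive).
- **PC₁ regression** on age and BMI by OLS with per-coefficient two-sided
  p-values; near-collinear designs (condition number > 1e8) are flagged
  with a warning but still reported. p-values everywhere are raw — the
  analysis reports per-cell significance, not family-wise claims.
- The report also carries both Pearson and Spearman correlation between the
  fitted E(ε_∞) and ε_max, since that comparison is conventionally quoted
  on an interval scale.

## Reproducibility and numerics

One master seed drives everything: cohort generation consumes a single
`numpy` Generator sequentially, the fit stage is deterministic, and reports
are JSON with sorted keys and shortest-round-trip floats, so a repeated run
is byte-identical (asserted in the test suite). CSV readers use
round-trip float parsing; record files reproduce every float bit-for-bit.
Degenerate inputs are defined, not accidental: empty event tables parse,
two events suffice for a (poorly constrained) fit, fewer raise an
insufficient-data error, and per-specimen failures in batch fitting are
logged and skipped rather than fatal.

Problem sizes in the shipped tests and acceptance script (20 000 simulated
cascades for the Monte-Carlo check, 700 replicate fits for recovery
medians, 100 cohorts of 200 specimens for the pipeline statistics) were
chosen so every statistic is stable to well within its asserted tolerance;
the full suite runs in under a minute on one CPU.

## Known limitations

- Only the geometric rate law is implemented; the rate function is a
  single point of extension, not a plug-in family.
- No uncertainty quantification is attached to (α̂, λ̂) beyond
  replicate-based spread; the penalty is not a likelihood, so standard
  asymptotics do not apply to it.
- The strain-indexed model ignores hold times and strain-rate effects;
  event tables must arrive with precomputed strains.
- The generator's friction model (uniform strain placement, sub-threshold
  uniform energies, guard channels only) is intentionally crude — it exists
  to exercise the exclusion logic, not to model tribology.
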