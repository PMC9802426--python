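# Methods

## The model

We consider a crowd of N pedestrians facing a binary route choice between
a straight reference path A (length L_A) and a longer detour B. The model
is time-independent: each realization is one snapshot in which the whole
crowd adopts the configuration c = (J⁽¹⁾, …, J⁽ᴺ⁾), Jᵢ ∈ {A, B}, that
minimizes the total perceived travel time

𝓛(c) = Σᵢ τ⁽ⁱ⁾_{Jᵢ}, with τ⁽ⁱ⁾_A = L_A / v⁽ⁱ⁾(N_A) and
τ⁽ⁱ⁾_B = λ_p L_A / v⁽ⁱ⁾(N_B).

Ingredients and assumptions:

- **Linear fundamental diagram.** Walking speed decays linearly in the
  occupancy of the pedestrian's own path: ⟨v(N_J)⟩ = v₀ − κ N_J. The same
  diagram is assumed on both paths. A pedestrian counts itself in N_J.
- **Velocity noise.** Each pedestrian carries one additive perturbation
  ε⁽ⁱ⁾ ~ 𝒩(0, σ_ε), drawn once per realization and applied on whichever
  path it evaluates (the noise models individual pace, not path
  conditions). Speeds are floored at v_min = 0.1 m/s so travel times stay
  positive even for pathological draws; at the default parameters the
  floor is never reached in optimal configurations.
- **Perceived length ratio.** The detour enters only through λ_p, the
  crowd-shared perceived ratio of the two path lengths, so the geometric
  ratio λ_g cancels and L_A may be set to 1 (the optimal assignment is
  invariant under rescaling L_A; costs scale linearly). λ_p is an
  exponentially modified Gaussian, λ_p = X + Y, X ~ 𝒩(μ, σ),
  Y ~ Exp(β), mean μ + β. One λ_p per realization, shared by everyone.
  Draws ≤ 0 are rejected and resampled (negligible probability at the
  default parameters); values in (0, 1) are retained — the empirical
  distribution has genuine mass below 1, and a lone pedestrian defects to
  the detour exactly when λ_p < 1.

Model variants: *deterministic* (ε ≡ 0, λ_p fixed at the EMG mean unless
overridden), *velocity_noise* (ε stochastic, λ_p fixed), *full* (both
stochastic). The fixed ratio of the non-full variants is the EMG mean —
the model's expected perception — because no other constant is singled
out by the problem.

## Solving the minimization

Γ contains 2^N configurations, but the cost structure collapses: at a
fixed split (N_A, N_B) every speed is fixed, each pedestrian contributes
either L_A/v_A⁽ⁱ⁾ or λ_p L_A/v_B⁽ⁱ⁾, and the optimal membership of B is
the N_B smallest differences δᵢ = λ_p L_A/v_B⁽ⁱ⁾ − L_A/v_A⁽ⁱ⁾. Scanning
all N+1 splits yields the exact global optimum in O(N² log N)
(`minimize_exact`, vectorized over realizations in
`minimize_split_batch`). An exhaustive enumeration
(`minimize_bruteforce`, guarded to N ≤ 20) serves as the oracle; the two
agree to 1e−9 relative cost on randomized instances, and the brute force
itself is validated against a pure-Python enumeration in the tests.

Tie-breaking is deterministic: among equal-cost configurations prefer the
larger N_A (matching the observed preference for the straight path), then
the lexicographically smallest label vector; among equal δᵢ the
highest-indexed pedestrians defect, which realizes that rule.

The noiseless fixed-ratio limit is the classical optical-length balance
L_A/v_A = L_B/(√λ v_B), giving the continuum split
N_A(N) = min{N, [κN + v₀(√λ−1)]/[κ(√λ+1)]} and the activation threshold
N\* = v₀(√λ−1)/(κ√λ) (0 for λ ≤ 1: an equal-length detour activates
immediately). The discrete optimum tracks the continuum value within one
pedestrian for N ≤ 30 across parameter grids.

## Monte Carlo ensembles

`sweep_counts` runs `m` independent realizations per global count and
aggregates P(N_B | N), mean occupancies, and the herding probability
P(N_B = 0 | N). Default sweep: N = 1..30 with m = 10⁴ realizations per
count, which puts the standard error of P(N_B = 0 | N) at or below 0.005.
Reproducibility: a base seed spawns one independent
`numpy.random.SeedSequence` child per (variant, N) via `spawn_key`, so
results are bit-stable and independent of which subset of counts is
requested.

## Synthetic data generator

`generate_frames` emulates decorrelated snapshots of the bifurcation: per
frame a global count is drawn (default: uniform on 1..25, covering both
sides of the activation threshold), routing follows the full model, and
each pedestrian's recorded speed is v₀ − κ N_J plus a fresh draw of the
velocity noise plus independent measurement noise (sd 0.05 m/s), floored
at 0.01 m/s. Frames are i.i.d. by construction — real tracking data must
be decorrelated upstream before the pipeline's independence assumptions
hold.

Two deliberate choices:

- **Recorded noise is an independent draw, not the decision draw.** The
  exact minimizer selects who defects partly on ε, so reusing the decision
  draw in the recorded speed induces a correlation between ε and own-path
  occupancy (measured at ≈0.13 covariance at default parameters) that
  biases any diagram fit (v₀ recovered ≈0.95 instead of 1.012). Treating
  the decision-relevant pace perception and the kinematic fluctuation
  captured in a single frame as independent realizations of the same
  Gaussian keeps the recorded speeds exogenous; the fit residual sd then
  equals √(σ_ε² + σ_meas²) ≈ 0.158 m/s exactly. The coupled alternative is
  a real caveat for fitting fundamental diagrams on field data where
  route choice and speed share causes.
- **Positions are cosmetic.** x/y, when requested, lie on two template
  paths sharing endpoints — a straight chord and a circular arc whose
  arc/chord ratio equals λ_g (default 1.35, the midpoint of
  trajectory-based estimates of the reference setup) — with jitter only
  transverse to path A. They support schema and geometry tests, not
  kinematic realism.

What passing tests on synthetic data do *not* show: robustness to frame
autocorrelation, tracking noise structure, social groups, or any
time-dependent choice dynamics — none of which the generator emulates.

## Empirical pipeline

All statistics condition on integer counts with no smoothing; a coarse
10-bin summary of the flow is available for error-bar style reporting.
The diagram fit is ordinary least squares of record speed on own-path
occupancy, pooled over both paths (per-path fits are available for the
equal-diagram verification); confidence intervals are the standard OLS
95% intervals. The perceived-ratio series takes one value
(v̂_B/v̂_A)² per frame with both paths occupied (frames failing the
restriction are counted and skipped), is fitted by maximum likelihood
(scipy's exponnorm, initialized from the sample skewness), and its
empirical mode is the densest Freedman–Diaconis histogram bin.
Throughput bounds assume equal cross-sections of the two paths
(flagged as an assumption on the result object):
φ_ideal(N) = v(N/2)·N and φ_unbalanced(N) = v(N)·N; the closed-form
relative gap (κN/2)/(v₀ − κN/2) stays below 20% for N ≤ 19 at the
default diagram. Herding probabilities carry 95% Wilson intervals.

## Numerical choices

- EMG density/CDF delegate to `scipy.stats.exponnorm` (shape K = β/σ);
  for K < 1e−4 the Gaussian limit is used directly, as the scipy density
  loses precision there. The density is cross-checked in the tests
  against a quadrature convolution of the normal and exponential
  densities.
- The EMG mode is found by bounded scalar maximization on
  [μ − 3σ, μ + 3(σ + β)] to 1e−9; for β ≤ 1e−8 σ it returns μ. At the
  data-fit parameters (0.77, 0.30, 0.68) the fitted EMG's mode evaluates
  to 1.09; the empirical mode of the generated ratio series is ≈1.2 —
  the two need not coincide, and the package reports both rather than
  forcing agreement.
- Degenerate inputs raise: zero-variance samples for fitting, κ = 0 for
  the continuum split (undefined), nonpositive mean speeds for the
  optical-length residual, empty datasets for the pipeline.

## Problem sizes

Default study sizes are Monte Carlo sweeps of 10⁴ realizations per count
and synthetic datasets of 5·10⁴ frames; the shared test fixture uses
2·10⁴ frames and unit tests use smaller ensembles where only structure is
being checked. These sizes keep the standard errors of every reported
probability below half a percentage point.

## Known limitations

- The model gives the activation threshold at 9 (the field value is 10)
  and understates the large-crowd herding probability
  (P(N_B = 0 | N = 20) ≈ 0.03 against ≈0.10 observed): with the default
  EMG tail, the critical perceived ratio for a completely empty detour at
  N = 20 is 2.175, an event of probability 0.054, and velocity noise can
  only lower it further since both fast and slow outliers defect more
  easily. Matching the observed herding frequency at large N would
  require a heavier perceived-ratio tail or an explicit following
  mechanism, which the time-independent functional deliberately omits.
- Two routes only; no spatial trajectories through the bifurcation; no
  sequential decision-making or temporal correlation.
- The EMG fit is plain maximum likelihood; censored or truncated fitting
  is out of scope.
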