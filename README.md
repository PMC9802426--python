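# crowdroute

Stochastic route-choice modeling and analysis for pedestrian crowds at an
asymmetric bifurcation.

When a unidirectional pedestrian flow meets a binary choice between a
straight path A and a slightly longer detour B, the observed traffic split
is far from the throughput-optimal partition: the straight path is heavily
preferred at low densities, the detour "activates" only above a critical
crowd size N\*, and even in large crowds the detour is left completely
empty surprisingly often (herding). `crowdroute` implements a variational
model of this process together with the empirical pipeline used to analyze
tracking data of such a setup, and a synthetic frame generator that stands
in for real tracking data.

## Model

A crowd of N pedestrians adopts the assignment c ∈ {A, B}^N minimizing the
crowd-level discomfort — the total *perceived* travel time

    𝓛(c) = Σᵢ τ⁽ⁱ⁾_{Jᵢ},    τ⁽ⁱ⁾_A = L_A / v⁽ⁱ⁾(N_A),
                            τ⁽ⁱ⁾_B = λ_p · L_A / v⁽ⁱ⁾(N_B),

where speeds follow a linear fundamental diagram with additive individual
noise, v⁽ⁱ⁾(N_J) = v₀ − κ N_J + ε⁽ⁱ⁾ with ε ~ 𝒩(0, σ_ε), and λ_p is the
crowd-shared *perceived* length ratio of the detour, modeled as an
exponentially modified Gaussian (EMG), λ_p = X + Y with X ~ 𝒩(μ, σ) and
Y ~ Exp(β), so E[λ_p] = μ + β. The noiseless fixed-ratio limit has a
closed-form continuum solution from the equal optical-length condition
L_A/v_A = L_B/(√λ · v_B), giving

    N_A(N) = min{ N, [κN + v₀(√λ − 1)] / [κ(√λ + 1)] }

and a detour activation threshold N\* = v₀(√λ − 1)/(κ√λ).

The minimization over all 2^N assignments is solved exactly in
O(N² log N): at a fixed split (N_A, N_B) all speeds are fixed, so the
optimal membership of the detour is the N_B smallest per-pedestrian cost
differences; an exhaustive 2^N enumeration is included as an oracle.

Reference parameters (shipped as defaults): v₀ = 1.012 m/s, κ = 0.017 m/s
per pedestrian, σ_ε = 0.15 m/s; EMG (0.77, 0.30, 0.68) fitted to observed
speed ratios (mean 1.45) and a tuned set (1.15, 0.20, 0.33) used for
simulation (mean 1.48).

## Worked example

```python
import numpy as np
import crowdroute as cr

fd = cr.FundamentalDiagram(v0=1.012, kappa=0.017)   # m/s, m/s per pedestrian
geom = cr.Geometry()

# sweep the full stochastic model over global counts N = 1..20
stats = cr.sweep_counts("full", geom, fd, cr.LAMBDA_P_TUNED,
                        range(1, 21), m=10_000, seed=1)
print("activation threshold N*:", cr.estimate_activation_threshold(stats))
print("mean detour occupancy <N_B> at N=5, 10, 20:",
      [round(float(stats.mean_n_b[n - 1]), 2) for n in (5, 10, 20)])
print("P(N_B=0 | N=20):", round(float(stats.p_empty_b[-1]), 3))

# deterministic continuum limit at the expected perceived ratio
lam = cr.emg_mean(cr.LAMBDA_P_TUNED)
print("continuum N_A at N=20, ratio", lam, "->",
      round(cr.deterministic_split(geom, fd, 20, ratio=lam), 2))

# synthetic tracking data -> empirical pipeline
manifest = cr.DatasetManifest(n_frames=50_000, seed=1)
frames = cr.generate_frames(manifest)
fit = cr.fit_local_diagram(frames)
print(f"diagram fit: v0 = {fit.v0_hat:.4f} m/s, kappa = {fit.kappa_hat:.5f},"
      f" R^2 = {fit.r_squared:.3f}")
series = cr.lambda_p_series(frames)
lam_fit = cr.fit_lambda_p(series)
print(f"perceived ratio: mean = {np.mean(series.values):.3f},"
      f" empirical mode = {lam_fit.empirical_mode:.2f}")
```

Output:

```
activation threshold N*: 9
mean detour occupancy <N_B> at N=5, 10, 20: [0.42, 1.44, 5.58]
P(N_B=0 | N=20): 0.029
continuum N_A at N=20, ratio 1.48 -> 14.84
diagram fit: v0 = 1.0123 m/s, kappa = 0.01698, R^2 = 0.219
perceived ratio: mean = 1.395, empirical mode = 1.21
```

Reading: the detour starts carrying one pedestrian on average at N\* = 9
(the continuum threshold at the expected ratio is 10.7; individual
fluctuations activate the detour slightly earlier). In a 20-person crowd
the average split is about 14.4 / 5.6 and the detour is left completely
empty in ≈3% of realizations. The pipeline applied to 50,000 synthetic
frames recovers the generating diagram (1.012, 0.017) within its
confidence intervals — the low R² reflects the large individual speed
variability around the mean trend, not a poor mean fit — and the per-frame
squared speed ratio (v̂_B/v̂_A)² reproduces the perceived-ratio
distribution with its mode near 1.2.

## Command line

```sh
crowdroute simulate --variant full --n-min 1 --n-max 30 --out-dir out/
crowdroute generate --seed 7 --out-dir out/
crowdroute analyze out/dataset.csv --out-dir out/
```

Configuration is a small TOML file (see `src/crowdroute/defaults.toml`);
every output embeds the configuration hash and seed.

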