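# Methods

## Signal model

A voxel is modeled as one or more populations of identical prolate,
axisymmetric diffusion tensors with eigenvalues D∥ ≥ D⊥, whose symmetry
axes n̂ are distributed around a mean direction μ̂ by an antipodally
symmetric Watson distribution

    W(n̂; μ̂, κ) = exp(κ (μ̂·n̂)²) / (4π M(1/2, 3/2, κ)),

where M is Kummer's confluent hypergeometric function, evaluated through
the numerically stable identity M(1/2, 3/2, κ) = (√π/2)·erfi(√κ)/√κ.
κ ≥ 0 is the concentration: κ = 1 is heavy dispersion, κ = 9 moderate,
and κ = ∞ (a sentinel value) the dispersion-free case, which
short-circuits to the pure tensor signal exp(−b ûᵀD(μ̂)û). Crossing
configurations are equal-fraction mixtures of two Watson populations
with the same tensor shape; because orientational averaging commutes
with the ODF convolution, their orientational average equals the
single-population one — a property the tests exploit.

The noise-free signal S(b, û) = ∫ W(n̂) exp(−b ûᵀD(n̂)û) dn̂ is evaluated
with a product Gauss–Legendre × uniform-azimuth spherical quadrature of
polynomial degree 47 (1152 nodes). The axisymmetric identity
ûᵀD(n̂)û = D⊥ + (D∥−D⊥)(û·n̂)² keeps the integrand a smooth function of
(û·n̂)², and the closed-form average provides an independent accuracy
check: dense-quadrature orientational means agree with it to better
than 1e-12 over the whole b grid for every κ used.

Default constants: D∥ = 1, D⊥ = 0.14 µm²/ms; μ̂ ∝ (0.4, 0.6, −0.693);
second crossing directions ∝ (−0.384, −0.576, −0.721) (90°) and
(−0.011, −0.017, −0.999) (45°); b ∈ {0, 1.5, …, 12} ms/µm² with
Δ = 43.1 ms, δ = 10.6 ms; noise σ_g ∈ {0.1414, 0.0707, 0.0283, 0.0071,
0.0014} on a unit b = 0 signal (so σ_g is 1/SNR). Gaussian noise adds
N(0, σ_g); Rician noise takes the magnitude of a complex signal with
independent N(0, σ_g) real/imaginary perturbations, producing the
familiar positive floor at low SNR.

## Sampling schemes

* *Shelled* schemes replicate one direction set over the 8 nonzero
  b-shells and carry one b = 0 sample per direction. Direction sets are
  either electrostatic-repulsion optimized (projected gradient descent
  on the antipodal Coulomb energy Σ 1/|uᵢ−uⱼ| + 1/|uᵢ+uⱼ|, step halving,
  relative-energy tolerance 1e-10, deterministic per seed) or halved
  Lebedev grids.
* *Lebedev rules* (6-, 38- and 86-point grids; degrees 3, 9, 15) are
  assembled from octahedral symmetry orbits whose parameters are
  polished at build time by least squares on the exactness equations,
  then reduced to one representative per antipodal pair with folded
  weights (valid because SDE magnitude signals are antipodally
  symmetric). Every constructed rule integrates all even spherical
  harmonics up to its degree to ~1e-15.
* *Non-shelled* schemes place n charges in the q-space ball: b-values
  uniform on (0, b_max], radii q ∝ √b, and angular positions optimized
  by the same antipodal repulsion applied to the 3D positions. This
  stand-in preserves the property under test — full 3D coverage with no
  shell structure — without reproducing any particular published 3D
  design. *Random* variants draw directions uniformly on the sphere
  (or, for the shelled random set, 43 of a 102-point repulsion set)
  and, when non-shelled, b uniformly up to b_max.
* Gradient-strength miscalibration is emulated by b → b(1 + δ),
  δ ~ U(−f, +f) per sample (f = 0.1 for a ±10% bias); shell labels are
  cleared since the data are then no longer shelled. A uniform rather
  than Gaussian perturbation was chosen; only the order of magnitude
  matters for the effect under study.

## Estimators

All shell estimators are linear in the signal. The SH, tensor and
optimal-weight methods use the real, even-degree spherical-harmonic
basis (odd degrees vanish for antipodally symmetric data); least-squares
solves use a pseudoinverse with relative cutoff 1e-10 rather than
explicit normal equations, and rank deficiency (clustered directions)
raises an error carrying the condition number. Two equivalences hold to
numerical precision and are enforced by tests: the quadratic-form trace
equals the SH estimate at L = 2, and the optimal weights with unit
harmonic-importance matrix up to order L reproduce the SH estimate at
order L (the minimum-norm weight solution realizes the SH projector).
The default harmonic-importance matrix is V = diag((1+k²/36)⁻¹) with
k_max = 18, 14, 10 for 61, 43, 19 directions; g₀ carries 1/√(4π) in its
degree-0 entry (the value an ideally isotropic unit-mass sampling
attains) and the weights are renormalized to sum to 1, to which the
weighted average is invariant anyway.

MAP-MRI uses the spherical-coordinate basis Ξ_jlm(u₀, q, q̂) =
√(4π) i^(−l) (2π²u₀²q²)^(l/2) e^(−2π²u₀²q²) L_{j−1}^{l+1/2}(4π²u₀²q²)
Y_l^m(q̂) over even l with 2j + l = N + 2, N = 0, 2, …, n_max (50
coefficients at n_max = 6, 95 at n_max = 8). For even l the phase
i^(−l) is the real sign (−1)^(l/2). Conventions:

* **q ↔ b mapping.** q = √(b/τ)/(2π) with τ = Δ − δ/3, chosen so that
  e^(−2π²u₀²q²) = e^(−b·MD) when u₀² = 2·MD·τ: the single-term fit is
  then *exact* for isotropic Gaussian diffusion. Published wavevector
  conventions differ in 2π factors; since the data-driven scale u₀
  absorbs any such constant, the choice is observationally irrelevant
  and this one makes the Gaussian case exact.
* **Scale estimation.** u₀ = √(2·MD·τ) with MD from a log-linear tensor
  fit restricted to b ≤ 3 ms/µm². The fit is signal-weighted (weights
  Sᵢ — the first-order variance correction for log-transformed noisy
  magnitudes): unweighted log-linear fits are dominated by the clipping
  floor of near-zero samples at the highest noise level, biasing MD up
  by tens of percent and destabilizing u₀, while the weighted fit is
  exact on noise-free data and keeps the scale stable at low SNR. u₀ is
  re-estimated from each noisy realization (as a per-voxel pipeline
  would).
* **Propagator dual.** The displacement-space (EAP) dual of the basis
  follows from the harmonic-oscillator eigenfunction property of the
  basis under the 3D Fourier transform: Ψ_jlm(r) =
  (−1)^(j−1) (2π)^(−3/2) u₀^(−3) √(4π) t^(l/2) e^(−t)
  L_{j−1}^{l+1/2}(2t) Y_l^m(r̂), t = r²/(2u₀²). The pair is verified
  numerically (Hankel transform) to 1e-6 in the tests before the
  constrained mode relies on it. The basis is orthogonal but not
  orthonormal under 4πq²dq: ‖Ξ_j00‖² = Γ(j+1/2)/((j−1)!·4π²u₀³), a
  relation the tests check against numerical quadrature.
* **Fit modes.** `ls` is a pseudoinverse least-squares fit (requires at
  least as many samples as coefficients). `constrained` (MAP) imposes
  propagator nonnegativity on a grid of 50 radii (0.02…1)×5u₀ crossed
  with the 43-pair Lebedev directions, solved as a dual
  bound-constrained QP over the Lagrange multipliers (L-BFGS-B with a
  working set of violated constraints); a positivity margin of 1e-7
  relative to the constraint scale keeps the recovered primal strictly
  feasible. `laplacian` (MAPL) minimizes ‖Ac − s‖² + λ cᵀRc where R is
  the Gram matrix of the q-space Laplacian of the basis, computed via
  Plancherel as 16π⁴ ∫ r⁴ Ψ_a Ψ_b d³r (block-diagonal in (l, m),
  radial factors by Gauss–Legendre quadrature). λ is selected by
  generalized cross-validation over a 13-point logarithmic grid spanning
  1e-5…1e1 relative to mean diag(AᵀA)/mean diag(R).
* Signals are normalized by the mean b = 0 value before fitting; the
  powder average S̄(b) = Σ_N c_{(1+N/2)00} Ξ_{(1+N/2)00}(u₀, q(b)) can be
  queried at arbitrary b, including between and beyond the acquired
  shells.

## Evaluation harness

For each noise realization, dispersion level and noise level, an
independent random stream is derived from the master seed via spawn keys
(realization, κ-index, σ-index), so adding or removing methods never
perturbs the noise draws and all methods see identical data (a
variance-reduction choice for the method comparison). d₁ averages
|S̄_est − S̄_gt| over the 8 nonzero b-shells and 3 κ values (b = 0 is
used only for normalization); d₂ is the Pearson correlation between b
and the κ-averaged signed bias, with the zero-variance case mapped to 0
(a constant bias has no b-dependent trend). Experiments use 100 noise
realizations per cell unless stated otherwise.

Normality of the averaged signal across realizations is screened with a
composite Anderson–Darling test (mean and variance estimated): the
order-statistic A² with the small-sample correction
A*² = A²(1 + 0.75/n + 2.25/n²) and the standard case-3 p-value
approximation. Its type-I error calibrates to 5% ± 2% in simulation and
it agrees with an independent implementation to 1e-10. Because all shell
estimators are linear, their Gaussian-noise averages are exactly
Gaussian and the screen's rejections are pure type-I events; the
normality check therefore pools the (b, κ) grid over all five noise
levels and the five shell estimators to give the acceptance-rate
estimate enough effectively independent cells.

## Problem sizes

Default experiment cells use 100 realizations on the 344-sample (43×8)
scheme; the monotonicity-in-noise check uses 25 realizations on the
488-sample scheme; Monte-Carlo noise-model checks use 1e6 draws; the
Anderson–Darling calibration uses 1000 repetitions of n = 100. These
sizes make every Monte-Carlo margin in the tests several standard errors
wide.

## What the generator does and does not emulate

The synthetic data reproduce the study conditions exactly: Watson (or
two-Watson crossing) axisymmetric tensor signals, the 8-shell protocol,
Gaussian/Rician noise at the five stated levels, shelled/non-shelled/
random/b-perturbed sampling. They do **not** emulate multi-compartment
exchange, non-Gaussian compartment kinetics, gradient-waveform effects
(only b, Δ, δ enter), spatial structure, motion/eddy artifacts, or the
scanner-specific preprocessing a real acquisition would need. Passing
tests therefore demonstrate estimator correctness and the noise
phenomenology of the model, not end-to-end fidelity on scanner data.

## Known limitations and observed behaviour

* The positivity-constrained MAP fit at n_max = 8 on *dispersion-free*
  (κ = ∞) noise-free data carries an irreducible bias: the truncated
  representation of a stick propagator goes negative, and constraining
  it inflates the high-b isotropic tail to a max per-shell error of
  ~1.0e-2 (κ = 1: 2.8e-4, κ = 9: 1.1e-3). This is a property of the
  constrained optimum (verified at the KKT point), not of the solver.
* GCV occasionally under-regularizes at very low noise; this is
  harmless there (the unregularized fit is already accurate).
* Lebedev averaging requires samples exactly at quadrature nodes and is
  inapplicable to repulsion-optimized or perturbed schemes — mirroring
  its practical limitation.
* The 3D non-shelled scheme is a repulsion-based stand-in with uniform
  b coverage, not a reimplementation of any specific published q-space
  design tool.
* Optional volumetric (4D image) processing is out of scope; the
  estimator API operates on per-sample signal vectors, and a voxel loop
  is the caller's responsibility.
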