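# powderavg

Estimation of the **orientationally-averaged ("powder-averaged")
diffusion-weighted MRI signal**, with a full simulation harness for
comparing estimators under controlled noise.

Many microstructure analyses work with the direction-averaged signal
S̄(b) — the mean of the diffusion-weighted signal over all gradient
directions at a fixed b-value — because it factors out macroscopic fiber
orientation and anisotropy. In practice S̄ must be estimated from a
finite set of gradient samples that may be unevenly spread over the
sphere, may not lie on clean b-shells at all (3D q-space schemes,
gradient-strength miscalibration), and are corrupted by Gaussian or
Rician measurement noise. This package implements and compares the
standard families of estimators:

* **shell-by-shell** — arithmetic mean; Lebedev quadrature weights;
  the isotropic (degree-0) term of a spherical-harmonic (SH)
  least-squares fit, S̄ = a₀/√(4π); the trace of a Cartesian quadratic
  form fit S(û) = ûᵀMû, S̄ = Tr(M)/3; and optimal weights w₀ =
  argmin (Bw − g₀)ᵀV(Bw − g₀) that make the weighted sampling function
  as rotationally invariant as possible, with V = diag((1 + k²/36)⁻¹);
* **whole-q-space** — the MAP-MRI representation in spherical
  coordinates, S(q, q̂) = Σ c_jlm Ξ_jlm(u₀, q, q̂) with Laguerre-radial ×
  spherical-harmonic basis functions, fitted by plain least squares,
  with propagator-positivity constraints (MAP), or with Laplacian
  regularization and GCV-selected penalty (MAPL); its l = 0 part is a
  *continuous* powder average S̄(b), valid off-shell.

The simulator generates signals from Watson-dispersed axisymmetric
tensor compartments (concentration κ; κ = ∞ is the dispersion-free
case), for which the exact orientational average has the closed form

    S̄_gt(b) = (√π/2) · e^(−b·D⊥) · erf(√(b(D∥−D⊥))) / √(b(D∥−D⊥)),

independent of the orientation distribution — the gold standard every
estimator is scored against via

* **d₁** — mean absolute deviation over the (b, κ) grid,
* **d₂** — Pearson correlation between b and the mean signed bias.

## Worked example

```python
import numpy as np
from powderavg import (build_scheme, simulate_signal, add_noise, TissueModel,
                       average_all_shells, ground_truth_average, MapMriModel)

scheme = build_scheme("shelled_lebedev", 43)          # 43 dirs x 8 shells + 43 b=0
model  = TissueModel.single(kappa=9.0)                # dispersed fibers
signal = add_noise(simulate_signal(scheme, model), 0.0283, "rician", seed=7)

b  = np.array([1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0])
gt = ground_truth_average(b)
arith = average_all_shells(scheme, signal, "arithmetic")
fit   = MapMriModel(signal, scheme, n_max=6).fit("laplacian")
```

prints (per-shell estimates vs the closed form):

```
    b  closed form  arithmetic   lebedev    mapl
  1.5       0.5640      0.5713    0.5713  0.5716
  3.0       0.3541      0.3543    0.3544  0.3533
  4.5       0.2386      0.2387    0.2388  0.2401
  6.0       0.1682      0.1777    0.1778  0.1760
  7.5       0.1221      0.1274    0.1275  0.1343
  9.0       0.0903      0.1038    0.1038  0.1035
 10.5       0.0678      0.0808    0.0809  0.0791
 12.0       0.0514      0.0640    0.0640  0.0594
```

The uncorrected Rician noise floor inflates every estimate above the
ground truth, and the bias grows with b (this is the positive d₂
signature of magnitude data at low SNR). `fit.summary()` reports the fit
diagnostics — basis scale u₀ = 5.61 µm estimated from the low-b data,
GCV-selected λ, residual norm and the leading isotropic coefficients.

A command-line surface wraps the same functionality:

```bash
powderavg scheme --kind shelled_lebedev --n 43 --out-csv scheme.csv
powderavg simulate --scheme-csv scheme.csv --kappa 9 --sigma 0.0283 --out sig.csv
powderavg average --signals-csv sig.csv --method lebedev --out avg.csv
powderavg mapfit --signals-csv sig.csv --method mapl --nmax 6 --out mapl.csv
powderavg reproduce --figure 2b --out-dir out/   # one experiment row
powderavg fixtures --out-dir fixtures/           # full synthetic data tree
```

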