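# ermspec

Euclidean-random-matrix (ERM) theory of neural covariance: why the
eigenvalue spectrum of large-scale neural activity barely changes when
you record ten times fewer neurons, and when that scale invariance
breaks.

Whole-brain recordings show that the covariance eigenspectrum, plotted
as eigenvalue against normalized rank `q = r/N`, nearly collapses onto a
single curve as the number of sampled neurons shrinks. `ermspec` models
the covariance as an ERM: neurons are random points in a latent
d-dimensional *functional space*, and correlation decays with functional
distance through a kernel with `f(0) = 1`,

    C_ij = σ_i σ_j f(‖x_i − x_j‖),
    f(u) = ε^μ (ε² + u²)^(−μ/2)   (≈ (ε/u)^μ for u ≫ ε).

For density `ρ = N/L^d`, the high-density spectrum is the closed form
`λ(q) = ρ E(σ²) f̃(k*)` on level sets of the kernel's Fourier transform,
which for large eigenvalues is the power law

    λ ~ (r/N)^(−1+μ/d) ρ^(μ/d),

so random subsampling (which only lowers ρ) leaves the spectrum
invariant exactly when `μ/d → 0`: slowly decaying correlations in a
high-dimensional functional space. At the intermediate densities that
fit real data the package solves the Gaussian-variational resolvent
self-consistency instead and converts densities to rank plots.

Around that core the package provides:

- **Sampling schemes** — random (RSap), anatomical slabs (ASap), and
  functional clustering (FSap, greedy most-correlated pairing); the
  **collapse index** (CI), the normalized log-log area between spectra
  at two sample sizes, computed from matrices and predicted from theory;
- **Dimensionality** — the participation ratio
  `D_PR = (Σλ)²/Σλ²`, its moment form, its large-N limit
  `E(σ²)²/E_{i≠j}(C_ij²)`, and per-scheme predictions including the
  anatomical interpolation
  `D_PR^ASap ≈ (1 − R² + k²R²)^(μ/d) D_PR`;
- **Null models** — Wishart (Marchenko–Pastur), eigenvector-randomized
  surrogates, and linear-rate recurrent-network covariances;
- **Fitting** — estimate `(μ, (ε/L)^d, ρε^d, σ² distribution)` from the
  pairwise-correlation histogram, then embed neurons into functional
  space by SMACOF multidimensional scaling under the Sammon stress;
- **CCA** — canonical correlation between anatomical and functional
  coordinates, a synthetic joint-coordinate generator with planted
  `R_CCA`, and a permutation significance test.

## Worked example

```python
import numpy as np
import ermspec as es

kernel = es.KernelSpec(variant="tpdf", mu=0.5, epsilon=0.03125)
space = es.FunctionalSpace(d=2, L=10.0, N=1024)   # rho = 10.24
erm = es.make_erm(space, kernel, es.VarianceModel(kind="unit"), seed=0)

lam = np.linalg.eigvalsh(erm.C)
print("D_PR =", round(es.dpr(np.clip(lam, 0, None)), 1))

ci = es.collapse_index(erm.C, n_repeats=20, seed=0)
print(f"CI = {ci.value:.3f}  (window q1={ci.q1:.3f} -> q0={ci.q0})")

fit = es.fit_kernel_params(erm.C, d=2)
print(f"fitted mu = {fit.mu:.3f}, rho*eps^d = {fit.rho_eps_d:.4f}")

ci_f = es.collapse_index(erm.C, scheme="fsap", seed=0)
print(f"CI under functional sampling = {ci_f.value:.3f}")
```

prints

```
D_PR = 98.6
CI = 0.087  (window q1=0.209 -> q0=0.01)
fitted mu = 0.525, rho*eps^d = 0.0123
CI under functional sampling = 0.039
```

Reading: this 1024-neuron ERM realization has an effective
dimensionality of ~99; random half-sampling shifts its spectrum by a
normalized area of 0.087 (small = nearly scale-invariant; a pure-noise
Wishart matrix of recording size scores ~0.20), and functional sampling
— which preserves the density in functional space — collapses it twice
as well. The fit recovers the generating kernel exponent `μ = 0.5`
within 5% and the dimensionless density `ρε^d = 0.01` within 25%, and
`ρε^d ≪ 1` correctly places the matrix in the intermediate-density
regime.

A command-line interface mirrors the library:

```sh
ermspec simulate -N 1024 -d 2 -L 10 --seed 1 -o erm.h5
ermspec ci erm.h5 --n-repeats 20
ermspec fit erm.h5
ermspec null --model wishart -N 1024 -T 7200 -o wishart.h5
```

Every command writes a JSON manifest with its full configuration and
seeds. See `docs/methods.md` for the model, solver details, parameter
conventions, and limitations.

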