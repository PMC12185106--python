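# Methods

`ermspec` models the covariance matrix of a large neural population as a
Euclidean random matrix (ERM): neurons are random points
`x_1 … x_N` in a latent d-dimensional *functional space* (a box
`[0, L]^d`), pairwise correlation decays with functional distance through
a kernel `f`, and per-neuron activity variances scale the result,

    C_ij = sigma_i sigma_j f(||x_i − x_j||),      f(0) = 1.

The package asks when the eigenvalue spectrum of `C` — and therefore the
geometry of population activity — is invariant under subsampling of
neurons, and provides the analytics, sampling machinery, metrics and
fitting tools around that question.

## Kernel family

The default kernel is the approximate power law

    f(u) = eps^mu (eps^2 + u^2)^(−mu/2),

which behaves as `(eps/u)^mu` for `u >> eps` and saturates smoothly at 1.
`mu` (dimensionless, default 0.5) sets the decay of correlation with
functional distance; `eps` (default 0.03125) is a resolution length that
regularizes the origin. `eps` and `L` are redundant up to a joint change
of units, so `eps` is pinned by convention and `L` carries the scale.
This kernel is *not integrable* over `R^d` when `mu < d`; its Fourier
transform

    f~(k) = 2^((d−mu+2)/2) pi^(d/2) k^((mu−d)/2) eps^((mu+d)/2)
            K_((d−mu)/2)(k eps) / Gamma(mu/2)

(`K` the modified Bessel function of the second kind) diverges as
`k → 0`, which is what permits a power-law covariance spectrum; it is
strictly positive, so every realized `C` is positive semidefinite
(Bochner). Shape variants near the origin (flat top, tangent, tent,
parabola caps) and non-power-law kernels (stretched exponential,
gaussian, exponential) exist for robustness checks. For the capped
variants the junction multiplier is *derived* from continuity with
`f(0) = 1` plus the cap's derivative condition — the three constraints
leave no freedom — giving junction distances `(1+mu)^(1/mu) eps`
(tangent), `(1+mu/2)^(1/mu) eps` (parabola), and, with the tent slope
fixed at twice the local power-law derivative (a documented choice),
`(1+2mu)^(1/mu) eps` (tent).

Non-tpdf Fourier transforms use the radially symmetric reduction to a
one-dimensional Hankel-type integral, split at Bessel-function zeros with
Euler acceleration of the alternating tail; the closed form agrees with
this quadrature to ~1e−9 relative over `mu ∈ [0.5, 1.3]`, `d ∈ {1,2,3}`,
`k ∈ [1e−2, 1e2]`.

## Spectral theory

The density of neurons in functional space, `rho = N/L^d`, is the order
parameter. Two regimes:

**High density** (`rho eps^d >> 1`): eigenvalues localize on level sets
of the kernel transform, giving the closed-form rank plot

    lambda(q) = rho E(sigma^2) f~(k*),
    k* = ((2 pi)^d rho q / v_d)^(1/d),

with `q = rank/N` and `v_d` the unit-ball volume. In the asymptotic range
`k* eps << 1` this is the power law
`lambda ~ q^(−(1−mu/d)) rho^(mu/d)`; subsampling only changes `rho`, so
the spectrum collapses across scales exactly when `mu/d → 0`. Note the
power-law *exponent* is reached only deep in that range — at, say,
`d = 1`, `rho = 256`, `eps = 0.03125`, the measurable slope around
`q ~ 1e−2` is closer to −1 because the Bessel-K cutoff is already felt —
so slope checks are run where `k* eps ≤ 0.02`.

**Intermediate density** (`rho eps^d ≲ 1`, the regime that fits data):
the resolvent `g(z)` follows the Gaussian-variational self-consistency

    g(z) = < 1/(z − sigma^2 G) >_sigma,
    1/f~(k) = 1/G~(k, z) + < rho sigma^2/(z − sigma^2 G) >_sigma,
    G = ∫ d^d k/(2 pi)^d G~(k, z),

solved per eigenvalue by damped fixed-point iteration (damping 0.5,
tolerance 1e−8 on `G`, warm start along the descending eigenvalue grid)
at `z = lambda + i eta` for `eta ∈ {1e−2, 3e−3, 1e−3}`, with linear
extrapolation of `Im g` to `eta → 0+`; the density is then
`p(lambda) = −Im g/pi` (Sokhotski–Plemelj). The k-integral uses ~600
log-spaced radial nodes truncated where `rho E(sigma^2) f~(k)` falls
below 1e−4 of the smallest eigenvalue of interest (the transform decays
exponentially there); variance averages use 32-node Gauss–Hermite
quadrature on the lognormal's log scale.

Converting a density to a rank plot integrates the complementary cdf
from an *anchor* `(q_s, lambda(q_s))` taken from simulation with the
three-rank log-log smoothing of the leading eigenvalues; the anchor only
fixes the integration constant, so the curve extends above it as well.
The first few eigenvalues of a realized ERM exceed the bulk theory — an
expected consequence of kernel non-integrability, not a boundary
artifact (periodic wrapping does not remove it) — which is why
comparisons to theory conventionally set aside the top few ranks.
Accuracy against averaged diagonalization (ranks 5–100, N = 1024): the
variational solver is within 10% at both `rho = 10.24` and `rho = 256`;
the closed form is within 10% beyond rank 10 at `rho = 256`.

## Sampling schemes and the collapse index

Three block hierarchies halve a covariance matrix `n` times (level `n`
has `2^n` equal blocks): **RSap** (random subsets), **ASap** (contiguous
slabs along an anatomical axis, anterior–posterior by default) and
**FSap** (functional clusters built by round-based greedy pairing: every
round merges the available cluster pairs with the highest mean pairwise
correlation, doubling cluster size — a renormalization-group-style
agglomeration requiring power-of-two N; against an oracle that bisects
the true functional coordinates it yields nearly identical collapse
statistics). Block spectra are sorted and averaged rank-wise per level.

The **collapse index** between the full matrix (`N_0`, trace-normalized)
and its half-samples (`N_s = N_0/2`, averaged over 20 halvings for
simulations, both blocks of each halving) is the normalized log-log area

    CI = 1/log(q_0/q_1) ∫ |d log lambda / d log rho| d log q,

with `d log lambda/d log rho ≈ |Δ log lambda(q)| / log 2` by finite
difference at `q = i/N_s` (the full spectrum log-log-interpolated onto
that grid), integrated by trapezoid — with the integrand interpolated at
the exact window endpoints — from `q_1` (the largest q with
`lambda ≥ 1`, the spectral mean after trace normalization) down to
`q_0 = 0.01`. CI = 0 means perfect collapse. A theoretical CI follows
from the variational `q(lambda)` at `rho` and `rho/2` via implicit
differentiation, each density anchored by its own simulated spectrum
(full and half-sampled; a shared anchor forces the curves to agree at
the anchor and underestimates CI by ~40%), finite-differenced on 20
eigenvalue nodes and cubic-spline integrated; it matches the sampled-
matrix CI within 20%.

## Dimensionality

The participation ratio `D_PR = (Σ lambda)² / Σ lambda²` has the moment
form `N² E(sigma²)² / [N E(sigma⁴) + N(N−1) E_{i≠j}(C_ij²)]` and the
large-N limit `E(sigma²)²/E_{i≠j}(C_ij²)`. Under RSap the moments are
N-independent, so dimensionality follows the moment curve and saturates;
under FSap the mean squared covariance inside blocks grows as
`k^(−2mu/d)` with sampled fraction `k`, giving
`D_PR^FSap ≈ k^(2mu/d) D_PR`; under ASap an anatomical–functional
correlation `R` interpolates through the effective functional fraction
`k_f = sqrt(1 − R² + k² R²)`, recovering RSap at `R = 0` and FSap at
`R = 1`. `mu/d` itself is estimable from the FSap hierarchy (slope of
`log E^k(C²)` vs `log k` is `−2 mu/d`).

## Null models

Scale-variant references for CI: a Wishart matrix from i.i.d. Gaussian
activity (Marchenko–Pastur spectrum, verified by KS distance < 0.02); a
surrogate with exact eigenvalues but Haar-random eigenvectors (sign-fixed
QR), which raises CI of a data-like ERM (intermediate density, lognormal
variances) from ~0.03 to ~0.17 — the collapse lives in the eigenvector
geometry, while for unit-variance power-law ERMs randomization barely
changes CI; and the covariance of a randomly connected linear-rate
network (`J_ij ~ N(0, g²/N)`). For the network, two standard covariances
exist and both are exposed: the stationary covariance of the
noise-driven dynamics `dx/dt = −x + Jx + xi` (Lyapunov solution; the
default, `mode="dynamical"`), and the long-time-window form
`(I−J)^{-1}(I−J^T)^{-1}` (`mode="static"`), which near criticality
(`g → 1`) carries the `lambda ∝ (r/N)^{−3/2}` rank-plot law with the
`k^{−1/2}` subsampling shift. The dynamical form reproduces the
reference collapse-index values for this model class; the static form
reproduces the near-critical spectral laws.

## Fitting and embedding

From a measured covariance, correlations `R_ij` follow
`h(R) ∝ R^(−(mu+d)/mu)` on the large-correlation branch, so a linear
least-squares fit of `log h(R)` vs `log R` (30 log-spaced bins) gives
`mu` from the slope and `(eps/L)^d` from the intercept; the dimensionless
`rho eps^d = N (eps/L)^d` then selects the spectral regime. The fit
window `[f(L/4), f(2 eps)]` — iterated to self-consistency from a
provisional `[0.01, 0.95]` — was calibrated on simulations with known
parameters: including pairs beyond `~L/4` biases the slope through
box-geometry corrections to the pair-distance density, and correlations
above `f(2 eps)` sit in the kernel's smoothing region. On the reference
ERM (true `mu = 0.5`, `rho eps^d = 0.01`) recovery is `mu = 0.52 ± 0.01`
and `rho eps^d` within 35%. `d` defaults to 2 for fitting and embedding;
variances are fitted lognormal by maximum likelihood on `log C_ii`.

Embedding inverts the kernel on `|R_ij|` (absolute value: the few
negative correlations have no defined distance) with a logarithmic soft
cut-off beyond the box size, `u* = L log(f^{-1}(|R|)/L) + L` for
`|R| < f(L)`, capped at `10 L`, and minimizes the Sammon stress
(weights `1/u*`) by weighted-SMACOF majorization from a classical-MDS
start; stress is non-increasing per iteration and iteration stops at a
relative stress change below 1e−4 (1e−6 for round-trip tests).
Rebuilding the covariance from the embedded coordinates and fitted
kernel reproduces random-sampling spectra within ~10% (ranks 5–100).

## Synthetic data and its limits

All experiments run on internally generated data: ERM realizations
(uniform box coordinates by default; gaussian/lognormal coordinate
densities matched through the self-overlap integral `∫p² = 1/L^d`),
Gaussian activity with prescribed covariance, and jointly Gaussian
anatomical (3-d) + functional (2-d) coordinates with a planted first
canonical correlation `R_CCA` on the leading axes (variances (1,1,1) and
(2,1)). The scheme-ordering experiments map the functional marginals
onto the uniform box (rank-preserving Gaussian-cdf transform) so the ERM
sits at the data-like density `rho ~ 10` where random sampling is not
already collapse-trivial.

What the generator does *not* emulate: calcium-imaging noise and
deconvolution artifacts, sparse nonnegative activity (the
mean-over-nonzero-frames normalization is exposed but fixtures are
Gaussian), negative covariances beyond small perturbations, non-uniform
cluster structure in functional space, and curved functional geometries.
Passing tests therefore validate the theory and estimators on the model
class, not the preprocessing of real recordings.

## Numerical conventions

Trace normalization `Tr(C)/N = 1` precedes every CI computation (CI is
scale-invariant by construction). Eigenvalues come from `eigvalsh`;
negative round-off eigenvalues are clipped at zero where positivity is
assumed. `q_1` ties (noisy spectra crossing 1 several times) resolve to
the largest-q crossing. Degenerate inputs raise: all-zero traces under
nonzero-frame normalization (with the neuron index), non-PSD covariance
for activity simulation (with the offending eigenvalue), spectra that
never cross 1 (CI undefined), non-converged fixed points (with the last
residual). Reference problem sizes used throughout the test suite:
N = 1024 matrices (N = 4096 only for the near-critical network laws),
20–30 realizations for averaged spectra, 10–20 halvings per CI; these
sizes put every averaged comparison well inside its stated tolerance.
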