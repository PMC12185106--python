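"""Fitting the Euclidean-random-matrix model to a covariance matrix.

The estimation route runs: correlation histogram -> kernel parameters ->
pairwise functional distances -> multidimensional-scaling embedding.

For the approximate power-law kernel, the density of large pairwise
correlations obeys

    log h(R) = log(eps^d Int p^2) + log(2 pi^(d/2) / (Gamma(d/2) mu))
               - ((mu + d)/mu) log R,

so a linear least-squares fit of log h(R) against log R on the
large-correlation branch yields mu from the slope and (eps/L)^d from the
intercept (for uniform coordinates Int p^2 = 1/L^d); the dimensionless
density rho eps^d = N (eps/L)^d then decides between the high-density and
intermediate-density spectral theories.

Embedding inverts the kernel on |R_ij| to target distances (with a
logarithmic soft cut-off beyond the box size, where small correlations
carry little metric information) and minimizes the Sammon stress

    E = (1/sum u*_ij) sum (u*_ij - u_ij)^2 / u*_ij

with the weighted SMACOF majorization algorithm, initialized by classical
MDS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .kernels import KernelSpec, kernel_eval, kernel_inverse

#: resolution length fixed by convention; epsilon and L are redundant up to
#: a joint rescaling of the functional-space unit, so one of them is pinned.
DEFAULT_EPSILON = 0.03125


@dataclass
class FitResult:
    """Estimated ERM parameters and histogram-fit diagnostics."""

    mu: float
    eps_over_L_pow_d: float
    L: float
    rho_eps_d: float
    sigma2_log_mean: float
    sigma2_log_sd: float
    d_used: int
    epsilon_used: float
    slope: float
    intercept: float
    r_squared: float

    def kernel(self) -> KernelSpec:
        return KernelSpec(variant="tpdf", mu=self.mu, epsilon=self.epsilon_used)


@dataclass
class Embedding:
    """MDS result: functional coordinates and the final Sammon stress."""

    coords: np.ndarray
    stress: float
    converged: bool
    n_iter: int


def _correlations(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C = np.asarray(C, dtype=float)
    diag = np.diag(C)
    if np.any(diag <= 0):
        raise ValueError("C must have positive diagonal")
    s = np.sqrt(diag)
    R = C / np.outer(s, s)
    iu = np.triu_indices_from(R, k=1)
    return R, R[iu]


def _hist_fit(Rvals: np.ndarray, d: int, lo: float, hi: float,
              n_bins: int = 30) -> tuple[float, float, float]:
    """Least-squares line through log h(R) vs log R on log-spaced bins."""
    pos = Rvals[(Rvals >= lo) & (Rvals <= hi)]
    if len(pos) < 50:
        raise ValueError(
            f"only {len(pos)} positive correlations in [{lo:.3g}, {hi:.3g}]; "
            "too few for a histogram fit")
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    counts, _ = np.histogram(pos, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / widths / len(Rvals)
    keep = dens > 0
    if keep.sum() < 5:
        raise ValueError("too few occupied histogram bins")
    x, y = np.log(centers[keep]), np.log(dens[keep])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - yhat) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def fit_kernel_params(C: np.ndarray, d: int = 2,
                      epsilon: float = DEFAULT_EPSILON) -> FitResult:
    """Estimate (mu, (eps/L)^d, L, rho eps^d) from pairwise correlations.

    The histogram is fitted on the branch where the pure power law
    R ~ (eps/u)^mu actually holds: the window [f(L/4), f(2 eps)] excludes
    box-geometry-affected small correlations below (the pair-distance
    density falls away from the S_{d-1}(u) Int p^2 form once u is a
    sizeable fraction of the box, biasing the slope) and the kernel's
    smoothing region (u < 2 eps) above.  The window limits were
    calibrated on simulated ERMs with known parameters.  Since the window
    depends on the unknown (mu, L), the fit starts from a provisional
    window [0.01, 0.95] and is iterated to self-consistency.  Per-neuron
    variances are fitted by a lognormal maximum likelihood (Gaussian MLE
    of log sigma^2).
    """
    from scipy.special import gamma as gamma_fn

    C = np.asarray(C, dtype=float)
    N = C.shape[0]
    _, Rvals = _correlations(C)

    def params_from_line(slope, intercept):
        if slope >= 0:
            raise ValueError(
                f"histogram slope {slope:.3g} is non-negative; correlations "
                "do not follow a decaying power law")
        mu = -d / (1.0 + slope)
        if mu <= 0:
            raise ValueError(
                f"slope {slope:.3g} implies non-positive mu; fit failed")
        geom = 2.0 * np.pi ** (d / 2.0) / (gamma_fn(d / 2.0) * mu)
        eps_over_L_d = np.exp(intercept) / geom
        L = epsilon / eps_over_L_d ** (1.0 / d)
        return mu, eps_over_L_d, L

    lo, hi = 0.01, 0.95
    slope, intercept, r2 = _hist_fit(Rvals, d, lo, hi)
    mu, eld, L = params_from_line(slope, intercept)
    for _ in range(3):
        kern = KernelSpec("tpdf", mu, epsilon)
        lo_new = max(float(kernel_eval(kern, L / 4.0)), 0.01)
        hi_new = min(float(kernel_eval(kern, 2.0 * epsilon)), 0.95)
        if hi_new <= lo_new * 2.0:
            break  # degenerate window; keep the previous fit
        lo, hi = lo_new, hi_new
        slope, intercept, r2 = _hist_fit(Rvals, d, lo, hi)
        mu, eld, L = params_from_line(slope, intercept)

    logs2 = np.log(np.diag(C))
    return FitResult(mu=mu, eps_over_L_pow_d=eld, L=L,
                     rho_eps_d=N * eld,
                     sigma2_log_mean=float(logs2.mean()),
                     sigma2_log_sd=float(logs2.std()),
                     d_used=d, epsilon_used=epsilon,
                     slope=slope, intercept=intercept, r_squared=r2)


def clip_negative(C: np.ndarray) -> np.ndarray:
    """Zero out negative off-diagonal covariances, keeping the diagonal."""
    C = np.array(C, dtype=float)
    diag = np.diag(C).copy()
    C[C < 0] = 0.0
    np.fill_diagonal(C, diag)
    return C


def corr_to_distance(C: np.ndarray, kernel: KernelSpec, L: float) -> np.ndarray:
    """Target functional distances u*_ij from correlation magnitudes.

    u* = f^{-1}(|R|) for |R| >= f(L); beyond the box size a logarithmic
    soft cut-off u* = L log(f^{-1}(|R|)/L) + L compresses unreliable large
    distances.  Distances are capped at 10 L (the R -> 0 degenerate case).
    """
    R, _ = _correlations(C)
    A = np.abs(R)
    if np.any(A > 1 + 1e-12):
        raise ValueError("|R| > 1 encountered; input is not a covariance")
    A = np.clip(A, 0.0, 1.0)
    fL = float(kernel_eval(kernel, L))
    tiny = np.exp(-9.0 / kernel.mu)  # avoids inf from f^{-1}(~0)
    raw = np.asarray(kernel_inverse(kernel, np.clip(A, tiny, 1.0)))
    far = A < fL
    out = np.where(far, L * np.log(np.maximum(raw, 1e-300) / L) + L, raw)
    out = np.clip(out, 0.0, 10.0 * L)
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2.0


def _classical_mds(D: np.ndarray, d: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:d]
    w_top = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(w_top)


def _sammon_stress(Dstar: np.ndarray, X: np.ndarray) -> float:
    iu = np.triu_indices(Dstar.shape[0], k=1)
    dstar = Dstar[iu]
    dd = pdist(X)
    w = 1.0 / np.clip(dstar, 1e-12, None)
    return float(np.sum(w * (dstar - dd) ** 2) / np.sum(dstar))


def mds_embed(distances: np.ndarray, d: int = 2, max_iter: int = 500,
              tol: float = 1e-4) -> Embedding:
    """Weighted SMACOF minimization of the Sammon stress.

    Majorization with weights 1/u*_ij guarantees the stress is
    non-increasing per iteration; iteration stops when the relative stress
    decrease falls below ``tol`` (returns ``converged=False`` if the
    budget is exhausted first).  The configuration is reported up to rigid
    motion and reflection.
    """
    Dstar = np.asarray(distances, dtype=float)
    n = Dstar.shape[0]
    if Dstar.shape[1] != n or not np.allclose(Dstar, Dstar.T, atol=1e-8):
        raise ValueError("distances must be square symmetric")
    if np.any(np.abs(np.diag(Dstar)) > 1e-12):
        raise ValueError("distances must have zero diagonal")
    W = 1.0 / np.clip(Dstar, 1e-12, None)
    np.fill_diagonal(W, 0.0)
    # V^+ for the Guttman transform
    V = np.diag(W.sum(axis=1)) - W
    Vp = np.linalg.pinv(V)

    X = _classical_mds(Dstar, d)
    stress = _sammon_stress(Dstar, X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Dx = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(Dx > 1e-12, W * Dstar / np.where(Dx > 1e-12, Dx, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = Vp @ (B @ X)
        new_stress = _sammon_stress(Dstar, X_new)
        drop = stress - new_stress
        X, stress = X_new, new_stress
        if drop >= 0 and drop < tol * max(stress, 1e-12):
            converged = True
            break
    return Embedding(coords=X, stress=stress, converged=converged, n_iter=it)
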