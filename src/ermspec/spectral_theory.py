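"""Analytic eigenspectra of Euclidean-random-matrix covariances.

Three routes to the spectrum are implemented.

1.  Direct diagonalization of a realized matrix (``eig_rank_plot``).

2.  High-density closed form: for density rho*eps^d >> 1 the resolvent

        g(z) = (1/rho) Int d^d k / (2 pi)^d  1 / (z - rho E(sigma^2) f~(k))

    localizes eigenvalues on the level sets of the kernel's Fourier
    transform, giving the rank plot directly:

        lambda(q) = rho E(sigma^2) f~(k*),
        k* = ((2 pi)^d rho q / v_d)^(1/d),

    with v_d the unit-ball volume (``high_density_rank_plot``).  For the
    power-law kernel this yields lambda ~ (r/N)^(-(1 - mu/d)) rho^(mu/d):
    the spectrum is density-independent, hence sampling-invariant, as
    mu/d -> 0.

3.  Gaussian-variational self-consistency for intermediate density
    (rho*eps^d <~ 1), where per-neuron variances matter.  Writing
    G = Int Dk G~(k, z), the pair

        g(z)     = < 1 / (z - sigma^2 G) >_sigma
        1/f~(k)  = 1/G~(k, z) + < rho sigma^2 / (z - sigma^2 G) >_sigma

    is solved by damped fixed-point iteration at z = lambda + i eta for a
    decreasing eta schedule, extrapolated to eta -> 0+; the density then
    follows from the Sokhotski-Plemelj formula
    p(lambda) = -(1/pi) Im g(lambda + i 0+)  (``variational_density``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn, roots_hermite

from .erm import FunctionalSpace, VarianceModel
from .kernels import KernelSpec, kernel_fourier


@dataclass
class RankPlot:
    """Eigenvalues sorted descending against normalized rank q = r/N."""

    q: np.ndarray
    lam: np.ndarray
    regime: str = "empirical"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if len(self.q) != len(self.lam):
            raise ValueError("q and lam must have the same length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(np.diff(self.lam) > 1e-9 * np.abs(self.lam[:-1])):
            raise ValueError("lam must be non-increasing")


@dataclass
class SpectralDensity:
    """Eigenvalue density p(lambda) on a grid, with its provenance regime."""

    lam_grid: np.ndarray
    pdf: np.ndarray
    regime: str

    def __post_init__(self) -> None:
        self.lam_grid = np.asarray(self.lam_grid, dtype=float)
        self.pdf = np.asarray(self.pdf, dtype=float)
        if np.any(self.pdf < -1e-6):
            raise ValueError("density has significantly negative values")
        self.pdf = np.clip(self.pdf, 0.0, None)


def eig_rank_plot(C: np.ndarray) -> RankPlot:
    """Descending eigenvalues of a symmetric matrix against q = r/N."""
    C = np.asarray(C)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("C must be symmetric")
    lam = np.sort(np.linalg.eigvalsh(C))[::-1]
    N = len(lam)
    return RankPlot(q=np.arange(1, N + 1) / N, lam=lam, regime="empirical")


def unit_ball_volume(d: int) -> float:
    return np.pi ** (d / 2.0) / gamma_fn(d / 2.0 + 1.0)


def high_density_rank_plot(kernel: KernelSpec, space: FunctionalSpace,
                           Esigma2: float = 1.0,
                           q_grid: np.ndarray | None = None) -> RankPlot:
    """Closed-form rank plot in the high-density regime.

    Requires an isotropic Fourier transform strictly decreasing in k;
    raises for kernels where the numerically checked transform is not
    monotone on the needed range.
    """
    if q_grid is None:
        q_grid = np.logspace(np.log10(1.0 / space.N), 0.0, 200)
    q_grid = np.asarray(q_grid, dtype=float)
    rho, d = space.rho, space.d
    v_d = unit_ball_volume(d)
    k_star = ((2.0 * np.pi) ** d * rho * q_grid / v_d) ** (1.0 / d)
    ft = np.asarray(kernel_fourier(kernel, k_star, d), dtype=float)
    if np.any(np.diff(ft) > 1e-12 * np.abs(ft[:-1]) + 1e-300):
        raise ValueError("kernel Fourier transform is not strictly "
                         "decreasing on the requested range; the level-set "
                         "inversion does not apply")
    lam = rho * Esigma2 * ft
    return RankPlot(q=q_grid, lam=lam, regime="high_density")


# ---------------------------------------------------------------------------
# variational solver


class VariationalConvergenceError(RuntimeError):
    def __init__(self, residual: float, message: str | None = None):
        self.residual = residual
        super().__init__(message or
                         f"fixed point did not converge (residual {residual:.3g})")


def _sigma2_nodes(variance_model: VarianceModel,
                  n_nodes: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for averages over the sigma^2 distribution.

    Unit variances collapse to a single node; the lognormal uses
    Gauss-Hermite quadrature on the log scale (exact for polynomials in
    log sigma^2, spectrally accurate for the smooth resolvent integrand).
    """
    if variance_model.kind == "unit":
        return np.array([1.0]), np.array([1.0])
    t, w = roots_hermite(n_nodes)
    s2 = np.exp(variance_model.location + np.sqrt(2.0) * variance_model.scale * t)
    w = w / np.sqrt(np.pi)
    if variance_model.normalize:
        s2 = s2 / np.sum(w * s2)
    return s2, w


def _k_quadrature(kernel: KernelSpec, space: FunctionalSpace, Esigma2: float,
                  lam_min: float, n_k: int = 600
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-spaced radial grid, weights and f~ values for Int Dk.

    Int d^dk/(2 pi)^d F(|k|) = S_{d-1}/(2 pi)^d Int_0^inf F(k) k^(d-1) dk.
    The grid is truncated at k_max where rho E(sigma^2) f~(k_max) is
    negligible against the smallest eigenvalue of interest (the transform
    decays exponentially there, so the truncation error is controlled).
    """
    d, rho = space.d, space.rho
    eps = kernel.epsilon
    target = 1e-4 * lam_min / (rho * Esigma2)
    k_hi = 10.0 / eps
    ft_hi = kernel_fourier(kernel, k_hi, d)
    while ft_hi > target and k_hi < 1e9 / eps:
        k_hi *= 1.5
        ft_hi = kernel_fourier(kernel, k_hi, d)
    k = np.logspace(np.log10(1e-7 / eps), np.log10(k_hi), n_k)
    ft = np.asarray(kernel_fourier(kernel, k, d), dtype=float)
    surf = 2.0 * np.pi ** (d / 2.0) / gamma_fn(d / 2.0)
    # trapezoid in log k:  Int F k^(d-1) dk = Int F k^d dlogk
    logk = np.log(k)
    w = np.zeros_like(k)
    w[1:-1] = 0.5 * (logk[2:] - logk[:-2])
    w[0] = 0.5 * (logk[1] - logk[0])
    w[-1] = 0.5 * (logk[-1] - logk[-2])
    weights = surf / (2.0 * np.pi) ** d * k**d * w
    return k, weights, ft


def _solve_fixed_point(z: complex, ft: np.ndarray, kw: np.ndarray,
                       s2: np.ndarray, sw: np.ndarray, rho: float,
                       G0: complex, damping: float = 0.5,
                       tol: float = 1e-8, max_iter: int = 5000) -> complex:
    """Damped iteration for G = Int Dk f~ / (1 - A(G) f~)."""
    G = G0
    for _ in range(max_iter):
        A = rho * np.sum(sw * s2 / (z - s2 * G))
        Gnew = np.sum(kw * ft / (1.0 - A * ft))
        if abs(Gnew - G) < tol * max(1.0, abs(G)):
            return Gnew
        G = damping * Gnew + (1.0 - damping) * G
    raise VariationalConvergenceError(abs(Gnew - G))


def variational_density(kernel: KernelSpec, space: FunctionalSpace,
                        variance_model: VarianceModel = VarianceModel(),
                        lam_grid: np.ndarray | None = None,
                        eta_schedule=(1e-2, 3e-3, 1e-3),
                        n_k: int = 600, n_sigma: int = 32) -> SpectralDensity:
    """Eigenvalue density from the Gaussian-variational self-consistency.

    Solves the resolvent fixed point at z = lambda + i eta for each eta in
    the schedule (descending), warm-starting along the descending lambda
    grid, and linearly extrapolates Im g to eta -> 0+ before applying the
    Sokhotski-Plemelj formula.
    """
    if lam_grid is None:
        lam_grid = np.logspace(-1, np.log10(50.0), 60)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if np.any(lam_grid <= 0):
        raise ValueError("lam_grid must be positive")
    lam_sorted = np.sort(lam_grid)[::-1]
    s2, sw = _sigma2_nodes(variance_model, n_sigma)
    Esigma2 = float(np.sum(sw * s2))
    _, kw, ft = _k_quadrature(kernel, space, Esigma2, lam_sorted[-1], n_k)
    rho = space.rho
    etas = np.sort(np.asarray(eta_schedule, dtype=float))[::-1]
    im_g = np.empty((len(etas), len(lam_sorted)))
    for ie, eta in enumerate(etas):
        G = complex(0.0, -1e-3)  # lower half for G so Im g < 0... start small
        for il, lam in enumerate(lam_sorted):
            z = lam + 1j * eta
            G = _solve_fixed_point(z, ft, kw, s2, sw, rho, G)
            g = np.sum(sw / (z - s2 * G))
            im_g[ie, il] = g.imag
    # linear-in-eta extrapolation using the two smallest etas
    if len(etas) >= 2:
        e1, e0 = etas[-2], etas[-1]
        im0 = im_g[-1] + (im_g[-1] - im_g[-2]) * e0 / (e1 - e0)
    else:
        im0 = im_g[-1]
    pdf_desc = -im0 / np.pi
    if np.any(pdf_desc < -1e-6):
        raise VariationalConvergenceError(
            float(-pdf_desc.min()),
            "variational density is significantly negative; solver failed")
    order = np.argsort(lam_sorted)
    return SpectralDensity(lam_grid=lam_sorted[order],
                           pdf=np.clip(pdf_desc[order], 0.0, None),
                           regime="variational")


def density_to_rank(density: SpectralDensity,
                    q_anchor: tuple[float, float]) -> RankPlot:
    """Convert a density to a rank plot via the complementary cdf.

    q(lambda) = q_s + Int_lambda^lambda_s p dl, anchored at
    ``q_anchor = (q_s, lambda_s)`` — typically the smoothed top-of-spectrum
    point taken from simulation, since the theory is least reliable for the
    leading eigenvalues.
    """
    q_s, lam_s = q_anchor
    lam = density.lam_grid
    pdf = density.pdf
    tol = 1e-9 * max(abs(lam[-1]), 1.0)
    if lam[0] - tol <= lam_s <= lam[-1] + tol:
        lam_s = float(np.clip(lam_s, lam[0], lam[-1]))
    else:
        raise ValueError(f"anchor lambda={lam_s} outside density grid "
                         f"[{lam[0]}, {lam[-1]}]")
    # signed cumulative integral; the anchor only fixes the constant, so the
    # rank plot extends both below and above lambda_s (q < q_s in the tail)
    seg = 0.5 * (pdf[1:] + pdf[:-1]) * np.diff(lam)
    cum = np.concatenate([[0.0], np.cumsum(seg)])  # Int_{lam[0]}^{lam}
    cum_s = float(np.interp(lam_s, lam, cum))
    q = q_s + (cum_s - cum)
    keep = q > 0
    q, lam_out = q[keep], lam[keep]
    order = np.argsort(q)
    q_sorted, lam_sorted = q[order], lam_out[order]
    uniq = np.concatenate([[True], np.diff(q_sorted) > 0])
    return RankPlot(q=q_sorted[uniq], lam=lam_sorted[uniq],
                    regime=density.regime)


def smoothed_anchor(lam_full: np.ndarray, q0: float = 0.01) -> tuple[float, float]:
    """Smoothed (q_s, lambda_s) anchor near the q0 rank from a simulated spectrum.

    Averages log lambda and log q over the rank j nearest below N*q0 and
    its two successors, damping the zigzag of the leading eigenvalues.
    """
    lam = np.sort(np.asarray(lam_full, dtype=float))[::-1]
    N = len(lam)
    j = max(int(np.floor(N * q0)), 1)
    ranks = np.array([j, j + 1, j + 2])
    log_lam = np.mean(np.log(lam[ranks - 1]))
    log_q = np.mean(np.log(ranks / N))
    return float(np.exp(log_q)), float(np.exp(log_lam))
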