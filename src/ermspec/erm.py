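"""Euclidean-random-matrix realizations of neural covariance.

Neurons are points in a d-dimensional functional space; pairwise
correlation is a decreasing kernel of functional distance, scaled by
per-neuron activity variances:

    C_ij = sigma_i sigma_j f(||x_i - x_j||),    C_ii = sigma_i^2.

This module samples coordinates and variances, assembles covariance
matrices, draws synthetic activity with a prescribed covariance, and
computes covariance from activity with the normalization conventions used
throughout the package (mean-over-nonzero-frames scaling for deconvolved
calcium-like traces, and trace normalization Tr(C)/N = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .kernels import KernelSpec, kernel_eval


@dataclass(frozen=True)
class FunctionalSpace:
    """Box geometry of the latent functional space.

    The density rho = N / L^d is the key order parameter of the spectral
    theory: rho * eps^d >> 1 is the high-density regime, << 1 the
    intermediate-density regime.
    """

    d: int
    L: float
    N: int

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.N < 2:
            raise ValueError("N must be >= 2")

    @property
    def rho(self) -> float:
        return self.N / self.L**self.d

    @classmethod
    def from_density(cls, d: int, N: int, rho: float) -> "FunctionalSpace":
        return cls(d=d, L=(N / rho) ** (1.0 / d), N=N)


@dataclass(frozen=True)
class VarianceModel:
    """Distribution of per-neuron activity variances sigma^2.

    ``unit`` fixes all variances at 1 (covariance = correlation matrix).
    ``lognormal`` draws log sigma^2 ~ Normal(location, scale^2) i.i.d.,
    independent of position.  With ``normalize`` set, the sample mean of
    sigma^2 is rescaled to exactly 1, matching the trace normalization
    applied to all reported spectra.
    """

    kind: str = "unit"
    location: float = 0.0
    scale: float = 0.5
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("unit", "lognormal"):
            raise ValueError("kind must be 'unit' or 'lognormal'")
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")

    def sample(self, N: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "unit":
            return np.ones(N)
        s2 = np.exp(rng.normal(self.location, self.scale, size=N))
        if self.normalize:
            s2 = s2 / s2.mean()
        return s2


@dataclass
class ERMRealization:
    """One draw of coordinates, variances, and the covariance they induce."""

    coords: np.ndarray
    sigma2: np.ndarray
    C: np.ndarray
    kernel: KernelSpec
    space: FunctionalSpace


def sample_coordinates(space: FunctionalSpace, distribution: str = "uniform",
                       params: dict | None = None,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw N functional coordinates in d dimensions.

    ``uniform`` sprinkles points in the box [0, L]^d.  ``gaussian`` and
    ``lognormal`` are alternative coordinate densities whose parameters
    are matched to the uniform case by fixing the self-overlap integral
    Int p(x)^2 dx = 1/L^d (the quantity that controls the pairwise
    correlation histogram); for the isotropic gaussian in d=2 this gives
    1/(4 pi sigma_p^2) = 1/L^2, and for the lognormal
    L exp(sigma_p^2/4 - mu_p) = 2 sqrt(pi) sigma_p.
    """
    rng = np.random.default_rng(seed)
    params = params or {}
    N, d, L = space.N, space.d, space.L
    if distribution == "uniform":
        return rng.uniform(0.0, L, size=(N, d))
    if distribution == "gaussian":
        # Int p^2 = (4 pi sigma_p^2)^(-d/2) matched to L^-d
        sigma_p = params.get("sigma_p", L / np.sqrt(4.0 * np.pi))
        return rng.normal(0.0, sigma_p, size=(N, d))
    if distribution == "lognormal":
        sigma_p = params.get("sigma_p", 1.0)
        # matching condition solved for the log-scale location mu_p
        mu_p = params.get(
            "mu_p", sigma_p**2 / 4.0 - np.log(2.0 * np.sqrt(np.pi) * sigma_p / L))
        return rng.lognormal(mu_p, sigma_p, size=(N, d))
    raise ValueError(f"unsupported coordinate distribution {distribution!r}")


def build_covariance(coords: np.ndarray, sigma2: np.ndarray,
                     kernel: KernelSpec) -> np.ndarray:
    """Assemble C_ij = sigma_i sigma_j f(||x_i - x_j||).

    Distances are plain Euclidean on the box (no periodic wrapping).
    """
    coords = np.asarray(coords, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if len(coords) != len(sigma2):
        raise ValueError("coords and sigma2 must have the same length")
    D = squareform(pdist(coords))
    F = kernel_eval(kernel, D)
    np.fill_diagonal(F, 1.0)
    sig = np.sqrt(sigma2)
    return F * np.outer(sig, sig)


def make_erm(space: FunctionalSpace, kernel: KernelSpec,
             variance_model: VarianceModel = VarianceModel(),
             distribution: str = "uniform",
             seed: int | np.random.Generator = 0) -> ERMRealization:
    """Sample a full ERM realization (coordinates, variances, covariance)."""
    rng = np.random.default_rng(seed)
    coords = sample_coordinates(space, distribution, seed=rng)
    sigma2 = variance_model.sample(space.N, rng)
    C = build_covariance(coords, sigma2, kernel)
    return ERMRealization(coords=coords, sigma2=sigma2, C=C,
                          kernel=kernel, space=space)


def simulate_activity(C: np.ndarray, T: int,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw an N x T Gaussian activity matrix with population covariance C."""
    C = np.asarray(C, dtype=float)
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(
            f"C is not positive semidefinite (smallest eigenvalue {w.min():.3g})")
    w = np.clip(w, 0.0, None)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((C.shape[0], T))
    return (V * np.sqrt(w)) @ (V.T @ Z)


def covariance_from_activity(activity: np.ndarray,
                             nonzero_mean_normalize: bool = False,
                             trace_normalize: bool = False) -> np.ndarray:
    """Sample covariance of activity traces with optional normalizations.

    ``nonzero_mean_normalize`` rescales each trace so its mean over nonzero
    time frames equals one before computing covariance (appropriate for
    sparse deconvolved calcium traces, where it removes per-neuron gain
    differences).  ``trace_normalize`` rescales the covariance so
    Tr(C)/N = 1 exactly, i.e. eigenvalues sum to N.
    """
    A = np.array(activity, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("activity must be N x T with T >= 2")
    if nonzero_mean_normalize:
        for i in range(A.shape[0]):
            nz = A[i] != 0
            if not nz.any():
                raise ValueError(
                    f"neuron {i} has an all-zero trace; cannot normalize "
                    "over nonzero frames")
            A[i] = A[i] / A[i, nz].mean()
    A = A - A.mean(axis=1, keepdims=True)
    C = A @ A.T / (A.shape[1] - 1)
    if trace_normalize:
        C = trace_normalized(C)
    return C


def trace_normalized(C: np.ndarray) -> np.ndarray:
    """Rescale a covariance so the mean diagonal entry is exactly 1."""
    C = np.asarray(C, dtype=float)
    m = np.trace(C) / C.shape[0]
    if m <= 0:
        raise ValueError("trace must be positive to normalize")
    return C / m
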