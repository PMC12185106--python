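"""Null covariance models and anatomical-functional canonical correlation.

The null models are scale-*variant* reference points for the collapse
index: a Wishart matrix from i.i.d. Gaussian activity (Marchenko-Pastur
spectrum), an eigenvector-randomized surrogate that keeps the exact
eigenvalues but destroys the geometry carried by the eigenvectors, and
the covariance of a randomly connected linear-rate recurrent network.

The CCA utilities quantify how anatomical position predicts functional
position: the synthetic joint-coordinate generator plants a prescribed
first canonical correlation R_CCA between the first anatomical axis and
the first functional axis, mirroring the moderate anatomical-functional
correlation seen in whole-brain data.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.linalg import qr, solve_lyapunov, svd

from .erm import trace_normalized


@dataclass
class JointCoords:
    """Anatomical (N x 3) and functional (N x 2) coordinates with planted R_CCA."""

    anat: np.ndarray
    func: np.ndarray
    target_R_CCA: float
    seed: int | None = None


def wishart_cov(N: int, T: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Trace-normalized Wishart covariance C = G G^T / (T-1), G i.i.d. N(0,1)."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((N, T))
    C = G @ G.T / (T - 1)
    return trace_normalized(C)


def eigvec_randomize(C: np.ndarray,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Replace eigenvectors with a Haar-random orthogonal basis.

    The output has exactly the same eigenvalues as C but random
    eigenvectors, obtained from the QR decomposition of an i.i.d. Gaussian
    matrix (sign-fixed so the factor is Haar-distributed).
    """
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("C must be symmetric")
    N = C.shape[0]
    rng = np.random.default_rng(seed)
    lam = np.linalg.eigvalsh(C)
    A = rng.standard_normal((N, N)) / np.sqrt(N)
    U, R = qr(A)
    U = U * np.sign(np.diag(R))  # make the distribution Haar
    return (U * lam) @ U.T


def rnn_covariance(N: int, g: float, seed: int | np.random.Generator = 0,
                   mode: str = "dynamical") -> np.ndarray:
    """Covariance of a randomly connected linear-rate network.

    Synaptic weights J_ij ~ N(0, g^2/N) with coupling strength 0 <= g < 1.
    ``mode="dynamical"`` returns the stationary covariance of the noise-
    driven rate dynamics dx/dt = -x + Jx + xi (the Lyapunov solution of
    (I-J) C + C (I-J)^T = 2I); ``mode="static"`` returns the long-time-
    window form C = (I-J)^{-1} (I-J^T)^{-1}.  Both are trace-normalized.
    A draw of J with spectral radius >= 1 (rare for g < 1) is resampled
    with a warning.
    """
    if not 0 <= g < 1:
        raise ValueError("coupling strength g must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    for _ in range(20):
        J = rng.standard_normal((N, N)) * g / np.sqrt(N)
        radius = np.abs(np.linalg.eigvals(J)).max() if g > 0 else 0.0
        if radius < 1.0:
            break
        warnings.warn(f"spectral radius {radius:.3f} >= 1; resampling J")
    else:  # pragma: no cover
        raise RuntimeError("could not draw a stable connectivity matrix")
    eye = np.eye(N)
    if mode == "dynamical":
        C = solve_lyapunov(-(eye - J), -2.0 * eye)
        C = (C + C.T) / 2.0
    elif mode == "static":
        A = np.linalg.inv(eye - J)
        C = A @ A.T
    else:
        raise ValueError("mode must be 'dynamical' or 'static'")
    return trace_normalized(C)


def synth_joint_coords(N: int, R_CCA: float,
                       anat_var: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       func_var: tuple[float, float] = (2.0, 1.0),
                       seed: int | np.random.Generator = 0) -> JointCoords:
    """Jointly Gaussian anatomical (3-d) and functional (2-d) coordinates.

    All five coordinates are zero-mean and mutually independent except the
    first anatomical and first functional axes, which are correlated at
    ``R_CCA``.  By construction the first canonical correlation equals
    R_CCA asymptotically and the canonical directions are the first axes.
    """
    if not -1.0 <= R_CCA <= 1.0:
        raise ValueError("R_CCA must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    sy = np.sqrt(np.asarray(anat_var, dtype=float))
    sx = np.sqrt(np.asarray(func_var, dtype=float))
    cov = np.zeros((5, 5))
    cov[:3, :3] = np.diag(sy**2)
    cov[3:, 3:] = np.diag(sx**2)
    cov[0, 3] = cov[3, 0] = R_CCA * sy[0] * sx[0]
    z = rng.multivariate_normal(np.zeros(5), cov, size=N,
                                method="cholesky" if abs(R_CCA) < 1 else "svd")
    return JointCoords(anat=z[:, :3], func=z[:, 3:], target_R_CCA=R_CCA,
                       seed=seed if isinstance(seed, int) else None)


def cca_first(anat_coords: np.ndarray, func_coords: np.ndarray
              ) -> tuple[float, np.ndarray, np.ndarray]:
    """First canonical correlation and directions between two coordinate sets.

    Uses the QR-based algorithm: center both blocks, take thin QR factors,
    and read the canonical structure off the SVD of Q_a^T Q_f.  Returns
    (R_CCA, v_anat, v_func) with unit-norm direction vectors in the
    original (centered) coordinate bases.
    """
    Y = np.asarray(anat_coords, dtype=float)
    X = np.asarray(func_coords, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim == 1:
        X = X[:, None]
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValueError("coordinate sets must have the same number of rows")
    if n <= max(Y.shape[1], X.shape[1]) + 2:
        raise ValueError("too few observations for CCA")
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    Qy, Ry = qr(Yc, mode="economic")
    Qx, Rx = qr(Xc, mode="economic")
    if (np.abs(np.diag(Ry)).min() < 1e-10 * np.abs(np.diag(Ry)).max() or
            np.abs(np.diag(Rx)).min() < 1e-10 * np.abs(np.diag(Rx)).max()):
        raise ValueError("rank-deficient coordinates")
    U, s, Vt = svd(Qy.T @ Qx)
    r = float(np.clip(s[0], 0.0, 1.0))
    v_anat = np.linalg.solve(Ry, U[:, 0])
    v_func = np.linalg.solve(Rx, Vt[0, :])
    v_anat = v_anat / np.linalg.norm(v_anat)
    v_func = v_func / np.linalg.norm(v_func)
    return r, v_anat, v_func


def cca_shuffle_test(anat: np.ndarray, func: np.ndarray,
                     n_shuffles: int = 1000,
                     seed: int | np.random.Generator = 0) -> float:
    """Permutation p-value for the first canonical correlation.

    Functional coordinates are shuffled across neuron identities and the
    canonical correlation recomputed; the p-value is the add-one-smoothed
    fraction of shuffles reaching the observed R_CCA.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    observed, _, _ = cca_first(anat, func)
    func = np.asarray(func)
    count = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(func.shape[0])
        r, _, _ = cca_first(anat, func[perm])
        if r >= observed:
            count += 1
    return (count + 1) / (n_shuffles + 1)
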