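"""Dimensionality and scale-invariance metrics for covariance spectra.

The participation ratio

    D_PR = (sum lambda)^2 / sum lambda^2
         = N^2 E(sigma^2)^2 / [N E(sigma^4) + N(N-1) E_{i!=j}(C_ij^2)]

measures the effective number of principal dimensions of activity; its
large-N limit E(sigma^2)^2 / E_{i!=j}(C_ij^2) is finite whenever the mean
squared pairwise covariance does not vanish with N.

The collapse index (CI) quantifies scale invariance of the eigenspectrum:
it is the normalized area, on the log-log rank plot, between the spectrum
of the full matrix (N0 neurons) and the averaged spectra of its sampled
half-blocks (N0/2), integrated from the 1%-largest eigenvalue (q0 = 0.01)
down to eigenvalue 1 (q1 defined by lambda(q1) = 1).  CI = 0 means the
curves collapse; larger CI means the spectrum shifts with sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .erm import trace_normalized
from .sampling import SamplingResult, sample


@dataclass
class CIResult:
    """Collapse index with the integration window that produced it."""

    value: float
    q0: float
    q1: float
    n_repeats: int
    scheme: str = "RSap"
    seed: int | None = None


@dataclass
class DimPrediction:
    """Predicted participation ratio under a sampling scheme."""

    scheme: str
    k: float
    predicted: float
    Esigma2: float
    Esigma4: float
    mean_sq_offdiag: float
    mu_over_d: float | None = None
    R_ASap: float | None = None
    k_f: float | None = None


def dpr(eigenvalues) -> float:
    """Participation ratio (sum lambda)^2 / sum lambda^2."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-12 * max(abs(lam).max(), 1.0)):
        raise ValueError("eigenvalues must be nonnegative")
    s2 = np.sum(lam**2)
    if s2 == 0:
        raise ValueError("all eigenvalues are zero")
    return float(np.sum(lam) ** 2 / s2)


def covariance_moments(C: np.ndarray) -> tuple[float, float, float]:
    """Plug-in moments (E(sigma^2), E(sigma^4), E_{i!=j}(C_ij^2)) of C."""
    C = np.asarray(C, dtype=float)
    diag = np.diag(C)
    off = C[~np.eye(C.shape[0], dtype=bool)]
    return float(diag.mean()), float((diag**2).mean()), float((off**2).mean())


def dpr_limit(Esigma2: float, mean_sq_offdiag: float) -> float:
    """Large-N participation ratio E(sigma^2)^2 / E_{i!=j}(C_ij^2).

    Returns ``inf`` for a diagonal covariance (zero mean squared
    off-diagonal), where the dimensionality grows without bound.
    """
    if mean_sq_offdiag < 0:
        raise ValueError("mean squared off-diagonal must be nonnegative")
    if mean_sq_offdiag == 0:
        return np.inf
    return Esigma2**2 / mean_sq_offdiag


def dpr_formula(N, Esigma2: float, Esigma4: float,
                mean_sq_offdiag: float) -> np.ndarray | float:
    """Moment form of the participation ratio at matrix size N."""
    N = np.asarray(N, dtype=float)
    return N**2 * Esigma2**2 / (N * Esigma4 + N * (N - 1) * mean_sq_offdiag)


def dpr_curve_pred(C: np.ndarray, N_grid) -> np.ndarray:
    """Predicted D_PR versus sample size from the plug-in moments of C.

    Estimates E(sigma^2), E(sigma^4) and E_{i!=j}(C_ij^2) from the full
    matrix and evaluates the moment form of D_PR for each N in ``N_grid``
    (random sampling leaves these moments unchanged in expectation).
    """
    N_grid = np.asarray(N_grid)
    if np.any(N_grid < 2):
        raise ValueError("all N values must be >= 2")
    e2, e4, m2 = covariance_moments(C)
    return np.asarray(dpr_formula(N_grid, e2, e4, m2), dtype=float)


def dpr_sampling_pred(scheme: str, k: float, moments: tuple[float, float, float],
                      N0: int, mu_over_d: float | None = None,
                      R_ASap: float | None = None) -> DimPrediction:
    """Predicted participation ratio after sampling a fraction k of N0 neurons.

    RSap leaves the covariance moments unchanged; FSap concentrates onto a
    functional subregion, boosting the mean squared covariance by
    k^(-2 mu/d); ASap interpolates through the anatomical-functional
    correlation R_ASap with an effective functional fraction
    k_f = sqrt(1 - R^2 + k^2 R^2).  At R_ASap = 0, ASap reduces to RSap;
    at R_ASap = 1, to FSap.
    """
    if not 0 < k <= 1:
        raise ValueError("sampling fraction k must lie in (0, 1]")
    e2, e4, m2 = moments
    s = scheme.lower()
    kf = None
    if s == "rsap":
        m2_eff = m2
    elif s == "fsap":
        if mu_over_d is None:
            raise ValueError("FSap prediction requires mu_over_d")
        m2_eff = k ** (-2.0 * mu_over_d) * m2
    elif s == "asap":
        if mu_over_d is None or R_ASap is None:
            raise ValueError("ASap prediction requires mu_over_d and R_ASap")
        if not 0 <= R_ASap <= 1:
            raise ValueError("R_ASap must lie in [0, 1]")
        factor = 1.0 - R_ASap**2 + k**2 * R_ASap**2
        kf = float(np.sqrt(factor))
        m2_eff = factor ** (-mu_over_d) * m2
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    N = k * N0
    pred = N * e2**2 / (e4 + (N - 1) * m2_eff)
    return DimPrediction(scheme=scheme, k=k, predicted=float(pred),
                         Esigma2=e2, Esigma4=e4, mean_sq_offdiag=m2,
                         mu_over_d=mu_over_d, R_ASap=R_ASap, k_f=kf)


def fsap_mu_over_d(C: np.ndarray, n_levels: int = 3) -> float:
    """Estimate mu/d from how E_{i!=j}(C_ij^2) grows across FSap levels.

    Within FSap blocks the mean squared covariance scales as k^(-2 mu/d)
    with block fraction k, so the slope of log E^k(C^2) versus log k
    across the block hierarchy is -2 mu/d.
    """
    res = sample(C, "fsap", n_levels)
    ks, m2s = [], []
    N0 = C.shape[0]
    for labels in res.block_assignments:
        vals = []
        for b in np.unique(labels):
            idx = np.flatnonzero(labels == b)
            if len(idx) < 2:
                continue
            blk = C[np.ix_(idx, idx)]
            vals.append(np.mean(blk[~np.eye(len(idx), dtype=bool)] ** 2))
        size = np.count_nonzero(labels == labels[0])
        ks.append(size / N0)
        m2s.append(np.mean(vals))
    slope = np.polyfit(np.log(ks), np.log(m2s), 1)[0]
    return float(-slope / 2.0)


# ---------------------------------------------------------------------------
# collapse index


def _rank_grid_log_lambda(lam_full: np.ndarray, N0: int, Ns: int) -> np.ndarray:
    """log lambda of the full spectrum interpolated onto q = i/Ns, log-log."""
    q_full = np.arange(1, N0 + 1) / N0
    q_s = np.arange(1, Ns + 1) / Ns
    return np.interp(np.log(q_s), np.log(q_full),
                     np.log(np.clip(lam_full, 1e-300, None)))


def collapse_index_from_spectra(lam_full: np.ndarray, lam_half: np.ndarray,
                                q0: float = 0.01) -> tuple[float, float, float]:
    """Collapse index between a full spectrum and an averaged half spectrum.

    Returns (CI, q0, q1).  ``lam_full`` has N0 entries, ``lam_half`` N0/2
    entries (block spectra already averaged rank-wise).  Both are assumed
    to come from a trace-normalized matrix so that eigenvalue 1 is the
    spectral mean, which defines the lower integration limit q1.
    """
    lam_full = np.sort(np.asarray(lam_full, dtype=float))[::-1]
    lam_half = np.sort(np.asarray(lam_half, dtype=float))[::-1]
    N0, Ns = len(lam_full), len(lam_half)
    if N0 != 2 * Ns:
        raise ValueError("half spectrum must have N0/2 entries")
    q_s = np.arange(1, Ns + 1) / Ns
    loglam0 = _rank_grid_log_lambda(lam_full, N0, Ns)
    loglam_s = np.log(np.clip(lam_half, 1e-300, None))
    integrand = np.abs(loglam0 - loglam_s) / np.log(N0 / Ns)
    # q1: the largest q at which the full spectrum is still >= 1; the
    # spectrum must actually cross 1 (guaranteed for trace-normalized C)
    if loglam0[0] < 0 or loglam0[-1] > 0:
        raise ValueError("spectrum does not cross eigenvalue 1; q1 undefined "
                         "(is the matrix trace-normalized?)")
    ge = np.flatnonzero(loglam0 >= 0.0)
    q1 = q_s[ge[-1]]
    if q1 <= q0:
        raise ValueError(f"integration window empty: q1={q1:.4g} <= q0={q0}")
    # trapezoid over grid points inside [q0, q1], with the integrand
    # linearly interpolated (in log q) at the exact window endpoints
    logq = np.log(q_s)
    mask = (q_s > q0) & (q_s < q1)
    x = np.concatenate([[np.log(q0)], logq[mask], [np.log(q1)]])
    y = np.concatenate([[np.interp(np.log(q0), logq, integrand)],
                        integrand[mask],
                        [np.interp(np.log(q1), logq, integrand)]])
    ci = np.trapezoid(y, x) / (np.log(q1) - np.log(q0))
    return float(ci), q0, float(q1)


def collapse_index(C: np.ndarray, n_repeats: int = 20, q0: float = 0.01,
                   scheme: str = "RSap",
                   seed: int | np.random.Generator = 0,
                   anatomical_coords: np.ndarray | None = None) -> CIResult:
    """Collapse index of a covariance matrix under half-sampling.

    The matrix is trace-normalized internally (CI is invariant to overall
    scaling).  The half-size spectra are averaged over ``n_repeats``
    random halvings (both blocks of each halving) for RSap; ASap/FSap use
    their deterministic level-1 blocks.
    """
    C = trace_normalized(np.asarray(C, dtype=float))
    N0 = C.shape[0]
    if N0 % 2 != 0:
        raise ValueError("N must be even")
    lam_full = np.sort(np.linalg.eigvalsh(C))[::-1]
    s = scheme.lower()
    rng = np.random.default_rng(seed)
    Ns = N0 // 2
    if s == "rsap":
        acc = np.zeros(Ns)
        cnt = 0
        for _ in range(n_repeats):
            perm = rng.permutation(N0)
            for half in (perm[:Ns], perm[Ns:]):
                acc += np.sort(np.linalg.eigvalsh(C[np.ix_(half, half)]))[::-1]
                cnt += 1
        lam_half = acc / cnt
        n_used = n_repeats
    elif s in ("asap", "fsap"):
        res = sample(C, s, 1, anatomical_coords=anatomical_coords, seed=rng)
        lam_half = res.levels[1][1]
        n_used = 1
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    ci, q0_, q1 = collapse_index_from_spectra(lam_full, lam_half, q0)
    return CIResult(value=ci, q0=q0_, q1=q1, n_repeats=n_used,
                    scheme=scheme, seed=seed if isinstance(seed, int) else None)


def collapse_index_theory(kernel, space, variance_model=None,
                          anchor: tuple[float, float] | None = None,
                          q0: float = 0.01, n_nodes: int = 20,
                          eta_schedule=(1e-2, 3e-3, 1e-3)) -> CIResult:
    """Theoretical collapse index from the variational spectral theory.

    Uses the identity (implicit differentiation of the rank plot)

        CI = (1/log(q0/q1)) Int_{lambda(q1)}^{lambda(q0)}
             | (1/lambda) d log q / d log rho |  d lambda,

    with d log q / d log rho estimated by a finite difference of the
    complementary cdf q(lambda) between densities rho and rho/2 (the
    half-sampling step), cubic-spline interpolated over ``n_nodes``
    lambda nodes.  ``anchor`` supplies the integration limits
    lambda(q_s ~ q0) from simulation — a pair ((q_s, lam_s) for the full
    density, (q_s, lam_s) for the halved density) — because the theory is
    least accurate for the leading eigenvalues; if omitted, ERM
    realizations are simulated internally to provide both.
    """
    from scipy.interpolate import CubicSpline

    from .erm import FunctionalSpace, VarianceModel, make_erm
    from .spectral_theory import smoothed_anchor, variational_density

    if variance_model is None:
        variance_model = VarianceModel(kind="unit")
    half_space = FunctionalSpace(d=space.d, L=space.L, N=space.N // 2)
    if anchor is None:
        rng = np.random.default_rng(0)
        Ns = space.N // 2
        acc_full = np.zeros(space.N)
        acc_half = np.zeros(Ns)
        n_sim = 10
        for s in range(n_sim):
            C = trace_normalized(make_erm(space, kernel, variance_model,
                                          seed=s).C)
            acc_full += np.sort(np.linalg.eigvalsh(C))[::-1]
            idx = rng.permutation(space.N)[:Ns]
            acc_half += np.sort(np.linalg.eigvalsh(C[np.ix_(idx, idx)]))[::-1]
        anchor = (smoothed_anchor(acc_full / n_sim, q0),
                  smoothed_anchor(acc_half / n_sim, q0))
    (q_s0, lam_s0), (q_s1, lam_s1) = anchor
    if lam_s0 <= 1.0 or lam_s1 <= 1.0:
        raise ValueError("anchor eigenvalues must exceed 1")
    q_s, lam_s = q_s0, lam_s0

    lam_top = max(lam_s0, lam_s1)
    lam_grid = np.unique(np.concatenate([
        np.logspace(np.log10(0.9), np.log10(lam_top), 50),
        [1.0, lam_s0, lam_s1, lam_top]]))

    def q_curve(sp, qs_a, lam_a):
        dens = variational_density(kernel, sp, variance_model, lam_grid,
                                   eta_schedule=eta_schedule)
        lam, pdf = dens.lam_grid, dens.pdf
        # q(lambda) = q_a + Int_lambda^lam_a p dl
        seg = 0.5 * (pdf[1:] + pdf[:-1]) * np.diff(lam)
        cum = np.concatenate([[0.0], np.cumsum(seg)])  # Int_{lam[0]}^{lam}
        total = np.interp(lam_a, lam, cum)
        qs_grid = qs_a + (total - cum)
        return lam, np.clip(qs_grid, 1e-12, None)

    lam0, qA = q_curve(space, q_s0, lam_s0)
    lam1, qB = q_curve(half_space, q_s1, lam_s1)
    nodes = np.linspace(1.0, lam_s, n_nodes)
    dlogq = np.abs(np.log(np.interp(nodes, lam0, qA))
                   - np.log(np.interp(nodes, lam1, qB))) / np.log(2.0)
    spline = CubicSpline(nodes, dlogq / nodes)
    fine = np.linspace(1.0, lam_s, 400)
    integral = np.trapezoid(spline(fine), fine)
    q1 = float(np.interp(1.0, lam0, qA))
    ci = integral / abs(np.log(q1 / q0))
    return CIResult(value=float(ci), q0=q0, q1=q1, n_repeats=0,
                    scheme="theory")


def alpha_fit(sampling_result: SamplingResult,
              top_fraction: float = 0.10,
              n_exclude: int = 4) -> tuple[float, float]:
    """Power-law exponent of the eigenspectrum rank plot across scales.

    Pools, from every sampling level, the top ``top_fraction`` of that
    level's averaged eigenvalues (excluding the ``n_exclude`` largest,
    whose departure from the bulk theory is expected), and fits a single
    line to log lambda versus log(rank/N).  Returns (alpha, R^2) with
    lambda ~ (r/N)^(-alpha).
    """
    if len(sampling_result.levels) < 4:
        raise ValueError("need at least 4 levels of spectra")
    xs, ys = [], []
    for size, lam in sampling_result.levels:
        lam = np.sort(np.asarray(lam))[::-1]
        top = max(int(np.floor(top_fraction * size)), n_exclude + 1)
        r = np.arange(n_exclude + 1, top + 1)
        vals = lam[n_exclude:top]
        keep = vals > 0
        xs.append(np.log(r[keep] / size))
        ys.append(np.log(vals[keep]))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 10:
        raise ValueError("fewer than 10 pooled points for the power-law fit")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-slope), float(max(min(r2, 1.0), 0.0))
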