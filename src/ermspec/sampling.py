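"""Iterative block-sampling of covariance matrices.

Three schemes define how a covariance matrix of N0 neurons is split into
2^n diagonal blocks of N0/2^n neurons at sampling level n:

* RSap -- random sampling: blocks are uniformly random disjoint subsets.
* ASap -- anatomical sampling: neurons are sorted by projection onto an
  anatomical axis (anterior-posterior by default) and cut into contiguous
  slabs, mimicking optical recording of a brain region.
* FSap -- functional sampling: blocks are clusters obtained by iteratively
  pairing the most correlated units (a renormalization-group style
  agglomeration), so each block stays dense in functional space.

At every level the spectra of all blocks are sorted descending and
averaged rank-wise; comparing these averaged spectra across levels is the
basis of the collapse index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SamplingResult:
    """Averaged per-level spectra of an iterative block-sampling run.

    Attributes
    ----------
    scheme
        One of "RSap", "ASap", "FSap".
    levels
        List of (block_size, averaged descending eigenvalues) per level,
        starting at level 0 (the full matrix).
    block_assignments
        Per-level integer labels (length N) mapping neurons to blocks.
    most_correlated_block
        For FSap: per level, the label of the block maximizing the mean
        squared off-diagonal covariance E_{i!=j}(C_ij^2).
    """

    scheme: str
    levels: list[tuple[int, np.ndarray]]
    block_assignments: list[np.ndarray]
    seed: int | None = None
    most_correlated_block: list[int] | None = None

    @property
    def n_levels(self) -> int:
        return len(self.levels) - 1


def _check_divisible(N: int, n_levels: int) -> None:
    if n_levels < 0:
        raise ValueError("n_levels must be >= 0")
    if N % (2**n_levels) != 0:
        raise ValueError(
            f"N={N} is not divisible by 2^{n_levels}; truncate the matrix "
            f"to {2**n_levels * (N // 2**n_levels)} neurons first")


def _level_spectra(C: np.ndarray, assignments: list[np.ndarray]
                   ) -> list[tuple[int, np.ndarray]]:
    """Average sorted block spectra for each level's assignment labels."""
    levels = []
    for labels in assignments:
        blocks = np.unique(labels)
        size = np.count_nonzero(labels == blocks[0])
        acc = np.zeros(size)
        for b in blocks:
            idx = np.flatnonzero(labels == b)
            lam = np.linalg.eigvalsh(C[np.ix_(idx, idx)])
            acc += np.sort(lam)[::-1]
        levels.append((size, acc / len(blocks)))
    return levels


def rsap(C: np.ndarray, n_levels: int,
         seed: int | np.random.Generator = 0) -> SamplingResult:
    """Random sampling: iteratively halve into random disjoint blocks."""
    C = np.asarray(C)
    N = C.shape[0]
    _check_divisible(N, n_levels)
    rng = np.random.default_rng(seed)
    assignments = [np.zeros(N, dtype=int)]
    labels = np.zeros(N, dtype=int)
    for n in range(1, n_levels + 1):
        new = np.empty(N, dtype=int)
        for b in range(2 ** (n - 1)):
            idx = np.flatnonzero(labels == b)
            perm = rng.permutation(idx)
            half = len(idx) // 2
            new[perm[:half]] = 2 * b
            new[perm[half:]] = 2 * b + 1
        labels = new
        assignments.append(labels.copy())
    return SamplingResult(scheme="RSap", levels=_level_spectra(C, assignments),
                          block_assignments=assignments,
                          seed=seed if isinstance(seed, int) else None)


def asap(C: np.ndarray, anatomical_coords: np.ndarray,
         axis_vector: np.ndarray | None = None,
         n_levels: int = 1) -> SamplingResult:
    """Anatomical sampling: contiguous slabs along an anatomical axis.

    Neurons are ranked by their projection onto ``axis_vector`` (default:
    the first anatomical axis); ties are broken by neuron index.  Level n
    cuts the ranking into 2^n equal contiguous slabs.
    """
    C = np.asarray(C)
    N = C.shape[0]
    coords = np.atleast_2d(np.asarray(anatomical_coords, dtype=float))
    if coords.shape[0] != N:
        if coords.shape[1] == N:
            coords = coords.T
        else:
            raise ValueError("anatomical coordinate count must match N")
    _check_divisible(N, n_levels)
    if axis_vector is None:
        axis_vector = np.zeros(coords.shape[1])
        axis_vector[0] = 1.0
    proj = coords @ np.asarray(axis_vector, dtype=float)
    order = np.argsort(proj, kind="stable")  # stable: ties broken by index
    assignments = []
    for n in range(n_levels + 1):
        labels = np.empty(N, dtype=int)
        size = N // 2**n
        for b in range(2**n):
            labels[order[b * size:(b + 1) * size]] = b
        assignments.append(labels)
    return SamplingResult(scheme="ASap", levels=_level_spectra(C, assignments),
                          block_assignments=assignments)


def _greedy_pair_round(score: np.ndarray) -> list[tuple[int, int]]:
    """Pair all items greedily by descending symmetric score."""
    m = score.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    order = np.argsort(score[iu, ju])[::-1]
    used = np.zeros(m, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for t in order:
        i, j = int(iu[t]), int(ju[t])
        if not used[i] and not used[j]:
            used[i] = used[j] = True
            pairs.append((i, j))
            if 2 * len(pairs) == m:
                break
    return pairs


def fsap(C: np.ndarray, n_levels: int) -> SamplingResult:
    """Functional sampling via iterative most-correlated pairing.

    Renormalization-group style agglomeration: starting from single
    neurons, every round greedily pairs the two available clusters with
    the highest mean pairwise correlation, doubling the cluster size.
    Level n blocks are the 2^n clusters of size N/2^n in the resulting
    binary hierarchy (N must be a power of two so the hierarchy tiles
    every level exactly).  Also records, per level, the block maximizing
    the mean squared off-diagonal covariance ("most correlated cluster").
    """
    C = np.asarray(C, dtype=float)
    N = C.shape[0]
    _check_divisible(N, n_levels)
    if n_levels > 0 and N & (N - 1) != 0:
        raise ValueError(
            f"functional sampling requires a power-of-two neuron count for "
            f"the pairing hierarchy; truncate N={N} to {2**int(np.log2(N))}")
    d = np.sqrt(np.clip(np.diag(C), 1e-300, None))
    R = C / np.outer(d, d)

    members = [np.array([i]) for i in range(N)]
    S = R - np.diag(np.diag(R))  # summed inter-cluster correlations
    hier: dict[int, list[np.ndarray]] = {}
    while len(members) > 2:
        m = len(members)
        size = N // m
        score = S / (size * size)
        np.fill_diagonal(score, -np.inf)
        pairs = _greedy_pair_round(score)
        # aggregate membership and summed correlations
        P = np.zeros((m, m // 2))
        for c, (i, j) in enumerate(pairs):
            P[i, c] = P[j, c] = 1.0
        members = [np.concatenate([members[i], members[j]]) for i, j in pairs]
        S = P.T @ S @ P
        n = int(np.log2(len(members)))
        if 0 < n <= n_levels:
            hier[n] = [c.copy() for c in members]
    assignments = [np.zeros(N, dtype=int)]
    for n in range(1, n_levels + 1):
        labels = np.empty(N, dtype=int)
        for b, idx in enumerate(hier[n]):
            labels[idx] = b
        assignments.append(labels)
    # most correlated cluster per level, scored by E_{i!=j}(C_ij^2)
    most = []
    for labels in assignments:
        best_b, best_score = 0, -np.inf
        for b in np.unique(labels):
            idx = np.flatnonzero(labels == b)
            if len(idx) < 2:
                continue
            blk = C[np.ix_(idx, idx)]
            off = blk[~np.eye(len(idx), dtype=bool)]
            score = np.mean(off**2)
            if score > best_score:
                best_b, best_score = int(b), score
        most.append(best_b)
    return SamplingResult(scheme="FSap", levels=_level_spectra(C, assignments),
                          block_assignments=assignments,
                          most_correlated_block=most)


def sample(C: np.ndarray, scheme: str, n_levels: int,
           anatomical_coords: np.ndarray | None = None,
           axis_vector: np.ndarray | None = None,
           seed: int | np.random.Generator = 0) -> SamplingResult:
    """Dispatch to rsap/asap/fsap by scheme name."""
    s = scheme.lower()
    if s == "rsap":
        return rsap(C, n_levels, seed)
    if s == "asap":
        if anatomical_coords is None:
            raise ValueError("ASap requires anatomical coordinates")
        return asap(C, anatomical_coords, axis_vector, n_levels)
    if s == "fsap":
        return fsap(C, n_levels)
    raise ValueError(f"unknown sampling scheme {scheme!r}")


def _toeplitz_target(C: np.ndarray) -> np.ndarray:
    """Toeplitz matrix whose first row is the mean row-sorted covariance."""
    from scipy.linalg import toeplitz

    rows_sorted = np.sort(C, axis=1)[:, ::-1]
    t = rows_sorted.mean(axis=0)
    return toeplitz(t)


def reorder_matrix(C: np.ndarray, n_proposals: int = 100_000,
                   cooling: float = 0.995,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Neuron ordering that concentrates large covariances near the diagonal.

    Finds a permutation P approximately minimizing ||T - P C P^T||_F by
    simulated annealing over index transpositions, where T is the Toeplitz
    target built from the mean sorted covariance row.  Used only for
    visualization; returns the permutation (identity if no improvement is
    found).
    """
    C = np.asarray(C, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("C must be square symmetric")
    N = C.shape[0]
    T = _toeplitz_target(C)
    rng = np.random.default_rng(seed)

    perm = np.arange(N)
    M = C.copy()  # C[perm][:, perm]
    obj = float(np.sum((T - M) ** 2))
    best_perm, best_obj = perm.copy(), obj
    temp = max(obj, 1e-12) / N**2  # temperature on the per-entry scale
    for _ in range(n_proposals):
        a, b = rng.integers(0, N, size=2)
        if a == b:
            continue
        # objective change from swapping rows/cols a and b of M
        rows = np.array([a, b])
        old = np.sum((T[rows] - M[rows]) ** 2) + np.sum((T[:, rows] - M[:, rows]) ** 2)
        Ms = M.copy()
        Ms[[a, b]] = Ms[[b, a]]
        Ms[:, [a, b]] = Ms[:, [b, a]]
        new = np.sum((T[rows] - Ms[rows]) ** 2) + np.sum((T[:, rows] - Ms[:, rows]) ** 2)
        delta = new - old
        if delta < 0 or rng.random() < np.exp(-delta / max(temp, 1e-300)):
            M = Ms
            perm[[a, b]] = perm[[b, a]]
            obj += delta
            if obj < best_obj:
                best_obj, best_perm = obj, perm.copy()
        temp *= cooling
    return best_perm
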