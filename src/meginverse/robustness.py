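"""External-noise robustness curves and between-algorithm similarity
with normalized-cuts clustering.

Robustness: i.i.d. Gaussian noise of variance ``sigma2 * trace(C_x)/N_x``
is added to the sensor data, the operator is rebuilt at the correspondingly
reduced predicted SNR, and the reconstruction is correlated (per dipole,
over time, averaged over dipoles) with the noise-free solution. The
standard deviation of that mean correlation across noise levels is the
robustness summary (lower = more robust).

Similarity: the same mean-over-dipoles temporal correlation between the
source estimates of two algorithms; the resulting symmetric matrix is
clustered by recursive spectral normalized cuts (second-smallest
generalized eigenvector of (D - S, D); higher cut cost = stronger cluster).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datatypes import Algorithm, Leadfield, Recording, SourceEstimate
from .crossval import AlgorithmSpec, _build_for_channels

DEFAULT_SIGMA2_GRID = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class RobustnessCurve:
    sigma2_grid: np.ndarray
    correlations: np.ndarray  # mean over dipoles of corr(s_sigma, s_0)
    algorithm: Algorithm

    @property
    def std_across_levels(self) -> float:
        return float(np.std(self.correlations))


@dataclass
class SimilarityMatrix:
    matrix: np.ndarray  # symmetric, unit diagonal, entries in [-1, 1]
    labels: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        self.matrix = 0.5 * (m + m.T)


@dataclass
class CutNode:
    """One node of the recursive-bipartition dendrogram."""

    members: tuple[int, ...]
    cost: float | None = None  # Ncut cost of the split below (None at leaves)
    left: "CutNode | None" = None
    right: "CutNode | None" = None

    def is_leaf(self) -> bool:
        return self.left is None

    def splits(self) -> list[tuple[float, tuple[int, ...], tuple[int, ...]]]:
        out = []
        if not self.is_leaf():
            out.append((self.cost, self.left.members, self.right.members))
            out.extend(self.left.splits())
            out.extend(self.right.splits())
        return out


def add_sensor_noise(rec: Recording, sigma2: float, seed: int) -> Recording:
    """Add i.i.d. Gaussian noise of variance ``sigma2 * trace(C_x)/N_x``
    per channel, where C_x is the sample covariance of the recording."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if sigma2 == 0:
        return Recording(data=rec.data.copy(), fs=rec.fs, kind=rec.kind, seed=seed)
    mean_var = rec.data.var(axis=1, ddof=1).mean()  # = trace(C_x)/N_x
    rng = np.random.default_rng(seed)
    noise = np.sqrt(sigma2 * mean_var) * rng.standard_normal(rec.data.shape)
    return Recording(data=rec.data + noise, fs=rec.fs, kind=rec.kind, seed=seed)


def effective_snr_db(snr_db: float, sigma2: float) -> float:
    """Predicted SNR after adding noise of variance sigma2 * mean data var.

    With prior signal/noise power ratio rho = 10^(snr_db/10), the data
    variance splits as signal rho/(1+rho) and noise 1/(1+rho) of the
    total; the injected noise adds sigma2 of the total, so the new ratio
    is rho / (1 + sigma2 (1 + rho)).
    """
    rho = 10 ** (snr_db / 10)
    return 10 * np.log10(rho / (1 + sigma2 * (1 + rho)))


def _mean_dipole_correlation(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Mean over dipoles of per-dipole temporal Pearson correlation.

    Dipoles with a constant time course in either input are excluded;
    returns (mean corr, n_excluded)."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    ok = (na > 0) & (nb > 0)
    corr = np.einsum("ij,ij->i", ac[ok], bc[ok]) / (na[ok] * nb[ok])
    return float(corr.mean()), int((~ok).sum())


def noise_robustness(
    rec: Recording,
    leadfield: Leadfield,
    spec: AlgorithmSpec,
    sigma2_grid=DEFAULT_SIGMA2_GRID,
    seed: int = 0,
) -> RobustnessCurve:
    """Correlation of noisy-data reconstructions with the noise-free one.

    At each sigma2 the operator is rebuilt at the effective predicted SNR
    (signal variance fixed, noise variance incremented) and applied to the
    noisy data without cross-validation.
    """
    grid = np.asarray(sigma2_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sigma2 grid must be non-empty")
    if grid[0] != 0:
        raise ValueError("sigma2 grid must start at 0 (the reference level)")
    base_op = _build_for_channels(spec, leadfield.matrix, rec.data)
    s0 = base_op.filters @ rec.data
    corrs = np.empty(grid.size)
    corrs[0] = 1.0  # the reference reconstruction correlates perfectly with itself
    # scrambled child seeds: avoids collisions with seeds used elsewhere
    # (e.g. the recording's own noise draw)
    child_seeds = np.random.SeedSequence(seed).generate_state(grid.size)
    for i, sigma2 in enumerate(grid[1:], start=1):
        noisy = add_sensor_noise(rec, sigma2, int(child_seeds[i]))
        eff_spec = AlgorithmSpec(
            algorithm=spec.algorithm,
            snr_db=effective_snr_db(spec.snr_db, sigma2),
            wmne_exponent=spec.wmne_exponent,
        )
        op = _build_for_channels(eff_spec, leadfield.matrix, noisy.data)
        s = op.filters @ noisy.data
        corrs[i], _ = _mean_dipole_correlation(s, s0)
    return RobustnessCurve(sigma2_grid=grid, correlations=corrs, algorithm=spec.algorithm)


def algorithm_similarity(est_a: SourceEstimate, est_b: SourceEstimate) -> float:
    """Mean over dipoles of per-dipole temporal correlation (signed)."""
    if est_a.data.shape != est_b.data.shape:
        raise ValueError("estimates must share dimensions")
    value, _ = _mean_dipole_correlation(est_a.data, est_b.data)
    return value


def similarity_matrix(estimates: dict[str, SourceEstimate]) -> SimilarityMatrix:
    """Pairwise similarity of a set of source estimates (unit diagonal)."""
    labels = list(estimates)
    n = len(labels)
    m = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        v = algorithm_similarity(estimates[labels[i]], estimates[labels[j]])
        m[i, j] = m[j, i] = v
    return SimilarityMatrix(matrix=m, labels=labels)


def ncut_cost(s: np.ndarray, part_a: np.ndarray, part_b: np.ndarray) -> float:
    """Exact normalized-cut cost of a bipartition of weight matrix s."""
    cut = s[np.ix_(part_a, part_b)].sum()
    assoc_a = s[part_a].sum()
    assoc_b = s[part_b].sum()
    if assoc_a == 0 or assoc_b == 0:
        return 0.0
    return float(cut / assoc_a + cut / assoc_b)


def _best_bipartition(s: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Spectral Ncut bipartition with an exact threshold sweep.

    Uses the second-smallest generalized eigenvector of (D - S, D) and
    evaluates the exact Ncut cost of every threshold along its ordering,
    keeping the minimum. Disconnected graphs split along components at
    cost 0.
    """
    n = s.shape[0]
    d = s.sum(axis=1)
    if np.any(d == 0):  # isolated nodes: split them off at zero cost
        iso = np.flatnonzero(d == 0)
        rest = np.setdiff1d(np.arange(n), iso)
        return iso, rest, 0.0
    lap = np.diag(d) - s
    vals, vecs = scipy.linalg.eigh(lap, np.diag(d))
    fiedler = vecs[:, 1]
    order = np.argsort(fiedler, kind="stable")
    best = None
    for cut_at in range(1, n):
        part_a = np.sort(order[:cut_at])
        part_b = np.sort(order[cut_at:])
        cost = ncut_cost(s, part_a, part_b)
        key = (cost, tuple(part_a))
        if best is None or key < best[0]:
            best = (key, part_a, part_b)
    return best[1], best[2], best[0][0]


def normalized_cuts_dendrogram(sim: SimilarityMatrix) -> CutNode:
    """Recursive two-way normalized-cuts clustering of a similarity matrix.

    Negative similarities are floored at zero (Ncut requires non-negative
    weights); the raw matrix is left untouched. Recursion continues to
    singletons, recording the exact Ncut cost of each split.
    """
    s_full = np.maximum(sim.matrix, 0.0)
    np.fill_diagonal(s_full, 0.0)  # self-weights do not affect cuts; drop them

    def recurse(members: np.ndarray) -> CutNode:
        if members.size == 1:
            return CutNode(members=tuple(members.tolist()))
        sub = s_full[np.ix_(members, members)]
        ia, ib, cost = _best_bipartition(sub)
        left = recurse(members[ia])
        right = recurse(members[ib])
        return CutNode(members=tuple(members.tolist()), cost=cost, left=left, right=right)

    return recurse(np.arange(len(sim.labels)))
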