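"""Two-group clustering of unlabeled CN samples.

The primary method is kernel K-means: K-means carried out in the implicit
feature space of a kernel matrix ``M[i, j] = phi(x_i) . phi(x_j)``.  Centers
are never materialized; the squared distance of a point to a cluster center
expands entirely in kernel evaluations,

    ||phi(x_i) - mu_k||^2 = M_ii - 2 * mean_{j in k} M_ij
                                 + mean_{j, l in k} M_jl,

and the stopping rule compares successive implicit centers through the same
expansion.  Lloyd's K-means and Bezdek's fuzzy c-means are provided as the
comparison baselines; with a linear kernel the kernel method reduces
algebraically to Lloyd's algorithm, which the tests exploit as an oracle.

All algorithms take an explicit integer seed (no global RNG), restart from
random balanced partitions, and break distance ties toward the lower cluster
index, so results are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import UnlabeledSampleMatrix


@dataclass
class KernelMatrix:
    """Pairwise kernel evaluations (symmetric PSD), with optional RBF bandwidth."""

    values: np.ndarray
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel matrix must be symmetric (tol 1e-10)")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterAssignment:
    """Hard cluster labels (1..K) plus convergence metadata."""

    labels: np.ndarray
    K: int
    objective: float
    iterations: int
    converged: bool
    seed: int
    restarts_used: int = 1
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    membership: np.ndarray | None = None  # fuzzy c-means only

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels - 1, minlength=self.K)
        if np.any(counts == 0):
            raise ValueError("returned assignment must have no empty cluster")


def _values_of(samples) -> np.ndarray:
    if isinstance(samples, UnlabeledSampleMatrix):
        return samples.values
    return np.asarray(samples, dtype=float)


def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def median_bandwidth(X: np.ndarray) -> float:
    """Median nonzero pairwise Euclidean distance (the median heuristic)."""
    d2 = _pairwise_sq_dists(X)
    iu = np.triu_indices_from(d2, k=1)
    d = np.sqrt(d2[iu])
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all samples identical: median bandwidth undefined")
    return float(np.median(d))


def rbf_kernel(samples, bandwidth: float | str = "median") -> KernelMatrix:
    """Gaussian kernel  exp(-||x_i - x_j||^2 / (2 sigma^2))."""
    X = _values_of(samples)
    if isinstance(bandwidth, str):
        if bandwidth != "median":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        sigma = median_bandwidth(X)
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ValueError("bandwidth must be positive")
    d2 = _pairwise_sq_dists(X)
    M = np.exp(-d2 / (2.0 * sigma * sigma))
    np.fill_diagonal(M, 1.0)
    return KernelMatrix(values=M, bandwidth=sigma)


def linear_kernel(samples) -> KernelMatrix:
    X = _values_of(samples)
    return KernelMatrix(values=X @ X.T, bandwidth=None)


def _balanced_init(N: int, K: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(N)
    labels = np.empty(N, dtype=int)
    labels[perm] = np.arange(N) % K
    return labels


def _check_psd(M: np.ndarray) -> None:
    w = np.linalg.eigvalsh(M)
    if w[0] < -1e-8 * max(1.0, abs(w[-1])):
        raise ValueError(f"kernel matrix is not PSD (min eigenvalue {w[0]:.3e})")


class _KernelGeometry:
    """Distance/objective computations against implicit kernel-space centers."""

    def __init__(self, M: np.ndarray, K: int):
        self.M = M
        self.K = K
        self.diag = np.diag(M).copy()

    def distances(self, labels: np.ndarray) -> np.ndarray:
        N = self.M.shape[0]
        d2 = np.empty((N, self.K))
        for k in range(self.K):
            idx = labels == k
            nk = int(idx.sum())
            if nk == 0:
                d2[:, k] = np.inf
                continue
            rowmean = self.M[:, idx].mean(axis=1)
            within = self.M[np.ix_(idx, idx)].mean()
            d2[:, k] = self.diag - 2.0 * rowmean + within
        return d2

    def objective(self, labels: np.ndarray) -> float:
        total = 0.0
        for k in range(self.K):
            idx = labels == k
            nk = int(idx.sum())
            if nk:
                total += self.diag[idx].sum() - self.M[np.ix_(idx, idx)].sum() / nk
        return float(total)

    def center_shift_sq(self, old: np.ndarray, new: np.ndarray) -> float:
        """max_k ||mu_k(new) - mu_k(old)||^2 via kernel expansions."""
        worst = 0.0
        for k in range(self.K):
            a = new == k
            b = old == k
            na, nb = int(a.sum()), int(b.sum())
            if na == 0 or nb == 0:
                return np.inf
            aa = self.M[np.ix_(a, a)].mean()
            bb = self.M[np.ix_(b, b)].mean()
            ab = self.M[np.ix_(a, b)].mean()
            worst = max(worst, aa - 2.0 * ab + bb)
        return worst


class _EuclideanGeometry:
    """The same interface in input space, for Lloyd's algorithm."""

    def __init__(self, X: np.ndarray, K: int):
        self.X = X
        self.K = K
        self.sq = np.sum(X * X, axis=1)

    def _centers(self, labels: np.ndarray) -> np.ndarray:
        C = np.empty((self.K, self.X.shape[1]))
        for k in range(self.K):
            idx = labels == k
            C[k] = self.X[idx].mean(axis=0) if idx.any() else np.nan
        return C

    def distances(self, labels: np.ndarray) -> np.ndarray:
        C = self._centers(labels)
        d2 = self.sq[:, None] - 2.0 * (self.X @ C.T) + np.sum(C * C, axis=1)[None, :]
        d2 = np.where(np.isnan(d2), np.inf, d2)
        np.maximum(d2, 0.0, out=d2)
        return d2

    def objective(self, labels: np.ndarray) -> float:
        C = self._centers(labels)
        diffs = self.X - C[labels]
        return float(np.sum(diffs * diffs))

    def center_shift_sq(self, old: np.ndarray, new: np.ndarray) -> float:
        Co, Cn = self._centers(old), self._centers(new)
        if np.any(np.isnan(Co)) or np.any(np.isnan(Cn)):
            return np.inf
        return float(np.max(np.sum((Cn - Co) ** 2, axis=1)))


def _repair_empty(labels: np.ndarray, d2: np.ndarray, K: int) -> np.ndarray:
    """Move the worst-fitting point into each empty cluster."""
    labels = labels.copy()
    for k in range(K):
        if np.any(labels == k):
            continue
        own = d2[np.arange(labels.size), labels]
        # never empty a singleton cluster in the process
        counts = np.bincount(labels, minlength=K)
        movable = counts[labels] > 1
        own = np.where(movable, own, -np.inf)
        labels[int(np.argmax(own))] = k
    return labels


def _alternate(geom, labels0: np.ndarray, epsilon: float, max_iter: int):
    """Shared Lloyd-type alternation; returns (labels, obj, iters, converged, history)."""
    prev = labels0.copy()
    obj_prev = geom.objective(prev)
    history = [obj_prev]
    converged = False
    iters = 0
    for iters in range(1, max_iter + 1):
        d2 = geom.distances(prev)
        new = np.argmin(d2, axis=1)  # ties -> lower cluster index
        if np.any(np.bincount(new, minlength=geom.K) == 0):
            new = _repair_empty(new, d2, geom.K)
        if np.array_equal(new, prev):
            converged = True
            break
        obj_new = geom.objective(new)
        if obj_new > obj_prev + 1e-9:
            # can only happen after an empty-cluster repair; keep the better state
            converged = True
            break
        shift = geom.center_shift_sq(prev, new)
        prev, obj_prev = new, obj_new
        history.append(obj_prev)
        if shift < epsilon:
            converged = True
            break
    return prev, obj_prev, iters, converged, np.array(history)


def _run_restarts(geom, N: int, K: int, seed: int, epsilon: float, max_iter: int,
                  restarts: int, init_labels) -> ClusterAssignment:
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > N:
        raise ValueError(f"K = {K} exceeds the number of samples ({N})")
    rng = np.random.default_rng(seed)
    if init_labels is not None:
        inits = [np.asarray(init_labels, dtype=int).copy()]
    else:
        inits = [_balanced_init(N, K, rng) for _ in range(max(1, restarts))]
    best = None
    for labels0 in inits:
        labels, obj, iters, conv, hist = _alternate(geom, labels0, epsilon, max_iter)
        if best is None or obj < best[1] - 1e-12:
            best = (labels, obj, iters, conv, hist)
    labels, obj, iters, conv, hist = best
    return ClusterAssignment(
        labels=labels + 1,
        K=K,
        objective=obj,
        iterations=iters,
        converged=conv,
        seed=seed,
        restarts_used=len(inits),
        objective_history=hist,
    )


def kernel_kmeans(kernel: KernelMatrix, K: int, seed: int, epsilon: float = 1e-6,
                  max_iter: int = 300, restarts: int = 10,
                  init_labels: np.ndarray | None = None,
                  check_psd: bool = True) -> ClusterAssignment:
    """Kernel K-means on a precomputed kernel matrix."""
    M = kernel.values if isinstance(kernel, KernelMatrix) else np.asarray(kernel, dtype=float)
    if check_psd:
        _check_psd(M)
    geom = _KernelGeometry(M, K)
    return _run_restarts(geom, M.shape[0], K, seed, epsilon, max_iter, restarts, init_labels)


def lloyd_kmeans(samples, K: int, seed: int, epsilon: float = 1e-6,
                 max_iter: int = 300, restarts: int = 10,
                 init_labels: np.ndarray | None = None) -> ClusterAssignment:
    """Standard Lloyd iteration in input space (baseline)."""
    X = _values_of(samples)
    geom = _EuclideanGeometry(X, K)
    return _run_restarts(geom, X.shape[0], K, seed, epsilon, max_iter, restarts, init_labels)


def fuzzy_cmeans(samples, K: int, seed: int, fuzzifier: float = 2.0,
                 epsilon: float = 1e-6, max_iter: int = 300) -> ClusterAssignment:
    """Bezdek fuzzy c-means; hard labels by maximal membership (baseline).

    Iterates the membership/center update equations until the largest
    membership change falls below ``epsilon``.  A sample coinciding with a
    center receives full membership there (split equally over coincident
    centers).
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    X = _values_of(samples)
    N = X.shape[0]
    if K < 2 or K > N:
        raise ValueError("need 2 <= K <= number of samples")
    rng = np.random.default_rng(seed)
    U = rng.random((N, K))
    U /= U.sum(axis=1, keepdims=True)
    expo = 2.0 / (fuzzifier - 1.0)
    converged = False
    iters = 0
    d2 = np.zeros((N, K))
    for iters in range(1, max_iter + 1):
        W = U**fuzzifier
        centers = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = (
            np.sum(X * X, axis=1)[:, None]
            - 2.0 * (X @ centers.T)
            + np.sum(centers * centers, axis=1)[None, :]
        )
        np.maximum(d2, 0.0, out=d2)
        zero = d2 <= 1e-300
        Unew = np.empty_like(U)
        with np.errstate(divide="ignore"):
            inv = d2 ** (-expo / 2.0)
        rows_zero = zero.any(axis=1)
        Unew[~rows_zero] = inv[~rows_zero] / inv[~rows_zero].sum(axis=1, keepdims=True)
        if rows_zero.any():
            Unew[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(axis=1, keepdims=True)
        delta = float(np.max(np.abs(Unew - U)))
        U = Unew
        if delta < epsilon:
            converged = True
            break
    labels = np.argmax(U, axis=1)  # ties -> lower cluster index
    objective = float(np.sum((U**fuzzifier) * d2))
    return ClusterAssignment(
        labels=labels + 1,
        K=K,
        objective=objective,
        iterations=iters,
        converged=converged,
        seed=seed,
        restarts_used=1,
        membership=U,
    )


def write_assignment(assignment: ClusterAssignment, sample_ids: list[str], path) -> None:
    with open(path, "w") as fh:
        if assignment.membership is None:
            fh.write("sample_id\tcluster\n")
            for sid, lab in zip(sample_ids, assignment.labels):
                fh.write(f"{sid}\t{lab}\n")
        else:
            K = assignment.K
            header = "\t".join(f"membership_{k + 1}" for k in range(K))
            fh.write(f"sample_id\tcluster\t{header}\n")
            for sid, lab, row in zip(sample_ids, assignment.labels, assignment.membership):
                mem = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{sid}\t{lab}\t{mem}\n")
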