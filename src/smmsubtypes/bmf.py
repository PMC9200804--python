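"""Binary matrix factorization (BMF).

Approximates a binary patients x features matrix X by binary factors
W (patients x K) and H (K x features). The solver is a penalty method:
continuous non-negative factors are optimized by multiplicative updates on

    ||X - WH||_F^2 + lambda * (||W*W - W||_F^2 + ||H*H - H||_F^2)

with the binariness penalty weight lambda increased on a fixed schedule, and
the factors thresholded at the end. The reconstruction is re-binarized as
(WH >= 0.5), so the reported residual is an exact Hamming count of mismatched
cells — an integer a brute-force oracle can reproduce on small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alterations import AlterationMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class BMFConfig:
    """Solver settings.

    ``lambda_init`` grows by ``lambda_factor`` every ``lambda_every``
    iterations up to ``lambda_max``; each constant-lambda stretch is a
    "phase" inside which the continuous objective is non-increasing.
    """

    K: int
    max_iter: int = 500
    tol: float = 1e-6
    lambda_init: float = 0.1
    lambda_factor: float = 10.0
    lambda_every: int = 50
    lambda_max: float = 1e4
    threshold: float = 0.5
    polish: bool = True
    loading_refit_iter: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.lambda_factor <= 1 or self.lambda_init <= 0:
            raise ValueError("lambda schedule must be strictly increasing")


@dataclass
class BMFResult:
    """One factorization run.

    ``W``/``H`` are the thresholded binary factors; ``W_cont``/``H_cont``
    the continuous factors before thresholding (used for generalized K-L
    diagnostics). ``loadings`` holds calibrated continuous patient loadings:
    W refit against the final dictionary by least-squares multiplicative
    updates with no binariness penalty, which is what cluster assignment
    uses. ``residual`` is the integer count of cells where (WH >= 0.5)
    disagrees with X.
    """

    W: np.ndarray
    H: np.ndarray
    W_cont: np.ndarray
    H_cont: np.ndarray
    loadings: np.ndarray
    residual: int
    variance_explained: float
    n_iter: int
    converged: bool
    seed: int
    objective_trace: np.ndarray = field(repr=False, default=None)
    lambda_trace: np.ndarray = field(repr=False, default=None)

    @property
    def K(self) -> int:
        return self.W.shape[1]


def _objective(X: np.ndarray, W: np.ndarray, H: np.ndarray, lam: float) -> float:
    R = X - W @ H
    pen = np.sum((W * W - W) ** 2) + np.sum((H * H - H) ** 2)
    return float(np.sum(R * R) + lam * pen)


def bmf_fit(X: AlterationMatrix | np.ndarray, config: BMFConfig) -> BMFResult:
    """Fit binary factors to a binary matrix.

    Deterministic for a fixed seed: factors are initialized i.i.d.
    Uniform(0.1, 0.9) from the seeded generator (strictly positive, as
    multiplicative updates require) and all updates are closed-form.
    """
    Xa = X.values if isinstance(X, AlterationMatrix) else np.asarray(X)
    Xa = Xa.astype(float)
    n, m = Xa.shape
    K = config.K
    if K > min(n, m):
        raise ValueError(f"K={K} exceeds matrix dimensions {n}x{m}")
    total = Xa.sum()
    if total == 0:
        raise ValueError("all-zero matrix is degenerate for factorization")

    rng = np.random.default_rng(config.seed)
    W = rng.uniform(0.1, 0.9, size=(n, K))
    H = rng.uniform(0.1, 0.9, size=(K, m))

    # lambda schedule: one phase per constant-lambda stretch
    lambdas: list[float] = []
    lam = config.lambda_init
    while lam < config.lambda_max:
        lambdas.append(lam)
        lam *= config.lambda_factor
    lambdas.append(config.lambda_max)

    trace: list[float] = []
    lam_trace: list[float] = []
    n_iter = 0
    converged = False
    for phase, lam in enumerate(lambdas):
        last_phase = phase == len(lambdas) - 1
        # final phase runs until max_iter; earlier phases get lambda_every
        budget = (config.max_iter - n_iter) if last_phase else min(
            config.lambda_every, config.max_iter - n_iter
        )
        prev = _objective(Xa, W, H, lam)
        for _ in range(budget):
            numW = Xa @ H.T + 3.0 * lam * W**2
            denW = W @ (H @ H.T) + 2.0 * lam * W**3 + lam * W
            W = W * numW / np.maximum(denW, _EPS)
            numH = W.T @ Xa + 3.0 * lam * H**2
            denH = (W.T @ W) @ H + 2.0 * lam * H**3 + lam * H
            H = H * numH / np.maximum(denH, _EPS)
            obj = _objective(Xa, W, H, lam)
            trace.append(obj)
            lam_trace.append(lam)
            n_iter += 1
            if abs(prev - obj) <= config.tol * max(prev, _EPS):
                if last_phase:
                    converged = True
                break
            prev = obj
        if n_iter >= config.max_iter:
            break
    Wb = (W >= config.threshold).astype(np.int8)
    Hb = (H >= config.threshold).astype(np.int8)
    if config.polish:
        Wb, Hb = _polish_factors(Xa.astype(np.int8), Wb, Hb)
    recon = ((Wb.astype(int) @ Hb.astype(int)) >= 0.5).astype(np.int8)
    residual = int(np.sum(np.abs(Xa - recon)))
    # calibrate continuous per-patient loadings on the learned dictionary:
    # W-only least-squares multiplicative updates, H fixed, no penalty
    loadings = np.maximum(W, 1e-6)
    HHt = H @ H.T
    XHt = Xa @ H.T
    for _ in range(config.loading_refit_iter):
        loadings = loadings * XHt / np.maximum(loadings @ HHt, _EPS)
    return BMFResult(
        W=Wb,
        H=Hb,
        W_cont=W,
        H_cont=H,
        loadings=loadings,
        residual=residual,
        variance_explained=1.0 - residual / total,
        n_iter=n_iter,
        converged=converged,
        seed=config.seed,
        objective_trace=np.asarray(trace),
        lambda_trace=np.asarray(lam_trace),
    )


def _polish_factors(
    X: np.ndarray, W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy bit-flip refinement of thresholded factors.

    Repeatedly applies, per sweep, the best residual-reducing flip in each
    row of W (row flips are mutually independent) and then in each column of
    H, until no single flip lowers the Hamming residual of the (WH >= 0.5)
    reconstruction. Each sweep strictly decreases the residual, so
    termination is guaranteed.
    """
    X = X.astype(np.int16)
    W = W.astype(np.int16).copy()
    H = H.astype(np.int16).copy()
    C = W @ H  # coverage counts; reconstruction is C >= 1
    while True:
        improved = False
        # W flips: flipping W[i, k] changes only row i by +/- H[k]
        row_mism = ((C >= 1) != X).sum(axis=1)
        sW = 1 - 2 * W  # +1 for 0->1 flips, -1 for 1->0
        Cn = C[:, None, :] + sW[:, :, None] * H[None, :, :]
        delta = ((Cn >= 1) != X[:, None, :]).sum(axis=2) - row_mism[:, None]
        best_k = np.argmin(delta, axis=1)
        rows = np.flatnonzero(delta[np.arange(len(best_k)), best_k] < 0)
        if rows.size:
            improved = True
            for i in rows:
                k = best_k[i]
                C[i] += sW[i, k] * H[k]
                W[i, k] ^= 1
        # H flips: flipping H[k, j] changes only column j by +/- W[:, k]
        col_mism = ((C >= 1) != X).sum(axis=0)
        sH = 1 - 2 * H
        Cn = C[None, :, :] + sH[:, None, :] * W.T[:, :, None]
        delta = ((Cn >= 1) != X[None, :, :]).sum(axis=1) - col_mism[None, :]
        best_k = np.argmin(delta, axis=0)
        cols = np.flatnonzero(delta[best_k, np.arange(len(best_k))] < 0)
        if cols.size:
            improved = True
            for j in cols:
                k = best_k[j]
                C[:, j] += sH[k, j] * W[:, k]
                H[k, j] ^= 1
        if not improved:
            return W.astype(np.int8), H.astype(np.int8)


def bmf_residual_bruteforce(X: np.ndarray, K: int) -> int:
    """Exhaustive-search optimum Hamming residual over all binary W, H.

    Enumerates every binary W (n x K) and H (K x m) with the (WH >= 0.5)
    reconstruction; only feasible for small matrices (n*K + K*m <~ 20).
    Serves as the independent oracle for :func:`bmf_fit` on tiny instances.
    """
    X = np.asarray(X, dtype=np.int8)
    n, m = X.shape
    if n * K > 16 or K * m > 16:
        raise ValueError("matrix too large for exhaustive enumeration")
    Ws = _all_binary(n, K)
    Hs = _all_binary(K, m)
    best = n * m + 1
    for W in Ws:
        WH = np.tensordot(W, Hs, axes=([1], [1]))  # (n, nH, m)
        recon = (WH >= 0.5).astype(np.int8).transpose(1, 0, 2)
        mism = np.abs(recon - X[None, :, :]).sum(axis=(1, 2))
        best = min(best, int(mism.min()))
    return best


def _all_binary(r: int, c: int) -> np.ndarray:
    count = 1 << (r * c)
    bits = ((np.arange(count)[:, None] >> np.arange(r * c)[None, :]) & 1).astype(np.int8)
    return bits.reshape(count, r, c)


def assign_from_factors(
    W_cont: np.ndarray,
    H: np.ndarray | None = None,
    profiles: np.ndarray | None = None,
) -> np.ndarray:
    """Hard cluster labels from continuous patient loadings.

    Each patient gets the index of its maximal pre-threshold loading, ties
    broken by the lowest cluster index. Patients whose loadings are all zero
    are assigned to the nearest binary H row in Hamming distance over their
    raw profile (requires ``H`` and ``profiles``); such rows are flagged with
    a warning.
    """
    W_cont = np.asarray(W_cont, dtype=float)
    labels = np.argmax(W_cont, axis=1)
    zero_rows = np.flatnonzero(W_cont.max(axis=1) <= 0)
    if zero_rows.size:
        if H is None or profiles is None:
            logger.warning(
                "%d all-zero loading rows assigned to cluster 0 (no H/profiles "
                "given for Hamming fallback)",
                zero_rows.size,
            )
        else:
            Hb = np.asarray(H, dtype=int)
            P = np.asarray(profiles, dtype=int)
            for i in zero_rows:
                dists = np.abs(Hb - P[i][None, :]).sum(axis=1)
                labels[i] = int(np.argmin(dists))
            logger.warning(
                "%d all-zero loading rows assigned by Hamming distance to H",
                zero_rows.size,
            )
    return labels.astype(int)


def write_factors(result: BMFResult, w_path, h_path) -> None:
    """Export binary factors as TSV with '#'-prefixed metadata headers."""
    meta = (
        f"# seed={result.seed} K={result.K} residual={result.residual} "
        f"variance_explained={result.variance_explained:.6f}\n"
    )
    for path, mat in ((w_path, result.W), (h_path, result.H)):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(meta)
            for row in mat:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")
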