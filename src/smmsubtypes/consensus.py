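"""Consensus subtyping over repeated BMF runs.

Repeated seeded BMF restarts yield per-run hard labels; the consensus matrix
records, for each pair of patients, the fraction of runs in which they were
co-assigned. Final subtypes come from hierarchical clustering of the
consensus matrix rows (Euclidean distance, Ward linkage). K-selection
diagnostics combine silhouette scores on Dice dissimilarities of the raw
binary profiles with factorization residuals, variance explained, and
generalized Kullback-Leibler divergence, optionally on random downsamples of
the cohort to probe stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .alterations import AlterationMatrix
from .bmf import BMFConfig, BMFResult, assign_from_factors, bmf_fit

logger = logging.getLogger(__name__)


def dice_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dice dissimilarity 1 - 2|a&b| / (|a| + |b|) between binary vectors.

    Defined as 0 when both vectors are all-zero (identical empty profiles).
    """
    a = np.asarray(a, dtype=int).ravel()
    b = np.asarray(b, dtype=int).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * int(np.sum(a & b)) / denom


def dice_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Dice dissimilarities between the rows of a binary matrix."""
    X = np.asarray(X, dtype=float)
    inter = X @ X.T
    sums = X.sum(axis=1)
    denom = sums[:, None] + sums[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 - 2.0 * inter / denom
    D[denom == 0] = 0.0
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class ConsensusResult:
    """Co-assignment frequencies plus the hierarchical cut at the run K."""

    consensus: np.ndarray
    labels: np.ndarray
    K: int
    n_runs: int
    seed: int
    best_run: BMFResult = field(repr=False, default=None)
    mean_residual: float = float("nan")
    mean_variance_explained: float = float("nan")


def _run_seeds(seed: int, n_runs: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_runs)]


def build_consensus(
    X: AlterationMatrix | np.ndarray,
    K: int,
    n_runs: int = 100,
    seed: int = 0,
    bmf_config: BMFConfig | None = None,
) -> ConsensusResult:
    """Consensus matrix from ``n_runs`` seeded BMF restarts at rank K.

    consensus(i, j) is the fraction of runs assigning i and j the same
    label; every patient appears in every run, so the diagonal is exactly 1.
    Deterministic for a fixed master seed.
    """
    if n_runs < 2:
        raise ValueError("consensus needs at least 2 runs")
    Xa = X.values if isinstance(X, AlterationMatrix) else np.asarray(X)
    n = Xa.shape[0]
    counts = np.zeros((n, n))
    best: BMFResult | None = None
    residuals = []
    varexps = []
    base = bmf_config or BMFConfig(K=K)
    for run_seed in _run_seeds(seed, n_runs):
        cfg = replace(base, K=K, seed=run_seed)
        result = bmf_fit(Xa, cfg)
        labels = assign_from_factors(result.loadings, result.H, Xa)
        counts += labels[:, None] == labels[None, :]
        residuals.append(result.residual)
        varexps.append(result.variance_explained)
        if best is None or result.residual < best.residual:
            best = result
    consensus = counts / n_runs
    labels = cut_consensus(consensus, K)
    return ConsensusResult(
        consensus=consensus,
        labels=labels,
        K=K,
        n_runs=n_runs,
        seed=seed,
        best_run=best,
        mean_residual=float(np.mean(residuals)),
        mean_variance_explained=float(np.mean(varexps)),
    )


def cut_consensus(consensus: np.ndarray, K: int) -> np.ndarray:
    """Ward/Euclidean hierarchical cut of consensus-matrix rows into K groups.

    Cluster ids are canonicalized 0..K-1 by decreasing cluster size (ties by
    lowest original id), so labels are stable across equivalent runs.
    """
    consensus = np.asarray(consensus, dtype=float)
    n = consensus.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of patients {n}")
    if K == 1:
        return np.zeros(n, dtype=int)
    Z = linkage(consensus, method="ward", metric="euclidean")
    raw = fcluster(Z, t=K, criterion="maxclust") - 1
    return canonicalize_labels(raw)


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 by decreasing size, ties by lowest original id."""
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    mapping = {ids[i]: rank for rank, i in enumerate(order)}
    return np.array([mapping[l] for l in labels], dtype=int)


def generalized_kl(X: np.ndarray, Y: np.ndarray, clamp: float = 1e-12) -> float:
    """Generalized K-L divergence D(X || Y) = sum x*log(x/y) - x + y.

    0*log 0 := 0 and y is clamped at ``clamp``; computed on the continuous
    reconstruction WH before thresholding.
    """
    X = np.asarray(X, dtype=float)
    Y = np.maximum(np.asarray(Y, dtype=float), clamp)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X > 0, X * np.log(X / Y), 0.0)
    return float(np.sum(term - X + Y))


@dataclass
class KDiagnostics:
    """Tidy per-(K, size, replicate) diagnostic table with aggregates."""

    table: pd.DataFrame
    k_range: list[int]
    n_runs: int
    seed: int

    def aggregate(self) -> pd.DataFrame:
        return (
            self.table.groupby(["K", "size"])[
                ["silhouette", "residual", "variance_explained", "kl"]
            ]
            .agg(["mean", "var"])
            .reset_index()
        )

    def full_size_means(self) -> pd.DataFrame:
        full = self.table["size"] == self.table["size"].max()
        return (
            self.table[full]
            .groupby("K")[["silhouette", "residual", "variance_explained", "kl"]]
            .mean()
            .reset_index()
        )


def k_diagnostics(
    X: AlterationMatrix | np.ndarray,
    k_range=range(2, 11),
    n_runs: int = 20,
    downsample_sizes: list[int] | None = None,
    n_downsamples: int = 3,
    seed: int = 0,
    bmf_config: BMFConfig | None = None,
) -> KDiagnostics:
    """Sweep K, computing consensus-cut silhouette (Dice on raw profiles),
    mean factorization residual and variance explained, and the generalized
    K-L divergence of the best-residual run.

    ``downsample_sizes`` adds replicated without-replacement subsamples per
    size (the full cohort is always included as its own size), so variance
    across replicates measures stability at each cohort size.
    """
    Xa = X.values if isinstance(X, AlterationMatrix) else np.asarray(X)
    n = Xa.shape[0]
    k_range = list(k_range)
    sizes = sorted(set(downsample_sizes or []))
    if any(s >= n for s in sizes):
        raise ValueError(f"downsample sizes must be < cohort size {n}")
    if sizes and min(sizes) < max(k_range) + 1:
        raise ValueError("downsample sizes must be >= max(K) + 1")
    rng = np.random.default_rng(seed)
    rows = []
    jobs: list[tuple[int, np.ndarray]] = [(n, np.arange(n))]
    for s in sizes:
        for _ in range(n_downsamples):
            jobs.append((s, rng.choice(n, size=s, replace=False)))
    for rep, (size, idx) in enumerate(jobs):
        sub = Xa[idx, :]
        D = dice_matrix(sub)
        for K in k_range:
            res = build_consensus(
                sub,
                K,
                n_runs=n_runs,
                seed=int(rng.integers(2**31)),
                bmf_config=bmf_config,
            )
            labels = res.labels
            if len(np.unique(labels)) > 1:
                sil = float(silhouette_score(D, labels, metric="precomputed"))
            else:
                sil = float("nan")
            best = res.best_run
            kl = generalized_kl(sub, best.W_cont @ best.H_cont)
            rows.append(
                {
                    "K": K,
                    "size": size,
                    "replicate": rep,
                    "silhouette": sil,
                    "residual": res.mean_residual,
                    "variance_explained": res.mean_variance_explained,
                    "best_residual": best.residual,
                    "best_variance_explained": best.variance_explained,
                    "kl": kl,
                }
            )
    return KDiagnostics(
        table=pd.DataFrame(rows), k_range=k_range, n_runs=n_runs, seed=seed
    )


@dataclass
class KSelection:
    K: int
    rationale: str
    table: pd.DataFrame


def select_k(diagnostics: KDiagnostics, silhouette_floor: float = 0.9) -> KSelection:
    """Pick K by the largest drop in mean K-L divergence.

    Default rule (overridable by inspecting the emitted table): among
    candidate K whose mean silhouette is at least ``silhouette_floor`` times
    the maximum over the range, choose the K with the largest decrease in
    mean K-L divergence relative to K-1. A single candidate is returned
    as-is. The rule captures the elbow where adding one more component stops
    buying reconstruction quality while cluster cohesion is still high.
    """
    means = diagnostics.full_size_means().sort_values("K").reset_index(drop=True)
    if len(means) == 0:
        raise ValueError("empty diagnostics")
    if len(means) == 1:
        k = int(means.loc[0, "K"])
        return KSelection(K=k, rationale="single candidate K", table=means)
    sil = means["silhouette"].to_numpy()
    sil_max = np.nanmax(sil)
    eligible = sil >= silhouette_floor * sil_max
    drops = np.full(len(means), -np.inf)
    kl = means["kl"].to_numpy()
    drops[1:] = kl[:-1] - kl[1:]
    drops[~eligible] = -np.inf
    if not np.isfinite(drops).any():
        # no eligible K with a predecessor: fall back to best silhouette
        k = int(means.loc[int(np.nanargmax(sil)), "K"])
        return KSelection(K=k, rationale="silhouette maximum (no K-L drop eligible)", table=means)
    best = int(np.argmax(drops))
    k = int(means.loc[best, "K"])
    return KSelection(
        K=k,
        rationale=(
            f"largest K-L drop ({drops[best]:.3f}) from K={k - 1} to K={k} with "
            f"silhouette {sil[best]:.3f} >= {silhouette_floor:.0%} of max {sil_max:.3f}"
        ),
        table=means,
    )
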