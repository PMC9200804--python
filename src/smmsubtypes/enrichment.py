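"""Cluster characterization by one-sided Fisher enrichment.

For every (cluster, feature) pair a 2x2 table is formed — in-cluster
carriers (a), in-cluster non-carriers (b), out-of-cluster carriers (c),
out-of-cluster non-carriers (d) — and tested for positive association with a
one-sided (greater) Fisher exact test. Within each cluster, p-values are
Benjamini-Hochberg adjusted and features ranked by significance; a feature
is called enriched when q < 0.1.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .alterations import AlterationMatrix

logger = logging.getLogger(__name__)

Q_THRESHOLD = 0.1


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p: P(X >= a) for X hypergeometric with
    population a+b+c+d, a+c successes, and a+b draws."""
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValueError(f"count {name}={v!r} must be a non-negative integer")
    a, b, c, d = int(a), int(b), int(c), int(d)
    total = a + b + c + d
    if total < 1:
        raise ValueError("table total must be >= 1")
    return float(hypergeom.sf(a - 1, total, a + c, a + b))


def fisher_one_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: the same upper tail by explicit enumeration of
    hypergeometric probabilities from binomial coefficients."""
    from math import comb

    a, b, c, d = int(a), int(b), int(c), int(d)
    total, succ, draws = a + b + c + d, a + c, a + b
    denom = comb(total, draws)
    hi = min(succ, draws)
    return sum(comb(succ, k) * comb(total - succ, draws - k) for k in range(a, hi + 1)) / denom


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order. Applied once; re-application to its own output is not a
    supported operation.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with Haldane-Anscombe 0.5 correction
    whenever any cell is zero (display value; tests use exact counts)."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    return float((a_ * d_) / (b_ * c_))


def enrich_clusters(
    X: AlterationMatrix,
    labels: Sequence[int],
    family: str = "per_cluster",
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-(cluster, feature) enrichment table.

    ``family`` selects the BH family: ``per_cluster`` (default; adjusts
    across features within one cluster, matching a per-cluster ranked
    readout) or ``global`` (one family over all cluster-feature pairs).
    Rows are ranked within cluster by ascending q then ascending p.
    Clusters with fewer than 2 patients are emitted with p = 1 and a
    warning.
    """
    if family not in ("per_cluster", "global"):
        raise ValueError("family must be 'per_cluster' or 'global'")
    labels = np.asarray(labels)
    if labels.shape[0] != X.n_patients:
        raise ValueError("labels must cover all patients")
    rows = []
    values = X.values
    prevalence = values.sum(axis=0)
    for cluster in np.unique(labels):
        mask = labels == cluster
        size = int(mask.sum())
        degenerate = size < 2
        if degenerate:
            logger.warning("cluster %s has %d patient(s); p set to 1", cluster, size)
        in_counts = values[mask].sum(axis=0)
        for j, fid in enumerate(X.feature_ids):
            a = int(in_counts[j])
            b = size - a
            c = int(prevalence[j]) - a
            d = X.n_patients - size - c
            p = 1.0 if degenerate else fisher_one_sided(a, b, c, d)
            rows.append(
                {
                    "cluster": cluster,
                    "feature": fid,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds_ratio(a, b, c, d),
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if family == "global":
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = np.nan
        for cluster in table["cluster"].unique():
            mask = table["cluster"] == cluster
            table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    table["enriched"] = table["q"] < q_threshold
    table = (
        table.sort_values(["cluster", "q", "p", "feature"], kind="stable")
        .reset_index(drop=True)
    )
    return table
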