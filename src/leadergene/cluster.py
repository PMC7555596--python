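"""Univariate clustering of the WNL spectrum and its statistical verification.

Three pieces:

* :func:`kmeans_1d_exact` — optimal univariate k-means.  In one dimension the
  clusters of a within-sum-of-squares optimum are contiguous intervals of the
  sorted data, so the global optimum is computable by dynamic programming over
  the distinct values (weighted by multiplicity).  This removes all
  initialisation randomness from the clustering step: only the gap statistic's
  reference draws are stochastic.

* :func:`gap_select_k` — Tibshirani gap statistic for choosing k.  For each k
  the log within-dispersion of the data is compared with its expectation under
  B reference datasets drawn uniformly on [min, max] of the observed values;
  the smallest k whose gap is within one standard error of the next gap is
  selected, falling back to the argmax of the gap when no k satisfies the
  rule (a "no structure" outcome, flagged in warnings).

* :func:`kruskal_wallis` — rank-based H test (tie-corrected, chi-square
  approximation with df = groups - 1) verifying that the clusters really do
  differ in WNL.

:func:`label_clusters` finally names clusters "A", "B", ... by strictly
descending WNL centroid and appends the orphan class; cluster "A" holds the
leader genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Clustering",
    "ClusterLabeling",
    "GapCurve",
    "KWResult",
    "cluster_labels_iter",
    "gap_select_k",
    "kmeans_1d_exact",
    "kruskal_wallis",
    "label_clusters",
    "wss_profile",
]


# ---------------------------------------------------------------------------
# exact 1-D k-means


@dataclass(frozen=True)
class Clustering:
    """Optimal 1-D k-means partition.

    ``labels[i]`` is the cluster index of ``values[i]`` in the original input
    order; indices run 0..k-1 in ascending centroid order, so clusters are
    contiguous intervals of the sorted data.
    """

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray
    within_ss: float


def _segment_cost(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """cost[i, j] = weighted within-SS of x[i..j] (upper triangle)."""
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cs = np.concatenate(([0.0], np.cumsum(w * x)))
    cs2 = np.concatenate(([0.0], np.cumsum(w * x * x)))
    W = cw[None, 1:] - cw[:-1, None]
    S = cs[None, 1:] - cs[:-1, None]
    S2 = cs2[None, 1:] - cs2[:-1, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = S2 - np.where(W > 0, S * S / np.where(W > 0, W, 1.0), 0.0)
    return np.maximum(cost, 0.0)  # clip float fuzz


def _dp(x: np.ndarray, w: np.ndarray, kmax: int):
    """DP tables for optimal partitions of weighted distinct values.

    Returns (D, split) where D[k-1, j] is the optimal within-SS of x[0..j]
    using k clusters and split[k-1, j] the start index of the last cluster.
    """
    m = len(x)
    cost = _segment_cost(x, w)
    D = np.full((kmax, m), np.inf)
    split = np.zeros((kmax, m), dtype=np.intp)
    D[0] = cost[0]
    for k in range(1, kmax):
        for j in range(k, m):
            cand = D[k - 1, k - 1 : j] + cost[k : j + 1, j]
            i = int(np.argmin(cand))
            D[k, j] = cand[i]
            split[k, j] = i + k
    return D, split


def kmeans_1d_exact(values: Sequence[float], k: int) -> Clustering:
    """Globally optimal univariate k-means by dynamic programming.

    Deterministic; requires ``1 <= k <= #distinct(values)`` (with k above the
    number of distinct values no partition with k distinct centroids exists).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    k = int(k)
    uniq, counts = np.unique(vals, return_counts=True)
    m = len(uniq)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > m:
        raise ValueError(
            f"k exceeds distinct values (k={k}, distinct={m})"
        )

    D, split = _dp(uniq, counts.astype(float), k)
    # backtrack segment boundaries over the distinct values
    bounds = np.empty(k + 1, dtype=np.intp)
    bounds[k] = m
    j = m - 1
    for kk in range(k - 1, -1, -1):
        start = split[kk, j] if kk > 0 else 0
        bounds[kk] = start
        j = start - 1

    uniq_label = np.empty(m, dtype=np.intp)
    centroids = np.empty(k)
    sizes = np.empty(k, dtype=np.intp)
    for c in range(k):
        lo, hi = bounds[c], bounds[c + 1]
        uniq_label[lo:hi] = c
        seg_w = counts[lo:hi]
        centroids[c] = np.average(uniq[lo:hi], weights=seg_w)
        sizes[c] = seg_w.sum()
    labels = uniq_label[np.searchsorted(uniq, vals)]
    return Clustering(
        k=k,
        labels=labels,
        centroids=centroids,
        sizes=sizes,
        within_ss=float(D[k - 1, m - 1]),
    )


def wss_profile(values: Sequence[float], kmax: int) -> np.ndarray:
    """Optimal within-SS for k = 1..kmax in one DP pass.

    ``kmax`` may not exceed the number of distinct values.
    """
    vals = np.asarray(values, dtype=float)
    uniq, counts = np.unique(vals, return_counts=True)
    if kmax < 1 or kmax > len(uniq):
        raise ValueError(
            f"kmax must lie in [1, #distinct] = [1, {len(uniq)}], got {kmax}"
        )
    D, _ = _dp(uniq, counts.astype(float), kmax)
    return np.maximum(D[:, len(uniq) - 1], 0.0)


# ---------------------------------------------------------------------------
# gap statistic


@dataclass(frozen=True)
class GapCurve:
    """Gap-statistic curve over a k range and the selected k."""

    k_range: np.ndarray
    log_wk: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    k_selected: int
    B: int
    seed: int | None
    warnings: tuple[str, ...] = ()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"k": self.k_range, "log_wk": self.log_wk, "gap": self.gap, "se": self.se}
        )

    def to_dict(self) -> dict:
        return {
            "k_range": [int(k) for k in self.k_range],
            "log_wk": [float(v) for v in self.log_wk],
            "gap": [float(v) for v in self.gap],
            "se": [float(v) for v in self.se],
            "k_selected": int(self.k_selected),
            "B": int(self.B),
            "seed": self.seed,
        }


def gap_select_k(
    values: Sequence[float],
    kmin: int = 2,
    kmax: int = 12,
    B: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GapCurve:
    """Choose the cluster count by the gap statistic on 1-D data.

    For each k in [kmin, kmax], ``gap(k) = mean_b log W*_kb - log W_k`` where
    W_k is the optimal within-SS of the data and W*_kb that of the b-th
    reference sample drawn uniformly on [min(values), max(values)];
    ``se(k) = sd_b(log W*_kb) * sqrt(1 + 1/B)``.  Selection follows the 1-SE
    rule — smallest k with ``gap(k) >= gap(k+1) - se(k+1)`` — with an
    argmax-gap fallback (flagged "no structure") when no k qualifies.

    A ``kmax`` beyond what the data support (fewer distinct values, or zero
    dispersion at large k) is truncated with a warning rather than rejected.
    Reproducible given ``seed`` (or an explicit ``rng``).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise ValueError("need at least two values")
    m = len(np.unique(vals))
    if m < 2:
        raise ValueError("values are constant; gap statistic undefined")
    kmin, kmax, B = int(kmin), int(kmax), int(B)
    if kmin < 1 or kmin > kmax:
        raise ValueError(f"invalid k range [{kmin}, {kmax}]")
    if B < 1:
        raise ValueError("B must be at least 1")

    warnings: list[str] = []
    if kmax > m:
        warnings.append(
            f"kmax truncated from {kmax} to {m} (only {m} distinct values)"
        )
        kmax = m
    wk_full = wss_profile(vals, kmax)
    # log W_k is undefined once the optimal partition is exact (W_k == 0)
    positive = np.nonzero(wk_full > 0)[0]
    max_pos_k = int(positive[-1]) + 1 if positive.size else 0
    if max_pos_k < kmin:
        raise ValueError(
            "within-cluster dispersion already zero at kmin; nothing to select"
        )
    if max_pos_k < kmax:
        warnings.append(
            f"kmax truncated from {kmax} to {max_pos_k} (zero dispersion beyond)"
        )
        kmax = max_pos_k
    if kmin > kmax:  # unreachable after the guards above, kept for clarity
        raise ValueError(f"empty k range after truncation [{kmin}, {kmax}]")

    if rng is None:
        rng = np.random.default_rng(seed)
    ks = np.arange(kmin, kmax + 1)
    log_wk = np.log(wk_full[kmin - 1 : kmax])
    lo, hi = float(vals.min()), float(vals.max())
    ref_log = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=vals.size)
        ref_log[b] = np.log(wss_profile(ref, kmax)[kmin - 1 : kmax])
    gap = ref_log.mean(axis=0) - log_wk
    se = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    k_selected = None
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            k_selected = int(ks[i])
            break
    if k_selected is None:
        k_selected = int(ks[np.argmax(gap)])
        if len(ks) > 1:
            warnings.append(
                "no k satisfied the 1-SE rule (no clear structure); "
                f"falling back to argmax gap, k={k_selected}"
            )
    return GapCurve(
        k_range=ks,
        log_wk=log_wk,
        gap=gap,
        se=se,
        k_selected=k_selected,
        B=B,
        seed=seed,
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# Kruskal–Wallis verification


@dataclass(frozen=True)
class KWResult:
    """Kruskal–Wallis H test outcome at significance level alpha."""

    H: float
    df: int
    p: float
    alpha: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "df": self.df,
            "p": self.p,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def kruskal_wallis(
    groups: Sequence[Sequence[float]], alpha: float = 0.01
) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p (df = groups - 1).

    All-identical data yields H = 0, p = 1 (nothing to distinguish) rather
    than an error.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    total = sum(a.size for a in arrays)
    if total < 3:
        raise ValueError("need at least 3 observations in total")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*arrays)
    return KWResult(
        H=float(H),
        df=len(arrays) - 1,
        p=float(p),
        alpha=float(alpha),
        significant=bool(p < alpha),
    )


# ---------------------------------------------------------------------------
# centroid-ordered labeling


def cluster_labels_iter():
    """Yield cluster labels A, B, ..., Z, AA, AB, ... indefinitely."""
    import itertools
    import string

    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


@dataclass(frozen=True)
class ClusterLabeling:
    """Gene → cluster label in strictly descending centroid order.

    "A" is the leader cluster; the orphan class (present only when orphans
    exist) carries label "orphan" with centroid 0.
    """

    labels: dict[str, str]
    centroid_by_label: dict[str, float]

    @property
    def leaders(self) -> list[str]:
        return sorted(g for g, lab in self.labels.items() if lab == "A")

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out


def label_clusters(
    clustering: Clustering,
    genes: Sequence[str],
    orphans: Iterable[str] = (),
) -> ClusterLabeling:
    """Name clusters "A", "B", ... by descending centroid; append orphans.

    ``genes`` must align with ``clustering.labels`` (same order as the values
    that were clustered) and be disjoint from ``orphans``.
    """
    genes = list(genes)
    orphan_set = set(orphans)
    if len(genes) != len(clustering.labels):
        raise ValueError(
            f"{len(genes)} genes but {len(clustering.labels)} cluster labels"
        )
    overlap = orphan_set.intersection(genes)
    if overlap:
        raise ValueError(f"orphans overlap clustered genes: {sorted(overlap)}")

    order = np.argsort(clustering.centroids)[::-1]  # descending centroid
    letter_of_index: dict[int, str] = {}
    centroid_by_label: dict[str, float] = {}
    letters = cluster_labels_iter()
    for idx in order:
        lab = next(letters)
        letter_of_index[int(idx)] = lab
        centroid_by_label[lab] = float(clustering.centroids[idx])

    labels = {g: letter_of_index[int(c)] for g, c in zip(genes, clustering.labels)}
    if orphan_set:
        for g in orphan_set:
            labels[g] = "orphan"
        centroid_by_label["orphan"] = 0.0
    return ClusterLabeling(labels=labels, centroid_by_label=centroid_by_label)
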