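"""Vitamin D response index and high/mid/low responder stratification.

Each participant is placed at the point (x, y) where x is the serum
25(OH)D3 day-1/day-0 ratio and y the mean |log2FC| over a target-gene set.
A trendline constrained through (1, 0) — no serum change implies no
expected transcriptomic response — divides the plane; the signed orthogonal
distance to that line is the response index. Participants are ranked by
descending distance and split into three groups with an exactly optimal
(dynamic-programming) one-dimensional k-means, so the stratification is
fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DETable, FoldChangeMatrix
from .io import CohortTable, CohortValidationError

__all__ = [
    "SerumStats",
    "serum_summary",
    "response_scores",
    "fit_trendline",
    "orthogonal_distances",
    "cluster_1d",
    "classify",
    "build_index",
    "stability_analysis",
    "index_correlations",
]

CLASS_ORDER = ("high", "mid", "low")

INDEX_COLUMNS = [
    "participant_id",
    "score",
    "serum_ratio",
    "slope",
    "distance",
    "rank",
    "class",
    "gene_set_label",
]


@dataclass(frozen=True)
class SerumStats:
    """Headline serum 25(OH)D3 statistics of a paired-bolus cohort (ng/ml)."""

    n: int
    mean_d0: float
    mean_d1: float
    mean_delta: float
    mean_pct_increase: float  # mean of per-participant 100*(d1-d0)/d0
    min_d0: float
    max_d0: float
    min_d1: float
    max_d1: float
    t_statistic: float
    p_paired: float


def serum_summary(cohort: CohortTable) -> SerumStats:
    """Paired d0/d1 serum summary with a two-sided paired t-test.

    The percent increase is the mean of per-participant percent changes
    (each subject's own relative rise), not the ratio of means.
    """
    if len(cohort) < 2:
        raise CohortValidationError("serum summary needs at least 2 participants")
    d0 = np.array([r.serum_d0 for r in cohort.records], dtype=float)
    d1 = np.array([r.serum_d1 for r in cohort.records], dtype=float)
    delta = d1 - d0
    if np.ptp(delta) == 0.0:
        if delta[0] == 0.0:
            raise CohortValidationError(
                "paired t-test undefined: d1 equals d0 for every participant"
            )
        # identical nonzero shifts: the t statistic diverges; report the limit
        t, p = float(np.sign(delta[0]) * np.inf), 0.0
    else:
        t, p = stats.ttest_rel(d1, d0)
    return SerumStats(
        n=len(cohort),
        mean_d0=float(d0.mean()),
        mean_d1=float(d1.mean()),
        mean_delta=float(delta.mean()),
        mean_pct_increase=float((100.0 * delta / d0).mean()),
        min_d0=float(d0.min()),
        max_d0=float(d0.max()),
        min_d1=float(d1.min()),
        max_d1=float(d1.max()),
        t_statistic=float(t),
        p_paired=float(p),
    )


def response_scores(fc: FoldChangeMatrix, gene_set) -> pd.Series:
    """Per-participant score: mean |log2FC| over the target-gene set."""
    genes = [gid for gid in fc.gene_ids if gid in set(gene_set)]
    if not genes:
        raise CohortValidationError("empty target-gene set")
    return fc.values[genes].abs().mean(axis=1).rename("score")


def fit_trendline(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y = m*(x - 1), constrained through (1, 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - 1.0
    denom = float(np.sum(dx * dx))
    if denom == 0.0:
        raise CohortValidationError("all serum ratios equal 1: trendline undefined")
    return float(np.sum(dx * y) / denom)


def orthogonal_distances(x: np.ndarray, y: np.ndarray, m: float) -> np.ndarray:
    """Signed orthogonal distance to y = m*(x - 1); positive above the line."""
    if not np.isfinite(m):
        raise CohortValidationError("slope must be finite")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (y - m * (x - 1.0)) / np.sqrt(1.0 + m * m)


def cluster_1d(values: np.ndarray, k: int = 3) -> np.ndarray:
    """Globally optimal 1-D k-means by dynamic programming.

    Clusters of an optimal 1-D k-means are contiguous intervals of the
    sorted values, so the minimum within-cluster sum of squares can be found
    exactly with an O(k n^2) DP — no random initialization, deterministic
    output. Returns per-point cluster indices 0..k-1 ordered by increasing
    cluster mean. If fewer than k distinct values exist, fewer clusters are
    returned (with a warning).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < k:
        raise CohortValidationError(f"need at least k={k} points, got {n}")
    n_distinct = len(np.unique(values))
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct values for k={k}; returning "
            f"{n_distinct} clusters",
            stacklevel=2,
        )
        k = n_distinct
    order = np.argsort(values, kind="stable")
    xs = values[order]
    cum = np.concatenate([[0.0], np.cumsum(xs)])
    cum2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def sse(a: int, b: int) -> float:  # cost of xs[a:b]
        s = cum[b] - cum[a]
        s2 = cum2[b] - cum2[a]
        return s2 - s * s / (b - a)

    inf = np.inf
    cost = np.full((k + 1, n + 1), inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            best, arg = inf, j - 1
            for t in range(j - 1, i):
                c = cost[j - 1, t] + sse(t, i)
                if c < best - 1e-15:
                    best, arg = c, t
            cost[j, i] = best
            split[j, i] = arg
    # backtrack boundaries
    bounds = [n]
    i = n
    for j in range(k, 0, -1):
        i = split[j, i]
        bounds.append(i)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    for c in range(k):
        labels_sorted[bounds[c]:bounds[c + 1]] = c
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def classify(distances: np.ndarray, participant_ids, k: int = 3) -> pd.DataFrame:
    """Cluster response-index distances and name the groups.

    The cluster with the largest mean distance is "high", the middle one
    "mid", the smallest "low". Rank is descending by distance with ties
    broken by participant id.
    """
    distances = np.asarray(distances, dtype=float)
    ids = [str(p) for p in participant_ids]
    cl = cluster_1d(distances, k=k)
    k_eff = cl.max() + 1
    means = [distances[cl == c].mean() for c in range(k_eff)]
    by_mean = np.argsort(means)[::-1]  # descending mean distance
    if k_eff == 3:
        names = ["high", "mid", "low"]
    elif k_eff == 2:
        names = ["high", "low"]
    else:
        names = ["mid"]
    name_of = {int(by_mean[i]): names[i] for i in range(k_eff)}
    order = sorted(range(len(ids)), key=lambda i: (-distances[i], ids[i]))
    rank = np.empty(len(ids), dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    return pd.DataFrame(
        {
            "participant_id": ids,
            "distance": distances,
            "rank": rank,
            "class": [name_of[int(c)] for c in cl],
        }
    )


def build_index(
    fc: FoldChangeMatrix,
    gene_set,
    serum_ratios: pd.Series,
    gene_set_label: str = "all-significant",
    k: int = 3,
    zscore_axes: bool = False,
) -> pd.DataFrame:
    """Full response-index table for one target-gene subset.

    Computes scores, fits the trendline through (1, 0), derives signed
    orthogonal distances, clusters them and labels classes. With
    ``zscore_axes`` both axes are standardized before the distance step
    (sensitivity analysis; off by default — the natural scales are used).
    """
    scores = response_scores(fc, gene_set)
    ids = list(scores.index.astype(str))
    x = serum_ratios.loc[scores.index].to_numpy(dtype=float)
    y = scores.to_numpy(dtype=float)
    if zscore_axes:
        x = 1.0 + (x - x.mean()) / x.std(ddof=0)
        y = (y - y.mean()) / y.std(ddof=0) if y.std(ddof=0) > 0 else y
    m = fit_trendline(x, y)
    d = orthogonal_distances(x, y, m)
    table = classify(d, ids, k=k)
    table.insert(1, "score", y)
    table.insert(2, "serum_ratio", x)
    table.insert(3, "slope", m)
    table["gene_set_label"] = gene_set_label
    return table[INDEX_COLUMNS]


def stability_analysis(
    fc: FoldChangeMatrix,
    de: pd.DataFrame,
    serum_ratios: pd.Series,
    k: int = 3,
) -> pd.DataFrame:
    """Reclassify under nested significance subsets and flag unstable calls.

    The classification is repeated from scratch (fresh trendline and
    clustering) for each of the three nested DE gene sets — p < 0.05,
    additionally |log2FC| > threshold, and FDR < 0.05. The canonical class
    comes from the all-significant set; a participant whose class changes
    under any subset is an "unstable <canonical> responder".
    """
    sets = DETable.significant_sets(de)
    fc_genes = set(fc.gene_ids)
    columns: dict[str, pd.Series] = {}
    for label in ("p05", "lfc", "fdr"):
        genes = sets[label] & fc_genes
        if not genes:
            warnings.warn(f"subset {label!r} is empty; skipped", stacklevel=2)
            continue
        table = build_index(fc, genes, serum_ratios, gene_set_label=label, k=k)
        columns[label] = table.set_index("participant_id")["class"]
    if "p05" not in columns:
        raise CohortValidationError("all-significant subset empty: no canonical class")
    out = pd.DataFrame({f"class_{lbl}": col for lbl, col in columns.items()})
    out.insert(0, "participant_id", out.index)
    out["canonical_class"] = out["class_p05"]
    subset_cols = [c for c in out.columns if c.startswith("class_")]
    out["stable"] = out[subset_cols].nunique(axis=1) == 1
    out["unstable_label"] = np.where(
        out["stable"], "", "unstable " + out["canonical_class"] + " responder"
    )
    return out.reset_index(drop=True)


def index_correlations(distances: np.ndarray, covariate: np.ndarray):
    """Pearson correlation of the response index with a covariate."""
    distances = np.asarray(distances, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if len(distances) < 3:
        raise CohortValidationError("correlation needs at least 3 points")
    if np.ptp(covariate) == 0.0:
        raise CohortValidationError("constant covariate")
    r, p = stats.pearsonr(distances, covariate)
    return float(r), float(p)
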