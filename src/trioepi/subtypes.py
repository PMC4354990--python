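"""Unsupervised structure: consensus clustering, classical MDS, per-probe
variance comparisons and cluster-clinical association tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ConsensusResult:
    """Monti-style consensus clustering output.

    ``consensus`` is the samples x samples co-clustering frequency among
    co-sampled resamples (symmetric, unit diagonal); ``assignments``
    label each sample 1..k.
    """

    k: int
    assignments: pd.Series
    consensus: pd.DataFrame
    n_resamples: int
    subsample: float
    seed: int
    cdf_area: dict[int, float] = field(default_factory=dict)


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows, clipped to [0, 2]."""
    c = np.corrcoef(x)
    return np.clip(1.0 - c, 0.0, 2.0)


def consensus_cluster(
    beta_subset: pd.DataFrame,
    k_range: range | tuple = range(2, 7),
    n_resamples: int = 1000,
    subsample: float = 0.8,
    method: str = "ward",
    distance: str = "euclidean",
    k: int | None = None,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of samples (columns) of a beta matrix.

    Repeated subsampling of samples, hierarchical clustering per
    resample, consensus = co-clustering frequency among co-sampled
    pairs; final assignment by hierarchical clustering of 1 - consensus.
    ``k`` is chosen by the largest relative change in the consensus-CDF
    area over ``k_range`` unless fixed.

    The default Ward linkage on Euclidean distances is robust to single
    hypervariable outlier samples; ``method="average"`` with
    ``distance="pearson"`` (1 - correlation) is available for the more
    traditional methylation-clustering recipe.
    """
    n = beta_subset.shape[1]
    ks = [k] if k is not None else list(k_range)
    if max(ks) > n:
        raise ValueError(f"k={max(ks)} exceeds the number of samples ({n})")

    x = beta_subset.to_numpy().T  # samples x probes
    if distance == "pearson":
        dist = _pearson_distance(x)
    elif distance == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))

    counts = {kk: np.zeros((n, n)) for kk in ks}
    sampled = np.zeros((n, n))
    draws = [rng.choice(n, size=m, replace=False) for _ in range(n_resamples)]
    for take in draws:
        take = np.sort(take)
        sampled[np.ix_(take, take)] += 1.0
        sub = dist[np.ix_(take, take)]
        z = linkage(squareform(sub, checks=False), method=method)
        for kk in ks:
            labels = fcluster(z, t=kk, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            counts[kk][np.ix_(take, take)] += same
    with np.errstate(invalid="ignore"):
        consensus = {kk: np.where(sampled > 0, counts[kk] / sampled, 0.0) for kk in ks}
    for kk in ks:
        np.fill_diagonal(consensus[kk], 1.0)

    # consensus-CDF area per k; pick the k with the largest relative change
    areas = {}
    for kk in ks:
        vals = consensus[kk][np.triu_indices(n, 1)]
        grid = np.linspace(0, 1, 101)
        cdf = np.searchsorted(np.sort(vals), grid, side="right") / len(vals)
        areas[kk] = float(np.trapezoid(cdf, grid))
    if k is None:
        deltas = {}
        for i, kk in enumerate(ks):
            deltas[kk] = areas[kk] if i == 0 else (areas[kk] - areas[ks[i - 1]]) / max(areas[ks[i - 1]], 1e-12)
        k = max(deltas, key=lambda kk: deltas[kk])

    final = linkage(squareform(1.0 - consensus[k], checks=False), method=method)
    labels = fcluster(final, t=k, criterion="maxclust")
    return ConsensusResult(
        k=k,
        assignments=pd.Series(labels, index=beta_subset.columns, name="cluster"),
        consensus=pd.DataFrame(consensus[k], index=beta_subset.columns, columns=beta_subset.columns),
        n_resamples=n_resamples,
        subsample=subsample,
        seed=seed,
        cdf_area=areas,
    )


def mds(beta_subset: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of samples from
    Euclidean distances over the probe subset.

    Coordinates are centred, axes ordered by eigenvalue, and each axis is
    signed so its first nonzero coordinate is positive.  Dimensions with
    non-positive eigenvalues are returned as zeros.
    """
    n = beta_subset.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for an embedding")
    x = beta_subset.to_numpy().T
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, n_dims))
    for i in range(min(n_dims, n)):
        if vals[i] > 1e-10:
            axis = vecs[:, i] * np.sqrt(vals[i])
            nz = np.flatnonzero(np.abs(axis) > 1e-12)
            if len(nz) and axis[nz[0]] < 0:
                axis = -axis
            coords[:, i] = axis
    return pd.DataFrame(
        coords, index=beta_subset.columns, columns=[f"dim{i + 1}" for i in range(n_dims)]
    )


@dataclass
class VarianceComparison:
    table: pd.DataFrame           # per-probe group variances, K2, df, p
    counts: dict[str, int]        # significant probes with each group's variance largest
    alpha: float
    n_significant: int


def bartlett_per_probe(
    beta: pd.DataFrame, groups: dict[str, list[str]], alpha: float = 0.01
) -> VarianceComparison:
    """Vectorised Bartlett homogeneity-of-variance test at every probe.

    ``groups`` maps group names to sample-id lists (each >= 2 samples).
    Among probes significant at ``alpha``, the summary counts tally which
    group shows the largest sample variance.  Probes with zero variance
    in every group get K2 = 0, p = 1 by convention.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.array([len(groups[g]) for g in names])
    if (sizes < 2).any():
        small = names[int(np.argmin(sizes))]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    k = len(names)
    big_n = sizes.sum()
    variances = np.column_stack([
        beta[groups[g]].to_numpy().var(axis=1, ddof=1) for g in names
    ])
    dfs = sizes - 1
    pooled = (variances * dfs[None, :]).sum(axis=1) / (big_n - k)
    c = 1.0 + ((1.0 / dfs).sum() - 1.0 / (big_n - k)) / (3.0 * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        k2 = ((big_n - k) * np.log(pooled) - (dfs[None, :] * np.log(variances)).sum(axis=1)) / c
    degenerate = pooled <= 0
    k2 = np.where(degenerate, 0.0, k2)
    p = np.where(degenerate, 1.0, stats.chi2.sf(k2, k - 1))

    table = pd.DataFrame(
        {f"var_{g}": variances[:, i] for i, g in enumerate(names)}, index=beta.index
    )
    table["K2"] = k2
    table["df"] = k - 1
    table["p"] = p
    table["degenerate"] = degenerate

    sig = table["p"] < alpha
    argmax = variances.argmax(axis=1)
    counts = {g: int(((argmax == i) & sig).sum()) for i, g in enumerate(names)}
    return VarianceComparison(table=table, counts=counts, alpha=alpha, n_significant=int(sig.sum()))


def cluster_association(
    assignments: pd.Series, clinical_labels: pd.Series, yates: bool = False
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square association between cluster assignment and a
    clinical label (no continuity correction by default).  Returns
    (chi2, df, p, contingency table)."""
    shared = assignments.index.intersection(clinical_labels.index)
    table = pd.crosstab(assignments.loc[shared], clinical_labels.loc[shared])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("association is undefined (fewer than 2 clusters or 2 labels)")
    res = stats.chi2_contingency(table.to_numpy(), correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue), table
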