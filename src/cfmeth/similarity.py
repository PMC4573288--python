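"""Pool-level similarity analytics: pairwise Pearson correlation of percent
methylation profiles, Ward hierarchical clustering on correlation distance,
PCA, and per-base percent-methylation histograms.

Profiles are restricted to the intersection of loci covered at the same
minimum depth in every pool (the depth used for DML calling), so every
statistic is computed over an identical locus index.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core import CfMethError, PoolMethylome
from .diffmeth import destrand_merge

logger = logging.getLogger(__name__)


def build_profiles(
    pools: Iterable[PoolMethylome], min_coverage: int = 5, destrand: bool = True
) -> pd.DataFrame:
    """Percent-methylation matrix over the common covered loci.

    Returns a DataFrame indexed by (chrom, pos) with one column per pool,
    restricted to loci with coverage >= ``min_coverage`` in *every* pool.
    """
    pools = list(pools)
    if len(pools) < 2:
        raise CfMethError("need at least two pools to build comparable profiles")
    columns = {}
    n_before = {}
    for pool in pools:
        if destrand and pool.strand_known:
            pool = destrand_merge(pool)
        covered = pool.filter_coverage(min_coverage)
        n_before[pool.label] = len(covered)
        s = pd.Series(
            covered.percent_methylation.to_numpy(),
            index=pd.MultiIndex.from_frame(covered.df[["chrom", "pos"]]),
            name=pool.label,
        )
        columns[pool.label] = s
    profiles = pd.concat(columns.values(), axis=1, join="inner")
    if profiles.empty:
        raise CfMethError(
            "no loci covered in all pools at the requested depth; per-pool "
            f"covered-locus counts: {n_before}"
        )
    logger.info(
        "profiles: %d common loci at coverage >= %d (per-pool covered: %s)",
        len(profiles), min_coverage, n_before,
    )
    return profiles


def pairwise_pearson(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over the pool columns.

    A zero-variance profile yields NaN entries (flagged by a warning),
    never a silent zero.
    """
    if len(profiles) < 2:
        raise CfMethError("profiles must contain at least two loci")
    zero_var = profiles.std(ddof=0) == 0
    if zero_var.any():
        logger.warning(
            "zero-variance profile(s): %s; their correlations are undefined (NaN)",
            list(profiles.columns[zero_var]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(profiles.to_numpy().T)
    mat = pd.DataFrame(r, index=profiles.columns, columns=profiles.columns)
    np.fill_diagonal(mat.values, 1.0)
    mat.values[np.ix_(zero_var.to_numpy(), ~zero_var.to_numpy())] = np.nan
    mat.values[np.ix_(~zero_var.to_numpy(), zero_var.to_numpy())] = np.nan
    return mat


def ward_cluster(pearson_matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward linkage on correlation distance d = 1 - r.

    Returns the scipy linkage matrix and the leaf labels in input order.
    """
    m = pearson_matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-12, equal_nan=True):
        raise CfMethError("correlation matrix must be square and symmetric")
    d = 1.0 - m
    d = (d + d.T) / 2.0  # remove float-level asymmetry before squareform
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=True)
    return linkage(condensed, method="ward"), list(pearson_matrix.columns)


def pca_profiles(
    profiles: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the pools-by-loci matrix after removing the per-locus mean.

    Returns per-pool scores on the leading components and the explained
    variance fractions.  Sign convention: the largest-magnitude loading of
    each component is made positive, so scores are reproducible.
    """
    n_pools = profiles.shape[1]
    if n_pools < 2:
        raise CfMethError("PCA needs at least two pools")
    if len(profiles) < n_components:
        raise CfMethError(
            f"fewer loci ({len(profiles)}) than requested components ({n_components})"
        )
    x = profiles.to_numpy(dtype=float).T            # pools x loci
    x = x - x.mean(axis=0, keepdims=True)           # per-locus centring
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    with np.errstate(invalid="ignore", divide="ignore"):
        evr = (s**2) / (s**2).sum() if (s**2).sum() > 0 else np.zeros_like(s)
    return (
        pd.DataFrame(
            scores, index=profiles.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        evr[:k],
    )


def methylation_histogram(
    values: Sequence[float] | pd.Series, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of percent methylation over [0, 100]."""
    if n_bins < 2:
        raise CfMethError("n_bins must be >= 2")
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=n_bins, range=(0, 100))
    return counts, edges


def similarity_report(
    pools: Iterable[PoolMethylome],
    min_coverage: int = 5,
    n_bins: int = 20,
    destrand: bool = True,
) -> dict:
    """All similarity analytics in one JSON-ready structure."""
    profiles = build_profiles(pools, min_coverage=min_coverage, destrand=destrand)
    pearson = pairwise_pearson(profiles)
    z, labels = ward_cluster(pearson)
    scores, evr = pca_profiles(profiles)
    histograms = {}
    for label in profiles.columns:
        counts, edges = methylation_histogram(profiles[label], n_bins)
        histograms[label] = {"counts": counts.tolist(), "bin_edges": edges.tolist()}
    return {
        "n_common_loci": int(len(profiles)),
        "min_coverage": min_coverage,
        "pool_labels": list(profiles.columns),
        "pearson": pearson.round(10).to_dict(),
        "ward_linkage": {"labels": labels, "merges": z.tolist()},
        "pca": {
            "scores": scores.round(10).to_dict(),
            "explained_variance_fractions": [float(v) for v in evr],
        },
        "histograms": histograms,
    }
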