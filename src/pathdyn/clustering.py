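"""Connectivity-seeded clustering of dynamic expression profiles.

Two variants share one seeding algorithm.  Compatibility of two genes is
either

* F-means: the variance of the profile difference does not exceed the
  reference group's pooled variance (F-test, p >= 0.05), or
* correlation: Pearson r with the seed is at least a threshold.

Connectivity of a gene is the number of other genes compatible with it.
Genes are sorted by connectivity; the most-connected unassigned gene seeds
the next cluster, which absorbs every compatible gene (already-clustered
genes included, so clusters may overlap).  Zero-connectivity genes stay
unclustered.  Ties in connectivity are broken by input gene order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selection import ReferenceGroup

log = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


@dataclass
class Cluster:
    seed: str
    members: list  # seed first, then members in input gene order


@dataclass
class ClusterSet:
    clusters: list  # ordered by seed connectivity, non-increasing
    connectivity: pd.Series
    unclustered: list
    method: str
    threshold_used: float

    def labels(self) -> pd.Series:
        """First-cluster assignment per gene (-1 = unclustered)."""
        lab = pd.Series(-1, index=self.connectivity.index, dtype=int)
        for ci, cl in enumerate(self.clusters):
            for g in cl.members:
                if lab.loc[g] == -1:
                    lab.loc[g] = ci
        return lab

    def membership(self) -> dict:
        out: dict[str, list[int]] = {}
        for ci, cl in enumerate(self.clusters):
            for g in cl.members:
                out.setdefault(g, []).append(ci)
        return out


@dataclass
class CorrelationMosaic:
    ordered_genes: list
    corr: pd.DataFrame
    cluster_boundaries: list
    group_label: str


def _diff_variance_matrix(X: np.ndarray) -> np.ndarray:
    """var(x_i - x_j) over timepoints (ddof=1) for every gene pair."""
    C = np.cov(X, ddof=1)
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2.0 * C


# A difference of two profiles carries the technological noise of both, so
# its null variance is twice the reference pooled variance.
_DIFF_VAR_FACTOR = 2.0


def _f_compat(profiles: pd.DataFrame, ref: ReferenceGroup, alpha: float) -> pd.DataFrame:
    X = profiles.to_numpy(dtype=float)
    T = X.shape[1]
    if T < 3:
        raise ClusteringError("need at least 3 timepoints")
    var_d = _diff_variance_matrix(X)
    p = stats.f.sf(var_d / (_DIFF_VAR_FACTOR * ref.pooled_variance), T - 1, ref.df)
    compat = p >= alpha
    np.fill_diagonal(compat, False)
    return pd.DataFrame(compat, index=profiles.index, columns=profiles.index)


def connectivity(seed_profile, others: pd.DataFrame, ref: ReferenceGroup, *, alpha: float = 0.05) -> int:
    """Number of genes whose deviation from the seed stays within reference
    variability (F-test p >= alpha, self excluded)."""
    seed = np.asarray(seed_profile, dtype=float)
    X = others.to_numpy(dtype=float)
    T = len(seed)
    if T < 3:
        raise ClusteringError("need at least 3 timepoints")
    d = X - seed[None, :]
    var_d = d.var(axis=1, ddof=1)
    p = stats.f.sf(var_d / (_DIFF_VAR_FACTOR * ref.pooled_variance), T - 1, ref.df)
    same = (var_d <= 1e-300) | np.all(np.abs(d - d.mean(axis=1, keepdims=True)) < 1e-12, axis=1)
    return int(((p >= alpha) | same).sum())


def _seeded_clusters(compat: pd.DataFrame, method: str, threshold: float) -> ClusterSet:
    genes = list(compat.index)
    conn = pd.Series(compat.to_numpy().sum(axis=1), index=compat.index, dtype=int)
    assigned: set = set()
    clusters: list[Cluster] = []
    order = sorted(range(len(genes)), key=lambda i: (-conn.iloc[i], i))
    while True:
        seed = next(
            (genes[i] for i in order if genes[i] not in assigned and conn.iloc[i] > 0),
            None,
        )
        if seed is None:
            break
        members = [seed] + [g for g in genes if g != seed and compat.loc[seed, g]]
        clusters.append(Cluster(seed=seed, members=members))
        assigned.update(members)
    unclustered = [g for g in genes if g not in assigned]
    return ClusterSet(
        clusters=clusters,
        connectivity=conn,
        unclustered=unclustered,
        method=method,
        threshold_used=threshold,
    )


def fmeans_cluster(
    profiles: pd.DataFrame, ref: ReferenceGroup, *, alpha: float = 0.05
) -> ClusterSet:
    """Seeded clustering with F-test profile compatibility."""
    if profiles.shape[0] < 2:
        raise ClusteringError("need at least 2 genes to cluster")
    compat = _f_compat(profiles, ref, alpha)
    # exact profile matches have zero difference variance -> p = 1 already
    return _seeded_clusters(compat, "fmeans", alpha)


def correlation_cluster(profiles: pd.DataFrame, cc_threshold: float) -> ClusterSet:
    """Seeded clustering with Pearson-correlation compatibility."""
    if not -1.0 < cc_threshold < 1.0:
        raise ClusteringError("cc_threshold must lie in (-1, 1)")
    if profiles.shape[0] < 2:
        raise ClusteringError("need at least 2 genes to cluster")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    constant = profiles.index[sd <= 1e-300]
    if len(constant):
        log.info("%d constant profiles excluded from clustering", len(constant))
    keep = profiles.index[sd > 1e-300]
    if len(keep) < 2:
        raise ClusteringError("fewer than 2 non-constant profiles")
    corr = np.corrcoef(profiles.loc[keep].to_numpy(dtype=float))
    compat = corr >= cc_threshold
    np.fill_diagonal(compat, False)
    cs = _seeded_clusters(
        pd.DataFrame(compat, index=keep, columns=keep), "correlation", cc_threshold
    )
    cs.unclustered = cs.unclustered + list(constant)
    full_conn = cs.connectivity.reindex(profiles.index, fill_value=0)
    cs.connectivity = full_conn
    return cs


def build_mosaic(
    cs: ClusterSet,
    profiles: pd.DataFrame,
    group_label: str,
    ordered_genes: list | None = None,
    cluster_boundaries: list | None = None,
) -> CorrelationMosaic:
    """Cluster-blocked pairwise correlation matrix.

    Genes appear once, at their first cluster (seed first).  Passing
    ``ordered_genes`` (typically the other phenotype group's order) reuses
    that ordering so the two group mosaics are directly comparable.
    """
    if ordered_genes is None:
        if not cs.clusters:
            raise ClusteringError("empty cluster set")
        ordered_genes, boundaries, seen = [], [], set()
        for cl in cs.clusters:
            added = [g for g in cl.members if g not in seen]
            ordered_genes.extend(added)
            seen.update(added)
            boundaries.append(len(ordered_genes))
        cluster_boundaries = boundaries
    corr = np.corrcoef(profiles.loc[ordered_genes].to_numpy(dtype=float))
    corr = pd.DataFrame(corr, index=ordered_genes, columns=ordered_genes)
    return CorrelationMosaic(
        ordered_genes=list(ordered_genes),
        corr=corr,
        cluster_boundaries=list(cluster_boundaries or []),
        group_label=group_label,
    )


def plot_mosaic(mosaic: CorrelationMosaic, path) -> None:
    """Render the mosaic as a blue-negative / red-positive heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mosaic.corr.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    for b in mosaic.cluster_boundaries[:-1]:
        ax.axhline(b - 0.5, color="black", lw=0.5)
        ax.axvline(b - 0.5, color="black", lw=0.5)
    ax.set_title(f"correlation mosaic ({mosaic.group_label})")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150)
    plt.close(fig)
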