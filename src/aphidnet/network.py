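"""Signed weighted co-expression network, TOM, modules, eigengenes, kME.

The construction follows the standard signed weighted-network formulation:

* adjacency  ``a_ij = ((1 + r_ij) / 2) ** beta``  with Pearson ``r`` over
  all samples, so anti-correlated genes receive near-zero edge weights;
* topological overlap
  ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
  over shared neighbours ``u != i, j`` with connectivity
  ``k_i = sum_{u != i} a_iu``;
* modules from average-linkage hierarchical clustering of ``1 - TOM`` with
  a static height cut, a minimum module size, and iterative merging of
  modules whose eigengenes correlate above a threshold;
* the module eigengene is the first principal component of the
  gene-standardized module submatrix, sign-fixed so that the mean module
  membership (kME, the gene-eigengene correlation) of its own members is
  positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ConfigError, PipelineError

__all__ = [
    "UNASSIGNED",
    "NetworkModel",
    "ModuleAssignment",
    "signed_adjacency",
    "pick_soft_threshold",
    "scale_free_fit",
    "tom",
    "module_eigengene",
    "kme",
    "detect_modules",
    "build_network",
]

logger = logging.getLogger(__name__)

#: Module label of genes outside every module.
UNASSIGNED = 0

DEFAULT_BETAS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
FALLBACK_BETA = 12.0


@dataclass
class NetworkModel:
    """Genes, soft power, TOM matrix, and per-gene connectivity."""

    genes: pd.Index
    beta: float
    tom: np.ndarray
    connectivity: pd.Series

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.tom.shape != (n, n):
            raise ConfigError("TOM shape does not match the gene list")

    def tom_row(self, gene: str) -> pd.Series:
        if gene not in self.genes:
            raise KeyError(f"gene {gene!r} is not in the network")
        i = self.genes.get_loc(gene)
        return pd.Series(self.tom[i], index=self.genes, name=gene)


@dataclass
class ModuleAssignment:
    """Gene -> module label (0 = unassigned), eigengenes, and kME matrix."""

    modules: pd.Series
    eigengenes: pd.DataFrame  # samples x module labels
    kme: pd.DataFrame  # genes x module labels
    zero_variance_genes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def labels(self) -> list[int]:
        return [int(c) for c in self.eigengenes.columns]

    def members(self, label: int) -> pd.Index:
        return self.modules.index[self.modules == label]

    def own_kme(self) -> pd.Series:
        """Each assigned gene's kME in its own module."""
        out = {}
        for label in self.labels:
            for gene in self.members(label):
                out[gene] = float(self.kme.at[gene, label])
        return pd.Series(out, name="kme_own")


def signed_adjacency(data: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Signed adjacency ``((1 + r) / 2) ** beta`` from a genes x samples table.

    Genes with zero variance are dropped with a warning before computing
    correlations; fewer than 4 samples is an error.
    """
    if data.shape[1] < 4:
        raise ConfigError("at least 4 samples are required for correlations")
    if beta < 1:
        raise ConfigError("beta must be >= 1")
    variances = data.to_numpy().var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = list(data.index[~keep])
        logger.warning("dropping %d zero-variance genes", len(dropped))
        data = data.loc[keep]
    r = np.corrcoef(data.to_numpy())
    adjacency = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(adjacency, 1.0)
    return pd.DataFrame(adjacency, index=data.index, columns=data.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 and slope of the log-log connectivity frequency fit.

    Connectivity values are binned into equal-width bins; the frequency of
    each non-empty bin is regressed on the mean connectivity of the bin,
    both on the log10 scale.  The R^2 is signed by the negated slope sign
    so that only decreasing (scale-free-like) distributions score high.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    predicted = slope * np.asarray(xs) + intercept
    total = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
    if total == 0:
        return 0.0, float(slope)
    rsq = 1.0 - np.sum((np.asarray(ys) - predicted) ** 2) / total
    return float(-np.sign(slope) * rsq), float(slope)


def pick_soft_threshold(
    data: pd.DataFrame,
    candidate_betas: tuple[float, ...] = DEFAULT_BETAS,
    rsq_threshold: float = 0.8,
    n_bins: int = 10,
) -> float:
    """Smallest candidate power with a signed scale-free fit R^2 >= threshold.

    Returns the fallback power 12 (the signed-network convention) with a
    warning when no candidate reaches the threshold.
    """
    if not candidate_betas:
        raise ConfigError("candidate beta list must be non-empty")
    base = signed_adjacency(data, beta=1.0).to_numpy()
    for beta in sorted(candidate_betas):
        adjacency = base ** beta
        np.fill_diagonal(adjacency, 1.0)
        k = adjacency.sum(axis=0) - 1.0
        rsq, _ = scale_free_fit(k, n_bins=n_bins)
        if rsq >= rsq_threshold:
            return float(beta)
    logger.warning(
        "no candidate power reached scale-free fit R^2 >= %.2f; using %.0f",
        rsq_threshold, FALLBACK_BETA,
    )
    return FALLBACK_BETA


def tom(adjacency: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Topological overlap matrix of a signed adjacency matrix.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with unit diagonal.  Input must be symmetric with entries in [0, 1] and
    unit diagonal.
    """
    a = np.asarray(
        adjacency.to_numpy() if isinstance(adjacency, pd.DataFrame) else adjacency,
        dtype=float,
    )
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ConfigError("adjacency must be a square matrix")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ConfigError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ConfigError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ConfigError("adjacency diagonal must be 1")
    k = a.sum(axis=0) - 1.0
    shared = a @ a - 2.0 * a  # sum over u != i, j of a_iu * a_uj
    numerator = shared + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = numerator / denominator
    t[~np.isfinite(t)] = 0.0
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return t


def module_eigengene(data: pd.DataFrame, members: pd.Index) -> pd.Series:
    """First principal component of the gene-standardized module submatrix.

    Returned as a unit-norm vector over samples with the sign fixed so the
    mean correlation of the member genes with the eigengene is positive.
    """
    members = pd.Index(members)
    if len(members) == 0:
        raise ConfigError("module is empty")
    sub = data.loc[members].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise PipelineError("module consists only of constant genes")
    keep = sd > 0
    sub = sub[keep]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=0, keepdims=True)
    # first right singular vector = leading PC over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eigen = vt[0]
    eigen = eigen / np.linalg.norm(eigen)
    mean_corr = (z @ eigen).mean()
    if mean_corr < 0:
        eigen = -eigen
    return pd.Series(eigen, index=data.columns, name="eigengene")


def kme(data: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Gene x module matrix of gene-eigengene Pearson correlations.

    Zero-variance genes get kME 0 (they carry no profile to correlate).
    """
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    centered = values - values.mean(axis=1, keepdims=True)
    out = np.zeros((values.shape[0], eigengenes.shape[1]))
    ok = sd > 0
    for j, label in enumerate(eigengenes.columns):
        e = eigengenes[label].to_numpy(dtype=float)
        e_centered = e - e.mean()
        denom = sd * np.sqrt((e_centered ** 2).sum()) * np.sqrt(values.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (centered @ e_centered) / denom
        out[ok, j] = corr[ok]
    return pd.DataFrame(out, index=data.index, columns=eigengenes.columns)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != UNASSIGNED].value_counts()
    order = sizes.sort_values(ascending=False).index
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping)


def _merge_by_eigengene(
    labels: pd.Series, data: pd.DataFrame, merge_threshold: float
) -> pd.Series:
    """Iteratively merge the module pair with the highest eigengene
    correlation until no pair exceeds the threshold."""
    while True:
        current = sorted(set(labels) - {UNASSIGNED})
        if len(current) < 2:
            break
        eigen = {
            c: module_eigengene(data, labels.index[labels == c]) for c in current
        }
        best: tuple[float, int, int] | None = None
        for i, ci in enumerate(current):
            for cj in current[i + 1:]:
                corr = float(np.corrcoef(eigen[ci], eigen[cj])[0, 1])
                if best is None or corr > best[0]:
                    best = (corr, ci, cj)
        if best is None or best[0] <= merge_threshold:
            break
        _, ci, cj = best
        logger.info("merging modules with eigengene correlation %.3f", best[0])
        labels = labels.copy()
        labels[labels == cj] = ci
    return labels


def detect_modules(
    tom_matrix: np.ndarray,
    data: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.78,
    merge_threshold: float = 0.9,
    kme_threshold: float | None = 0.7,
) -> ModuleAssignment:
    """Average-linkage clustering of ``1 - TOM`` with static cut, eigengene
    merging, and kME membership cleanup.

    The static cut at ``cut_height`` yields seed clusters; clusters smaller
    than ``min_module_size`` are pooled as unassigned and module pairs whose
    eigengenes correlate above ``merge_threshold`` are merged iteratively.
    When ``kme_threshold`` is set (the default), membership is then refined
    by module membership: every gene joins the module whose eigengene it
    correlates with most, provided that kME reaches the threshold, and is
    unassigned otherwise.  This rescues members split off by the cut and
    strips weakly attached genes; pass ``kme_threshold=None`` for the raw
    tree-cut behavior.  Final labels are integers ranked by decreasing
    module size; 0 marks unassigned genes.  An outcome with zero modules is
    legal.
    """
    n = len(data.index)
    if tom_matrix.shape != (n, n):
        raise ConfigError("TOM shape does not match the expression table")
    dissimilarity = 1.0 - tom_matrix
    np.fill_diagonal(dissimilarity, 0.0)
    condensed = squareform(dissimilarity, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=data.index, dtype=int)

    sizes = labels.value_counts()
    for cluster, size in sizes.items():
        if size < min_module_size:
            labels[labels == cluster] = UNASSIGNED

    labels = _merge_by_eigengene(labels, data, merge_threshold)

    if kme_threshold is not None and (labels != UNASSIGNED).any():
        current = sorted(set(labels) - {UNASSIGNED})
        eigengenes = pd.DataFrame(
            {c: module_eigengene(data, labels.index[labels == c]) for c in current},
            index=data.columns,
        )
        membership = kme(data, eigengenes)
        best = membership.idxmax(axis=1)
        best_kme = membership.max(axis=1)
        labels = pd.Series(
            np.where(best_kme >= kme_threshold, best, UNASSIGNED),
            index=data.index,
            dtype=int,
        )
        sizes = labels.value_counts()
        for cluster, size in sizes.items():
            if cluster != UNASSIGNED and size < min_module_size:
                labels[labels == cluster] = UNASSIGNED
        labels = _merge_by_eigengene(labels, data, merge_threshold)

    labels = _relabel_by_size(labels)
    final = sorted(set(labels) - {UNASSIGNED})
    eigengenes = pd.DataFrame(
        {c: module_eigengene(data, labels.index[labels == c]) for c in final},
        index=data.columns,
    )
    if final:
        kme_matrix = kme(data, eigengenes)
        flagged = tuple(
            data.index[data.to_numpy().std(axis=1) == 0]
        )
    else:
        kme_matrix = pd.DataFrame(index=data.index)
        flagged = tuple()
    return ModuleAssignment(
        modules=labels,
        eigengenes=eigengenes,
        kme=kme_matrix,
        zero_variance_genes=flagged,
    )


def build_network(
    data: pd.DataFrame,
    beta: float | None = None,
    candidate_betas: tuple[float, ...] = DEFAULT_BETAS,
) -> NetworkModel:
    """Convenience wrapper: pick power (unless given), adjacency, TOM."""
    if beta is None:
        beta = pick_soft_threshold(data, candidate_betas)
    adjacency = signed_adjacency(data, beta=beta)
    k = adjacency.to_numpy().sum(axis=0) - 1.0
    return NetworkModel(
        genes=adjacency.index,
        beta=float(beta),
        tom=tom(adjacency),
        connectivity=pd.Series(k, index=adjacency.index, name="connectivity"),
    )
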