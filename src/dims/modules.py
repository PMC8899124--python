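"""Module detection on the topological overlap dissimilarity.

Average-linkage hierarchical clustering of ``1 - TOM`` is cut at a grid of
candidate heights; undersized clusters are merged into their nearest proper
cluster by average TOM (or left unassigned when none exists); among the
candidate partitions the one maximizing Newman modularity Q of the weighted
adjacency is kept. A permutation Z_summary (density + connectivity
components) assesses whether a module found in one condition's network is
preserved in another's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .network import CoexpressionNetwork

__all__ = [
    "UNASSIGNED",
    "ModulePartition",
    "PreservationResult",
    "cluster_and_cut",
    "modularity_q",
    "select_optimal_partition",
    "detect_modules",
    "z_summary",
]

UNASSIGNED = 0  # reserved module id for genes not in any proper module


@dataclass
class ModulePartition:
    """Total gene -> module assignment for one condition network.

    Module ids are ordinal (1..k, in decreasing size order); id 0 is the
    reserved unassigned label.
    """

    gene_ids: list[str]
    labels: np.ndarray  # int module id per gene, 0 = unassigned
    cut_height: float
    min_module_size: int
    q: float = np.nan
    q_per_module: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.gene_ids),):
            raise ValueError("labels length does not match gene ids")

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in set(self.labels) if m != UNASSIGNED)

    def members(self, module_id: int) -> set[str]:
        return {g for g, l in zip(self.gene_ids, self.labels) if l == module_id}

    def modules(self) -> dict[int, set[str]]:
        """Proper modules only (unassigned excluded)."""
        return {m: self.members(m) for m in self.module_ids}

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == UNASSIGNED).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "module_id": self.labels})


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel proper modules 1..k by decreasing size (ties by first member)."""
    out = np.zeros_like(labels)
    proper = [m for m in set(labels) if m != UNASSIGNED]
    sizes = {m: (labels == m).sum() for m in proper}
    order = sorted(proper, key=lambda m: (-sizes[m], np.argmax(labels == m)))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def _default_heights(tree: np.ndarray, n_top: int = 30, n_low: int = 10) -> list[float]:
    """Candidate cut heights from the tree's own merge structure.

    Cluster merges concentrate near the top of a TOM-dissimilarity tree, so
    midpoints between the highest ``n_top`` consecutive merge heights are all
    tried individually, plus ``n_low`` quantile heights covering the lower
    range. Every distinct partition near the top of the tree is therefore a
    candidate.
    """
    merges = np.sort(np.unique(tree[:, 2]))
    if merges.size == 1:
        return [float(merges[0] / 2)]
    mids = (merges[1:] + merges[:-1]) / 2.0
    top = mids[-n_top:]
    low = mids[:-n_top]
    if low.size > n_low:
        low = np.quantile(low, np.linspace(0, 1, n_low))
    return sorted(float(h) for h in np.unique(np.concatenate([low, top])))


def cluster_and_cut(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 10,
    candidate_heights=None,
) -> list[ModulePartition]:
    """Cut the average-linkage tree of 1 - TOM at each candidate height.

    Clusters below ``min_module_size`` are merged into the nearest proper
    cluster by average TOM, or marked unassigned when no proper cluster
    exists at that height. Returns one partition per height.
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if n != len(gene_ids):
        raise ValueError("TOM size does not match gene ids")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    dist = squareform(np.clip(diss, 0.0, None), checks=False)
    tree = linkage(dist, method="average")
    if candidate_heights is None:
        candidate_heights = _default_heights(tree)
    candidate_heights = list(candidate_heights)
    if not candidate_heights:
        raise ValueError("candidate height list is empty")

    if min_module_size > n:
        warnings.warn("min_module_size exceeds gene count; all genes unassigned")
        return [
            ModulePartition(
                gene_ids,
                np.zeros(n, dtype=int),
                float(candidate_heights[0]),
                min_module_size,
            )
        ]

    partitions = []
    for h in candidate_heights:
        raw = fcluster(tree, t=h, criterion="distance")
        labels = _merge_small(raw, tom, min_module_size)
        partitions.append(
            ModulePartition(gene_ids, _renumber(labels), float(h), min_module_size)
        )
    return partitions


def _merge_small(raw: np.ndarray, tom: np.ndarray, min_size: int) -> np.ndarray:
    """Merge undersized clusters into the nearest proper cluster by mean TOM."""
    labels = raw.astype(int).copy()
    sizes = pd.Series(labels).value_counts()
    proper = [int(c) for c in sizes.index[sizes >= min_size]]
    small = [int(c) for c in sizes.index[sizes < min_size]]
    if not proper:
        return np.zeros_like(labels)
    out = np.where(np.isin(labels, proper), labels, 0)
    proper_masks = {c: labels == c for c in proper}
    for c in small:
        mask = labels == c
        best, best_sim = None, -1.0
        for p in proper:
            sim = tom[np.ix_(mask, proper_masks[p])].mean()
            if sim > best_sim:
                best, best_sim = p, sim
        out[mask] = best
    return out


def modularity_q(
    net: CoexpressionNetwork, partition: ModulePartition
) -> tuple[float, dict[int, float]]:
    """Newman modularity of a weighted network under a partition.

    Q = 1/(2n) * sum_ij [a_ij - k_i k_j / (2n)] * sigma(c_i, c_j) with n the
    total edge weight (half the adjacency sum) and sigma = 1 only for pairs
    in the same proper module; pairs involving unassigned genes contribute 0.
    Returns Q plus each module's contribution.
    """
    if partition.gene_ids != net.gene_ids:
        raise ValueError("partition does not cover the network's genes")
    a = net.adjacency
    two_n = a.sum()
    if two_n <= 0:
        warnings.warn("empty network: modularity defined as 0")
        return 0.0, {m: 0.0 for m in partition.module_ids}
    k = net.degrees
    per_module = {}
    for m in partition.module_ids:
        mask = partition.labels == m
        within = a[np.ix_(mask, mask)].sum()
        k_m = k[mask].sum()
        per_module[m] = within / two_n - (k_m / two_n) ** 2
    q = float(sum(per_module.values()))
    return q, per_module


def select_optimal_partition(
    candidates: list[ModulePartition], net: CoexpressionNetwork
) -> ModulePartition:
    """Pick the candidate partition maximizing modularity Q.

    Ties go to fewer unassigned genes, then to the lower cut height. The Q
    values are stored on the returned (and all candidate) partitions.
    """
    if not candidates:
        raise ValueError("no candidate partitions")
    for part in candidates:
        q, per = modularity_q(net, part)
        part.q, part.q_per_module = q, per
    return min(
        candidates, key=lambda p: (-round(p.q, 12), p.n_unassigned, p.cut_height)
    )


def detect_modules(
    net: CoexpressionNetwork,
    min_module_size: int = 10,
    candidate_heights=None,
) -> ModulePartition:
    """Cluster, cut at every candidate height, keep the Q-optimal partition."""
    candidates = cluster_and_cut(
        net.tom, net.gene_ids, min_module_size, candidate_heights
    )
    return select_optimal_partition(candidates, net)


@dataclass
class PreservationResult:
    """Permutation preservation of one module between two networks."""

    module_genes: list[str]
    z_density: float
    z_connectivity: float
    n_perm: int
    seed: int

    @property
    def z_summary(self) -> float:
        return float(np.nanmean([self.z_density, self.z_connectivity]))

    @property
    def preserved(self) -> bool:
        return self.z_summary >= 2.0


def _module_stats(idx, ref_adj, test_adj):
    """Density in the test net; connectivity correlation between nets."""
    sub_t = test_adj[np.ix_(idx, idx)]
    m = len(idx)
    density = sub_t.sum() / (m * (m - 1))
    k_ref = ref_adj[np.ix_(idx, idx)].sum(axis=1)
    k_test = sub_t.sum(axis=1)
    if np.isclose(k_ref.std(), 0) or np.isclose(k_test.std(), 0):
        cor_k = 0.0
    else:
        cor_k = float(np.corrcoef(k_ref, k_test)[0, 1])
    return density, cor_k


def z_summary(
    module_genes,
    reference_net: CoexpressionNetwork,
    test_net: CoexpressionNetwork,
    n_perm: int = 200,
    seed: int = 0,
) -> PreservationResult:
    """Permutation Z for preservation of a module in a second network.

    Observed statistics: mean intramodular adjacency in the test network
    (density) and the correlation of intramodular connectivity between the
    reference and test networks. Both are compared against ``n_perm`` random
    gene sets of equal size drawn from the genes shared by both networks;
    Z = (obs - mean) / sd per statistic, Z_summary is their mean, and a
    module with Z_summary >= 2 counts as preserved.
    """
    module_genes = sorted(set(module_genes))
    if len(module_genes) < 3:
        raise ValueError("module must have at least 3 genes")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    common = [g for g in test_net.gene_ids if g in set(reference_net.gene_ids)]
    missing = set(module_genes) - set(common)
    if missing:
        raise ValueError(
            f"module genes absent from one of the networks: {sorted(missing)[:5]}"
        )
    pos_ref = {g: i for i, g in enumerate(reference_net.gene_ids)}
    pos_test = {g: i for i, g in enumerate(test_net.gene_ids)}
    # align both nets on the common gene order
    ref_idx_all = np.array([pos_ref[g] for g in common])
    test_idx_all = np.array([pos_test[g] for g in common])
    ref_adj = reference_net.adjacency[np.ix_(ref_idx_all, ref_idx_all)]
    test_adj = test_net.adjacency[np.ix_(test_idx_all, test_idx_all)]
    common_pos = {g: i for i, g in enumerate(common)}
    obs_idx = np.array([common_pos[g] for g in module_genes])

    obs_d, obs_c = _module_stats(obs_idx, ref_adj, test_adj)
    rng = np.random.default_rng(seed)
    perm_d = np.empty(n_perm)
    perm_c = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(common), size=len(obs_idx), replace=False)
        perm_d[i], perm_c[i] = _module_stats(idx, ref_adj, test_adj)

    def _z(obs, perm):
        sd = perm.std(ddof=1)
        if np.isclose(sd, 0.0):
            return 0.0 if np.isclose(obs, perm.mean()) else np.inf * np.sign(obs - perm.mean())
        return float((obs - perm.mean()) / sd)

    return PreservationResult(
        module_genes=module_genes,
        z_density=_z(obs_d, perm_d),
        z_connectivity=_z(obs_c, perm_c),
        n_perm=n_perm,
        seed=seed,
    )
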