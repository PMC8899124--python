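"""Weighted co-expression network construction.

Standard weighted-network recipe: Pearson correlation across one condition's
samples, unsigned soft-threshold adjacency ``|r|**beta`` with beta chosen by
the scale-free fit criterion, and the topological overlap matrix (TOM) that
rewards shared neighborhoods, whose complement ``1 - TOM`` is the clustering
dissimilarity used for module detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study import ExpressionStudy

__all__ = [
    "CoexpressionNetwork",
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency_from_correlation",
    "tom_similarity",
    "build_network",
]


@dataclass
class CoexpressionNetwork:
    """Unsigned weighted network for one condition.

    ``adjacency`` is symmetric in [0, 1] with zero diagonal (the convention
    used by all network statistics here); ``tom`` is the topological overlap
    similarity with unit diagonal.
    """

    gene_ids: list[str]
    adjacency: np.ndarray
    beta: float
    tom: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValueError("adjacency shape does not match gene ids")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a
        if self.tom is None:
            self.tom = tom_similarity(a)

    @property
    def degrees(self) -> np.ndarray:
        """Weighted connectivity k_i (row sums of the adjacency)."""
        return self.adjacency.sum(axis=1)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def correlation_matrix(
    study: ExpressionStudy, group: str, genes=None
) -> pd.DataFrame:
    """Pearson correlation of gene pairs across one group's samples.

    Diagonal is exactly 1; constant genes get correlation 0 to every other
    gene by convention.
    """
    sub = study.group_matrix(group, genes)
    if sub.shape[1] < 3:
        raise ValueError(f"group {group!r} has fewer than 3 samples")
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    x = sub.to_numpy()
    sd = x.std(axis=1)
    constant = np.isclose(sd, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(x)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=sub.index, columns=sub.index)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index of a weighted adjacency.

    R^2 of log10(frequency) vs log10(mean connectivity) over connectivity
    bins, signed: a positive degree-frequency slope (anti-scale-free) makes
    the index negative. NaN when fewer than 2 occupied bins remain.
    """
    k = adjacency.sum(axis=1)
    k = k[k > 0]
    if k.size < 2 or np.isclose(k.min(), k.max()):
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        freqs.append(mask.sum())
        means.append(k[mask].mean())
    if len(freqs) < 2:
        return np.nan
    lx = np.log10(np.asarray(means))
    ly = np.log10(np.asarray(freqs) / sum(freqs))
    r = np.corrcoef(lx, ly)[0, 1]
    if np.isnan(r):
        return np.nan
    return -np.sign(r) * r * r if r > 0 else r * r


def pick_soft_threshold(
    corr: pd.DataFrame | np.ndarray,
    candidate_powers=tuple(range(1, 21)),
    fit_cut: float = 0.8,
) -> tuple[float, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free criterion.

    Returns the smallest candidate whose fit index reaches ``fit_cut``, else
    the candidate with maximal fit; when no candidate yields a defined fit
    (degenerate connectivity spread) the smallest candidate is returned with
    a warning. Also returns the per-candidate fit table.
    """
    candidate_powers = list(candidate_powers)
    if not candidate_powers:
        raise ValueError("candidate power list is empty")
    c = np.abs(np.asarray(corr, dtype=float))
    np.fill_diagonal(c, 0.0)
    if np.allclose(c, 0.0):
        raise ValueError("degenerate network: all correlations are zero")
    rows = []
    for beta in candidate_powers:
        fit = scale_free_fit(c**beta)
        rows.append({"power": beta, "fit": fit})
    table = pd.DataFrame(rows)
    fits = table["fit"].to_numpy()
    ok = np.where(fits >= fit_cut)[0]
    if ok.size:
        chosen = candidate_powers[int(ok[0])]
    elif np.isnan(fits).all():
        warnings.warn(
            "scale-free fit undefined for every candidate power; "
            "falling back to the smallest candidate"
        )
        chosen = candidate_powers[0]
    else:
        chosen = candidate_powers[int(np.nanargmax(fits))]
    return float(chosen), table


def adjacency_from_correlation(corr, beta: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency |r|**beta with zero diagonal."""
    a = np.abs(np.asarray(corr, dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, and TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def build_network(
    study: ExpressionStudy,
    group: str,
    genes=None,
    beta: float | None = None,
    candidate_powers=tuple(range(1, 21)),
) -> CoexpressionNetwork:
    """Correlation -> soft threshold -> adjacency -> TOM for one condition."""
    corr = correlation_matrix(study, group, genes)
    if beta is None:
        beta, _ = pick_soft_threshold(corr, candidate_powers)
    adj = adjacency_from_correlation(corr, beta)
    return CoexpressionNetwork(list(corr.index), adj, beta)
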