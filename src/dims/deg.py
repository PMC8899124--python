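"""Differential-expression screen: one-way ANOVA, fold change, multiplicity.

Genes are screened per drug group against the Vehicle background: a one-way
fixed-effects ANOVA across the study groups supplies the p-value, the
direction-symmetric fold change (on the linear intensity scale) supplies the
effect-size filter, and Bonferroni (or Benjamini-Hochberg) correction guards
the family-wise error. A gene is called differentially expressed when the
adjusted p falls below ``alpha`` *and* fold change exceeds ``fc_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy

__all__ = [
    "DegScreenConfig",
    "anova_per_gene",
    "fold_change",
    "select_degs",
    "screen_group",
    "overlap_report",
]

CORRECTIONS = ("bonferroni", "benjamini-hochberg", "none")


@dataclass(frozen=True)
class DegScreenConfig:
    """Thresholds of the differential-expression screen."""

    alpha: float = 0.05
    fc_threshold: float = 1.5
    correction: str = "bonferroni"
    # override of the multiplicity universe size (e.g. full array size);
    # None means the number of genes actually tested
    n_tests: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold < 1.0:
            raise ValueError("fc_threshold must be >= 1")
        if self.correction not in CORRECTIONS:
            raise ValueError(f"correction must be one of {CORRECTIONS}")


def anova_per_gene(study: ExpressionStudy, groups: list[str] | None = None) -> pd.DataFrame:
    """Classical one-way fixed-effects ANOVA per gene across ``groups``.

    Returns a DataFrame indexed by gene with columns ``F`` and ``p``. Genes
    with zero between- and within-group variance get F = 0, p = 1 by
    convention; zero within-group variance with real between-group spread
    gives p = 0 (infinite F).
    """
    if groups is None:
        groups = study.groups
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    blocks = []
    for g in groups:
        m = study.group_matrix(g).to_numpy()
        if m.shape[1] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        blocks.append(m)

    n_total = sum(b.shape[1] for b in blocks)
    k = len(blocks)
    grand = np.hstack(blocks).mean(axis=1)
    ssb = np.zeros(len(grand))
    ssw = np.zeros(len(grand))
    for b in blocks:
        mean_g = b.mean(axis=1)
        ssb += b.shape[1] * (mean_g - grand) ** 2
        ssw += ((b - mean_g[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / df_b) / (ssw / df_w)
    p = np.full(len(grand), np.nan)
    finite = np.isfinite(f_stat)
    p[finite] = stats.f.sf(f_stat[finite], df_b, df_w)
    degenerate = np.isclose(ssw, 0.0)
    both_zero = degenerate & np.isclose(ssb, 0.0)
    p[degenerate & ~both_zero] = 0.0
    f_stat[degenerate & ~both_zero] = np.inf
    p[both_zero] = 1.0
    f_stat[both_zero] = 0.0
    return pd.DataFrame({"F": f_stat, "p": p}, index=study.gene_ids)


def fold_change(
    study: ExpressionStudy, drug_group: str, reference_group: str
) -> pd.DataFrame:
    """Direction-symmetric fold change on the linear intensity scale.

    Log2 values are exponentiated, group means taken, and
    ``fc = max(m_d / m_r, m_r / m_d)`` with direction ``up`` when the drug
    mean exceeds the reference mean.
    """
    m_d = np.exp2(study.group_matrix(drug_group).to_numpy()).mean(axis=1)
    m_r = np.exp2(study.group_matrix(reference_group).to_numpy()).mean(axis=1)
    if (m_d <= 0).any() or (m_r <= 0).any():
        raise ValueError("nonpositive linear group mean")
    ratio = m_d / m_r
    fc = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio > 1.0, "up", "down")
    return pd.DataFrame(
        {"fold_change": fc, "direction": direction}, index=study.gene_ids
    )


def select_degs(
    p: pd.Series, fc: pd.Series, config: DegScreenConfig = DegScreenConfig()
) -> pd.DataFrame:
    """Apply multiplicity correction and both thresholds jointly.

    ``p`` and ``fc`` must cover the same gene universe. Correction is applied
    across all tested genes first (Bonferroni: ``min(1, m*p)`` with m the
    number of genes tested unless ``n_tests`` overrides it), then a gene is a
    DEG iff adjusted p < alpha and fold change > fc_threshold. Rows come back
    sorted by p.
    """
    if set(p.index) != set(fc.index):
        raise ValueError("p-values and fold changes cover different gene universes")
    fc = fc.reindex(p.index)
    m = len(p)
    if config.n_tests is not None:
        if config.n_tests < m:
            raise ValueError("n_tests override smaller than number of genes tested")
        m = config.n_tests
    if config.correction == "bonferroni":
        p_adj = np.minimum(1.0, p.to_numpy() * m)
    elif config.correction == "benjamini-hochberg":
        p_adj = multipletests(p.to_numpy(), method="fdr_bh")[1]
    else:
        p_adj = p.to_numpy().copy()
    out = pd.DataFrame(
        {
            "p": p,
            "p_adjusted": p_adj,
            "fold_change": fc,
            "is_deg": (p_adj < config.alpha) & (fc.to_numpy() > config.fc_threshold),
        },
        index=p.index,
    )
    return out.sort_values("p", kind="stable")


def screen_group(
    study: ExpressionStudy,
    drug_group: str,
    reference_group: str,
    config: DegScreenConfig = DegScreenConfig(),
    anova_groups: list[str] | None = None,
) -> pd.DataFrame:
    """Full screen of one drug group vs the reference.

    The ANOVA runs across ``anova_groups`` (default: all study groups, the
    omnibus design); fold change is specific to the drug/reference pair.
    Returns per-gene F, p, adjusted p, fold change, direction and the DEG
    flag, sorted by p.
    """
    aov = anova_per_gene(study, anova_groups)
    fc = fold_change(study, drug_group, reference_group)
    sel = select_degs(aov["p"], fc["fold_change"], config)
    sel.insert(0, "F", aov["F"].reindex(sel.index))
    sel["direction"] = fc["direction"].reindex(sel.index)
    return sel


def overlap_report(
    deg_sets: dict[str, set[str]], reference: set[str] | None = None
) -> dict:
    """Intersection bookkeeping across named DEG sets and a reference list.

    Reports set sizes, all pairwise and higher-order intersection counts,
    unique-per-set counts, and — when a reference gene list is given — the
    overlap count, the percentage of the reference covered by the union of
    all sets (one decimal), and per-set Jaccard with the reference.
    """
    names = list(deg_sets)
    sets = {n: set(s) for n, s in deg_sets.items()}
    union_all = set().union(*sets.values()) if sets else set()
    report: dict = {
        "set_sizes": {n: len(s) for n, s in sets.items()},
        "union_size": len(union_all),
        "intersections": {},
        "unique": {},
    }
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            report["intersections"]["&".join(combo)] = len(inter)
    for n in names:
        if len(names) > 1:
            unique = sets[n] - set().union(*(sets[m] for m in names if m != n))
        else:
            unique = sets[n]
        report["unique"][n] = len(unique)
    if reference is not None:
        reference = set(reference)
        covered = union_all & reference
        report["reference_size"] = len(reference)
        report["reference_overlap"] = len(covered)
        report["reference_coverage_pct"] = (
            round(100.0 * len(covered) / len(reference), 1) if reference else 0.0
        )
        report["reference_jaccard"] = {
            n: (len(sets[n] & reference) / len(sets[n] | reference))
            if sets[n] | reference
            else 0.0
            for n in names
        }
        report["reference_overlap_members"] = sorted(covered)
    report["members"] = {n: sorted(s) for n, s in sets.items()}
    return report
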