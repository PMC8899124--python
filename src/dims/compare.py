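"""Cross-condition module comparison and classification.

Modules of two condition networks are compared by the pairwise Jaccard
matrix B; each module's response score ``s`` is its best match
(``s_i = max_j B_ij``). With the score spread anchored by its extremes, a
module scoring below ``min(s) + theta1`` is drug-responsive (an On-module)
and one above ``max(s) - theta2`` is conserved. An On-module of the
combination that stays On against *both* monotherapies is an additive
(Add-) module. Over-representation of gene sets in a module uses the
one-sided Fisher exact test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .modules import ModulePartition

__all__ = [
    "ModuleSimilarityMatrix",
    "ModuleClassification",
    "AddModuleResult",
    "set_jaccard",
    "module_similarity_matrix",
    "classify_modules",
    "identify_add_modules",
    "enrich_gene_sets",
    "read_gmt",
]

LABELS = ("conserved", "on-module", "intermediate", "ambiguous")


def set_jaccard(a, b) -> float:
    """Jaccard index |a & b| / |a | b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class ModuleSimilarityMatrix:
    """Jaccard matrix B between two partitions' module gene sets."""

    row_modules: list[int]
    col_modules: list[int]
    b: pd.DataFrame  # rows: condition-1 modules, cols: condition-2 modules

    @property
    def s(self) -> pd.Series:
        """Per-row response score: best Jaccard match of each row module."""
        return self.b.max(axis=1)


def module_similarity_matrix(
    partition1: ModulePartition, partition2: ModulePartition
) -> ModuleSimilarityMatrix:
    """Pairwise Jaccard similarity between the proper modules of two
    partitions (unassigned genes excluded)."""
    mods1 = partition1.modules()
    mods2 = partition2.modules()
    if not mods1 or not mods2:
        raise ValueError("each partition must contain at least one proper module")
    b = pd.DataFrame(
        [[set_jaccard(mods1[i], mods2[j]) for j in mods2] for i in mods1],
        index=list(mods1),
        columns=list(mods2),
        dtype=float,
    )
    return ModuleSimilarityMatrix(list(mods1), list(mods2), b)


@dataclass
class ModuleClassification:
    """Label of one module from the similarity-score spread."""

    module_id: int
    s: float
    label: str
    theta1: float
    theta2: float
    s_min: float
    s_max: float


def classify_modules(
    sim: ModuleSimilarityMatrix, theta1: float = 0.1, theta2: float = 0.1
) -> list[ModuleClassification]:
    """Classify each row module as conserved / on-module / intermediate.

    Strict inequalities: On when ``s < min(s) + theta1``, conserved when
    ``s > max(s) - theta2``. A module satisfying both (possible when the
    score spread is narrower than theta1 + theta2) is labeled ambiguous and
    a warning is emitted.
    """
    if theta1 < 0 or theta2 < 0:
        raise ValueError("theta thresholds must be >= 0")
    s = sim.s
    lo, hi = float(s.min()), float(s.max())
    on_cut, cm_cut = lo + theta1, hi - theta2
    out = []
    any_ambiguous = False
    for m, si in s.items():
        on_eligible = si < on_cut
        cm_eligible = si > cm_cut
        if on_eligible and cm_eligible:
            label = "ambiguous"
            any_ambiguous = True
        elif on_eligible:
            label = "on-module"
        elif cm_eligible:
            label = "conserved"
        else:
            label = "intermediate"
        out.append(
            ModuleClassification(int(m), float(si), label, theta1, theta2, lo, hi)
        )
    if any_ambiguous:
        warnings.warn(
            "similarity-score spread narrower than theta1 + theta2: "
            "overlapping-eligible modules labeled ambiguous"
        )
    return out


def on_module_ids(classifications: list[ModuleClassification]) -> set[int]:
    return {c.module_id for c in classifications if c.label == "on-module"}


def conserved_module_ids(classifications: list[ModuleClassification]) -> set[int]:
    return {c.module_id for c in classifications if c.label == "conserved"}


@dataclass
class AddModuleResult:
    """Combination-specific (additive) module screen."""

    on_vs_vehicle: set[int]
    on_vs_mono_a: set[int]
    on_vs_mono_b: set[int]
    add_modules: set[int]
    gene_lists: dict[int, list[str]]
    deg_overlap: dict | None = None


def identify_add_modules(
    on_vs_vehicle: set[int],
    class_vs_mono_a: list[ModuleClassification],
    class_vs_mono_b: list[ModuleClassification],
    partition: ModulePartition,
    combo_specific_degs: set[str] | None = None,
) -> AddModuleResult:
    """Screen the combination's On-modules for additive modules.

    An Add-module is an On-module vs Vehicle that is *also* labeled
    on-module against each monotherapy's network. ``partition`` is the
    combination partition the classifications were computed on; when the
    combination-specific DEG list is given, overlap statistics (count and
    Jaccard) of the pooled Add-module genes against it are attached.
    """
    ids_a = {c.module_id for c in class_vs_mono_a}
    ids_b = {c.module_id for c in class_vs_mono_b}
    known = set(partition.module_ids)
    for name, ids in (("vs-monoA", ids_a), ("vs-monoB", ids_b), ("vs-vehicle", on_vs_vehicle)):
        if not ids <= known:
            raise ValueError(
                f"classification {name} refers to unknown module ids {sorted(ids - known)}"
            )
    on_a = on_module_ids(class_vs_mono_a)
    on_b = on_module_ids(class_vs_mono_b)
    add = set(on_vs_vehicle) & on_a & on_b
    gene_lists = {m: sorted(partition.members(m)) for m in sorted(add)}
    deg_overlap = None
    if combo_specific_degs is not None:
        pooled = {g for genes in gene_lists.values() for g in genes}
        inter = pooled & set(combo_specific_degs)
        deg_overlap = {
            "add_module_genes": len(pooled),
            "combo_specific_degs": len(set(combo_specific_degs)),
            "overlap": len(inter),
            "overlap_pct_of_add_genes": (
                round(100.0 * len(inter) / len(pooled)) if pooled else 0
            ),
            "jaccard": set_jaccard(pooled, combo_specific_degs),
        }
    return AddModuleResult(
        on_vs_vehicle=set(on_vs_vehicle),
        on_vs_mono_a=on_a,
        on_vs_mono_b=on_b,
        add_modules=add,
        gene_lists=gene_lists,
        deg_overlap=deg_overlap,
    )


def enrich_gene_sets(
    module_genes, universe, collection: dict[str, set[str]], alpha: float = 0.05
) -> pd.DataFrame:
    """Over-representation of named gene sets in a module.

    One-sided Fisher exact (hypergeometric upper tail) p per set from the
    2x2 table of module membership vs set membership within the universe,
    BH adjustment across the collection, rows sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    module_genes = set(module_genes)
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    rows = []
    for name, genes in collection.items():
        genes = set(genes) & universe
        overlap = len(genes & module_genes)
        # hypergeometric upper tail: P(X >= overlap)
        p = float(
            stats.hypergeom.sf(
                overlap - 1, len(universe), len(genes), len(module_genes)
            )
        )
        rows.append(
            {
                "gene_set": name,
                "overlap": overlap,
                "set_size": len(genes),
                "universe_size": len(universe),
                "module_size": len(module_genes),
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "gene_set", "overlap", "set_size", "universe_size",
                "module_size", "p", "p_adjusted", "significant",
            ]
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["p_adjusted"] < alpha
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set collection (name, description, members...)."""
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            collection[parts[0]] = {g for g in parts[2:] if g}
    return collection
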