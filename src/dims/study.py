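"""Expression study container and plain-text I/O.

An :class:`ExpressionStudy` holds a genes x samples matrix of log2-scale
intensities together with a sample -> group design. It is the universal
input of every pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionStudy", "read_study", "write_study_tables"]


@dataclass
class ExpressionStudy:
    """Genes x samples expression matrix with a sample -> group design.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample; entries are
        log2-scale intensities.
    design
        Series mapping sample id -> group label, indexed by sample id, in the
        same order as ``values.columns``.
    """

    values: pd.DataFrame
    design: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        self.design = self.design.reindex(self.values.columns)
        if self.design.isna().any():
            missing = self.design.index[self.design.isna()]
            raise ValueError(f"samples missing from design: {list(missing[:5])}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance in the design."""
        return list(dict.fromkeys(self.design))

    def samples_of(self, group: str) -> list[str]:
        if group not in set(self.design):
            raise KeyError(f"group {group!r} not present in design")
        return list(self.design.index[self.design == group])

    def group_matrix(self, group: str, genes=None) -> pd.DataFrame:
        """Sub-matrix of one group's samples, optionally restricted to genes."""
        cols = self.samples_of(group)
        sub = self.values[cols]
        if genes is not None:
            genes = list(genes)
            missing = set(genes) - set(sub.index)
            if missing:
                raise KeyError(f"genes not in study: {sorted(missing)[:5]}")
            sub = sub.loc[genes]
        return sub

    def subset_genes(self, genes) -> "ExpressionStudy":
        return ExpressionStudy(self.values.loc[list(genes)].copy(), self.design.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        return (
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.allclose(self.values.to_numpy(), other.values.to_numpy())
            and self.design.tolist() == other.design.tolist()
        )


def write_study_tables(study: ExpressionStudy, directory: str | Path) -> dict[str, Path]:
    """Write expression and design TSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr_path = directory / "expression.tsv"
    design_path = directory / "design.tsv"
    out = study.values.copy()
    out.index.name = "gene_id"
    out.to_csv(expr_path, sep="\t")
    design = study.design.rename("group").rename_axis("sample_id")
    design.to_csv(design_path, sep="\t")
    return {"expression": expr_path, "design": design_path}


def read_study(expression: str | Path, design: str | Path) -> ExpressionStudy:
    """Load a study from an expression TSV and a two-column design TSV.

    The expression TSV has gene ids in the first column and one column per
    sample; the design TSV maps sample id -> group. Duplicate gene or sample
    ids are rejected.
    """
    values = pd.read_csv(expression, sep="\t", index_col=0)
    des = pd.read_csv(design, sep="\t", index_col=0)
    if des.shape[1] != 1:
        raise ValueError("design must have exactly two columns: sample, group")
    return ExpressionStudy(values, des.iloc[:, 0])
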