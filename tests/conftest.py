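import numpy as np
import pandas as pd
import pytest

from dims.simulate import PlantedModuleSpec, StudyConfig, generate_study
from dims.study import ExpressionStudy


def make_study(arrays: dict[str, np.ndarray], gene_ids=None) -> ExpressionStudy:
    """Build a study from {group: genes x samples array} blocks."""
    blocks, design, cols = [], [], []
    for g, a in arrays.items():
        a = np.atleast_2d(np.asarray(a, dtype=float))
        blocks.append(a)
        for i in range(a.shape[1]):
            cols.append(f"{g}_{i + 1}")
            design.append(g)
    values = np.hstack(blocks)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    return ExpressionStudy(
        pd.DataFrame(values, index=gene_ids, columns=cols),
        pd.Series(design, index=cols),
    )


@pytest.fixture(scope="session")
def small_config():
    """A reduced synthetic study: quick, but with all planted-module classes."""
    all_groups = ("Sham", "Vehicle", "DrugA", "DrugB", "Combo")
    return StudyConfig(
        n_genes=500,
        module_specs=[
            PlantedModuleSpec("cons1", 35, all_groups, 0.8),
            PlantedModuleSpec("cons2", 30, all_groups, 0.8),
            PlantedModuleSpec("shared", 30, ("DrugA", "DrugB", "Combo"), 0.8),
            PlantedModuleSpec("combo_only", 30, ("Combo",), 0.7, n_drivers=1),
        ],
        deg_fraction=0.08,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)
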