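"""Classify modules by cross-condition Jaccard similarity; screen Add-modules.

Each drug group's modules are scored against the Vehicle background partition
(s = best Jaccard match); modules below min(s)+theta1 are On-modules
(drug-responsive), above max(s)-theta2 conserved. The combination's
On-modules that stay On against both monotherapies' partitions are the
additive (Add-) modules; their genes are compared with the
combination-specific DEG list.

Reads:  results/modules/, results/degs/
Writes: results/add_modules.json, results/similarity/*.tsv
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dims.compare import (classify_modules, identify_add_modules,
                          module_similarity_matrix, on_module_ids)
from dims.modules import ModulePartition

ROOT = Path(__file__).resolve().parents[1] / "results"
THETA1 = THETA2 = 0.1


def read_partition(path: Path) -> ModulePartition:
    frame = pd.read_csv(path, sep="\t")
    return ModulePartition(list(frame["gene_id"]), frame["module_id"].to_numpy(),
                           cut_height=np.nan, min_module_size=3)


def deg_set(group: str) -> set[str]:
    t = pd.read_csv(ROOT / "degs" / f"{group}.tsv", sep="\t", index_col=0)
    return set(t.index[t["is_deg"]])


def main() -> None:
    meta = json.loads((ROOT / "modules" / "meta.json").read_text())
    drug_groups = [k for k in meta if not k.startswith(("Vehicle_bg_", "preservation"))]
    mono_a, mono_b, combo = drug_groups
    (ROOT / "similarity").mkdir(parents=True, exist_ok=True)

    parts = {g: read_partition(ROOT / "modules" / f"{g}.tsv") for g in drug_groups}
    classifications, on_ids = {}, {}
    for g in drug_groups:
        vehicle = read_partition(ROOT / "modules" / f"Vehicle_bg_{g}.tsv")
        sim = module_similarity_matrix(parts[g], vehicle)
        sim.b.to_csv(ROOT / "similarity" / f"{g}_vs_vehicle.tsv", sep="\t")
        cls = classify_modules(sim, THETA1, THETA2)
        classifications[g] = cls
        on_ids[g] = on_module_ids(cls)
        labels = {c.module_id: c.label for c in cls}
        print(f"{g} vs Vehicle: s = "
              + ", ".join(f"M{c.module_id}:{c.s:.2f}({c.label})" for c in cls))

    cls_a = classify_modules(module_similarity_matrix(parts[combo], parts[mono_a]),
                             THETA1, THETA2)
    cls_b = classify_modules(module_similarity_matrix(parts[combo], parts[mono_b]),
                             THETA1, THETA2)
    combo_specific = deg_set(combo) - deg_set(mono_a) - deg_set(mono_b)
    result = identify_add_modules(on_ids[combo], cls_a, cls_b, parts[combo],
                                  combo_specific)
    print(f"{combo} On-modules vs Vehicle: {sorted(result.on_vs_vehicle)}; "
          f"vs {mono_a}: {sorted(result.on_vs_mono_a)}; "
          f"vs {mono_b}: {sorted(result.on_vs_mono_b)}")
    print(f"Add-modules: {sorted(result.add_modules)} "
          f"({sum(len(v) for v in result.gene_lists.values())} genes)")
    ov = result.deg_overlap
    print(f"overlap with {combo}-specific DEGs: {ov['overlap']} of "
          f"{ov['add_module_genes']} Add-module genes "
          f"({ov['overlap_pct_of_add_genes']}%), Jaccard {ov['jaccard']:.3f}")
    (ROOT / "add_modules.json").write_text(json.dumps({
        "roles": {"mono_a": mono_a, "mono_b": mono_b, "combo": combo},
        "add_modules": sorted(result.add_modules),
        "gene_lists": result.gene_lists,
        "deg_overlap": result.deg_overlap,
    }, indent=1))


if __name__ == "__main__":
    main()
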