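"""Build per-condition co-expression networks and detect modules.

For each drug group, an unsigned weighted network (power 6) is built on that
group's DEGs from its own samples, plus a Vehicle background network on the
same genes from Vehicle samples; modules come from average-linkage clustering
of 1 - TOM with the cut height chosen by maximal modularity Q. A permutation
Z_summary checks which combination modules are preserved in the Vehicle
network (conserved biology) and which are not (drug-responsive candidates).

Reads:  results/study/, results/degs/
Writes: results/modules/{condition}.tsv, results/modules/meta.json
"""

import json
from pathlib import Path

import pandas as pd

from dims.modules import detect_modules, z_summary
from dims.network import build_network
from dims.simulate import load_study

ROOT = Path(__file__).resolve().parents[1] / "results"
SOFT_POWER = 6.0
MIN_MODULE_SIZE = 10
N_PERM = 200


def main() -> None:
    study, truth = load_study(ROOT / "study")
    out = ROOT / "modules"
    out.mkdir(parents=True, exist_ok=True)
    drug_groups = truth.drug_groups if truth else [g for g in study.groups
                                                  if g not in ("Sham", "Vehicle")]
    meta = {}
    nets, parts = {}, {}
    for g in drug_groups:
        degs = pd.read_csv(ROOT / "degs" / f"{g}.tsv", sep="\t", index_col=0)
        genes = sorted(degs.index[degs["is_deg"]])
        for condition, label in ((g, g), ("Vehicle", f"Vehicle_bg_{g}")):
            net = build_network(study, condition, genes, beta=SOFT_POWER)
            part = detect_modules(net, MIN_MODULE_SIZE)
            nets[label], parts[label] = net, part
            part.to_frame().to_csv(out / f"{label}.tsv", sep="\t", index=False)
            meta[label] = {
                "n_genes": net.n_genes,
                "beta": net.beta,
                "n_modules": len(part.module_ids),
                "q": part.q,
                "cut_height": part.cut_height,
                "n_unassigned": part.n_unassigned,
            }
            print(f"{label}: {meta[label]['n_modules']} modules from "
                  f"{net.n_genes} genes, Q={part.q:.3f}")

    combo = drug_groups[-1]
    pres = {}
    for mid in parts[combo].module_ids:
        res = z_summary(parts[combo].members(mid), nets[combo],
                        nets[f"Vehicle_bg_{combo}"], n_perm=N_PERM, seed=1000 + mid)
        pres[mid] = round(res.z_summary, 2)
    meta["preservation_of_combo_modules_in_vehicle"] = pres
    print(f"{combo} module preservation in Vehicle (Z_summary, >=2 preserved): {pres}")
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


if __name__ == "__main__":
    main()
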