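"""Identify synergistic driver genes of the Add-modules by network control.

Per Add-module, a differential co-expression network (|corr change| >= 0.5)
between the combination and each monotherapy is oriented hub -> periphery and
its possible drivers (nodes belonging to at least one minimum driver set
under maximum matching) are computed; drivers shared by both comparisons are
the synergistic drivers. Five centrality indicators on each Add-module's
combination-condition co-expression network validate that drivers — and in
particular the planted hubs — occupy topologically important positions.

Reads:  results/study/, results/add_modules.json
Writes: results/drivers.json, results/importance.tsv
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dims.drivers import (DirectedInteractionNetwork, build_condition_network,
                          minimum_driver_set, node_importance, orient_edges,
                          possible_drivers, synergistic_drivers,
                          validate_drivers, IMPORTANCE_METRICS)
from dims.network import correlation_matrix
from dims.simulate import load_study

ROOT = Path(__file__).resolve().parents[1] / "results"
CORR_THRESHOLD = 0.5


def main() -> None:
    study, truth = load_study(ROOT / "study")
    add = json.loads((ROOT / "add_modules.json").read_text())
    mono_a, mono_b, combo = (add["roles"][k] for k in ("mono_a", "mono_b", "combo"))
    gene_lists = {int(k): v for k, v in add["gene_lists"].items()}

    unions = {}
    per_module = {}
    for mono in (mono_a, mono_b):
        union = set()
        for mid, genes in gene_lists.items():
            net = build_condition_network(genes, study, (combo, mono), CORR_THRESHOLD)
            ds = minimum_driver_set(net)
            poss = possible_drivers(net)
            per_module[f"M{mid}_vs_{mono}"] = {
                "n_arcs": len(net.arcs), "matching_size": ds.matching_size,
                "n_d": ds.n_d, "possible_drivers": len(poss),
            }
            union |= set(poss)
        unions[mono] = union
        print(f"vs {mono}: {len(union)} possible drivers over "
              f"{len(gene_lists)} Add-module networks")
    syn = synergistic_drivers(unions[mono_a], unions[mono_b])
    print(f"synergistic drivers (intersection): {len(syn)}")

    frames = []
    for mid, genes in gene_lists.items():
        corr = correlation_matrix(study, combo, sorted(set(genes)))
        glist = list(corr.index)
        ii, jj = np.where(np.triu(np.abs(corr.to_numpy()) >= CORR_THRESHOLD, k=1))
        edges = [(glist[i], glist[j]) for i, j in zip(ii, jj)]
        deg = {g: 0 for g in glist}
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        net = DirectedInteractionNetwork(glist, orient_edges(edges, deg),
                                         f"M{mid}_coexpr_{combo}")
        table = node_importance(net)
        table["module_id"] = mid
        frames.append(table)
    importance = pd.concat(frames)
    importance.to_csv(ROOT / "importance.tsv", sep="\t")
    validation = validate_drivers(importance[list(IMPORTANCE_METRICS)], syn)
    print("driver vs non-driver rank-sum p:",
          {m: f"{p:.2e}{validation.stars[m]}" for m, p in validation.p_values.items()})
    if truth:
        hubs = truth.all_driver_genes
        print(f"planted hubs: {hubs}; recovered in synergistic set: "
              f"{[h for h in hubs if h in syn]}")
        decs = {h: int(validation.deciles.loc[h, "degree_centrality"])
                for h in hubs if h in validation.deciles.index}
        print(f"planted hub degree-centrality decile (10 = top): {decs}")
    (ROOT / "drivers.json").write_text(json.dumps({
        "per_module": per_module,
        "union_vs_mono_a": sorted(unions[mono_a]),
        "union_vs_mono_b": sorted(unions[mono_b]),
        "synergistic": syn,
        "validation_p": validation.p_values,
    }, indent=1))


if __name__ == "__main__":
    main()
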