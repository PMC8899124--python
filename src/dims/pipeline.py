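"""End-to-end orchestration of the modular screening pipeline.

Stages: ingest or simulate a five-group study -> per-drug-group DEG screen vs
Vehicle -> per-condition co-expression networks and Q-optimal module
partitions -> On-/conserved-module classification against the Vehicle
background -> combination-specific (Add-) module screen against both
monotherapies -> minimum-control driver genes per Add-module with the
synergistic intersection -> centrality-based driver validation, and an
optional permutation preservation check of the combination's modules in the
Vehicle network. Every stage writes its artifact under the output directory
and the run report collects all ids, counts and statistics.

Stage seeds are derived from the master seed by fixed offsets (simulation:
+0, preservation permutations: +1000 + module id), recorded in the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import compare, deg, drivers as drv, modules as mod, network as net
from .simulate import GroundTruth, StudyConfig, generate_study, write_study
from .study import ExpressionStudy, read_study

__all__ = ["PipelineConfig", "run_pipeline", "summarize_counts"]

SEED_OFFSET_SIMULATE = 0
SEED_OFFSET_PRESERVATION = 1000


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    Group roles: ``vehicle`` is the untreated background, ``mono_a``/
    ``mono_b`` the monotherapies, ``combo`` the combination; they must name
    distinct groups of the study design.
    """

    # input
    source: str = "simulate"  # "simulate" | "files"
    study_config: StudyConfig | None = None
    expression_path: str | None = None
    design_path: str | None = None
    reference_genes_path: str | None = None
    # group roles
    vehicle: str = "Vehicle"
    mono_a: str = "DrugA"
    mono_b: str = "DrugB"
    combo: str = "Combo"
    # DEG screen
    alpha: float = 0.05
    fc_threshold: float = 1.5
    correction: str = "bonferroni"
    anova_groups: str = "all"  # "all" | "pair"
    # networks / modules
    soft_power: float | str = 6.0  # numeric, or "auto" for scale-free selection
    min_module_size: int = 10
    # module comparison
    theta1: float = 0.1
    theta2: float = 0.1
    # drivers
    corr_threshold: float = 0.5
    driver_mode: str = "possible"  # "possible" | "canonical"
    orientation: str = "degree"
    # preservation
    run_preservation: bool = True
    n_perm: int = 200
    # misc
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        roles = [self.vehicle, self.mono_a, self.mono_b, self.combo]
        if len(set(roles)) != 4:
            raise ValueError(f"group roles must be four distinct labels, got {roles}")
        if self.source not in ("simulate", "files"):
            raise ValueError("source must be 'simulate' or 'files'")
        if self.source == "files" and not (self.expression_path and self.design_path):
            raise ValueError("source='files' requires expression_path and design_path")
        if self.driver_mode not in ("possible", "canonical"):
            raise ValueError("driver_mode must be 'possible' or 'canonical'")
        if self.anova_groups not in ("all", "pair"):
            raise ValueError("anova_groups must be 'all' or 'pair'")
        if not (0 <= self.theta1 and 0 <= self.theta2):
            raise ValueError("theta thresholds must be >= 0")
        if isinstance(self.soft_power, str) and self.soft_power != "auto":
            raise ValueError("soft_power must be numeric or 'auto'")


def _load_input(config: PipelineConfig) -> tuple[ExpressionStudy, GroundTruth | None]:
    if config.source == "files":
        return read_study(config.expression_path, config.design_path), None
    sc = config.study_config or StudyConfig()
    sc.seed = config.seed + SEED_OFFSET_SIMULATE
    sc.__post_init__()
    return generate_study(sc)


def _condition_partition(
    study: ExpressionStudy, group: str, genes: list[str], config: PipelineConfig
) -> tuple[net.CoexpressionNetwork, mod.ModulePartition]:
    beta = None if config.soft_power == "auto" else float(config.soft_power)
    network = net.build_network(study, group, genes, beta=beta)
    partition = mod.detect_modules(network, config.min_module_size)
    return network, partition


def _classify(
    partition_a: mod.ModulePartition,
    partition_b: mod.ModulePartition,
    config: PipelineConfig,
):
    sim = compare.module_similarity_matrix(partition_a, partition_b)
    cls = compare.classify_modules(sim, config.theta1, config.theta2)
    return sim, cls


def _driver_sets_for_modules(
    study: ExpressionStudy,
    gene_lists: dict[int, list[str]],
    condition_pair: tuple[str, str],
    config: PipelineConfig,
) -> dict[int, dict[str, Any]]:
    out = {}
    for mid, genes in gene_lists.items():
        network = drv.build_condition_network(
            genes, study, condition_pair, config.corr_threshold, config.orientation
        )
        ds = drv.minimum_driver_set(network)
        entry = {
            "n_nodes": network.n_nodes,
            "n_arcs": len(network.arcs),
            "matching_size": ds.matching_size,
            "n_d": ds.n_d,
            "drivers": ds.drivers,
        }
        if config.driver_mode == "possible":
            entry["drivers"] = drv.possible_drivers(network)
        out[mid] = entry
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run report (a JSON-able dict).

    When ``config.out_dir`` is set, per-stage artifact files and the report
    itself are written there. Identical config + seed give identical reports.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "stage_seeds": {
            "simulate": config.seed + SEED_OFFSET_SIMULATE,
            "preservation_base": config.seed + SEED_OFFSET_PRESERVATION,
        },
        "parameters": {
            "alpha": config.alpha,
            "fc_threshold": config.fc_threshold,
            "correction": config.correction,
            "soft_power": config.soft_power,
            "min_module_size": config.min_module_size,
            "theta1": config.theta1,
            "theta2": config.theta2,
            "corr_threshold": config.corr_threshold,
            "driver_mode": config.driver_mode,
            "orientation": config.orientation,
        },
    }

    study, truth = _load_input(config)
    for role in (config.vehicle, config.mono_a, config.mono_b, config.combo):
        if role not in study.groups:
            raise ValueError(f"role group {role!r} missing from study design")
    if out_dir and truth is not None:
        write_study(study, truth, out_dir / "study")
    report["groups"] = study.groups
    report["n_genes"] = len(study.gene_ids)
    report["n_samples"] = len(study.sample_ids)

    # ---- stage 1: DEG screen per drug group vs Vehicle -------------------
    drug_groups = [config.mono_a, config.mono_b, config.combo]
    screen_cfg = deg.DegScreenConfig(
        alpha=config.alpha, fc_threshold=config.fc_threshold, correction=config.correction
    )
    deg_tables: dict[str, pd.DataFrame] = {}
    deg_sets: dict[str, set[str]] = {}
    for g in drug_groups:
        groups = None if config.anova_groups == "all" else [g, config.vehicle]
        table = deg.screen_group(study, g, config.vehicle, screen_cfg, groups)
        deg_tables[g] = table
        deg_sets[g] = set(table.index[table["is_deg"]])
        if out_dir:
            (out_dir / "degs").mkdir(exist_ok=True)
            table.to_csv(out_dir / "degs" / f"{g}.tsv", sep="\t")
    report["deg_counts"] = {g: len(deg_sets[g]) for g in drug_groups}

    reference = None
    if config.reference_genes_path:
        reference = {
            line.strip()
            for line in Path(config.reference_genes_path).read_text().splitlines()
            if line.strip()
        }
    overlap = deg.overlap_report({g: deg_sets[g] for g in drug_groups}, reference)
    report["deg_overlap"] = {
        k: v for k, v in overlap.items() if k not in ("members", "reference_overlap_members")
    }
    if out_dir:
        (out_dir / "deg_overlap.json").write_text(json.dumps(overlap, indent=1))

    empty = [g for g in drug_groups if not deg_sets[g]]
    if empty:
        raise RuntimeError(
            f"stage deg_screen: no DEGs for group(s) {empty}; "
            "cannot build condition networks"
        )

    # ---- stage 2: condition networks + module partitions -----------------
    networks: dict[str, net.CoexpressionNetwork] = {}
    partitions: dict[str, mod.ModulePartition] = {}
    for g in drug_groups:
        genes = sorted(deg_sets[g])
        networks[g], partitions[g] = _condition_partition(study, g, genes, config)
    # Vehicle background network per drug group, on that group's DEG genes
    vehicle_nets: dict[str, net.CoexpressionNetwork] = {}
    vehicle_parts: dict[str, mod.ModulePartition] = {}
    for g in drug_groups:
        genes = sorted(deg_sets[g])
        vehicle_nets[g], vehicle_parts[g] = _condition_partition(
            study, config.vehicle, genes, config
        )
    report["module_counts"] = {g: len(partitions[g].module_ids) for g in drug_groups}
    report["module_assignments"] = {
        g: dict(zip(partitions[g].gene_ids, partitions[g].labels.tolist()))
        for g in drug_groups
    }
    report["modularity_q"] = {g: partitions[g].q for g in drug_groups}
    if out_dir:
        (out_dir / "modules").mkdir(exist_ok=True)
        for g in drug_groups:
            partitions[g].to_frame().to_csv(
                out_dir / "modules" / f"{g}.tsv", sep="\t", index=False
            )

    # ---- stage 3: On-/conserved-module classification vs Vehicle ---------
    classifications: dict[str, list] = {}
    on_ids: dict[str, set[int]] = {}
    conserved_ids: dict[str, set[int]] = {}
    for g in drug_groups:
        sim, cls = _classify(partitions[g], vehicle_parts[g], config)
        classifications[g] = cls
        on_ids[g] = compare.on_module_ids(cls)
        conserved_ids[g] = compare.conserved_module_ids(cls)
        if out_dir:
            (out_dir / "similarity").mkdir(exist_ok=True)
            sim.b.to_csv(out_dir / "similarity" / f"{g}_vs_vehicle.tsv", sep="\t")
    report["on_modules"] = {g: sorted(on_ids[g]) for g in drug_groups}
    report["conserved_modules"] = {g: sorted(conserved_ids[g]) for g in drug_groups}

    # ---- stage 4: Add-module screen --------------------------------------
    _, cls_vs_a = _classify(partitions[config.combo], partitions[config.mono_a], config)
    _, cls_vs_b = _classify(partitions[config.combo], partitions[config.mono_b], config)
    combo_specific_degs = (
        deg_sets[config.combo] - deg_sets[config.mono_a] - deg_sets[config.mono_b]
    )
    add_result = compare.identify_add_modules(
        on_ids[config.combo],
        cls_vs_a,
        cls_vs_b,
        partitions[config.combo],
        combo_specific_degs,
    )
    report["add_modules"] = sorted(add_result.add_modules)
    report["add_module_genes"] = add_result.gene_lists
    report["add_module_deg_overlap"] = add_result.deg_overlap
    report["combo_specific_deg_count"] = len(combo_specific_degs)
    if out_dir:
        (out_dir / "add_modules.json").write_text(
            json.dumps(
                {
                    "add_modules": sorted(add_result.add_modules),
                    "on_vs_vehicle": sorted(add_result.on_vs_vehicle),
                    "on_vs_mono_a": sorted(add_result.on_vs_mono_a),
                    "on_vs_mono_b": sorted(add_result.on_vs_mono_b),
                    "gene_lists": add_result.gene_lists,
                    "deg_overlap": add_result.deg_overlap,
                },
                indent=1,
            )
        )

    # ---- stage 5: drivers of the Add-modules -----------------------------
    report["drivers"] = {}
    synergistic: list[str] = []
    if add_result.add_modules:
        per_a = _driver_sets_for_modules(
            study, add_result.gene_lists, (config.combo, config.mono_a), config
        )
        per_b = _driver_sets_for_modules(
            study, add_result.gene_lists, (config.combo, config.mono_b), config
        )
        union_a = sorted({d for e in per_a.values() for d in e["drivers"]})
        union_b = sorted({d for e in per_b.values() for d in e["drivers"]})
        synergistic = drv.synergistic_drivers(set(union_a), set(union_b))
        report["drivers"] = {
            "per_module_vs_mono_a": per_a,
            "per_module_vs_mono_b": per_b,
            "union_vs_mono_a": union_a,
            "union_vs_mono_b": union_b,
            "synergistic": synergistic,
        }
        if out_dir:
            (out_dir / "drivers.json").write_text(json.dumps(report["drivers"], indent=1))
    else:
        warnings.warn("no Add-modules found; driver stage skipped")
    report["synergistic_drivers"] = synergistic

    # ---- stage 6: driver validation on the Add-module networks -----------
    report["driver_validation"] = None
    if synergistic:
        frames = []
        for mid, genes in add_result.gene_lists.items():
            # importance lives on the combination-condition co-expression
            # graph of the module, not the differential control network
            corr = net.correlation_matrix(study, config.combo, sorted(set(genes)))
            ii, jj = np.where(
                np.triu(np.abs(corr.to_numpy()) >= config.corr_threshold, k=1)
            )
            glist = list(corr.index)
            edges = [(glist[i], glist[j]) for i, j in zip(ii, jj)]
            degree: dict[str, int] = {x: 0 for x in glist}
            for u, v in edges:
                degree[u] += 1
                degree[v] += 1
            coexpr_net = drv.DirectedInteractionNetwork(
                glist, drv.orient_edges(edges, degree), f"add_module_{mid}_coexpr"
            )
            table = drv.node_importance(coexpr_net)
            table["module_id"] = mid
            frames.append(table)
        importance = pd.concat(frames)
        is_driver = importance.index.isin(set(synergistic))
        if is_driver.any() and not is_driver.all():
            validation = drv.validate_drivers(
                importance[list(drv.IMPORTANCE_METRICS)], synergistic
            )
            report["driver_validation"] = {
                "p_values": validation.p_values,
                "stars": validation.stars,
                "n_drivers": validation.n_drivers,
                "n_non_drivers": validation.n_non_drivers,
            }
            if out_dir:
                importance.to_csv(out_dir / "importance.tsv", sep="\t")
                validation.deciles.to_csv(out_dir / "driver_deciles.tsv", sep="\t")
            report["driver_deciles"] = {
                g: {m: int(validation.deciles.loc[g, m]) for m in drv.IMPORTANCE_METRICS}
                for g in synergistic
                if g in validation.deciles.index
            }

    # ---- stage 7: preservation of combination modules in Vehicle ---------
    if config.run_preservation:
        pres = {}
        combo_part = partitions[config.combo]
        for mid in combo_part.module_ids:
            genes = combo_part.members(mid)
            if len(genes) < 3:
                continue
            res = mod.z_summary(
                genes,
                networks[config.combo],
                vehicle_nets[config.combo],
                n_perm=config.n_perm,
                seed=config.seed + SEED_OFFSET_PRESERVATION + mid,
            )
            pres[mid] = {
                "z_density": res.z_density,
                "z_connectivity": res.z_connectivity,
                "z_summary": res.z_summary,
                "preserved": res.preserved,
            }
        report["preservation_vs_vehicle"] = pres

    if truth is not None:
        report["ground_truth_summary"] = {
            "planted_deg_counts": {g: len(v) for g, v in truth.deg_genes.items()},
            "planted_modules": {m: len(v) for m, v in truth.module_members.items()},
            "planted_add_modules": truth.add_modules,
            "planted_drivers": truth.all_driver_genes,
        }

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=str))
        summary = summarize_counts(report)
        (out_dir / "summary.tsv").write_text(summary["tsv"])
        (out_dir / "summary.txt").write_text(summary["text"])
    return report


def summarize_counts(report: dict) -> dict[str, str]:
    """Render the report's headline counts as aligned text and TSV."""
    required = ["deg_counts", "module_counts", "on_modules", "conserved_modules",
                "add_modules", "synergistic_drivers"]
    missing = [k for k in required if k not in report]
    if missing:
        raise ValueError(f"incomplete report; missing stages: {missing}")
    rows = []
    for g in report["deg_counts"]:
        rows.append(
            {
                "group": g,
                "degs": report["deg_counts"][g],
                "modules": report["module_counts"].get(g, 0),
                "on_modules": len(report["on_modules"].get(g, [])),
                "conserved_modules": len(report["conserved_modules"].get(g, [])),
            }
        )
    frame = pd.DataFrame(rows)
    n_add = len(report["add_modules"])
    n_drv = len(report["synergistic_drivers"])
    lines = [frame.to_string(index=False)]
    lines.append(f"add_modules: {n_add}" + ("  (none found)" if n_add == 0 else ""))
    lines.append(f"synergistic_drivers: {n_drv}")
    tsv = frame.to_csv(sep="\t", index=False)
    tsv += f"add_modules\t{n_add}\nsynergistic_drivers\t{n_drv}\n"
    return {"text": "\n".join(lines), "tsv": tsv}
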