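"""Benchmark computations: worked examples, planted-structure recovery,
statistical calibration.

These functions exercise the package end to end on its study conditions —
the default synthetic design (2000 genes, five groups, nine profiles per
group) — and on the worked set-overlap examples whose input sizes are known.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .compare import classify_modules, identify_add_modules, set_jaccard
from .deg import anova_per_gene, overlap_report, screen_group
from .drivers import rank_sum_greater
from .modules import ModulePartition, z_summary
from .network import build_network
from .pipeline import PipelineConfig, run_pipeline
from .simulate import StudyConfig, generate_study

__all__ = [
    "worked_examples",
    "recovery_benchmark",
    "deg_null_type_one_rate",
    "rank_sum_null_uniformity",
    "preservation_behavior",
]


def worked_examples() -> dict[str, float]:
    """Set-overlap statistics recomputed from their known input sizes.

    Constructs gene sets of the stated sizes (79 module genes, 336
    comparison genes with 47 shared; a 1,026-gene disease reference covered
    by 112 screen hits) and runs them through the package's set operations.
    """
    module_genes = {f"m{i}" for i in range(79)}
    comparison = {f"m{i}" for i in range(47)} | {f"u{i}" for i in range(289)}
    assert len(comparison) == 336 and len(module_genes & comparison) == 47
    jaccard = round(set_jaccard(module_genes, comparison), 3)

    part = ModulePartition(
        sorted(module_genes) + [f"o{i}" for i in range(10)],
        np.array([1] * 79 + [2] * 10),
        cut_height=0.5,
        min_module_size=3,
    )

    class _Sim:  # minimal similarity stub: module 1 responsive, module 2 not
        def __init__(self):
            import pandas as pd

            self.s = pd.Series([0.0, 0.9], index=[1, 2])
            self.b = pd.DataFrame({1: [0.0, 0.9]}, index=[1, 2])

    cls = classify_modules(_Sim(), 0.1, 0.1)
    add = identify_add_modules({1}, cls, cls, part, comparison)
    overlap_pct = add.deg_overlap["overlap_pct_of_add_genes"]

    reference = {f"r{i}" for i in range(1026)}
    hits = {f"r{i}" for i in range(112)} | {f"x{i}" for i in range(76)}
    report = overlap_report({"screen": hits}, reference)
    coverage_pct = report["reference_coverage_pct"]
    return {
        "jaccard": jaccard,
        "overlap_pct": float(overlap_pct),
        "coverage_pct": float(coverage_pct),
    }


def _ari_for_report(report: dict, truth) -> float:
    """Adjusted Rand index of the combination partition against the planted
    modules active in the combination, over planted genes in the network."""
    combo = truth.drug_groups[-1]
    assignments = report["module_assignments"][combo]
    planted = {
        g: name
        for name, genes in truth.module_members.items()
        if combo in truth.module_active_in[name]
        for g in genes
    }
    genes = [g for g in planted if g in assignments]
    return adjusted_rand_score(
        [planted[g] for g in genes], [assignments[g] for g in genes]
    )


def recovery_benchmark(seeds=range(10), study_config: StudyConfig | None = None) -> dict:
    """Planted-structure recovery of the full pipeline over fixed seeds.

    Reports mean module-recovery ARI, sensitivity of the Add-module screen
    for combination-only planted modules (best-match Jaccard > 0.5),
    specificity violations (planted Vehicle-active modules called Add),
    sensitivity of the synergistic-driver intersection for planted hubs,
    and how often hubs land in the top degree-centrality decile.
    """
    aris, add_sens, drv_sens, decile_hits = [], [], [], []
    spec_violations = 0
    for seed in seeds:
        cfg = PipelineConfig(seed=int(seed), study_config=study_config,
                             run_preservation=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_pipeline(cfg)
        sc = study_config or StudyConfig()
        sc.seed = int(seed)
        sc.__post_init__()
        _, truth = generate_study(sc)
        aris.append(_ari_for_report(report, truth))
        add_sets = [set(v) for v in report["add_module_genes"].values()]
        planted_add = truth.add_modules
        hits = sum(
            any(set_jaccard(set(truth.module_members[m]), s) > 0.5 for s in add_sets)
            for m in planted_add
        )
        add_sens.append(hits / len(planted_add) if planted_add else np.nan)
        for name, groups in truth.module_active_in.items():
            if truth.vehicle_group in groups and any(
                set_jaccard(set(truth.module_members[name]), s) > 0.5 for s in add_sets
            ):
                spec_violations += 1
        hubs = truth.all_driver_genes
        syn = set(report["synergistic_drivers"])
        if hubs:
            drv_sens.append(np.mean([h in syn for h in hubs]))
            deciles = report.get("driver_deciles", {})
            for h in hubs:
                decile_hits.append(deciles.get(h, {}).get("degree_centrality", 0) == 10)
    return {
        "ari_mean": float(np.mean(aris)),
        "ari_per_seed": [float(a) for a in aris],
        "add_module_sensitivity": float(np.nanmean(add_sens)),
        "add_module_specificity_violations": spec_violations,
        "driver_sensitivity": float(np.mean(drv_sens)),
        "hub_top_decile_rate": float(np.mean(decile_hits)),
        "n_seeds": len(list(seeds)),
    }


def deg_null_type_one_rate(seed: int = 0, n_genes: int = 2000) -> float:
    """Fraction of null genes with unadjusted ANOVA p < 0.05 (expect ~0.05)."""
    cfg = StudyConfig(n_genes=n_genes, module_specs=[], deg_fraction=0.0, seed=seed)
    study, _ = generate_study(cfg)
    p = anova_per_gene(study)["p"]
    return float((p < 0.05).mean())


def rank_sum_null_uniformity(seed: int = 0, n_rep: int = 200) -> float:
    """KS p-value for uniformity of the one-sided rank-sum p under the null."""
    rng = np.random.default_rng(seed)
    ps = [
        rank_sum_greater(rng.normal(size=6), rng.normal(size=8))
        for _ in range(n_rep)
    ]
    return float(stats.kstest(ps, "uniform").pvalue)


def preservation_behavior(seed: int = 0, n_random: int = 20, n_perm: int = 150) -> dict:
    """Z_summary of a planted conserved module vs random gene sets.

    The combination and Vehicle networks are built on the combination's DEG
    genes; the planted all-condition module must score Z_summary >= 2 there,
    while random gene sets of the same size should stay inside |Z| < 2.
    """
    sc = StudyConfig(seed=seed)
    study, truth = generate_study(sc)
    combo = truth.drug_groups[-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scr = screen_group(study, combo, truth.vehicle_group)
        genes = sorted(scr.index[scr["is_deg"]])
        ref = build_network(study, combo, genes, beta=6)
        test = build_network(study, truth.vehicle_group, genes, beta=6)
    conserved = next(
        name
        for name, groups in truth.module_active_in.items()
        if set(groups) >= {combo, truth.vehicle_group}
    )
    members = [g for g in truth.module_members[conserved] if g in set(genes)]
    planted_z = z_summary(members, ref, test, n_perm=n_perm, seed=seed + 1).z_summary
    rng = np.random.default_rng(seed + 2)
    inside = 0
    for i in range(n_random):
        random_set = list(rng.choice(genes, size=len(members), replace=False))
        z = z_summary(random_set, ref, test, n_perm=n_perm, seed=seed + 10 + i).z_summary
        inside += abs(z) < 2
    return {
        "planted_z_summary": float(planted_z),
        "random_sets_inside": inside,
        "n_random": n_random,
    }
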