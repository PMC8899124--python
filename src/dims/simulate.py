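"""Synthetic multi-group expression studies with planted structure.

The generator emulates a five-group drug-combination microarray design
(Sham, Vehicle, two monotherapies, and their combination) with a configurable
number of expression profiles per group. Three kinds of structure are
planted so every downstream stage has a known answer:

* **differential expression** — selected genes receive a group-mean shift of
  ``log2(deg_fold_change)`` in one or more drug groups relative to Vehicle;
* **co-expression modules** — blocks of genes share a single latent factor
  within each group the module is *active* in, giving pairwise expected
  correlation ``loading**2`` there and ~0 elsewhere (condition-specific
  rewiring);
* **driver hubs** — designated module members whose factor loading is boosted
  toward 1, so they acquire top intramodular connectivity.

Values are log2-scale intensities; fold change downstream is computed after
exponentiation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .study import ExpressionStudy, read_study, write_study_tables

__all__ = [
    "PlantedModuleSpec",
    "StudyConfig",
    "GroundTruth",
    "default_module_specs",
    "generate_study",
    "write_study",
    "load_study",
]

DRIVER_LOADING_CAP = 0.99


@dataclass(frozen=True)
class PlantedModuleSpec:
    """One planted co-expression module.

    ``active_in`` lists the groups in which the module's genes co-vary
    through a shared latent factor. ``n_drivers`` members (the first ones
    assigned) are hub genes whose loading is raised to ``driver_loading``.
    """

    name: str
    size: int
    active_in: tuple[str, ...]
    loading: float = 0.8
    n_drivers: int = 0
    driver_loading: float = DRIVER_LOADING_CAP

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError(f"module {self.name!r}: size must be >= 3")
        if not 0.0 < self.loading < 1.0:
            raise ValueError(f"module {self.name!r}: loading must be in (0, 1)")
        if not 0 <= self.n_drivers <= self.size:
            raise ValueError(f"module {self.name!r}: n_drivers must be in [0, size]")
        if not 0.0 < self.driver_loading <= DRIVER_LOADING_CAP:
            raise ValueError(
                f"module {self.name!r}: driver_loading must be in (0, {DRIVER_LOADING_CAP}]"
            )


def default_module_specs(
    vehicle: str = "Vehicle",
    sham: str = "Sham",
    mono_a: str = "DrugA",
    mono_b: str = "DrugB",
    combo: str = "Combo",
) -> list[PlantedModuleSpec]:
    """Default planted-module layout covering every downstream module class.

    Two conserved modules active in all groups anchor the high end of the
    cross-condition similarity score; one module per monotherapy and one
    shared drug-response module exercise On-module calls; two combination-only
    modules (each carrying one driver hub) are the planted additive modules.
    """
    all_groups = (sham, vehicle, mono_a, mono_b, combo)
    drugs = (mono_a, mono_b, combo)
    return [
        PlantedModuleSpec("conserved_1", 50, all_groups, loading=0.80),
        PlantedModuleSpec("conserved_2", 40, all_groups, loading=0.80),
        PlantedModuleSpec("monoA_resp", 35, (mono_a,), loading=0.80),
        PlantedModuleSpec("monoB_resp", 35, (mono_b,), loading=0.80),
        PlantedModuleSpec("shared_resp", 35, drugs, loading=0.80),
        PlantedModuleSpec("combo_add_1", 35, (combo,), loading=0.70, n_drivers=1),
        PlantedModuleSpec("combo_add_2", 35, (combo,), loading=0.70, n_drivers=1),
    ]


@dataclass
class StudyConfig:
    """Configuration of one synthetic study.

    Defaults mirror a five-group design with nine expression profiles per
    group. ``deg_fraction`` controls background (non-module) differential
    genes; module members active in a drug condition are additionally shifted
    there so they pass the expression screen that feeds network construction.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 9
    group_names: tuple[str, ...] = ("Sham", "Vehicle", "DrugA", "DrugB", "Combo")
    sham_group: str = "Sham"
    vehicle_group: str = "Vehicle"
    module_specs: list[PlantedModuleSpec] = field(default_factory=default_module_specs)
    deg_fraction: float = 0.10
    deg_fold_change: float = 2.0
    noise_sd: float = 0.35
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_names) < 2:
            raise ValueError("need at least two groups")
        if len(set(self.group_names)) != len(self.group_names):
            raise ValueError("duplicate group names")
        if self.vehicle_group not in self.group_names:
            raise ValueError(f"vehicle group {self.vehicle_group!r} not in group_names")
        if not 0.0 <= self.deg_fraction < 1.0:
            raise ValueError("deg_fraction must be in [0, 1)")
        if self.deg_fold_change <= 1.0:
            raise ValueError("deg_fold_change must be > 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        total = sum(m.size for m in self.module_specs)
        if total > self.n_genes:
            raise ValueError(
                f"module sizes total {total} exceeds n_genes={self.n_genes}"
            )
        for spec in self.module_specs:
            unknown = set(spec.active_in) - set(self.group_names)
            if unknown:
                raise ValueError(
                    f"module {spec.name!r} active in unknown groups {sorted(unknown)}"
                )
        names = [m.name for m in self.module_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate module names")

    @property
    def drug_groups(self) -> tuple[str, ...]:
        """Treatment groups: everything except Sham and Vehicle."""
        skip = {self.sham_group, self.vehicle_group}
        return tuple(g for g in self.group_names if g not in skip)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic study."""

    deg_genes: dict[str, list[str]]  # drug group -> planted DEG ids
    module_members: dict[str, list[str]]  # module name -> gene ids
    module_active_in: dict[str, list[str]]  # module name -> groups
    driver_genes: dict[str, list[str]]  # module name -> hub gene ids
    vehicle_group: str
    drug_groups: list[str]

    def on_modules(self, condition: str, reference: str) -> list[str]:
        """Planted On-modules of ``condition`` relative to ``reference``:
        modules active in the condition but not in the reference."""
        return [
            name
            for name, groups in self.module_active_in.items()
            if condition in groups and reference not in groups
        ]

    @property
    def add_modules(self) -> list[str]:
        """Modules active in the combination only (no Vehicle, no monotherapy)."""
        combo = self.drug_groups[-1]
        monos = set(self.drug_groups[:-1]) | {self.vehicle_group}
        return [
            name
            for name, groups in self.module_active_in.items()
            if combo in groups and not monos & set(groups)
        ]

    @property
    def all_driver_genes(self) -> list[str]:
        return sorted({g for genes in self.driver_genes.values() for g in genes})

    def to_dict(self) -> dict:
        return {
            "deg_genes": self.deg_genes,
            "module_members": self.module_members,
            "module_active_in": self.module_active_in,
            "driver_genes": self.driver_genes,
            "vehicle_group": self.vehicle_group,
            "drug_groups": self.drug_groups,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


def _group_factors(rng: np.random.Generator, k: int, n: int) -> np.ndarray:
    """Draw ``k`` latent factor vectors of length ``n``, centered and mutually
    uncorrelated in-sample.

    With few samples, independently drawn factors correlate substantially by
    chance (sd ~ 1/sqrt(n-1)), which would plant spurious between-module
    correlation and make the ground-truth partition ambiguous. Centering and
    orthogonalizing the realized factors (possible while k <= n-1) pins the
    sample correlation between different modules' factors at exactly zero;
    each factor is scaled to unit sample variance.
    """
    if k == 0:
        return np.empty((0, n))
    raw = rng.standard_normal((n, k))
    if k > n - 1:
        warnings.warn(
            "more active modules than centered dimensions; factors left "
            "unorthogonalized"
        )
        raw = raw - raw.mean(axis=0)
        return (raw / raw.std(axis=0)).T
    raw = raw - raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # deterministic orientation
    q = q - q.mean(axis=0)  # centered span is preserved; re-center for safety
    return (q / q.std(axis=0)).T


def generate_study(config: StudyConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate a synthetic study and its ground truth.

    Per-module single-latent-factor model: within each group g the module is
    active in, a member with loading ``l`` has residual
    ``l * f_g + sqrt(1 - l**2) * eps`` (fresh factor per group and sample),
    so member pairs have expected within-group correlation ``l_i * l_j``.
    Background genes are independent noise. Identical seeds give bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_per = config.n_genes, config.n_samples_per_group
    width = len(str(n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    sample_ids, design = [], []
    for g in config.group_names:
        for i in range(n_per):
            sample_ids.append(f"{g}_{i + 1}")
            design.append(g)
    design = pd.Series(design, index=sample_ids, name="group")

    # assign module members from the front of the gene list (ids are opaque)
    members: dict[str, list[str]] = {}
    drivers: dict[str, list[str]] = {}
    cursor = 0
    loadings: dict[str, dict[str, float]] = {}  # module -> gene -> loading
    for spec in config.module_specs:
        ids = gene_ids[cursor : cursor + spec.size]
        cursor += spec.size
        members[spec.name] = ids
        drivers[spec.name] = ids[: spec.n_drivers]
        load = {}
        for j, gid in enumerate(ids):
            load[gid] = spec.driver_loading if j < spec.n_drivers else spec.loading
        loadings[spec.name] = load
    background = gene_ids[cursor:]

    # planted differential expression: module members shifted in every drug
    # group they are active in; background DEGs assigned one drug group each
    drug_groups = config.drug_groups
    log_fc = np.log2(config.deg_fold_change)
    shift = pd.DataFrame(
        0.0, index=gene_ids, columns=list(config.group_names)
    )
    deg_sets: dict[str, set[str]] = {g: set() for g in drug_groups}
    gene_sign = pd.Series(rng.choice([-1.0, 1.0], size=n_genes), index=gene_ids)
    for spec in config.module_specs:
        for g in drug_groups:
            if g in spec.active_in:
                for gid in members[spec.name]:
                    shift.loc[gid, g] = gene_sign[gid] * log_fc
                deg_sets[g].update(members[spec.name])
    n_bg_deg = int(round(config.deg_fraction * n_genes))
    n_bg_deg = min(n_bg_deg, len(background))
    if n_bg_deg and drug_groups:
        chosen = rng.choice(len(background), size=n_bg_deg, replace=False)
        assigned = rng.integers(0, len(drug_groups), size=n_bg_deg)
        for idx, gi in zip(chosen, assigned):
            gid = background[idx]
            g = drug_groups[gi]
            shift.loc[gid, g] = gene_sign[gid] * log_fc
            deg_sets[g].add(gid)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    values = np.empty((n_genes, len(sample_ids)))
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    col = 0
    for g in config.group_names:
        resid = rng.standard_normal((n_genes, n_per))
        active = [m for m in config.module_specs if g in m.active_in]
        factors = _group_factors(rng, len(active), n_per)
        for spec, factor in zip(active, factors):
            for gid in members[spec.name]:
                l = loadings[spec.name][gid]
                i = gene_pos[gid]
                resid[i] = l * factor + np.sqrt(1.0 - l * l) * resid[i]
        block = (
            baseline[:, None]
            + shift[g].to_numpy()[:, None]
            + config.noise_sd * resid
        )
        values[:, col : col + n_per] = block
        col += n_per

    study = ExpressionStudy(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), design
    )
    truth = GroundTruth(
        deg_genes={g: sorted(s) for g, s in deg_sets.items()},
        module_members=members,
        module_active_in={m.name: list(m.active_in) for m in config.module_specs},
        driver_genes=drivers,
        vehicle_group=config.vehicle_group,
        drug_groups=list(drug_groups),
    )
    return study, truth


def write_study(
    study: ExpressionStudy, truth: GroundTruth, directory: str | Path
) -> dict[str, Path]:
    """Write expression TSV, design TSV and ground-truth JSON to a directory."""
    directory = Path(directory)
    paths = write_study_tables(study, directory)
    truth_path = directory / "ground_truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    paths["ground_truth"] = truth_path
    return paths


def load_study(directory: str | Path) -> tuple[ExpressionStudy, GroundTruth | None]:
    """Load a study written by :func:`write_study`; ground truth is optional."""
    directory = Path(directory)
    study = read_study(directory / "expression.tsv", directory / "design.tsv")
    truth_path = directory / "ground_truth.json"
    truth = None
    if truth_path.exists():
        truth = GroundTruth.from_dict(json.loads(truth_path.read_text()))
    return study, truth
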