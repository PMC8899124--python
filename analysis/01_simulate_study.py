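"""Generate the synthetic five-group expression study used by all analyses.

Emulates a drug-combination microarray design: Sham, Vehicle, two
monotherapies and their combination, nine profiles per group, 2000 genes,
with planted differential expression, condition-specific co-expression
modules (conserved, monotherapy-, shared- and combination-specific) and one
driver hub per combination-specific module. Also writes a synthetic
"known disease gene" reference list (an enriched mixture of planted DEGs and
background genes) for the overlap analysis.

Writes: results/study/{expression.tsv,design.tsv,ground_truth.json},
results/study/synthetic_disease_genes.txt
"""

import sys
from pathlib import Path

import numpy as np

from dims.simulate import StudyConfig, generate_study, write_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    config = StudyConfig(seed=SEED)
    study, truth = generate_study(config)
    paths = write_study(study, truth, OUT)

    # synthetic disease-gene reference: half planted DEGs, half background
    rng = np.random.default_rng(SEED + 500)
    planted = sorted({g for s in truth.deg_genes.values() for g in s})
    background = sorted(set(study.gene_ids) - set(planted))
    n_ref = 200
    ref = sorted(
        list(rng.choice(planted, size=n_ref // 2, replace=False))
        + list(rng.choice(background, size=n_ref // 2, replace=False))
    )
    ref_path = OUT / "synthetic_disease_genes.txt"
    ref_path.write_text("\n".join(ref) + "\n")

    print(f"study: {len(study.gene_ids)} genes x {len(study.sample_ids)} samples "
          f"({', '.join(study.groups)})")
    for name, members in truth.module_members.items():
        print(f"  planted module {name}: {len(members)} genes, "
              f"active in {','.join(truth.module_active_in[name])}")
    print(f"  planted DEGs: " +
          ", ".join(f"{g}={len(v)}" for g, v in truth.deg_genes.items()))
    print(f"  planted drivers: {', '.join(truth.all_driver_genes)}")
    print("wrote:", ", ".join(str(p) for p in paths.values()), "and", ref_path)


if __name__ == "__main__":
    main()
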