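"""Screen differentially expressed genes per drug group versus Vehicle.

One-way ANOVA across all five groups, direction-symmetric fold change on the
linear scale, Bonferroni correction; DEG = adjusted p < 0.05 and FC > 1.5.
Reports per-group DEG counts, cross-group overlaps and coverage of the
synthetic disease-gene reference list.

Reads:  results/study/
Writes: results/degs/{group}.tsv, results/degs/overlap.json
"""

import json
from pathlib import Path

from dims.deg import DegScreenConfig, overlap_report, screen_group
from dims.simulate import load_study

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study, truth = load_study(ROOT / "study")
    out = ROOT / "degs"
    out.mkdir(parents=True, exist_ok=True)
    config = DegScreenConfig()
    drug_groups = truth.drug_groups if truth else [g for g in study.groups
                                                  if g not in ("Sham", "Vehicle")]
    deg_sets = {}
    for g in drug_groups:
        table = screen_group(study, g, "Vehicle", config)
        table.to_csv(out / f"{g}.tsv", sep="\t")
        deg_sets[g] = set(table.index[table["is_deg"]])
        line = f"{g}: {len(deg_sets[g])} DEGs"
        if truth:
            planted = set(truth.deg_genes[g])
            recall = len(deg_sets[g] & planted) / len(planted)
            fp = len(deg_sets[g] - planted)
            line += f" (planted {len(planted)}, recall {recall:.2f}, false positives {fp})"
        print(line)

    ref_path = ROOT / "study" / "synthetic_disease_genes.txt"
    reference = {l.strip() for l in ref_path.read_text().splitlines() if l.strip()}
    report = overlap_report(deg_sets, reference)
    (out / "overlap.json").write_text(json.dumps(report, indent=1))
    shared = report["intersections"].get("&".join(drug_groups))
    print(f"shared DEGs across all {len(drug_groups)} drug groups: {shared}")
    print(f"reference coverage: {report['reference_overlap']} of "
          f"{report['reference_size']} known genes "
          f"({report['reference_coverage_pct']}%)")


if __name__ == "__main__":
    main()
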