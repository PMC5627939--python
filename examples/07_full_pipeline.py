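"""Run the whole case analysis end to end from files on disk.

This mirrors real use: per-sample variant tables, bin counts, fusion calls
and expression tables are read from paths in a PipelineConfig, each stage
writes its intermediate table, and a single JSON case report summarizes the
clonal history of the tumor.
"""

import json
from pathlib import Path

import serialclones as sc

cohort = sc.simulate_cohort(sc.CohortConfig(seed=7))
samples = list(cohort.config.sample_labels)

fixture_dir = Path("scratch/full_pipeline/fixtures")
paths = sc.write_fixtures(cohort, fixture_dir)

config = sc.PipelineConfig(
    samples=samples,
    variant_tables={s: str(paths[f"variants_{s}"]) for s in samples},
    cn_bins=str(paths["cn_bins"]),
    fusions=str(paths["fusions"]),
    expression=str(paths["expression"]),
    expression_reference=str(paths["expression_reference"]),
    gene_regions=str(paths["gene_regions"]),
    purity={s: p for s, p in zip(samples, cohort.truth.purity)},
    out_dir="scratch/full_pipeline/out",
    seed=7,
)
report = sc.run_pipeline(config)

print(f"clone sizes: {report.clone_sizes}")
print(f"exclusivity index: {report.exclusivity_index}")
for e in report.replacement_events:
    print(f"replacement: {e['clone_out']} -> {e['clone_in']} "
          f"({e['sample_from']} -> {e['sample_to']})")
print(f"fusion concordant: {report.fusion['concordant']}, "
      f"copies per sample: {report.fusion['copy_estimates']}")
top = [c for c in report.candidates if c["status"] == "candidate"][0]
print(f"top candidate: {top['gene']} ({top['fold_display']})")

out = Path(config.out_dir)
print(f"\nintermediates in {out}/: "
      f"{sorted(p.name for p in out.iterdir())}")
print("\ncase_report.json keys:",
      sorted(json.loads((out / 'case_report.json').read_text())))
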