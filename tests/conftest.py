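"""Shared fixtures: one default synthetic cohort and one pipeline run, built
once per session so the many tests that interrogate them stay fast."""

from __future__ import annotations

from pathlib import Path

import pytest

import serialclones as sc


@pytest.fixture(scope="session")
def default_cohort() -> sc.SyntheticCohort:
    """Default four-sample cohort (37 A / 21 B / 3 shared, depth 100)."""
    return sc.simulate_cohort(sc.CohortConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory) -> dict[str, Path]:
    out = tmp_path_factory.mktemp("cohort")
    return sc.write_fixtures(default_cohort, out)


@pytest.fixture(scope="session")
def pipeline_config(default_cohort, cohort_dir, tmp_path_factory) -> sc.PipelineConfig:
    samples = list(default_cohort.config.sample_labels)
    return sc.PipelineConfig(
        samples=samples,
        variant_tables={s: str(cohort_dir[f"variants_{s}"]) for s in samples},
        cn_bins=str(cohort_dir["cn_bins"]),
        fusions=str(cohort_dir["fusions"]),
        expression=str(cohort_dir["expression"]),
        expression_reference=str(cohort_dir["expression_reference"]),
        gene_regions=str(cohort_dir["gene_regions"]),
        purity={s: p for s, p in zip(samples, default_cohort.truth.purity)},
        out_dir=str(tmp_path_factory.mktemp("pipeline_out")),
        seed=11,
    )


@pytest.fixture(scope="session")
def case_report(pipeline_config) -> sc.CaseReport:
    return sc.run_pipeline(pipeline_config)
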