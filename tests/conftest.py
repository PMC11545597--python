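"""Shared fixtures: reference-cohort margins, replanted end-to-end runs and
the (expensive) SKAT null-calibration p-values, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from rarecollapse.io_cohort import SampleManifest
from rarecollapse.pipeline import RunConfig, run_scan
from rarecollapse.synthetic_data import (
    null_skat_scenario,
    replant_reference_tables,
    simulate_cohort,
    write_cohort,
)

N_CASE, N_CONTROL = 146, 1395


def make_manifest(n_case: int, n_control: int) -> SampleManifest:
    return SampleManifest.from_pairs(
        [(f"CASE{i:04d}", "case") for i in range(n_case)]
        + [(f"CTRL{i:04d}", "control") for i in range(n_control)]
    )


@pytest.fixture(scope="session")
def cohort_manifest() -> SampleManifest:
    """The reference cohort margins: 146 cases vs 1395 controls."""
    return make_manifest(N_CASE, N_CONTROL)


@pytest.fixture(scope="session")
def replant_riv_run(tmp_path_factory):
    """Full pipeline run on the replanted RIV tables (variant + gene counts)."""
    outdir = tmp_path_factory.mktemp("replant_riv")
    scenario = replant_reference_tables(seed=1)["riv"]
    paths = write_cohort(simulate_cohort(scenario), outdir / "cohort")
    cfg = RunConfig(
        vcf=str(paths["vcf"]),
        annotations=str(paths["annotations"]),
        manifest=str(paths["manifest"]),
        outdir=str(outdir / "out"),
    )
    return run_scan(cfg)


@pytest.fixture(scope="session")
def null_skat_pvalues() -> np.ndarray:
    """SKAT p-values for 2000 genes simulated with no association signal."""
    from rarecollapse import skat as sk
    from rarecollapse.classify import (
        ClassificationConfig,
        classify_variant,
        cohort_af,
        select_variant_set,
    )

    sim = simulate_cohort(null_skat_scenario(seed=20240, n_genes=2000))
    null = sk.fit_null(sim.manifest)
    cfg = ClassificationConfig()
    assigns = [
        classify_variant(a, cohort_af(sim.geno, a.key, "controls"), cfg)
        for a in sim.annotations
    ]
    sets = select_variant_set(assigns, "NONSYN", sim.geno)
    return np.array([
        sk.skat_test_gene(g, null, sim.geno, gs).p_value for g, gs in sets.items()
    ])
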