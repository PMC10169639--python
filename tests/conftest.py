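import numpy as np
import pandas as pd
import pytest

from demkin.datamodel import BetaMatrix, CpGAnnotation, SampleSheet, filter_cpgs
from demkin.pipeline import RunConfig, run_pipeline
from demkin.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scale cohort shared across detection tests."""
    return simulate_cohort(CohortConfig(), seed=11)


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """Full pipeline run on the default synthetic cohort."""
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(RunConfig(simulate=CohortConfig(), seed=11), out)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort for cheap structural tests."""
    cfg = CohortConfig(
        n_cpgs=2000,
        n_genes=80,
        n_patients_blast=6,
        n_patients_tcell=2,
        n_cycle2_patients=2,
        signature_size=30,
        n_anticorr_genes=10,
    )
    return simulate_cohort(cfg, seed=3)


@pytest.fixture(scope="session")
def small_filtered(small_cohort):
    return filter_cpgs(small_cohort.beta, small_cohort.annotation)


def make_beta(values, cpgs=None, samples=None) -> BetaMatrix:
    arr = np.asarray(values, dtype=float)
    cpgs = cpgs or [f"cg{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=cpgs, columns=samples))


def make_annotation(rows: dict) -> CpGAnnotation:
    """rows: cpg_id -> dict of annotation column overrides."""
    defaults = dict(
        chromosome="chr1",
        position=100,
        nearest_gene="GENE",
        tss_distance=0,
        region_categories=frozenset({"intergenic"}),
        island_status="OpenSea",
        repeat_overlap=False,
        snp_overlap=False,
    )
    data = {cpg: {**defaults, **over} for cpg, over in rows.items()}
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "cpg_id"
    return CpGAnnotation(df)


def make_sheet(rows) -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "patient_id",
                "timepoint",
                "cycle",
                "cell_type",
                "response_group",
            ],
        )
    )
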