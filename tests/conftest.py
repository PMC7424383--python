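import numpy as np
import pandas as pd
import pytest

from cerna_prognost import (
    ClinicalTable,
    ExpressionMatrix,
    RunConfig,
    log_cpm,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared by end-to-end tests."""
    return simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def cohort_logcpm(cohort):
    matrices, db, clin, truth = cohort
    return {c: log_cpm(m) for c, m in matrices.items()}, db, clin, truth


@pytest.fixture()
def cfg():
    return RunConfig()


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples of counts, 2 tumor / 2 normal."""
    values = pd.DataFrame(
        [[10, 20, 5, 8], [0, 3, 1, 2], [100, 90, 40, 60]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    group = pd.Series(
        ["tumor", "tumor", "normal", "normal"], index=values.columns
    )
    return ExpressionMatrix(values=values, rna_class="mRNA", group=group)


def make_clinical(times, events, ids=None):
    ids = ids or [f"P{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame(
            {"time_days": times, "event": events},
            index=pd.Index(ids, name="sample_id"),
        )
    )
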