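import numpy as np
import pandas as pd
import pytest

from skinmut import CohortConfig, generate_cohort, write_fixtures
from skinmut.expression import ExpressionMatrix
from skinmut.triage import VariantCall


def make_call(
    sample_id="S1",
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    coverage=100,
    count=20,
    q_score=80.0,
    qual=200.0,
    **kwargs,
):
    return VariantCall(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        coverage=coverage,
        count=count,
        frequency=None,
        q_score=q_score,
        qual=qual,
        **kwargs,
    )


@pytest.fixture
def call_factory():
    return make_call


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort that still populates every mutation x exposure cell."""
    return CohortConfig(
        n_healthy=8,
        n_tumor=16,
        tumor_class=("BCC",) * 13 + ("SCC",) * 3,
        somatic_rate=30,
        germline_rate=5,
        decoy_rate=5,
        n_genes=300,
        n_panel_genes=80,
        set_size=20,
        seed=2,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def fixture_dir(small_cohort, tmp_path_factory):
    directory = tmp_path_factory.mktemp("fixtures")
    paths = write_fixtures(small_cohort, directory)
    return directory, paths


@pytest.fixture
def expr_3groups():
    """Null normal expression matrix over healthy + two tumor subgroups."""
    rng = np.random.default_rng(42)
    labels = ["healthy"] * 16 + ["mut0"] * 14 + ["mut1"] * 12
    samples = [f"s{i}" for i in range(len(labels))]
    values = pd.DataFrame(
        rng.normal(size=(60, len(labels))),
        index=[f"g{i}" for i in range(60)],
        columns=samples,
    )
    return ExpressionMatrix(values), pd.Series(labels, index=samples)
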