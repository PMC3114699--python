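import numpy as np
import pytest

from estrores.arrayio import ExpressionMatrix


def make_matrix(values, classes, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i:04d}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        classes=list(classes),
        values=values,
    )


@pytest.fixture
def three_class_design():
    return ["control"] * 4 + ["E2"] * 3 + ["E2_ICI"] * 3


@pytest.fixture
def null_matrix(three_class_design):
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(0, 0.5, (300, 10)), three_class_design)


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """One full default-scale synthetic pipeline run, shared across tests."""
    from estrores import RunConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = RunConfig(outdir=str(outdir), seed=1)
    report = run_pipeline(config)
    return config, report, outdir
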