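import numpy as np
import pandas as pd
import pytest

from plastevo.expression import ExpressionMatrix, GeneStageSummary


def make_matrix(values: np.ndarray, genes=None, stages=("ancestral", "plastic", "colonized"), per_stage=2):
    """Build an ExpressionMatrix from a genes x samples array with a simple design."""
    n_genes, n_samples = values.shape
    assert n_samples == per_stage * len(stages)
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = []
    design_rows = []
    for stage in stages:
        for k in range(per_stage):
            sid = f"{stage[:3]}{k}"
            samples.append(sid)
            design_rows.append({"sample_id": sid, "stage": stage, "tissue": "t", "individual": sid})
    design = pd.DataFrame(design_rows).set_index("sample_id")
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), design)


def make_summary(triples, ses=None):
    """GeneStageSummary from a list of (E_ancestral, E_plastic, E_colonized) triples."""
    triples = np.asarray(triples, dtype=float)
    genes = pd.Index([f"g{i}" for i in range(len(triples))])
    mean = pd.DataFrame(triples, index=genes, columns=["ancestral", "plastic", "colonized"])
    if ses is None:
        ses = np.zeros_like(triples)
    se = pd.DataFrame(np.asarray(ses, dtype=float), index=genes, columns=mean.columns)
    return GeneStageSummary(mean=mean, se=se, n={"ancestral": 5, "plastic": 5, "colonized": 5})


@pytest.fixture
def six_sample_matrix():
    rng = np.random.default_rng(0)
    return make_matrix(rng.lognormal(2, 0.3, size=(20, 6)))
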