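import warnings

import numpy as np
import pandas as pd
import pytest

from spherotime.containers import ExpressionMatrix
from spherotime.synthetic import (
    ExpressionSimConfig,
    generate_expression_timecourse,
)


@pytest.fixture(scope="session")
def small_timecourse():
    """A compact two-condition count time course with ground truth."""
    cfg = ExpressionSimConfig(
        n_genes=120,
        n_dynamic=30,
        n_condition_divergent=10,
        n_samples_per_condition=88,
        seed=11,
    )
    return generate_expression_timecourse(cfg)


@pytest.fixture(scope="session")
def small_log2(small_timecourse):
    from spherotime.preprocessing import preprocess

    matrix, truth = small_timecourse
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        logm, _ = preprocess(matrix, batch_correct=False)
    return logm, truth


def make_matrix(values, collection_time=None, condition="control", batch="A",
                library_size=1e7, scale="counts"):
    """Small helper to build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    if collection_time is None:
        collection_time = np.arange(values.shape[1], dtype=float)
    meta = pd.DataFrame(
        {
            "collection_time": collection_time,
            "condition": condition,
            "batch": batch,
            "library_size": library_size,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), meta, scale
    )
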