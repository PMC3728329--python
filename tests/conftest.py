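import numpy as np
import pandas as pd
import pytest

import radresponse as rr


@pytest.fixture(scope="session")
def small_sim():
    """A small five-group dataset with planted structure and its truth."""
    params = rr.SimulationParams(
        n_probesets=1200, seed=11, n_sets=6, set_size=12, set_shift=1.5
    )
    matrix, design, truth = rr.simulate_probeset_matrix(params)
    return params, matrix, design, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Moderated fit of the filtered small dataset."""
    _, matrix, design, _ = small_sim
    filtered, _ = rr.iqr_filter(matrix)
    fit = rr.fit_group_means(filtered, design)
    return rr.moderated_tests(fit, q=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, row_prefix="g", col_prefix="s", scale="log2"):
    values = np.asarray(values, dtype=float)
    return rr.ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{row_prefix}{i}" for i in range(values.shape[0])],
            columns=[f"{col_prefix}{j}" for j in range(values.shape[1])],
        ),
        scale=scale,
    )


def five_group_design(n_reps=3):
    return rr.SampleDesign.from_groups(
        {f"{g}{r+1}": g for g in "ABCDE" for r in range(n_reps)}
    )
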