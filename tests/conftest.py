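import numpy as np
import pandas as pd
import pytest

from clrnet.expr_data import ExpressionMatrix, SampleDesign
from clrnet.synthetic import SyntheticParams, generate_dataset


@pytest.fixture
def small_params():
    """Down-scaled generator settings for fast pipeline tests."""
    return SyntheticParams(
        n_modules=3,
        genes_per_module=12,
        n_bridge_genes=2,
        n_background_genes=6,
        conditions=("trtA", "trtB", "trtC"),
        timepoints=("t1", "t2", "t3", "t4"),
        replicates=3,
        n_baseline_controls=4,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_params):
    return generate_dataset(small_params)


@pytest.fixture
def two_group_design():
    """Two conditions x two times, 3 replicates each, plus 4 controls."""
    rows = []
    for cond in ("a", "b"):
        for time in ("t1", "t2"):
            for rep in (1, 2, 3):
                rows.append((f"{cond}_{time}_r{rep}", cond, time, rep, False))
    for rep in range(1, 5):
        rows.append((f"ctl_r{rep}", "control", "baseline", rep, True))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "time", "replicate", "is_baseline_control"],
    ).set_index("sample_id")
    return SampleDesign(df)


def make_matrix(values, probe_prefix="p", sample_ids=None):
    values = np.asarray(values, dtype=float)
    probes = tuple(f"{probe_prefix}{i}" for i in range(values.shape[0]))
    samples = tuple(sample_ids) if sample_ids is not None else tuple(
        f"s{j}" for j in range(values.shape[1])
    )
    return ExpressionMatrix(probes, samples, values)
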