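import numpy as np
import pandas as pd
import pytest

import subpathx as sx


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort reused by read-only tests."""
    config = sx.SimulationConfig(
        seed=5, n_pathways=4, n_nodes=10, n_reference=30, n_tumor=6
    )
    return sx.generate_cohort(config)


@pytest.fixture()
def tiny_expression(tmp_path):
    """Write a 4-gene x 5-sample expression TSV and return its path."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tR1\tR2\tR3\tT1\tT2\n"
        "TP53\t2\t4\t1\t3\t5\n"
        "TP53\t4\t6\t3\t5\t7\n"
        "EGFR\t1\t2\t3\t4\t5\n"
        "ZERO\t0\t0\t0\t0\t0\n"
    )
    return path


def make_clinical(times, status):
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(len(times))],
            "time": np.asarray(times, dtype=float),
            "status": np.asarray(status, dtype=int),
        }
    )
    return sx.ClinicalTable(table=table)
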