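import numpy as np
import pandas as pd
import pytest

from invasig.datatypes import DrugPanel, ExpressionMatrix, InvasionProfile, ProbeMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, 0.5, 0.5, 0.5]],
        index=["P1", "P2", "P3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix("A", values)


@pytest.fixture
def small_invasion():
    return InvasionProfile(
        pd.DataFrame(
            {
                "icc": [100.0, 300.0, 900.0, 2700.0, 150.0, 450.0],
                "tissue_group": ["LC", "LC", "BR", "BR", "ME", "ME"],
            },
            index=pd.Index([f"CL{i}" for i in range(1, 7)], name="cell_line"),
        )
    )


@pytest.fixture
def small_drug_panel():
    lines = [f"CL{i}" for i in range(1, 7)]
    sens = pd.DataFrame(
        [
            [5.0, 5.5, 6.0, 6.5, 7.0, 7.5],
            [7.5, 7.0, 6.5, 6.0, 5.5, 5.0],
            [4.0, 4.0, 4.0, 4.0, 4.0, 4.0],
        ],
        index=pd.Index(["d_up", "d_down", "d_flat"], name="drug_id"),
        columns=lines,
    )
    mech = pd.Series(
        ["targeted", "tubulin_binding", "other"],
        index=sens.index,
        name="mechanism_class",
    )
    return DrugPanel(sens, mech)


@pytest.fixture
def small_probe_map():
    return ProbeMap(
        pd.DataFrame(
            {
                "probe_a": ["P1", "P2", "P3"],
                "probe_b": ["Q1", "Q2", "Q3"],
                "gene_symbol": ["G1", "G2", "G3"],
            }
        )
    )
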