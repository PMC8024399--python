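import numpy as np
import pandas as pd
import pytest

from depsig import (
    CohortDesign,
    ExpressionMatrix,
    GeneSetCollection,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=["G1", "G2", "G3"],
            columns=["S1", "S2"],
        )
    )


@pytest.fixture
def small_design() -> CohortDesign:
    rows = []
    for i in range(1, 5):
        group = "MDD" if i <= 2 else "nonMDD"
        rows.append((f"P{i}_baseline", f"P{i}", group, "baseline", 20.0 if group == "MDD" else 5.0))
        rows.append((f"P{i}_post", f"P{i}", group, "post", 6.0 if group == "MDD" else 2.0))
    t = pd.DataFrame(rows, columns=["sample_id", "patient_id", "group", "timepoint", "madrs"])
    return CohortDesign(t.set_index("sample_id"))


@pytest.fixture(scope="session")
def fast_config() -> SimulationConfig:
    """Small but structurally complete cohort for pipeline-level tests."""
    return SimulationConfig(
        seed=11, n_genes=300, targets_per_regulator=30, n_cell_types=2, markers_per_type=10
    )


@pytest.fixture(scope="session")
def simulated(fast_config):
    return simulate_cohort(fast_config)
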