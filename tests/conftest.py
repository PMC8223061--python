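import numpy as np
import pandas as pd
import pytest

from mbsarc import (
    ExpressionMatrix,
    SimulationConfig,
    SubgroupLabels,
    simulate_ct,
    simulate_expression,
)


@pytest.fixture(scope="session")
def four_class_small():
    """A small, clearly separable four-subgroup study (100 genes x 40 samples)."""
    cfg = SimulationConfig(
        n_per_class={"WNT": 10, "SHH": 10, "Group3": 10, "Group4": 10},
        n_noise_genes=92,
        markers_per_class=2,
        effect_size=3.0,
        noise_sd=1.0,
        seed=7,
    )
    return simulate_expression(cfg)


@pytest.fixture(scope="session")
def ct_cohort():
    """A three-class qPCR cohort with 2 markers per class, strong separation."""
    markers = {
        "SHH": ["PCG1", "PCG2"],
        "Group3": ["PCG3", "PCG4"],
        "Group4": ["PCG5", "PCG6"],
    }
    ct, labels = simulate_ct(
        {"SHH": 5, "Group3": 3, "Group4": 8}, markers, delta=5.0, sd=0.2, seed=3
    )
    return ct, labels, markers


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def two_point_toy():
    """Two samples, two genes: the hard-margin SVM solution is analytic."""
    m = make_matrix([[0.0, 2.0], [0.0, 0.0]])
    labels = SubgroupLabels({"s1": "WNT", "s2": "SHH"})
    return m, labels
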