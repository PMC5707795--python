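import numpy as np
import pandas as pd
import pytest

import neuromark as nm


@pytest.fixture
def toy_hierarchy():
    return nm.RegionHierarchy(
        {
            "name": "whole brain",
            "children": [
                {"name": "cortex"},
                {
                    "name": "brainstem",
                    "children": [{"name": "midbrain"}],
                },
                {"name": "cerebellum"},
            ],
        }
    )


@pytest.fixture
def toy_annotations():
    return [
        nm.SampleAnnotation("s_dopa", "Dopaminergic", "midbrain", "studyA", "microarray"),
        nm.SampleAnnotation(
            "s_micro", "Microglia", "whole brain", "studyB", "microarray",
            override_regions=["all"],
        ),
        nm.SampleAnnotation("s_ctx", "Pyramidal", "cortex", "studyC", "microarray"),
    ]


def make_matrix(values, genes=None, samples=None, scale=nm.LOG2_INTENSITY):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return nm.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale
    )


@pytest.fixture
def small_atlas():
    """Deterministic small synthetic atlas shared across tests."""
    config = nm.SimConfig(
        n_genes=200,
        cell_types={f"t{i}": 5 for i in range(1, 5)},
        n_studies=2,
        samples_per_study_per_type=3,
        seed=7,
    )
    return config, *nm.simulate_atlas(config)
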