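import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pcspanel import SimulationConfig, simulate_cohort
from pcspanel.models import available_models
from pcspanel.preprocess import CtMatrix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort with two clearly planted genes (G01, G04)."""
    cfg = SimulationConfig(
        n_samples=240,
        n_genes=12,
        block_size=3,
        signal_effects={"G01": 1.5, "G04": 1.2},
        seed=11,
    )
    return simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def cheap_specs():
    """Reduced-grid model specs keyed by name (compute knob for tests)."""
    specs = {s.name: s for s in available_models()}
    return {
        "logistic": specs["logistic"],
        "ridge-logistic": specs["ridge-logistic"].with_grid(clf__C=[0.1, 1.0]),
        "lasso-logistic": specs["lasso-logistic"].with_grid(clf__C=[0.1, 1.0]),
        "random-forest": specs["random-forest"].with_grid(
            n_estimators=[50], min_samples_leaf=[5]
        ),
        "gbdt": specs["gbdt"].with_grid(
            n_estimators=[50], learning_rate=[0.1], min_samples_leaf=[5], max_depth=[3]
        ),
        "elasticnet-logistic": specs["elasticnet-logistic"].with_grid(
            clf__C=[0.1, 1.0], clf__l1_ratio=[0.5]
        ),
    }


def make_ct(values: np.ndarray, genes: list[str], reference_gene: str = "REF",
            mask: np.ndarray | None = None) -> CtMatrix:
    """Handy CtMatrix builder for hand-crafted fixtures."""
    idx = pd.Index([f"S{i}" for i in range(values.shape[0])], name="sample_id")
    vals = pd.DataFrame(values, index=idx, columns=genes, dtype=float)
    m = pd.DataFrame(
        mask if mask is not None else np.zeros_like(values, dtype=bool),
        index=idx, columns=genes,
    )
    return CtMatrix(values=vals.where(~m), mask=m, reference_gene=reference_gene)
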