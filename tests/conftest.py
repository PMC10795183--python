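import numpy as np
import pandas as pd
import pytest

from medequip import indicators, synthetic
from medequip.core import DecisionMatrix, WeightVector


@pytest.fixture(scope="session")
def case_study():
    """Embedded reference tables of the published MRI case study."""
    return synthetic.mri_case_study()


@pytest.fixture(scope="session")
def exact_cohort():
    """Noise-free synthetic fleet plus its recovered decision matrix."""
    spec = synthetic.default_cohort_spec(seed=7)
    profiles, records, failures = synthetic.generate_cohort(spec)
    matrix = indicators.build_decision_matrix(profiles, records)
    return spec, profiles, records, failures, matrix


@pytest.fixture()
def small_matrix():
    """A hand-sized 4x3 decision matrix with mixed directions."""
    df = pd.DataFrame(
        {"X11": [0.9, 0.6, 0.3, 0.5],
         "X32": [6.0, 2.0, 1.0, 3.0],
         "X41": [1.5, 2.5, 3.0, 2.0]},
        index=["A", "B", "C", "D"],
    )
    return DecisionMatrix(values=df)


@pytest.fixture()
def equal_weights():
    return WeightVector(
        indicator_ids=["X11", "X32", "X41"],
        weights=np.full(3, 1 / 3),
        method_tag="test",
    )
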