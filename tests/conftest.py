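import numpy as np
import pytest

from smmsubtypes.alterations import AlterationMatrix
from smmsubtypes.simulate import CohortConfig, SyntheticCohort, generate_cohort


def make_matrix(values, patient_ids=None, feature_ids=None) -> AlterationMatrix:
    values = np.asarray(values)
    n, m = values.shape
    return AlterationMatrix(
        patient_ids=patient_ids or [f"P{i}" for i in range(n)],
        feature_ids=feature_ids or [f"F{j}" for j in range(m)],
        values=values,
    )


@pytest.fixture
def block_matrix() -> np.ndarray:
    """Two noiseless patient blocks with disjoint feature support."""
    return np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
        ]
    )


@pytest.fixture(scope="session")
def default_cohort() -> SyntheticCohort:
    """One default-condition synthetic cohort (n=214, six subtypes)."""
    return generate_cohort(CohortConfig(seed=1))


def planted_config(n_patients=120, subtypes=("HL1", "TL1", "TL2"), seed=0, **kw):
    """Small planted cohort over a subtype subset, uniform mixing."""
    return CohortConfig(
        n_patients=n_patients,
        k_true=len(subtypes),
        mixing_proportions={s: 1.0 / len(subtypes) for s in subtypes},
        seed=seed,
        **kw,
    )
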