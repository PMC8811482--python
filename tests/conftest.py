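import numpy as np
import pytest

import morphcat as mc


@pytest.fixture(scope="session")
def config():
    return mc.DesignConfig(design_seed=123)


@pytest.fixture(scope="session")
def lists(config):
    return mc.build_stimulus_lists(config)


@pytest.fixture(scope="session")
def semi_cohort():
    """A modest semi-supervised cohort reused by the analysis tests."""
    spec = mc.PopulationSpec(n_subjects=40, master_seed=77)
    return mc.run_cohort(spec, "semi_supervised")


@pytest.fixture(scope="session")
def fixtures_by_name():
    return mc.make_fixtures()


def make_minimal_records(subject_id, responses, valid=None, condition="supervised"):
    """Minimal trial-record frame for exclusion-rule tests."""
    import pandas as pd

    n = len(responses)
    if valid is None:
        valid = [r is not None and not (isinstance(r, float) and np.isnan(r)) for r in responses]
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "condition": condition,
            "list_id": "L1",
            "block": [1 + i // 16 for i in range(n)],
            "block_type": "A",
            "trial": range(1, n + 1),
            "morph": 0.0,
            "group": 1,
            "category": 1,
            "indicative": False,
            "feedback_given": False,
            "response": [np.nan if r is None else float(r) for r in responses],
            "rt": [700.0 if v else np.nan for v in valid],
            "valid": valid,
        }
    )
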