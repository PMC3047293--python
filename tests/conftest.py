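import numpy as np
import pytest

import sfindex as s


@pytest.fixture(scope="session")
def reference_cohort():
    records, _ = s.simulate_cohort(
        s.CohortConfig(n_eyes=500, group="reference", seed=10)
    )
    return records


@pytest.fixture(scope="session")
def right_model(reference_cohort):
    return s.fit_reference_model(reference_cohort, "right")


@pytest.fixture(scope="session")
def right_linkage():
    return s.build_linkage(s.default_map("right"))


@pytest.fixture(scope="session")
def right_regions():
    return s.default_regions("right")


@pytest.fixture(scope="session")
def fitted_model(reference_cohort, right_model, right_linkage, right_regions):
    """Reference model with hemifield reference distributions attached."""
    results = [s.score_eye(r, right_model, right_linkage) for r in reference_cohort]
    right_model.ht_reference = s.fit_ht_reference(results, right_regions)
    return right_model


@pytest.fixture()
def small_cohort():
    records, _ = s.simulate_cohort(s.CohortConfig(n_eyes=10, group="suspect", seed=3))
    return records


def make_sfi_result(laterality="right", value=0.0, values=None, subject_id="T"):
    pts = s.grid_24_2(laterality)
    vals = {p: value for p in pts}
    if values:
        vals.update(values)
    return s.SFIResult(laterality=laterality, values=vals, subject_id=subject_id)


@pytest.fixture()
def sfi_result_factory():
    return make_sfi_result
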