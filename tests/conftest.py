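import pytest
from hypothesis import HealthCheck, settings

import panelsoma as ps

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel() -> ps.PanelDesign:
    return ps.make_panel(n_genes=30, mean_cds_length=3000, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_panel) -> ps.SyntheticCohort:
    cfg = ps.CohortConfig(n_patients=10, snvs_per_tumor=8, seed=202)
    return ps.simulate_cohort(small_panel, cfg)
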