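import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def well_config():
    from methplex import WellSimConfig

    return WellSimConfig(seed=0)


@pytest.fixture
def paper_lob():
    """The published per-assay limits of blank, in positive droplets."""
    from methplex import LobTable

    return LobTable(
        lob={"ACTRT2": 5, "EVX1": 1, "HOXD13": 2, "DOCK2": 0, "HAPLN3": 1},
        n_blanks={m: 40 for m in ("ACTRT2", "EVX1", "HOXD13", "DOCK2", "HAPLN3")},
    )


@pytest.fixture
def small_beta_config():
    from methplex import BetaSimConfig

    return BetaSimConfig(
        n_prad=50, n_rest=50, n_probes=400, n_planted_islands=3,
        probes_per_island=2, missing_rate=0.05, seed=0,
    )
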