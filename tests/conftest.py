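import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_ref():
    """A 12-hairpin, 6-UTR synthetic reference shared across tests."""
    from exomir.simulate import make_reference

    return make_reference(12, 6, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_ref, tmp_path_factory):
    """Small simulated two-condition libraries (depth 4000/replicate)."""
    from exomir.simulate import default_truth, simulate_libraries

    truth = default_truth(small_ref, seed=11, depth=4000)
    out = tmp_path_factory.mktemp("sim")
    manifest = simulate_libraries(small_ref, truth, out)
    return truth, manifest
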