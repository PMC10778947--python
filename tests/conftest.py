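"""Shared fixtures: seeded synthetic studies reused across the suite."""

import pytest

from nilscan.simulate import SimConfig, simulate_study, export_fixture
from nilscan.snp_matrix import build_consolidated_matrix


@pytest.fixture(scope="session")
def study():
    """Default-condition breeding study: 11 scaled chromosomes, two donors,
    two BC2F4 NILs, noisy call sets."""
    return simulate_study(SimConfig(seed=11, depth_mean=20.0, error_rate=0.005))


@pytest.fixture(scope="session")
def matrix(study):
    return build_consolidated_matrix(study.call_sets)


@pytest.fixture(scope="session")
def noiseless_study():
    """Error-free, complete calls at depth deep enough that the depth
    filter never triggers; used for exact truth-recovery checks."""
    return simulate_study(SimConfig(seed=23, depth_mean=40.0,
                                    depth_dispersion=50.0,
                                    error_rate=0.0, missing_rate=0.0))


@pytest.fixture(scope="session")
def noiseless_matrix(noiseless_study):
    return build_consolidated_matrix(noiseless_study.call_sets)


@pytest.fixture(scope="session")
def fixture_dir(study, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    export_fixture(study, out)
    return out
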