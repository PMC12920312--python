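import pytest
from hypothesis import HealthCheck, settings

import ferredup as fd

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ferredoxin() -> fd.SequenceRecord:
    return fd.load_ferredoxin()


@pytest.fixture(scope="session")
def fd_split(ferredoxin) -> fd.HalfSplit:
    return fd.split_halves(ferredoxin)


@pytest.fixture(scope="session")
def fd_alignment(fd_split) -> fd.HalfAlignment:
    return fd.align_halves(fd_split, mode="prescribed", pairing=fd.load_half_pairing())


@pytest.fixture(scope="session")
def fd_consensus(fd_alignment) -> fd.AncestralConsensus:
    return fd.reconstruct_ancestor(fd_alignment)
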