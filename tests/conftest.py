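import pytest
from hypothesis import settings

from dimerscreen import (
    BundleSpec,
    DimerPoseSpec,
    ModelDesignation,
    Thresholds,
    build_ideal_bundle,
    place_dimer,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle7():
    """Full 7TM subject bundle, chain A."""
    return build_ideal_bundle(BundleSpec(chain_id="A", role="subject"))


@pytest.fixture(scope="session")
def bundle7_b():
    """Full 7TM partner bundle, chain B (same receptor as bundle7)."""
    return build_ideal_bundle(BundleSpec(chain_id="B", role="partner"))


@pytest.fixture(scope="session")
def iso2():
    """Truncated 2TM isoform bundle, chain B."""
    return build_ideal_bundle(BundleSpec(n_tm=2, chain_id="B", role="isoform"))


@pytest.fixture(scope="session")
def homodimer(bundle7, bundle7_b):
    """Compliant symmetric homodimer with a designed TM4/TM5 interface."""
    return place_dimer(
        bundle7, bundle7_b, DimerPoseSpec((4, 5), (4, 5)),
        ModelDesignation.parse("AF-1"), "RecA-RecA",
    )


@pytest.fixture(scope="session")
def blocker_complex(bundle7, iso2):
    """Subject-isoform complex occupying the same TM4/TM5 face."""
    return place_dimer(
        bundle7, iso2, DimerPoseSpec((4, 5), (1, 2)),
        ModelDesignation.parse("CP-1"), "RecA-Iso_2TM",
    )


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()
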