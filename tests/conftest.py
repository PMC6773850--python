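import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_germlines():
    from tcrforge.numbering import load_reference_germlines

    return load_reference_germlines()


@pytest.fixture(scope="session")
def curated():
    from tcrforge.candidates import load_curated_candidates

    return load_curated_candidates()


@pytest.fixture(scope="session")
def fabricated_germlines():
    from tcrforge.simulate import generate_germline_set

    return generate_germline_set(4, seed=42)


@pytest.fixture()
def weak1_tcr(reference_germlines):
    """The weak 1 TCR fixture (TRAV13-2/TRBV7-3)."""
    from tcrforge.design import build_tcr_pair

    return build_tcr_pair(
        "weak1", "TRAV13-2", "TRBV7-3", "CAASGGSYIPTF", "CASSLAPGATNEK",
        reference_germlines,
    )


@pytest.fixture()
def dom_tcr(reference_germlines):
    """The dominant TCR fixture (TRAV38-2/TRBV7-8)."""
    from tcrforge.design import build_tcr_pair

    return build_tcr_pair(
        "dom", "TRAV38-2", "TRBV7-8", "CAYRSAGGTSYGK", "CASSLGVATEAFF",
        reference_germlines,
    )
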