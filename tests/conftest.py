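import pytest

from magforge.synthetic_data import CommunityDesign, simulate_bundle


@pytest.fixture(scope="session")
def complete_community():
    """30 genomes at completeness 100 / contamination 0: planted truth is
    fully recoverable."""
    design = CommunityDesign(n_genomes=30, completeness_range=(100, 100),
                             contamination_range=(0, 0), seed=42)
    bundle, truth = simulate_bundle(design)
    return design, bundle, truth


@pytest.fixture(scope="session")
def degraded_community():
    """20 genomes in the plausible quality regime (75-100% complete)."""
    design = CommunityDesign(n_genomes=20, seed=7)
    bundle, truth = simulate_bundle(design)
    return design, bundle, truth
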