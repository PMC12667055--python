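import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")

# The default architecture intentionally lets two repeats overhang their
# parent segments (documented fuzzy boundaries); silence those warnings here.
warnings.filterwarnings("ignore", message=r"repeat .* overhangs")


@pytest.fixture(scope="session")
def arch():
    """Default architecture with a synthetic reference sequence attached."""
    from sorlvar.domain import load_architecture
    from sorlvar.simulate import synthetic_reference_sequence

    a = load_architecture()
    a.reference_sequence = synthetic_reference_sequence(a, seed=1)
    return a


@pytest.fixture(scope="session")
def arch_noseq():
    """Default architecture without a reference sequence (for classifying
    literal published variants whose true sequence context we do not ship)."""
    from sorlvar.domain import load_architecture

    return load_architecture()


@pytest.fixture(scope="session")
def rules():
    from sorlvar.prioritize import load_ruleset

    return load_ruleset()


@pytest.fixture(scope="session")
def variant_table(arch, rules):
    """Seeded synthetic variant table with truth labels (250 variants)."""
    from sorlvar.simulate import simulate_variant_table

    return simulate_variant_table(arch, rules, n_variants=250, seed=1)


@pytest.fixture(scope="session")
def small_cohort(variant_table):
    """A 4,000-individual simulated cohort joined to the variant table."""
    from sorlvar.simulate import SimulationParams, simulate_cohort

    variants, truth = variant_table
    params = SimulationParams(n_cases=2000, n_controls=2000, seed=7)
    return simulate_cohort(params, variants, truth), truth
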