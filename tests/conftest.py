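import pytest

from mircna import (SimulationConfig, differential_expression,
                    generate_bundle, normalize_geometric_mean)

# master seed for all seeded stochastic tests
SEED = 1


def small_config(**overrides) -> SimulationConfig:
    """A fast, fully-featured configuration for unit tests."""
    base = dict(
        n_mirnas=60, n_samples_a=8, n_samples_b=9, n_de=12, n_concordant=4,
        n_age_associated=2, n_chromosomes=4, bands_per_chrom=4,
        chrom_length=6_000_000, probe_spacing=100_000,
        n_recurrent_regions=3, n_cna_regions=2, n_genes=120,
        n_missing_clinical=2, seed=SEED)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config())


@pytest.fixture(scope="session")
def study_bundle():
    """A bundle at the study's cohort sizes and planted-effect magnitudes."""
    return generate_bundle(seed=SEED)


@pytest.fixture(scope="session")
def study_de(study_bundle):
    norm = normalize_geometric_mean(study_bundle.expression)
    return norm, differential_expression(norm)
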