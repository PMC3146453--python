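import warnings

import numpy as np
import pytest

from exocap import (
    DesignConfig,
    GenomeSpec,
    IndividualSpec,
    ReadSimSpec,
    TargetIndex,
    derive_individual,
    design_targets,
    generate_reference,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_reference():
    spec = GenomeSpec(
        chromosome_lengths=(100_000, 50_000),
        n_genes=30,
        n_candidate_genes=3,
        seed=7,
    )
    return generate_reference(spec)


@pytest.fixture(scope="session")
def small_targets(small_reference):
    config = DesignConfig(
        n_genomewide_genes=15,
        total_bp_budget=40_000,
        candidate_gene_ids=frozenset(small_reference.candidate_ids),
    )
    targets, report = design_targets(
        small_reference.genes, small_reference.sequences, config, seed=3
    )
    return targets


@pytest.fixture(scope="session")
def small_target_index(small_targets):
    return TargetIndex(small_targets)


@pytest.fixture(scope="session")
def small_individual(small_reference):
    return derive_individual(
        small_reference, IndividualSpec(divergence_rate=0.005,
                                        heterozygosity_rate=0.001, seed=1)
    )


@pytest.fixture(scope="session")
def small_reads(small_individual, small_targets, small_reference):
    spec = ReadSimSpec(
        mean_on_target_depth=15.0,
        per_quality_error={30: 0.001},
        duplicate_fraction=0.1,
        seed=5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_reads(
            small_individual, small_targets, spec,
            small_reference.chromosome_lengths,
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
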