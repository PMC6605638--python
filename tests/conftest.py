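from types import SimpleNamespace

import pytest

from ctt.align import build_profile
from ctt.pipeline import (
    PipelineConfig,
    step1_prior_members,
    step2_reference_sets,
    step3_putative_loci,
)
from ctt.synthetic import make_family, plant_genome


@pytest.fixture(scope="session")
def small_family():
    """A 20-member family with a 48-aa signature domain."""
    return make_family(20, domain_length=48, divergence_rate=0.1, rng_seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_family):
    """A 120-kb contig with 8 annotated, 5 hidden coding (2 tandem) and 3
    pseudogenized family loci."""
    seed_set, members = small_family
    genome, features, proteome, truth = plant_genome(
        [(seed_set, members)], n_annotated=8, n_hidden=5, n_tandem_pairs=2,
        n_pseudo=3, intron_rate=0.5, contig_length=120_000, rng_seed=2)
    return SimpleNamespace(seed_set=seed_set, members=members,
                           genome=genome, features=features,
                           proteome=proteome, truth=truth)


@pytest.fixture(scope="session")
def small_refs(small_dataset):
    """Steps 1-3 precomputed on the small dataset (shared, read-only)."""
    config = PipelineConfig()
    profile = build_profile(small_dataset.seed_set)
    members = step1_prior_members({"g": small_dataset.proteome},
                                  small_dataset.seed_set, config, profile)
    refpep, combined = step2_reference_sets(members, small_dataset.seed_set,
                                            config)
    windows = step3_putative_loci(combined, small_dataset.genome,
                                  small_dataset.features, config)
    return SimpleNamespace(config=config, profile=profile,
                           prior=members, refpep=refpep,
                           combined_seeds=combined, windows=windows)
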