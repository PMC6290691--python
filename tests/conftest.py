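"""Shared fixtures: a scaled-down simulated cohort for unit tests and the
default-scale reference for tests that exercise the study conditions."""
import numpy as np
import pytest

from driftprof import simgenome
from driftprof.simgenome import DriftConfig, PlantedCNV


def small_config(seed=11, **overrides) -> DriftConfig:
    """A miniature cohort (1.2 Mb) for fast unit tests."""
    kwargs = dict(
        seed=seed,
        chrom_lengths={"chr1": 600_000, "chr2": 600_000},
        n_ancestor_variants=3000,
        n_db_decoys=60,
        n_shared_rare=12,
        n_private_a=40,
        n_private_b=40,
        n_private_coding=2,
        n_genes=8,
        cnv_plant_list=(
            PlantedCNV("chr1", 100_000, 130_000, 3.0, "private_a"),
            PlantedCNV("chr1", 300_000, 330_000, 1.0, "shared"),
            PlantedCNV("chr2", 200_000, 230_000, 1.0, "common"),
            PlantedCNV("chr2", 400_000, 440_000, 3.0, "private_b"),
        ),
    )
    kwargs.update(overrides)
    return DriftConfig(**kwargs)


@pytest.fixture(scope="session")
def small_genome():
    cfg = small_config()
    reference, genes = simgenome.simulate_reference(cfg)
    return cfg, reference, genes


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    cfg, reference, genes = small_genome
    return simgenome.derive_subpopulations(reference, genes, cfg)


@pytest.fixture(scope="session")
def small_cohort_clean():
    """Same miniature cohort with platform noise switched off."""
    cfg = small_config(platform_error_rate=0.0)
    reference, genes = simgenome.simulate_reference(cfg)
    return cfg, reference, genes, simgenome.derive_subpopulations(
        reference, genes, cfg)


@pytest.fixture(scope="session")
def default_genome():
    """Reference + gene models at the default (study-condition) scale."""
    cfg = DriftConfig(seed=2024)
    reference, genes = simgenome.simulate_reference(cfg)
    return cfg, reference, genes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
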