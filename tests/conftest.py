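"""Shared fixtures: a small founder genome for fast unit tests.

The small genome keeps the program structure (multiple chromosomes, SNP
and QTL panels, drift-generated LD) at a fraction of the study scale so
that unit and engine tests run in seconds.  Full-scale founder simulation
lives in its own session fixture in test_acceptance.py.
"""

import numpy as np
import pytest

from ryesim.genome import (
    FounderSet,
    build_locus_panel,
    create_initial_varieties,
    simulate_historical_population,
)
from ryesim.params import BreedingSpec, ChainSpec, GenomeSpec, TraitSpec
from ryesim.rng import substream
from ryesim.traits import (
    calibrate_to_plot_h2,
    sample_qtl_effects,
    simulate_f2_calibration_plots,
)

SEED = 20260924


@pytest.fixture(scope="session")
def small_spec():
    return GenomeSpec(
        n_chromosomes=2,
        chrom_length_cm=100.0,
        n_snp_per_chrom=60,
        n_qtl_per_chrom=15,
        n_initial_loci_per_chrom=200,
        n_hist_generations=150,
        hist_size_start=300,
        hist_size_end=200,
        hist_constant_generations=80,
    )


@pytest.fixture(scope="session")
def small_history(small_spec):
    rng = substream(SEED, "history")
    cohort, pool = simulate_historical_population(small_spec, rng)
    panel = build_locus_panel(cohort, pool, small_spec, rng)
    base = cohort.subset_loci(panel._pool_indices)
    return panel, base


@pytest.fixture(scope="session")
def small_founders(small_history):
    panel, base = small_history
    varieties = create_initial_varieties(
        base, panel, substream(SEED, "varieties"), n_varieties=8, variety_size=40
    )
    return FounderSet(panel=panel, base=base, varieties=varieties)


@pytest.fixture(scope="session")
def small_breeding():
    return BreedingSpec(
        n_varieties=8,
        variety_size=40,
        n_f1_families=40,
        f1_family_size=10,
        f2_plot_size=10,
        f2_sp_per_family=10,
        n_selected_f2=10,
        n_polycross_parents=40,
        syn_group_size=8,
        syn1_size=10,
        syn2_size=10,
        syn3_size=10,
        n_selected_syn2=4,
        plot_dosage_sample=5,
        parents_per_cycle=60,
    )


@pytest.fixture(scope="session")
def small_arch(small_founders, small_breeding):
    arch = sample_qtl_effects(small_founders.panel, TraitSpec(), substream(SEED, "effects"))
    plots = simulate_f2_calibration_plots(
        small_founders.varieties,
        small_founders.panel,
        arch,
        substream(SEED, "calibration"),
        n_plots=200,
        family_size=small_breeding.f1_family_size,
        plot_size=small_breeding.f2_plot_size,
    )
    return calibrate_to_plot_h2(plots, arch)


@pytest.fixture(scope="session")
def tiny_chain():
    return ChainSpec(n_iter=400, burn_in=100)


@pytest.fixture
def rng():
    return substream(SEED, "test-local")
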