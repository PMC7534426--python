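"""Parameter containers with the study's default values.

The defaults describe a diploid, outcrossing, self-incompatible forage
grass (perennial ryegrass) breeding program: a neutral historical
population that generates standing variation and linkage disequilibrium,
20 initial varieties, and a 12-year synthetic-variety breeding cycle
(250 pair-cross F1 families -> F2 family plots -> greenhouse single
plants -> 8-parent polycross synthetics SYN1..SYN3) with two rounds of
index selection.  All counts are per-replicate simulation sizes and can
be scaled down for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomeSpec",
    "TraitSpec",
    "BreedingSpec",
    "ChainSpec",
    "PAPER_CHAIN",
    "FAST_CHAIN",
    "default_size_schedule",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Genome and historical-population parameters.

    ``n_initial_loci_per_chrom`` oversamples the panel (about 2.3x the
    1100 loci needed per chromosome) so that enough loci segregate with
    MAF > ``maf_min`` after 2000 generations of drift and recurrent
    mutation.
    """

    n_chromosomes: int = 7
    chrom_length_cm: float = 100.0
    n_snp_per_chrom: int = 1000
    n_qtl_per_chrom: int = 100
    n_initial_loci_per_chrom: int = 2500
    mutation_rate: float = 2.5e-5  # per locus per transmitted gamete
    maf_min: float = 0.05
    n_hist_generations: int = 2000
    hist_size_start: int = 2000
    hist_size_end: int = 1000
    hist_constant_generations: int = 1000

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chrom_length_cm <= 0:
            raise ValueError("genome must have >=1 chromosome of positive length")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.n_snp_per_chrom + self.n_qtl_per_chrom > self.n_initial_loci_per_chrom:
            raise ValueError("initial locus pool smaller than requested SNP+QTL panel")

    @property
    def n_panel_per_chrom(self) -> int:
        return self.n_snp_per_chrom + self.n_qtl_per_chrom

    def size_schedule(self) -> np.ndarray:
        return default_size_schedule(
            self.n_hist_generations,
            self.hist_size_start,
            self.hist_size_end,
            self.hist_constant_generations,
        )


def default_size_schedule(
    n_generations: int = 2000,
    size_start: int = 2000,
    size_end: int = 1000,
    constant_generations: int = 1000,
) -> np.ndarray:
    """Population size per historical generation.

    Constant at ``size_start`` for the first ``constant_generations``, then
    a linear decline to ``size_end`` in the final generation ("gradual
    decrease" implemented as linear interpolation).
    """
    if n_generations < 1 or size_start < 2 or size_end < 2:
        raise ValueError("need >=1 generation and sizes >=2")
    if constant_generations > n_generations:
        raise ValueError("constant phase longer than the history")
    n_decline = n_generations - constant_generations
    sched = np.full(n_generations, size_start, dtype=np.int64)
    if n_decline > 0:
        sched[constant_generations:] = np.rint(
            np.linspace(size_start, size_end, n_decline + 1)[1:]
        ).astype(np.int64)
    return sched


@dataclass(frozen=True)
class TraitSpec:
    """Four pleiotropic traits; trait 2 is heading date (grouping only)."""

    plot_h2: tuple = (0.3, 0.6, 0.4, 0.2)
    rg_trait3_trait4: float = 0.7

    @property
    def n_traits(self) -> int:
        return len(self.plot_h2)

    def effect_corr(self) -> np.ndarray:
        c = np.eye(self.n_traits)
        c[2, 3] = c[3, 2] = self.rg_trait3_trait4
        return c


@dataclass(frozen=True)
class BreedingSpec:
    """Per-cycle structure of the synthetic-variety program."""

    n_varieties: int = 20
    variety_size: int = 200
    n_f1_families: int = 250
    f1_family_size: int = 40
    f2_plot_size: int = 40
    f2_sp_per_family: int = 40  # greenhouse single plants per family
    n_selected_f2: int = 50
    n_polycross_parents: int = 400  # single plants feeding the synthetics
    syn_group_size: int = 8
    syn1_size: int = 40
    syn2_size: int = 40
    syn3_size: int = 40
    n_selected_syn2: int = 20
    plot_dosage_sample: int = 20  # plants genotyped per plot
    parents_per_cycle: int = 500  # -> parents_per_cycle/2 pair crosses
    index_weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    index_traits: tuple = (0, 2, 3)  # traits 1, 3, 4 (0-based)
    heading_trait: int = 1  # trait 2 (0-based)

    def __post_init__(self):
        if self.n_polycross_parents != self.syn_group_size * (
            self.n_polycross_parents // self.syn_group_size
        ):
            raise ValueError("polycross parent count must be divisible by the group size")
        if abs(sum(self.index_weights) - 1.0) > 1e-9:
            raise ValueError("index weights must sum to 1")

    @property
    def n_syn_groups(self) -> int:
        return self.n_polycross_parents // self.syn_group_size


@dataclass(frozen=True)
class ChainSpec:
    """Gibbs chain length for the Bayesian ridge regression sampler."""

    n_iter: int = 50_000
    burn_in: int = 10_000
    df_prior: float = 5.0
    r2_prior: float = 0.5  # share of var(y) assigned to markers a priori

    def __post_init__(self):
        if not 0 < self.burn_in < self.n_iter:
            raise ValueError("need 0 < burn_in < n_iter")


PAPER_CHAIN = ChainSpec(50_000, 10_000)
FAST_CHAIN = ChainSpec(5_000, 1_000)


def scaled(spec, **overrides):
    """Convenience: dataclass copy with field overrides (for small test runs)."""
    return replace(spec, **overrides)
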