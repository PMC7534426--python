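"""Founder genome simulation: historical population, locus panel, varieties.

The historical population is a monoecious Wright-Fisher population (random
mating with replacement, selfing possible) simulated by gene dropping over
an oversampled pool of bi-allelic loci with uniform initial allele
frequencies, Poisson(lambda=1) crossovers per chromosome per meiosis and
recurrent symmetric mutation restricted to this phase.  From the final
generation a panel of segregating SNPs and QTL (MAF > 0.05) is drawn, and
20 initial varieties are formed by sampling 200 plants each and random
mating for one generation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import drop_gametes
from .params import GenomeSpec

__all__ = [
    "Cohort",
    "LocusPanel",
    "FounderSet",
    "make_gametes",
    "simulate_historical_population",
    "build_locus_panel",
    "create_initial_varieties",
    "founder_population",
    "write_vcf",
]


@dataclass
class LocusPanel:
    """Loci on a genetic map, optionally flagged as SNP or QTL.

    positions are continuous cM, sorted within chromosome; ``chrom_start``
    gives locus-index offsets per chromosome (length n_chrom+1).
    """

    chrom: np.ndarray  # (L,) int16 chromosome index (0-based)
    pos: np.ndarray  # (L,) float64 cM position
    chrom_start: np.ndarray  # (n_chrom+1,) int64
    chrom_length_cm: float
    is_qtl: np.ndarray | None = None  # (L,) bool; None => untyped pool
    founder_freq: np.ndarray | None = None  # allele-1 frequency at panel build

    def __post_init__(self):
        for c in range(self.n_chromosomes):
            lo, hi = self.chrom_start[c], self.chrom_start[c + 1]
            if np.any(np.diff(self.pos[lo:hi]) < 0):
                raise ValueError(f"positions not sorted on chromosome {c + 1}")

    @property
    def n_loci(self) -> int:
        return self.pos.size

    @property
    def n_chromosomes(self) -> int:
        return self.chrom_start.size - 1

    @property
    def snp_indices(self) -> np.ndarray:
        if self.is_qtl is None:
            raise ValueError("pool panel has no SNP/QTL designation")
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_indices(self) -> np.ndarray:
        if self.is_qtl is None:
            raise ValueError("pool panel has no SNP/QTL designation")
        return np.flatnonzero(self.is_qtl)

    def subset(self, idx: np.ndarray) -> "LocusPanel":
        """Panel restricted to the given (sorted) locus indices."""
        idx = np.asarray(idx)
        chrom = self.chrom[idx]
        counts = np.bincount(chrom, minlength=self.n_chromosomes)
        start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return LocusPanel(
            chrom=chrom,
            pos=self.pos[idx],
            chrom_start=start,
            chrom_length_cm=self.chrom_length_cm,
            is_qtl=None if self.is_qtl is None else self.is_qtl[idx],
            founder_freq=None if self.founder_freq is None else self.founder_freq[idx],
        )


def _uniform_pool(spec: GenomeSpec, rng: np.random.Generator) -> LocusPanel:
    per = spec.n_initial_loci_per_chrom
    pos = np.sort(rng.random((spec.n_chromosomes, per)) * spec.chrom_length_cm, axis=1)
    chrom = np.repeat(np.arange(spec.n_chromosomes, dtype=np.int16), per)
    start = (np.arange(spec.n_chromosomes + 1) * per).astype(np.int64)
    return LocusPanel(chrom, pos.ravel(), start, spec.chrom_length_cm)


@dataclass
class Cohort:
    """A set of diploid individuals as paired haplotypes over a locus panel."""

    haplotypes: np.ndarray  # (n, 2, L) uint8, alleles in {0, 1}
    ids: np.ndarray = None  # (n,) int64
    stage: str = ""
    cycle: int = 0
    labels: np.ndarray = None  # (n,) variety/family/group label

    def __post_init__(self):
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, L)")
        if self.ids is None:
            self.ids = np.arange(self.n, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosage(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Genotypes coded 0/1/2 (copies of allele 1), (n, L) or (n, len(loci))."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int16).astype(np.uint8)

    def allele_freq(self, loci: np.ndarray | None = None) -> np.ndarray:
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.mean(axis=(0, 1))

    def take(self, idx: np.ndarray, stage: str | None = None) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            haplotypes=self.haplotypes[idx],
            ids=self.ids[idx],
            stage=self.stage if stage is None else stage,
            cycle=self.cycle,
            labels=None if self.labels is None else self.labels[idx],
        )

    def subset_loci(self, loci: np.ndarray) -> "Cohort":
        return replace(self, haplotypes=np.ascontiguousarray(self.haplotypes[:, :, loci]))


def make_gametes(
    parent_haps: np.ndarray,
    parent_idx: np.ndarray,
    panel: LocusPanel,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parent_idx`` (shape (G, L)).

    Per chromosome the crossover count is Poisson(1) with breakpoints
    uniform on the map and a fair-coin starting chromatid (no
    interference).
    """
    G = parent_idx.size
    n_chrom = panel.n_chromosomes
    start_chrom = rng.integers(0, 2, size=(G, n_chrom), dtype=np.int64).astype(np.uint8)
    counts = rng.poisson(1.0, G * n_chrom)
    cx_off = np.zeros(G * n_chrom + 1, dtype=np.int64)
    np.cumsum(counts, out=cx_off[1:])
    cx_pos = rng.random(cx_off[-1]) * panel.chrom_length_cm
    out = np.empty((G, panel.n_loci), dtype=np.uint8)
    drop_gametes(
        np.ascontiguousarray(parent_haps),
        parent_idx.astype(np.int64),
        start_chrom,
        cx_pos,
        cx_off,
        panel.pos,
        panel.chrom_start,
        out,
    )
    return out


def _mutate(gametes: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Symmetric allele flips on transmitted gametes, in place."""
    total = gametes.size
    n_mut = rng.binomial(total, rate)
    if n_mut:
        idx = rng.integers(0, total, n_mut)
        gametes.reshape(-1)[idx] ^= 1


def simulate_historical_population(
    spec: GenomeSpec,
    rng: np.random.Generator,
    n_generations: int | None = None,
    size_schedule: np.ndarray | None = None,
) -> tuple[Cohort, LocusPanel]:
    """Gene-drop the historical population; return the final cohort and pool map.

    Initial allele frequencies are uniform(0, 1) per pool locus; each
    generation every offspring draws two parents uniformly with
    replacement; mutation applies per transmitted gamete and only in this
    phase.
    """
    if size_schedule is None:
        size_schedule = spec.size_schedule() if n_generations is None else None
    if size_schedule is None:
        raise ValueError("size_schedule required when n_generations is overridden")
    size_schedule = np.asarray(size_schedule, dtype=np.int64)
    if n_generations is not None and size_schedule.size != n_generations:
        raise ValueError("size_schedule length must equal n_generations")
    if np.any(size_schedule < 2):
        raise ValueError("population sizes must be >= 2")

    pool = _uniform_pool(spec, rng)
    L = pool.n_loci
    n0 = int(size_schedule[0])
    p0 = rng.random(L)
    haps = (rng.random((n0, 2, L)) < p0).astype(np.uint8)

    for gen_size in size_schedule:
        n_next = int(gen_size)
        parent_idx = rng.integers(0, haps.shape[0], 2 * n_next)
        gam = make_gametes(haps, parent_idx, pool, rng)
        _mutate(gam, spec.mutation_rate, rng)
        haps = gam.reshape(n_next, 2, L)

    return Cohort(haplotypes=haps, stage="historical"), pool


def build_locus_panel(
    cohort: Cohort, pool: LocusPanel, spec: GenomeSpec, rng: np.random.Generator
) -> LocusPanel:
    """Draw the SNP/QTL panel from loci segregating with MAF > maf_min.

    Per chromosome, ``n_snp_per_chrom + n_qtl_per_chrom`` loci are drawn at
    random (without replacement) among the eligible ones and then split at
    random into disjoint SNP and QTL sets.  Raises if any chromosome lacks
    eligible loci, which signals a mutation-rate/pool-size miscalibration.
    """
    freq = cohort.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    eligible = maf > spec.maf_min
    need = spec.n_panel_per_chrom
    chosen = []
    is_qtl = []
    for c in range(pool.n_chromosomes):
        lo, hi = pool.chrom_start[c], pool.chrom_start[c + 1]
        cand = np.flatnonzero(eligible[lo:hi]) + lo
        if cand.size < need:
            raise ValueError(
                f"chromosome {c + 1}: only {cand.size} loci with MAF > "
                f"{spec.maf_min}, need {need}"
            )
        pick = np.sort(rng.choice(cand, size=need, replace=False))
        qtl_flag = np.zeros(need, dtype=bool)
        qtl_flag[rng.choice(need, size=spec.n_qtl_per_chrom, replace=False)] = True
        chosen.append(pick)
        is_qtl.append(qtl_flag)
    idx = np.concatenate(chosen)
    panel = pool.subset(idx)
    panel.is_qtl = np.concatenate(is_qtl)
    panel.founder_freq = freq[idx]
    panel._pool_indices = idx  # kept for provenance/export
    return panel


def create_initial_varieties(
    cohort: Cohort,
    panel: LocusPanel,
    rng: np.random.Generator,
    n_varieties: int = 20,
    variety_size: int = 200,
) -> list[Cohort]:
    """Form varieties: sample ``variety_size`` plants, random-mate one generation.

    Samples are drawn without replacement within a variety and with
    replacement across varieties (20 x 200 exceeds the 1000 founders).  The
    mating generation draws a distinct parent pair per offspring (selfing
    excluded, as enforced by self-incompatibility in the breeding phase).
    """
    if variety_size < 2:
        raise ValueError("variety_size must be >= 2")
    out = []
    L = cohort.n_loci
    for v in range(n_varieties):
        sample = rng.choice(cohort.n, size=variety_size, replace=False)
        parents = cohort.haplotypes[sample]
        pa = rng.integers(0, variety_size, variety_size)
        pb = (pa + 1 + rng.integers(0, variety_size - 1, variety_size)) % variety_size
        parent_idx = np.empty(2 * variety_size, dtype=np.int64)
        parent_idx[0::2] = pa
        parent_idx[1::2] = pb
        gam = make_gametes(parents, parent_idx, panel, rng)
        haps = gam.reshape(variety_size, 2, L)
        out.append(
            Cohort(
                haplotypes=haps,
                stage="variety",
                labels=np.full(variety_size, v, dtype=np.int64),
            )
        )
    return out


@dataclass
class FounderSet:
    """Shared founder genome: panel, generation-2000 base cohort, varieties."""

    panel: LocusPanel
    base: Cohort  # final historical generation, restricted to panel loci
    varieties: list

    @property
    def pooled_varieties(self) -> Cohort:
        haps = np.concatenate([v.haplotypes for v in self.varieties])
        labels = np.concatenate([v.labels for v in self.varieties])
        return Cohort(haplotypes=haps, stage="variety", labels=labels)


def founder_population(
    spec: GenomeSpec,
    seed_history: np.random.Generator,
    seed_varieties: np.random.Generator,
    n_varieties: int = 20,
    variety_size: int = 200,
    history: tuple | None = None,
) -> FounderSet:
    """History + panel + varieties in one call.

    ``history`` may carry a precomputed ``(cohort, pool)`` pair so the
    historical phase (shared across replicates and scenarios) is simulated
    once per run.
    """
    if history is None:
        history = simulate_historical_population(spec, seed_history)
    cohort, pool = history
    panel = build_locus_panel(cohort, pool, spec, seed_history)
    base = cohort.subset_loci(panel._pool_indices)
    varieties = create_initial_varieties(
        base, panel, seed_varieties, n_varieties=n_varieties, variety_size=variety_size
    )
    return FounderSet(panel=panel, base=base, varieties=varieties)


def write_vcf(cohort: Cohort, panel: LocusPanel, path: str, cm_to_bp: float = 1e6) -> None:
    """Export a cohort as phased diploid VCF (synthetic A/T alleles).

    cM positions are scaled to integer bp (1 cM = 1 Mbp by default).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=ryesim\n##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in range(panel.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1},length={int(panel.chrom_length_cm * cm_to_bp) + 2}>\n")
        samples = "\t".join(f"ind{int(i)}" for i in cohort.ids)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples + "\n")
        h = cohort.haplotypes
        for l in range(panel.n_loci):
            chrom = f"chr{panel.chrom[l] + 1}"
            bp = int(round(panel.pos[l] * cm_to_bp)) + 1
            role = "QTL" if (panel.is_qtl is not None and panel.is_qtl[l]) else "SNP"
            gts = "\t".join(f"{h[i, 0, l]}|{h[i, 1, l]}" for i in range(cohort.n))
            fh.write(f"{chrom}\t{bp}\t{role.lower()}_{l}\tA\tT\t.\tPASS\tROLE={role}\tGT\t{gts}\n")
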