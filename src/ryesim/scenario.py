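"""The 36-year overlapping breeding program for the five scenarios.

A new 12-year cycle starts every year; 36 years hold 25 complete cycles.
Scenarios differ in how selection is done (phenotypic index vs GEBV index)
and in which previous-cycle material may seed a new cycle:

========  ==================  ======================================
name      independent cycles  parent sources after independence
========  ==================  ======================================
Phen-Y12  11                  SYN2 group plants
Phen      5                   F2 single plants, SYN2 group plants
GS-Y12    11                  SYN2 group plants
GS        5                   F2 single plants, SYN2 group plants
GS-SP     5                   F2 single plants, SYN2 single plants
========  ==================  ======================================

Within-cycle event years (offsets from the cycle start year c) follow the
availability anchors of the program: F2 plots are phenotyped by c+3 and
the family/single-plant selection happens in year c+4 using reference
records entered through year c+3 (a cycle's own F2 families are the newest
usable records); F2 single plants can parent a new cycle from year c+5;
SYN2 plots are phenotyped and genotyped into the reference by c+9 and
selected in year c+10 using records entered through c+10 (freshly
genotyped SYN2 groups of the next cycle are usable); SYN2 output can
parent a new cycle from year c+11, and SYN3 (terminal) is sown then too.

Phenotypic scenarios never touch genotypes for selection; GS scenarios
never touch TBVs for selection — TBVs feed only the recorded metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .breeding import (
    cross,
    group_by_heading,
    index_scores,
    intermate_family,
    make_f1_families,
    polycross,
    random_mate,
    select_top,
)
from .genome import Cohort, FounderSet, LocusPanel
from .params import BreedingSpec, ChainSpec, FAST_CHAIN
from .prediction import ReferencePopulation, compute_gebv, fit_brr, plot_dosage
from .rng import substream, substream_seed
from .traits import TraitArchitecture, compute_tbv, plot_phenotype, single_plant_phenotype

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "CycleCalendar",
    "event_calendar",
    "parent_pool",
    "run_scenario",
    "SimulationResult",
]

SCENARIOS = {
    "Phen-Y12": {"independent_cycles": 11, "parent_sources": ("SYN2",), "gs": False},
    "Phen": {"independent_cycles": 5, "parent_sources": ("F2SP", "SYN2"), "gs": False},
    "GS-Y12": {"independent_cycles": 11, "parent_sources": ("SYN2",), "gs": True},
    "GS": {"independent_cycles": 5, "parent_sources": ("F2SP", "SYN2"), "gs": True},
    "GS-SP": {"independent_cycles": 5, "parent_sources": ("F2SP", "SYN2SP"), "gs": True},
}


@dataclass(frozen=True)
class CycleCalendar:
    """Event years of one cycle (absolute years, cycle starts in ``start``)."""

    start: int
    f1_cross: int
    f2_pheno: int
    f2_selection: int
    f2_sp_available: int
    syn2_pheno: int
    syn2_selection: int
    syn2_available: int
    syn3: int
    f2sel_ref_cutoff: int
    syn2sel_ref_cutoff: int

    @property
    def span(self) -> int:
        return self.syn3 - self.start + 1


def event_calendar(cycle_start_year: int, n_cycles: int = 25) -> CycleCalendar:
    """Offsets of the 12-year cycle anchored at the stated availabilities."""
    c = int(cycle_start_year)
    if not 1 <= c <= n_cycles:
        raise ValueError(f"cycle start year {c} outside 1..{n_cycles}")
    return CycleCalendar(
        start=c,
        f1_cross=c,
        f2_pheno=c + 3,
        f2_selection=c + 4,
        f2_sp_available=c + 5,
        syn2_pheno=c + 9,
        syn2_selection=c + 10,
        syn2_available=c + 11,
        syn3=c + 11,
        f2sel_ref_cutoff=c + 3,
        syn2sel_ref_cutoff=c + 10,
    )


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    years: int = 36
    breeding: BreedingSpec = field(default_factory=BreedingSpec)
    chain: ChainSpec = field(default_factory=lambda: FAST_CHAIN)
    selection_mode: str = "index"  # "random" disables selection (null model)
    make_syn3: bool = True

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; valid: {sorted(SCENARIOS)}")
        if self.selection_mode not in ("index", "random"):
            raise ValueError("selection_mode must be 'index' or 'random'")

    @property
    def independent_cycles(self) -> int:
        return SCENARIOS[self.name]["independent_cycles"]

    @property
    def parent_sources(self) -> tuple:
        return SCENARIOS[self.name]["parent_sources"]

    @property
    def uses_gs(self) -> bool:
        return SCENARIOS[self.name]["gs"]

    @property
    def n_cycles(self) -> int:
        return max(self.years - 11, 0)


@dataclass
class _ArchiveEntry:
    kind: str  # F2SP | SYN2 | SYN2SP
    cycle: int
    available_year: int
    haplotypes: np.ndarray  # (n, 2, L)
    labels: np.ndarray  # (n,) family/group label, globally unique per source
    tbv: np.ndarray  # (n, n_traits), metrics only


@dataclass
class SimulationResult:
    scenario: str
    seed: int
    gain: pd.DataFrame
    accuracy: pd.DataFrame
    variance: pd.DataFrame
    reference_size: pd.DataFrame
    audit: pd.DataFrame


def parent_pool(
    cfg: ScenarioConfig, year: int, archive: list
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Eligible parent material at the start of ``year``.

    Returns None while cycles still start from the initial varieties;
    otherwise (haplotypes, labels, tbv) pooled over every archived entry of
    the scenario's source kinds whose availability year has been reached.
    """
    if year <= cfg.independent_cycles:
        return None
    entries = [
        e
        for e in archive
        if e.kind in cfg.parent_sources and e.available_year <= year
    ]
    if not entries:
        raise RuntimeError(f"empty parent pool in year {year}")
    haps = np.concatenate([e.haplotypes for e in entries])
    labels = np.concatenate([e.labels for e in entries])
    tbv = np.concatenate([e.tbv for e in entries])
    return haps, labels, tbv


class _Engine:
    def __init__(self, cfg, founders, arch, seed):
        self.cfg = cfg
        self.b = cfg.breeding
        self.founders = founders
        self.panel: LocusPanel = founders.panel
        self.arch: TraitArchitecture = arch
        self.seed = seed
        self.snp = self.panel.snp_indices
        self.ref = ReferencePopulation(n_snp=self.snp.size) if cfg.uses_gs else None
        self.state = {}
        self.archive: list[_ArchiveEntry] = []
        self.f1_mean = {}
        self.f1_fam_means = {}
        self.f1_sd1 = None
        self.acc_rows = []
        self.audit_rows = []
        self.itraits = list(self.b.index_traits)

    # -- helpers ---------------------------------------------------------
    def _rng(self, *keys) -> np.random.Generator:
        return substream(self.seed, self.cfg.name, *keys)

    def _train(self, cutoff: int, event: str, cycle: int) -> list:
        X, y = self.ref.snapshot(cutoff)
        ests = []
        for t in self.itraits:
            s = substream_seed(self.seed, self.cfg.name, "gibbs", event, cycle, t)
            ests.append(fit_brr(X, y[:, t], self.cfg.chain, s))
        return ests

    def _gebv_matrix(self, x: np.ndarray, ests: list) -> np.ndarray:
        return np.column_stack([compute_gebv(x, e) for e in ests])

    def _scores(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cfg.selection_mode == "random":
            return rng.random(values.shape[0])
        return index_scores(values, self.b.index_weights)

    def _record_acc(self, cycle, stage, est_matrix, tbv_matrix):
        for k, t in enumerate(self.itraits):
            r = _metrics.selection_accuracy(est_matrix[:, k], tbv_matrix[:, t])
            self.acc_rows.append(
                {"cycle": cycle, "stage": stage, "trait": t + 1, "r": r}
            )

    def _audit(self, year, cycle, stage, event, n):
        self.audit_rows.append(
            {"year": year, "cycle": cycle, "stage": stage, "event": event, "n": n}
        )

    # -- events ----------------------------------------------------------
    def start_cycle(self, c: int):
        b = self.b
        rng = self._rng("cycle", c, "f1")
        if c <= self.cfg.independent_cycles:
            fams = make_f1_families(
                self.founders.varieties,
                self.panel,
                rng,
                n_families=b.n_f1_families,
                family_size=b.f1_family_size,
                cycle=c,
            )
            self._audit(c, c, "F1", "cross_from_varieties", b.n_f1_families)
        else:
            fams = self._recruit_and_cross(c, rng)
            self._audit(c, c, "F1", "cross_from_archive", b.n_f1_families)

        n_traits = self.arch.n_traits
        fam_means = np.empty((b.n_f1_families, n_traits))
        all_tbv = []
        plot_tbv = np.empty((b.n_f1_families, n_traits))
        plot_pheno = np.empty((b.n_f1_families, n_traits))
        sp_haps = np.empty(
            (b.n_f1_families, b.f2_sp_per_family, 2, self.panel.n_loci), dtype=np.uint8
        )
        sp_tbv = np.empty((b.n_f1_families, b.f2_sp_per_family, n_traits))
        dosages = (
            np.empty((b.n_f1_families, self.snp.size), dtype=np.float32)
            if self.cfg.uses_gs
            else None
        )
        rng_f2 = self._rng("cycle", c, "f2")
        rng_ph = self._rng("cycle", c, "pheno")
        rng_ds = self._rng("cycle", c, "dosage")
        for i, fam in enumerate(fams):
            tbv = compute_tbv(fam.members, self.panel, self.arch)
            fam_means[i] = tbv.mean(axis=0)
            all_tbv.append(tbv)
            f2 = intermate_family(fam, b.f2_plot_size, self.panel, rng_f2)
            f2_tbv = compute_tbv(f2.members, self.panel, self.arch)
            plot_tbv[i] = f2_tbv.mean(axis=0)
            if self.cfg.uses_gs:
                dosages[i] = plot_dosage(
                    f2.members, self.panel, rng_ds, n_sample=b.plot_dosage_sample
                )
            sp = intermate_family(fam, b.f2_sp_per_family, self.panel, rng_f2)
            sp_haps[i] = sp.members.haplotypes
            sp_tbv[i] = compute_tbv(sp.members, self.panel, self.arch)
        plot_pheno[:] = plot_phenotype(plot_tbv, self.arch, rng_ph)

        all_tbv = np.concatenate(all_tbv)
        self.f1_mean[c] = all_tbv.mean(axis=0)
        self.f1_fam_means[c] = fam_means
        if c == 1:
            self.f1_sd1 = all_tbv.std(axis=0, ddof=1)
        if self.cfg.uses_gs:
            self.ref.add(dosages, plot_pheno, "F2", c, entry_year=c + 3)
        self.state[c] = {
            "plot_tbv": plot_tbv,
            "plot_pheno": plot_pheno,
            "dosage": dosages,
            "sp_haps": sp_haps,
            "sp_tbv": sp_tbv,
        }

    def _recruit_and_cross(self, c: int, rng: np.random.Generator) -> list:
        b = self.b
        pool = parent_pool(self.cfg, c, self.archive)
        haps, labels, tbv = pool
        if np.unique(labels).size < 2:
            raise RuntimeError("parent pool holds a single family/group")
        if self.cfg.uses_gs and self.cfg.selection_mode == "index":
            ests = self._train(c - 1, "parents", c)
            geno = haps.sum(axis=1, dtype=np.int16)[:, self.snp].astype(np.float64)
            gebv = self._gebv_matrix(geno, ests)
            scores = index_scores(gebv, b.index_weights)
            k = min(b.parents_per_cycle, haps.shape[0])
            chosen = select_top(scores, k)
        else:
            k = min(b.parents_per_cycle, haps.shape[0])
            chosen = rng.choice(haps.shape[0], size=k, replace=False)
        ph = np.ascontiguousarray(haps[chosen])
        pl = labels[chosen]
        parents = Cohort(haplotypes=ph, labels=pl)
        fams = []
        for f in range(b.n_f1_families):
            a = int(rng.integers(parents.n))
            bb = int(rng.integers(parents.n))
            while pl[bb] == pl[a]:
                bb = int(rng.integers(parents.n))
            fams.append(
                cross(parents, a, bb, b.f1_family_size, self.panel, rng, "F1", c, f)
            )
        return fams

    def f2_selection(self, c: int):
        b = self.b
        st = self.state[c]
        cal = event_calendar(c, self.cfg.n_cycles)
        rng = self._rng("cycle", c, "f2sel")
        if self.cfg.uses_gs:
            ests = self._train(cal.f2sel_ref_cutoff, "f2sel", c)
            plot_est = self._gebv_matrix(st["dosage"].astype(np.float64), ests)
        else:
            ests = None
            plot_est = st["plot_pheno"][:, self.itraits]
        self._record_acc(c, "F2", plot_est, st["plot_tbv"])
        scores = self._scores(plot_est, rng)
        top = select_top(scores, b.n_selected_f2)
        self._audit(cal.f2_selection, c, "F2", "family_selection", b.n_selected_f2)

        # greenhouse single plants of the selected families
        sp_haps = st["sp_haps"][top].reshape(-1, 2, self.panel.n_loci)
        sp_tbv = st["sp_tbv"][top].reshape(-1, self.arch.n_traits)
        sp_labels = np.repeat(top, b.f2_sp_per_family).astype(np.int64)
        n_cand = sp_haps.shape[0]

        if self.cfg.uses_gs and self.cfg.selection_mode == "index":
            geno = sp_haps.sum(axis=1, dtype=np.int16)[:, self.snp].astype(np.float64)
            sp_gebv = self._gebv_matrix(geno, ests)
            self._record_acc(c, "F2SP", sp_gebv, sp_tbv)
            sp_scores = index_scores(sp_gebv, b.index_weights)
            chosen = select_top(sp_scores, b.n_polycross_parents)
        else:
            # random choice of 8 single plants per selected family
            per = b.n_polycross_parents // b.n_selected_f2
            chosen = np.concatenate(
                [
                    rng.choice(b.f2_sp_per_family, size=per, replace=False)
                    + k * b.f2_sp_per_family
                    for k in range(b.n_selected_f2)
                ]
            )
        self._audit(cal.f2_selection, c, "F2SP", "single_plant_selection", chosen.size)

        # archive parent material for later cycles
        if self.cfg.uses_gs:
            arch_idx = np.arange(n_cand)  # whole greenhouse stands available
        else:
            arch_idx = chosen
        self.archive.append(
            _ArchiveEntry(
                "F2SP",
                c,
                cal.f2_sp_available,
                sp_haps[arch_idx].copy(),
                c * 1000 + sp_labels[arch_idx],
                sp_tbv[arch_idx].copy(),
            )
        )

        # heading-date grouping and synthetics
        hd = single_plant_phenotype(
            sp_tbv[chosen][:, b.heading_trait],
            self.arch,
            self._rng("cycle", c, "hd"),
            trait=b.heading_trait,
        )
        groups, _cat = group_by_heading(hd, group_size=b.syn_group_size)
        rng_syn = self._rng("cycle", c, "syn")
        rng_ds = self._rng("cycle", c, "syn_dosage")
        n_groups = groups.shape[0]
        syn2_haps = np.empty((n_groups, b.syn2_size, 2, self.panel.n_loci), dtype=np.uint8)
        syn2_tbv = np.empty((n_groups, b.syn2_size, self.arch.n_traits))
        plot_tbv = np.empty((n_groups, self.arch.n_traits))
        dosage = (
            np.empty((n_groups, self.snp.size), dtype=np.float32)
            if self.cfg.uses_gs
            else None
        )
        sel_cohort = Cohort(haplotypes=sp_haps[chosen], labels=sp_labels[chosen])
        for g in range(n_groups):
            par = sel_cohort.take(groups[g])
            par.ids = np.asarray(groups[g], dtype=np.int64)
            syn1 = polycross(
                par, b.syn1_size, self.panel, rng_syn,
                n_parents=b.syn_group_size, cycle=c, group_id=g,
            )
            syn2 = intermate_family(syn1, b.syn2_size, self.panel, rng_syn)
            syn2_haps[g] = syn2.members.haplotypes
            syn2_tbv[g] = compute_tbv(syn2.members, self.panel, self.arch)
            plot_tbv[g] = syn2_tbv[g].mean(axis=0)
            if self.cfg.uses_gs:
                dosage[g] = plot_dosage(
                    syn2.members, self.panel, rng_ds, n_sample=b.plot_dosage_sample
                )
        plot_pheno = plot_phenotype(plot_tbv, self.arch, self._rng("cycle", c, "syn_pheno"))
        if self.cfg.uses_gs:
            self.ref.add(dosage, plot_pheno, "SYN2", c, entry_year=cal.syn2_pheno)
        st.clear()
        self.state[c] = {
            "syn2_haps": syn2_haps,
            "syn2_tbv": syn2_tbv,
            "syn2_plot_tbv": plot_tbv,
            "syn2_plot_pheno": plot_pheno,
            "syn2_dosage": dosage,
        }

    def syn2_selection(self, c: int):
        b = self.b
        st = self.state.pop(c)
        cal = event_calendar(c, self.cfg.n_cycles)
        rng = self._rng("cycle", c, "syn2sel")
        if self.cfg.uses_gs:
            ests = self._train(cal.syn2sel_ref_cutoff, "syn2sel", c)
            plot_est = self._gebv_matrix(st["syn2_dosage"].astype(np.float64), ests)
            # genomic SYN2 accuracy: plot GEBV against plot TBV
            self._record_acc(c, "SYN2", plot_est, st["syn2_plot_tbv"])
        else:
            ests = None
            plot_est = st["syn2_plot_pheno"][:, self.itraits]
            # phenotypic SYN2 accuracy: plot performance against the TBVs of
            # the individual plants in the groups (parents are single plants
            # picked via their group's plot record, so this is the accuracy
            # that limits gain); the plot-level correlation is kept under a
            # separate stage label
            member_tbv = st["syn2_tbv"].reshape(-1, self.arch.n_traits)
            member_est = np.repeat(plot_est, self.b.syn2_size, axis=0)
            self._record_acc(c, "SYN2", member_est, member_tbv)
            self._record_acc(c, "SYN2_plot", plot_est, st["syn2_plot_tbv"])
        if self.cfg.uses_gs:
            members = st["syn2_haps"].reshape(-1, 2, self.panel.n_loci)
            member_tbv = st["syn2_tbv"].reshape(-1, self.arch.n_traits)
            geno = members.sum(axis=1, dtype=np.int16)[:, self.snp].astype(np.float64)
            sp_gebv = self._gebv_matrix(geno, ests)
            self._record_acc(c, "SYN2SP", sp_gebv, member_tbv)
        scores = self._scores(plot_est, rng)
        top = select_top(scores, b.n_selected_syn2)
        self._audit(cal.syn2_selection, c, "SYN2", "plot_selection", b.n_selected_syn2)

        sel_haps = st["syn2_haps"][top].reshape(-1, 2, self.panel.n_loci)
        sel_tbv = st["syn2_tbv"][top].reshape(-1, self.arch.n_traits)
        # offset keeps SYN2 group labels disjoint from F2SP family labels
        sel_labels = (500_000 + c * 1000 + np.repeat(top, b.syn2_size)).astype(np.int64)
        kind = "SYN2SP" if "SYN2SP" in self.cfg.parent_sources else "SYN2"
        self.archive.append(
            _ArchiveEntry(kind, c, cal.syn2_available, sel_haps.copy(), sel_labels, sel_tbv.copy())
        )
        if self.cfg.make_syn3:
            rng_s3 = self._rng("cycle", c, "syn3")
            for g in top:  # terminal stage: produced, feeds nothing
                grp = Cohort(haplotypes=st["syn2_haps"][g], labels=None)
                random_mate(grp, b.syn3_size, self.panel, rng_s3)
            self._audit(cal.syn3, c, "SYN3", "seed_increase", b.n_selected_syn2)

    # -- driver ----------------------------------------------------------
    def run(self) -> SimulationResult:
        cfg = self.cfg
        if cfg.n_cycles < 1:
            raise ValueError("years must cover at least one 12-year cycle")
        ref_rows = []
        for year in range(1, cfg.years + 1):
            if 1 <= year <= cfg.n_cycles:
                self.start_cycle(year)
            c2 = year - 4
            if 1 <= c2 <= cfg.n_cycles:
                self.f2_selection(c2)
            c3 = year - 10
            if 1 <= c3 <= cfg.n_cycles:
                self.syn2_selection(c3)
            if cfg.uses_gs:
                n = sum(1 for p in self.ref.provenance if p["entry_year"] <= year)
                ref_rows.append({"year": year, "n_records": n})

        cycles = sorted(self.f1_mean)
        mean_mat = np.array([self.f1_mean[c] for c in cycles])
        gain_rows = []
        dg = _metrics.genetic_gain(mean_mat, self.f1_sd1)
        for i, c in enumerate(cycles):
            for t in range(self.arch.n_traits):
                gain_rows.append(
                    {
                        "cycle": c,
                        "trait": t + 1,
                        "f1_mean_tbv": mean_mat[i, t],
                        "delta_g": dg[i, t],
                    }
                )
        var_rows = []
        for t in range(self.arch.n_traits):
            series = _metrics.additive_variance(
                [self.f1_fam_means[c][:, t] for c in cycles]
            )
            raw0 = self.f1_fam_means[cycles[0]][:, t].var(ddof=1)
            for i, c in enumerate(cycles):
                var_rows.append(
                    {
                        "cycle": c,
                        "trait": t + 1,
                        "var_f1_family_means": series[i] * raw0,
                        "standardized": series[i],
                    }
                )
        return SimulationResult(
            scenario=cfg.name,
            seed=self.seed,
            gain=pd.DataFrame(gain_rows),
            accuracy=pd.DataFrame(self.acc_rows),
            variance=pd.DataFrame(var_rows),
            reference_size=pd.DataFrame(ref_rows),
            audit=pd.DataFrame(self.audit_rows),
        )


def run_scenario(
    cfg: ScenarioConfig,
    founders: FounderSet,
    arch: TraitArchitecture,
    seed: int,
) -> SimulationResult:
    """Run one replicate of one scenario on a shared founder genome."""
    arch.require_calibrated()
    return _Engine(cfg, founders, arch, seed).run()
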