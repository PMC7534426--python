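"""Breeding operations: meiosis, crossing, family construction, selection.

Every mating respects gametophytic self-incompatibility: the two parents
of any offspring are distinct plants.  Stochastic draws consume the
Generator passed in, so callers control the substream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Cohort, LocusPanel, make_gametes

__all__ = [
    "Family",
    "meiosis",
    "cross",
    "make_f1_families",
    "intermate_family",
    "polycross",
    "random_mate",
    "standardize",
    "index_scores",
    "phenotypic_index",
    "gebv_index",
    "select_top",
    "group_by_heading",
]


@dataclass
class Family:
    members: Cohort
    parent_ids: tuple
    stage: str
    cycle: int = 0
    family_id: int = 0


def meiosis(parent_haplotypes: np.ndarray, panel: LocusPanel, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent (2, L) -> (L,)."""
    ph = np.asarray(parent_haplotypes, dtype=np.uint8)
    if ph.shape != (2, panel.n_loci):
        raise ValueError("parent haplotypes must have shape (2, n_loci)")
    return make_gametes(ph[None, :, :], np.zeros(1, dtype=np.int64), panel, rng)[0]


def random_mate(
    cohort: Cohort,
    n_offspring: int,
    panel: LocusPanel,
    rng: np.random.Generator,
) -> Cohort:
    """Offspring from uniformly drawn *distinct* parent pairs (no selfing)."""
    n = cohort.n
    if n < 2:
        raise ValueError("need at least 2 parents for random mating")
    pa = rng.integers(0, n, n_offspring)
    pb = (pa + 1 + rng.integers(0, n - 1, n_offspring)) % n
    parent_idx = np.empty(2 * n_offspring, dtype=np.int64)
    parent_idx[0::2] = pa
    parent_idx[1::2] = pb
    gam = make_gametes(cohort.haplotypes, parent_idx, panel, rng)
    return Cohort(haplotypes=gam.reshape(n_offspring, 2, cohort.n_loci))


def cross(
    parents: Cohort,
    a: int,
    b: int,
    n_offspring: int,
    panel: LocusPanel,
    rng: np.random.Generator,
    stage: str = "F1",
    cycle: int = 0,
    family_id: int = 0,
) -> Family:
    """Pair cross of two distinct plants (indices into ``parents``)."""
    if a == b:
        raise ValueError("selfing attempt: the two parents must be distinct plants")
    parent_idx = np.empty(2 * n_offspring, dtype=np.int64)
    parent_idx[0::2] = a
    parent_idx[1::2] = b
    gam = make_gametes(parents.haplotypes, parent_idx, panel, rng)
    members = Cohort(
        haplotypes=gam.reshape(n_offspring, 2, parents.n_loci),
        stage=stage,
        cycle=cycle,
        labels=np.full(n_offspring, family_id, dtype=np.int64),
    )
    return Family(members, (int(parents.ids[a]), int(parents.ids[b])), stage, cycle, family_id)


def make_f1_families(
    varieties: list,
    panel: LocusPanel,
    rng: np.random.Generator,
    n_families: int = 250,
    family_size: int = 40,
    cycle: int = 0,
) -> list:
    """F1 full-sib families from the initial varieties.

    For each family a random pair of distinct varieties is drawn and one
    random plant taken from each, so with 20 varieties and 250 families
    each variety contributes 25 parents on average.
    """
    if len(varieties) < 2:
        raise ValueError("need at least 2 source varieties")
    out = []
    for f in range(n_families):
        va, vb = rng.choice(len(varieties), size=2, replace=False)
        ia = int(rng.integers(varieties[va].n))
        ib = int(rng.integers(varieties[vb].n))
        pair = Cohort(
            haplotypes=np.stack(
                [varieties[va].haplotypes[ia], varieties[vb].haplotypes[ib]]
            ),
            ids=np.array([va * 10_000 + ia, vb * 10_000 + ib], dtype=np.int64),
        )
        out.append(cross(pair, 0, 1, family_size, panel, rng, "F1", cycle, f))
    return out


def intermate_family(
    family: Family, n_offspring: int, panel: LocusPanel, rng: np.random.Generator
) -> Family:
    """Random mating among full sibs (F1->F2, SYN1->SYN2, SYN2->SYN3)."""
    if family.members.n < 2:
        raise ValueError("cannot intermate a family of one")
    members = random_mate(family.members, n_offspring, panel, rng)
    members.stage = _next_stage(family.stage)
    members.cycle = family.cycle
    members.labels = np.full(n_offspring, family.family_id, dtype=np.int64)
    return Family(members, family.parent_ids, members.stage, family.cycle, family.family_id)


_STAGE_SUCCESSOR = {"F1": "F2", "SYN1": "SYN2", "SYN2": "SYN3"}


def _next_stage(stage: str) -> str:
    return _STAGE_SUCCESSOR.get(stage, stage)


def polycross(
    parents: Cohort,
    n_offspring: int,
    panel: LocusPanel,
    rng: np.random.Generator,
    n_parents: int = 8,
    cycle: int = 0,
    group_id: int = 0,
) -> Family:
    """8-parent polycross founding a synthetic (stage SYN1)."""
    if parents.n != n_parents:
        raise ValueError(f"polycross needs exactly {n_parents} parents, got {parents.n}")
    if np.unique(parents.ids).size != parents.n:
        raise ValueError("polycross parents must be distinct plants")
    members = random_mate(parents, n_offspring, panel, rng)
    members.stage = "SYN1"
    members.cycle = cycle
    members.labels = np.full(n_offspring, group_id, dtype=np.int64)
    return Family(members, tuple(int(i) for i in parents.ids), "SYN1", cycle, group_id)


def standardize(values: np.ndarray) -> np.ndarray:
    """Column-wise z-scores within the candidate cohort."""
    v = np.asarray(values, dtype=float)
    sd = v.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (v - v.mean(axis=0)) / sd


def index_scores(
    values: np.ndarray,
    weights=(1 / 3, 1 / 3, 1 / 3),
    standardize_within: bool = True,
) -> np.ndarray:
    """Multi-trait selection index I = b1*v1 + b2*v3 + b3*v4.

    ``values`` holds the three index-trait columns (traits 1, 3, 4);
    z-standardization within the candidate cohort operationalizes the
    "standardized emphasis on each trait" of the equal 1/3 weights.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != len(weights):
        raise ValueError("values must be (n_candidates, n_index_traits)")
    if standardize_within:
        v = standardize(v)
    return v @ np.asarray(weights, dtype=float)


def phenotypic_index(plot_means: np.ndarray, weights=(1 / 3, 1 / 3, 1 / 3), **kw) -> np.ndarray:
    """Index on plot mean phenotypes of the three yield-type traits."""
    return index_scores(plot_means, weights, **kw)


def gebv_index(gebvs: np.ndarray, weights=(1 / 3, 1 / 3, 1 / 3), **kw) -> np.ndarray:
    """Index on GEBVs of the three yield-type traits."""
    return index_scores(gebvs, weights, **kw)


def select_top(scores: np.ndarray, n: int, ids: np.ndarray | None = None) -> np.ndarray:
    """Indices of the ``n`` highest scores; ties broken by ascending id."""
    scores = np.asarray(scores, dtype=float)
    if n > scores.size:
        raise ValueError("cannot select more candidates than available")
    if ids is None:
        ids = np.arange(scores.size)
    order = np.lexsort((np.asarray(ids), -scores))
    return order[:n]


def group_by_heading(
    hd_phenotype: np.ndarray,
    group_size: int = 8,
    ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sort-and-block grouping by heading-date phenotype.

    Returns (groups, category): ``groups`` is (n_groups, group_size) candidate
    indices, sorted by heading date and cut into consecutive blocks (ties,
    and hence the all-equal case, resolve deterministically by id);
    ``category`` labels the block terciles 0/1/2 = early/intermediate/late.
    """
    hd = np.asarray(hd_phenotype, dtype=float)
    if hd.size % group_size:
        raise ValueError("candidate count must be divisible by the group size")
    if ids is None:
        ids = np.arange(hd.size)
    order = np.lexsort((np.asarray(ids), hd))
    groups = order.reshape(-1, group_size)
    n_groups = groups.shape[0]
    category = np.minimum(np.arange(n_groups) * 3 // max(n_groups, 1), 2)
    return groups, category
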