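"""Breeding operations: crossing, families, polycross, indices, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ryesim.breeding import (
    Family,
    cross,
    group_by_heading,
    index_scores,
    intermate_family,
    make_f1_families,
    meiosis,
    phenotypic_index,
    polycross,
    random_mate,
    select_top,
)
from ryesim.genome import Cohort, LocusPanel
from ryesim.rng import substream


@pytest.fixture(scope="module")
def one_locus_panel():
    return LocusPanel(
        chrom=np.zeros(1, dtype=np.int16),
        pos=np.array([50.0]),
        chrom_start=np.array([0, 1], dtype=np.int64),
        chrom_length_cm=100.0,
    )


def _cohort(genos, panel):
    """Cohort from single-locus genotype codes 0/1/2."""
    haps = np.zeros((len(genos), 2, 1), dtype=np.uint8)
    for i, g in enumerate(genos):
        if g == 1:
            haps[i, 0, 0] = 1
        elif g == 2:
            haps[i, :, 0] = 1
    return Cohort(haplotypes=haps)


def test_cross_aa_x_aa_gives_all_het(one_locus_panel, rng):
    parents = _cohort([2, 0], one_locus_panel)
    fam = cross(parents, 0, 1, 200, one_locus_panel, rng)
    assert np.all(fam.members.dosage() == 1)


def test_cross_het_x_het_mendelian_ratios(one_locus_panel, rng):
    parents = _cohort([1, 1], one_locus_panel)
    fam = cross(parents, 0, 1, 10_000, one_locus_panel, rng)
    counts = np.bincount(fam.members.dosage().ravel(), minlength=3) / 10_000
    for obs, exp in zip(counts, (0.25, 0.5, 0.25)):
        se = np.sqrt(exp * (1 - exp) / 10_000)
        assert abs(obs - exp) < 3 * se


def test_selfing_rejected_everywhere(one_locus_panel, rng):
    parents = _cohort([1, 1], one_locus_panel)
    with pytest.raises(ValueError, match="selfing"):
        cross(parents, 0, 0, 5, one_locus_panel, rng)
    with pytest.raises(ValueError):
        intermate_family(
            Family(_cohort([1], one_locus_panel), (0,), "F1"), 5, one_locus_panel, rng
        )
    dup = _cohort([1] * 8, one_locus_panel)
    dup.ids = np.zeros(8, dtype=np.int64)
    with pytest.raises(ValueError, match="distinct"):
        polycross(dup, 10, one_locus_panel, rng)


def test_random_mate_never_selfs(one_locus_panel):
    """Parent-pair draws exclude (i, i) by construction: a cohort of two
    always pairs both members, and offspring of a 3-plant cohort with
    distinguishable genomes never carry two copies of one parent genome."""
    rng = substream(1, "rm")
    panel = LocusPanel(
        chrom=np.zeros(4, dtype=np.int16),
        pos=np.array([10.0, 20.0, 80.0, 90.0]),
        chrom_start=np.array([0, 4], dtype=np.int64),
        chrom_length_cm=100.0,
    )
    # three parents homozygous for distinct haplotype patterns
    pats = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [0, 1, 0, 1]], dtype=np.uint8)
    haps = np.stack([np.stack([p, p]) for p in pats])
    off = random_mate(Cohort(haplotypes=haps), 2000, panel, rng)
    same = (off.haplotypes[:, 0, :] == off.haplotypes[:, 1, :]).all(axis=1)
    assert not same.any()


def test_f1_families_counts_and_variety_usage(small_founders):
    rng = substream(2, "f1")
    fams = make_f1_families(small_founders.varieties, small_founders.panel, rng,
                            n_families=250, family_size=4)
    assert len(fams) == 250
    assert all(f.members.n == 4 for f in fams)
    # each family's parents come from two different varieties
    draws = np.zeros(len(small_founders.varieties))
    for f in fams:
        va, vb = f.parent_ids[0] // 10_000, f.parent_ids[1] // 10_000
        assert va != vb
        draws[va] += 1
        draws[vb] += 1
    # multinomial oracle: expected draws/variety = 500/8, sd = sqrt(n p (1-p))
    exp = 500 / len(draws)
    se = np.sqrt(500 * (1 / len(draws)) * (1 - 1 / len(draws)))
    assert np.all(np.abs(draws - exp) < 4 * se)
    with pytest.raises(ValueError):
        make_f1_families(small_founders.varieties[:1], small_founders.panel, rng)


def test_intermate_conserves_allele_frequency(one_locus_panel):
    rng = substream(3, "im")
    fam = Family(_cohort([2, 1, 1, 0, 0], one_locus_panel), (0, 1), "F1")
    out = intermate_family(fam, 10_000, one_locus_panel, rng)
    f_parent = fam.members.allele_freq()[0]
    f_off = out.members.allele_freq()[0]
    se = np.sqrt(f_parent * (1 - f_parent) / (2 * 10_000))
    assert abs(f_off - f_parent) < 4 * se
    assert out.stage == "F2"


def test_polycross_contributions_and_identity(one_locus_panel):
    rng = substream(4, "pc")
    # 8 identical homozygotes -> identical homozygous offspring
    same = _cohort([2] * 8, one_locus_panel)
    fam = polycross(same, 50, one_locus_panel, rng)
    assert np.all(fam.members.dosage() == 2)
    assert fam.stage == "SYN1"
    with pytest.raises(ValueError, match="exactly"):
        polycross(_cohort([1] * 7, one_locus_panel), 10, one_locus_panel, rng)
    # contribution oracle: mark parent k by frequency k/16 at a many-locus genome
    panel = LocusPanel(
        chrom=np.zeros(64, dtype=np.int16),
        pos=np.sort(substream(5, "pos").random(64) * 100),
        chrom_start=np.array([0, 64], dtype=np.int64),
        chrom_length_cm=100.0,
    )
    haps = np.zeros((8, 2, 64), dtype=np.uint8)
    for k in range(8):
        haps[k, :, : 8 * k] = 1  # parent k dosage = 2 at first 8k loci
    fam = polycross(Cohort(haplotypes=haps), 8000, panel, rng)
    # expected allele frequency at locus block b is the mean parental freq
    f = fam.members.allele_freq()
    for k in range(1, 8):
        block = slice(8 * (k - 1), 8 * k)
        exp = 1 - k / 8  # parents k..7 carry allele 1 here
        se = np.sqrt(exp * (1 - exp) / (2 * 8000))
        assert np.all(np.abs(f[block] - exp) < 4 * se + 1e-9)


def test_index_examples_and_ranking_oracle(rng):
    assert phenotypic_index(np.array([[3.0, 3.0, 3.0]]), standardize_within=False)[0] == pytest.approx(3.0)
    assert phenotypic_index(np.array([[1.0, 0.0, -1.0]]), standardize_within=False)[0] == pytest.approx(0.0)
    vals = rng.standard_normal((100, 3))
    scores = index_scores(vals, standardize_within=False)
    oracle = vals @ np.full(3, 1 / 3)
    assert np.array_equal(np.argsort(scores), np.argsort(oracle))
    # standardization leaves ranking of equal-scale traits' weighted sum intact
    z = index_scores(vals, standardize_within=True)
    assert z.shape == (100,)


def test_select_top_ties_and_oracle(rng):
    scores = np.arange(1, 101, dtype=float)
    top = select_top(scores, 50)
    assert set(scores[top]) == set(range(51, 101))
    equal = np.ones(10)
    assert np.array_equal(select_top(equal, 3), [0, 1, 2])  # tie -> id order
    with pytest.raises(ValueError):
        select_top(equal, 11)
    s = rng.standard_normal(500)
    assert np.array_equal(np.sort(s[select_top(s, 100)]), np.sort(s)[-100:])


@settings(deadline=None, max_examples=25)
@given(st.lists(st.integers(0, 1000), min_size=16, max_size=64).filter(lambda v: len(v) % 8 == 0))
def test_group_by_heading_blocks_are_ordered(vals):
    """Sort-and-block: every group's heading-date range precedes the next
    group's, and the tercile labels are non-decreasing."""
    hd = np.array(vals, dtype=float)
    groups, cat = group_by_heading(hd, group_size=8)
    assert groups.shape == (len(vals) // 8, 8)
    maxes = [hd[g].max() for g in groups]
    mins = [hd[g].min() for g in groups]
    for i in range(len(groups) - 1):
        assert maxes[i] <= mins[i + 1]
    assert np.all(np.diff(cat) >= 0) and cat.min() == 0
    # partition covers all candidates exactly once
    assert sorted(groups.ravel()) == list(range(len(vals)))


def test_group_by_heading_equal_values_deterministic():
    groups, _ = group_by_heading(np.zeros(400), group_size=8)
    assert np.array_equal(groups.ravel(), np.arange(400))
    with pytest.raises(ValueError):
        group_by_heading(np.zeros(401), group_size=8)


def test_meiosis_single_gamete(small_founders, rng):
    panel = small_founders.panel
    parent = small_founders.base.haplotypes[0]
    gam = meiosis(parent, panel, rng)
    assert gam.shape == (panel.n_loci,)
    # each allele comes from one of the two parental haplotypes
    ok = (gam == parent[0]) | (gam == parent[1])
    assert np.all(ok)
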