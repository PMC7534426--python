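"""Founder genome: history, meiosis kernel, locus panel, varieties."""

import numpy as np
import pytest

from ryesim._kernels import drop_gametes
from ryesim.genome import (
    Cohort,
    LocusPanel,
    build_locus_panel,
    create_initial_varieties,
    make_gametes,
    simulate_historical_population,
    write_vcf,
)
from ryesim.params import GenomeSpec, default_size_schedule
from ryesim.rng import substream


def tiny_spec(**kw):
    defaults = dict(
        n_chromosomes=2,
        chrom_length_cm=100.0,
        n_snp_per_chrom=10,
        n_qtl_per_chrom=2,
        n_initial_loci_per_chrom=40,
        n_hist_generations=12,
        hist_size_start=30,
        hist_size_end=12,
        hist_constant_generations=6,
    )
    defaults.update(kw)
    return GenomeSpec(**defaults)


# --- size schedule and history ----------------------------------------------


def test_size_schedule_constant_then_linear_decline():
    s = default_size_schedule(2000, 2000, 1000, 1000)
    assert s.size == 2000
    assert np.all(s[:1000] == 2000)
    assert s[-1] == 1000
    assert np.all(np.diff(s[1000:]) <= 0)  # gradual, monotone decline


def test_history_final_cohort_size_follows_schedule():
    spec = tiny_spec()
    cohort, pool = simulate_historical_population(spec, substream(1, "h"))
    assert cohort.n == spec.hist_size_end
    assert pool.n_loci == spec.n_chromosomes * spec.n_initial_loci_per_chrom


def test_history_rejects_bad_schedule():
    spec = tiny_spec()
    with pytest.raises(ValueError):
        simulate_historical_population(
            spec, substream(1, "h"), n_generations=5, size_schedule=np.array([10, 10])
        )
    with pytest.raises(ValueError):
        simulate_historical_population(
            spec, substream(1, "h"), n_generations=2, size_schedule=np.array([10, 1])
        )


def test_fixed_locus_stays_fixed_without_mutation():
    """No variation plus no mutation: a fixed allele frequency never moves."""
    from ryesim.genome import _uniform_pool

    spec = tiny_spec(mutation_rate=0.0)
    rng = substream(4, "h")
    pool = _uniform_pool(spec, rng)
    haps = np.ones((20, 2, pool.n_loci), dtype=np.uint8)
    c = Cohort(haplotypes=haps)
    for _ in range(5):
        gam = make_gametes(c.haplotypes, rng.integers(0, c.n, 2 * c.n), pool, rng)
        c = Cohort(haplotypes=gam.reshape(c.n, 2, pool.n_loci))
    assert np.all(c.haplotypes == 1)


def test_drift_small_in_large_population():
    """With mutation off and a large constant size, per-generation frequency
    moves stay within 3 binomial standard errors for almost all loci."""
    spec = tiny_spec(mutation_rate=0.0, n_hist_generations=5, hist_size_start=500,
                     hist_size_end=500, hist_constant_generations=5)
    rng = substream(5, "h")
    from ryesim.genome import _uniform_pool

    pool = _uniform_pool(spec, rng)
    p0 = np.full(pool.n_loci, 0.5)
    haps = (rng.random((500, 2, pool.n_loci)) < p0).astype(np.uint8)
    c = Cohort(haplotypes=haps)
    f_prev = c.allele_freq()
    gam = make_gametes(c.haplotypes, rng.integers(0, c.n, 2 * c.n), pool, rng)
    c = Cohort(haplotypes=gam.reshape(500, 2, pool.n_loci))
    f_new = c.allele_freq()
    se = np.sqrt(f_prev * (1 - f_prev) / (2 * 500))
    frac_ok = np.mean(np.abs(f_new - f_prev) <= 3 * se)
    assert frac_ok > 0.98


# --- meiosis kernel vs a brute-force replay oracle ---------------------------


def _oracle_gamete(parent_haps, start, cx_sorted, pos):
    """Reference gamete: walk loci, switching chromatid at each crossover."""
    L = pos.size
    out = np.empty(L, dtype=np.uint8)
    cur = start
    k = 0
    for l in range(L):
        while k < len(cx_sorted) and cx_sorted[k] <= pos[l]:
            cur ^= 1
            k += 1
        out[l] = parent_haps[cur, l]
    return out


def test_kernel_matches_replay_oracle():
    """The vectorized kernel reproduces a brute-force per-locus walk for
    recorded crossover points, parents and starting chromatids."""
    rng = np.random.default_rng(11)
    n_loci = 25
    pos = np.sort(rng.random(n_loci) * 100.0)
    chrom_start = np.array([0, n_loci], dtype=np.int64)
    parents = rng.integers(0, 2, size=(4, 2, n_loci)).astype(np.uint8)
    for trial in range(50):
        G = 3
        parent_idx = rng.integers(0, 4, G).astype(np.int64)
        start = rng.integers(0, 2, size=(G, 1)).astype(np.uint8)
        counts = rng.poisson(1.5, G)
        cx_off = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        cx_pos = rng.random(cx_off[-1]) * 100.0
        out = np.empty((G, n_loci), dtype=np.uint8)
        drop_gametes(parents, parent_idx, start, cx_pos.copy(), cx_off, pos, chrom_start, out)
        for g in range(G):
            cx = np.sort(cx_pos[cx_off[g]: cx_off[g + 1]])
            exp = _oracle_gamete(parents[parent_idx[g]], start[g, 0], cx, pos)
            assert np.array_equal(out[g], exp), f"trial {trial} gamete {g}"


def test_homozygous_parent_transmits_identical_gamete(rng):
    pos = np.sort(rng.random(30) * 100.0)
    panel = LocusPanel(
        chrom=np.zeros(30, dtype=np.int16),
        pos=pos,
        chrom_start=np.array([0, 30], dtype=np.int64),
        chrom_length_cm=100.0,
    )
    hap = rng.integers(0, 2, 30).astype(np.uint8)
    parent = np.stack([hap, hap])[None]
    gam = make_gametes(parent, np.zeros(200, dtype=np.int64), panel, rng)
    assert np.all(gam == hap)


def test_crossover_rate_and_transmission_frequency(rng):
    """Observable switch rate near Poisson(1) mean; heterozygous loci
    transmit allele 1 at frequency 0.5 over many meioses."""
    n_loci = 100
    pos = np.sort(rng.random(n_loci) * 100.0)
    panel = LocusPanel(
        chrom=np.zeros(n_loci, dtype=np.int16),
        pos=pos,
        chrom_start=np.array([0, n_loci], dtype=np.int64),
        chrom_length_cm=100.0,
    )
    parent = np.stack([np.zeros(n_loci), np.ones(n_loci)]).astype(np.uint8)[None]
    n_meioses = 20_000
    gam = make_gametes(parent, np.zeros(n_meioses, dtype=np.int64), panel, rng)
    # switches along the fully informative chromosome undercount crossovers
    # only via double-crossovers within a ~1 cM gap (rare)
    switches = np.abs(np.diff(gam.astype(np.int8), axis=1)).sum(axis=1).mean()
    assert 0.92 < switches < 1.03
    assert abs(gam.mean() - 0.5) < 0.015


# --- locus panel -------------------------------------------------------------


def test_panel_counts_and_maf_recount():
    spec = tiny_spec()
    rng = substream(6, "h")
    cohort, pool = simulate_historical_population(spec, rng)
    panel = build_locus_panel(cohort, pool, spec, rng)
    per = spec.n_snp_per_chrom + spec.n_qtl_per_chrom
    assert panel.n_loci == spec.n_chromosomes * per
    assert panel.snp_indices.size == spec.n_chromosomes * spec.n_snp_per_chrom
    assert panel.qtl_indices.size == spec.n_chromosomes * spec.n_qtl_per_chrom
    assert not np.any(panel.is_qtl[panel.snp_indices])
    # frequency recount oracle on the restricted cohort
    sub = cohort.subset_loci(panel._pool_indices)
    freq = sub.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    assert np.all(maf > spec.maf_min)
    np.testing.assert_allclose(freq, panel.founder_freq)
    # positions sorted within chromosome
    for c in range(panel.n_chromosomes):
        lo, hi = panel.chrom_start[c], panel.chrom_start[c + 1]
        assert np.all(np.diff(panel.pos[lo:hi]) >= 0)


def test_panel_raises_when_too_few_segregating_loci():
    spec = tiny_spec(n_snp_per_chrom=35, n_qtl_per_chrom=5)  # 40 of 40 cannot pass MAF
    rng = substream(7, "h")
    cohort, pool = simulate_historical_population(spec, rng)
    with pytest.raises(ValueError, match="chromosome"):
        build_locus_panel(cohort, pool, spec, rng)


# --- initial varieties -------------------------------------------------------


def test_varieties_sizes_and_frequency_tracking(small_history):
    panel, base = small_history
    rng = substream(8, "v")
    # deterministic parent sample check: variety frequency ~ parent sample
    vs = create_initial_varieties(base, panel, rng, n_varieties=5, variety_size=60)
    assert len(vs) == 5
    for v in vs:
        assert v.n == 60
    pooled_f = base.allele_freq()
    for v in vs:
        f = v.allele_freq()
        se = np.sqrt(np.maximum(pooled_f * (1 - pooled_f), 1e-9) / (2 * 60))
        # one mating generation adds Mendelian noise; variety frequency should
        # track the base closely (two sampling layers => use 5 SE, 2x binomial)
        frac = np.mean(np.abs(f - pooled_f) <= 5 * np.sqrt(2) * se + 1e-12)
        assert frac > 0.95


def test_variety_size_must_allow_mating(small_history):
    panel, base = small_history
    with pytest.raises(ValueError):
        create_initial_varieties(base, panel, substream(9, "v"), n_varieties=1, variety_size=1)


# --- VCF export --------------------------------------------------------------


def test_vcf_round_trip(tmp_path, small_history):
    pysam = pytest.importorskip("pysam")
    panel, base = small_history
    sub = base.take(np.arange(5))
    path = str(tmp_path / "founders.vcf")
    write_vcf(sub, panel, path)
    vcf = pysam.VariantFile(path)
    recs = list(vcf)
    assert len(recs) == panel.n_loci
    dose = sub.dosage()
    for l, rec in enumerate(recs):
        for i, sample in enumerate(rec.samples.values()):
            assert sum(sample["GT"]) == dose[i, l]
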