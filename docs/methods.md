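# Methods

This note documents the simulation model, its tunable parameters, the
numerical choices, and the limits of what the synthetic data can show.

## Founder genome

The historical population is a neutral, monoecious Wright–Fisher model:
every offspring draws two parents uniformly with replacement (selfing
possible in this phase; self-incompatibility is enforced only from variety
formation onward). Population size is constant at 2000 for 1000
generations, then declines to 1000; "gradual" is implemented as linear
interpolation, which is the least-structured reading of a monotone decline.
The declining phase generates the linkage disequilibrium that genomic
prediction later exploits.

Each chromosome carries an oversampled pool of 2500 bi-allelic loci at
uniform random map positions with initial allele frequencies uniform(0,1).
Meiosis draws a Poisson(λ=1) crossover count per 100 cM chromosome with
breakpoints uniform on the map and no interference, and a fair-coin
starting chromatid. Recurrent mutation is a symmetric allele flip at
2.5 × 10⁻⁵ per locus per transmitted gamete, applied only during the
historical phase; it keeps enough loci segregating that the panel draw
(1000 SNPs + 100 QTL per chromosome among loci with MAF > 0.05 in the final
generation) always succeeds — an explicit error naming the deficient
chromosome signals a miscalibrated pool otherwise. The 2500-locus pool is
about 2.3× the panel requirement and is configurable.

The 20 initial varieties are random samples of 200 plants from the final
generation (without replacement within a variety, necessarily with
replacement across varieties, since 20 × 200 > 1000), followed by one
generation of random mating with distinct parent pairs. The historical
population, panel and base cohort are shared across replicates and
scenarios; varieties and everything downstream are re-drawn per replicate.

Under these defaults the simulated founder varieties show observed
heterozygosity ≈ 0.36 over panel SNPs and mean adjacent-SNP r² ≈ 0.18
(adjacent panel SNPs are ~0.1 cM apart; a drift expectation of
1/(1 + 4Nc) with the recent effective size ~1100 and Haldane's map function
predicts ~0.19, consistent). Both statistics are recomputed by
`scripts/acceptance.py` and the test suite rather than asserted as
constants.

## Trait architecture and phenotypes

All four traits share the same 700 QTL. Effect vectors are i.i.d.
MVN(0, Σ) rows with unit variances and correlation 0.7 between traits 3
and 4. Correlation, not covariance, is the binding constraint: effect
scales are arbitrary before calibration, and correlations are
scale-invariant, so the realized genetic correlation between the two traits
is ~0.7 in the founder cohort regardless of subsequent calibration.

Phenotypes exist at plot level: y = plot TBV + N(0, σ²ₑ) per trait, with
plot TBV the mean member TBV. Residual variances are calibrated in one
deterministic step, σ²ₑ = var(plot TBV)·(1−h²)/h², on a calibration set of
F2-style plots (default 250, built from the initial varieties exactly like
production F2 plots). This replaces trial-and-error tuning with its fixed
point; the realized plot h², re-estimated on an independent plot sample as
the squared correlation between plot TBV and phenotype, recovers the
targets (0.3, 0.6, 0.4, 0.2) to within sampling noise. Plot-level
phenotypic variance is emergent (var(plot TBV) + σ²ₑ), not fixed globally.
Single-plant heading-date phenotypes reuse the trait-2 plot σ²ₑ — the
individual-level error is not separately identified by the program, and
heading date only orders plants for grouping.

## Breeding operations

All matings respect gametophytic self-incompatibility: every offspring has
two distinct parents. F1 families pair one random plant from each of two
random distinct varieties (250 families of 40 ⇒ ~25 parents per variety on
average). F2 plots (40 plants) and greenhouse F2 single plants (40) are
separate intermatings of the same F1 family; the one-year greenhouse delay
is encoded in the availability calendar, not the generation order. Plot
size 40 matches the stated family size; real plots hold many more plants,
so plot-TBV Mendelian noise is somewhat larger here than in the field.

Both selection rounds use the index I = ⅓v₁ + ⅓v₃ + ⅓v₄ on traits 1, 3, 4,
with inputs z-standardized within the candidate cohort ("standardized
emphasis"); a raw-scale option exists. Ties break by stable candidate id,
and every stochastic component draws from its own named substream, so runs
are replayable decision-for-decision. Heading-date grouping is
sort-and-block: the 400 selected single plants are ordered by trait-2
phenotype and cut into 50 consecutive groups of 8, whose terciles
correspond to early/intermediate/late maturity classes. SYN1 and SYN2 are
40 plants per group (polycross, then within-group intermating); SYN3 is
produced but terminal.

## Genomic prediction

Family plots are genotyped as mean allele dosage of 20 sampled plants per
SNP (values in [0,2]); single plants contribute their observed 0/1/2
genotypes. Marker effects are estimated per trait (the model is
univariate) by Bayesian ridge regression: Gaussian i.i.d. marker prior with
a common variance, flat intercept prior, scaled-inverse-χ² priors with 5
degrees of freedom on both variances. The prior scales follow the standard
variance-partition rule: the prior mode of σ²ₑ is (1−R²₀)·var(y) and the
prior mode of the marker variance is R²₀·var(y)/Σⱼvar(Xⱼ), with R²₀ = 0.5;
both df and R²₀ are configurable. Columns of X are centered by training
means, reapplied at prediction; GEBVs omit the intercept (a constant shift
that cannot change a ranking).

The sampler is single-site Gibbs with residual updating (O(n) per marker),
compiled with numba and seeded explicitly, hence bit-reproducible per
chain seed. With variance components frozen, its posterior mean equals the
closed-form ridge solution (Xᵀ X + λI)⁻¹Xᵀ(y−μ) — the oracle test of the
implementation. Chain profiles: "paper" 50 000/10 000, "fast" 5 000/1 000.
At the reference sizes used here (hundreds to a few thousand records) the
fast profile changes cycle-1 F2 single-plant accuracy by less than the
replicate noise; it is the default for desk-scale runs.

## Program logistics

One cycle per year for 25 cycles in 36 years. Within-cycle event years
(offsets from start year c) form a single authoritative calendar: F2 plots
phenotyped by c+3; F2 family and single-plant selection in year c+4 using
reference records entered through c+3 (so a cycle's own F2 families are
the newest usable records: cycle 1 trains on cycle-1 families only);
F2 single plants parent-available from c+5; SYN2 phenotyped and genotyped
into the reference by c+9; SYN2 selection in year c+10 using records
through c+10 (the cycle-1 SYN2 selection in year 11 trains on F2 families
of cycles 1–8 plus SYN2 groups of cycles 1–2); SYN2 output
parent-available from c+11.

Recruitment after the independent cycles pools all eligible archived
material (Phen-Y12/GS-Y12: plants of selected SYN2 groups; Phen/GS: also
the cycle's F2 single plants; GS-SP: F2 and SYN2 single plants). The
phenotypic scenarios have no cross-cycle comparison device, so 500 parents
are drawn uniformly from the pool; GS scenarios rank the pool by GEBV
index (effects trained on records through the preceding year) and take the
top 500. Crosses then draw parent pairs from the chosen set with distinct
family/group labels, allowing reuse across crosses as in cycle 1 — parent
counts for recruited cycles are a design choice, mirroring the 500-parent
structure of cycle 1. The eligible material is: Phen, the 400
polycross-chosen single plants per cycle; GS, the full greenhouse stand of
the 50 selected families (2000 single plants); SYN2 sources, the members
of the 20 selected groups.

## Recorded metrics

* **Genetic gain**: ΔG = (mean F1 TBV of cycle i − cycle 1) / SD of cycle-1
  F1 TBVs, per trait; cycle 1 is 0 by definition.
* **Additive variance**: variance of the 250 F1 family-mean TBVs per cycle,
  standardized to cycle 1.
* **Accuracy**: for GS, corr(plot GEBV, plot TBV) over the 50 candidate
  SYN2 plots (stage `SYN2`) and corr(GEBV, TBV) over candidate single
  plants (stages `F2SP`, `SYN2SP`). For phenotypic scenarios, the SYN2
  selection accuracy (stage `SYN2`) correlates the plot phenotype with the
  TBVs of the individual plants in the candidate groups — the quantity that
  limits gain, because parents are single plants chosen via their group's
  plot record and plot performance predicts individual breeding values
  poorly (~0.15 here). The plot-level correlation (~0.36) is recorded
  separately as stage `SYN2_plot`.
* **LD**: composite r² (squared Pearson correlation of genotype dosages)
  within varieties, SNPs filtered to within-variety MAF > 0.05; binned at
  1 cM up to 20 cM, with empty bins reported missing. Haplotype phase is
  known in simulation but family pools are conceptually unphased, so the
  dosage-based measure is the default. The Sved-type drift expectation
  E[r²] = 1/(1 + 4·Ne·c) with Haldane's map function is provided for
  comparison, with the constant configurable.

## Problem sizes and validation scale

The full design (50 replicates × 5 scenarios × 36 years × 50k-iteration
chains) is a cluster-scale computation. The package's own validation uses:
the complete founder simulation (the statistics above are insensitive to
replicate count beyond a few variety draws); 10 single-cycle conventional
replicates for the phenotypic SYN2 accuracy; 2–3 single-cycle genomic
replicates with the fast chain for cycle-1 F2 single-plant GEBV accuracy
(≈0.26, matching the reported early-cycle range); and reduced-genome,
reduced-cohort program runs for the multi-cycle comparisons, where genomic
scenarios show the expected larger cumulative gain than their phenotypic
counterparts and the faster erosion of additive variance. Directions and
ratios at reduced scale are indicative, not estimates of the full-scale
magnitudes.

## Known limitations

* Strictly additive, pleiotropic trait model: no dominance, epistasis,
  genotype-by-environment interaction, or multi-location/replicated-trial
  structure; one phenotype per plot.
* Variety formation from a single admixed base population gives weak
  between-variety differentiation; within-family variation therefore
  dominates, as in the founder statistics above.
* The greenhouse stands and archives hold full haplotypes in memory; at
  paper scale a multi-decade GS run holds a few hundred MB of archived
  genotypes per scenario.
* No inbreeding management (optimum-contribution selection) and no
  economic layer; both are deliberate non-goals.
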