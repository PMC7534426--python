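"""Reported statistics: genetic gain, accuracy, variance, LD, heterozygosity.

Genetic gain is cumulative and expressed in cycle-1 genetic standard
deviations of the F1 stage; additive variance is the variance of F1
family-mean TBVs standardized to cycle 1; LD is composite r^2 (squared
Pearson correlation of genotype dosages) within varieties.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Cohort, LocusPanel

__all__ = [
    "genetic_gain",
    "selection_accuracy",
    "additive_variance",
    "ld_decay",
    "adjacent_snp_r2",
    "observed_heterozygosity",
    "expected_r2_sved",
    "haldane_c",
]


def genetic_gain(f1_mean_tbv_by_cycle: np.ndarray, f1_tbv_cycle1_sd: float) -> np.ndarray:
    """Cumulative gain dG_i = (mean TBV_i - mean TBV_1) / sd(TBV_1)."""
    m = np.asarray(f1_mean_tbv_by_cycle, dtype=float)
    if m.size < 1:
        raise ValueError("need at least one cycle")
    f1_tbv_cycle1_sd = np.asarray(f1_tbv_cycle1_sd, dtype=float)
    if np.any(f1_tbv_cycle1_sd <= 0):
        raise ValueError("cycle-1 TBV standard deviation must be positive")
    return (m - m[0]) / f1_tbv_cycle1_sd


def selection_accuracy(estimates: np.ndarray, tbvs: np.ndarray) -> float:
    """Sample Pearson correlation between selection criteria and TBVs.

    Returns NaN (flagged, not raised) when either side is degenerate.
    """
    e = np.asarray(estimates, dtype=float).ravel()
    t = np.asarray(tbvs, dtype=float).ravel()
    if e.size != t.size or e.size < 3:
        raise ValueError("need >= 3 paired values")
    if e.std() == 0 or t.std() == 0:
        return float("nan")
    return float(np.corrcoef(e, t)[0, 1])


def additive_variance(f1_family_mean_tbvs_by_cycle: list) -> np.ndarray:
    """Per-cycle variance of F1 family-mean TBVs, standardized to cycle 1."""
    out = []
    for fam_means in f1_family_mean_tbvs_by_cycle:
        fam_means = np.asarray(fam_means, dtype=float)
        if fam_means.size < 2:
            raise ValueError("need >= 2 families per cycle")
        out.append(fam_means.var(ddof=1))
    out = np.asarray(out)
    return out / out[0]


def observed_heterozygosity(cohort: Cohort, panel: LocusPanel | None = None) -> float:
    """Mean fraction of heterozygous genotypes over individuals and SNPs."""
    loci = None if panel is None else panel.snp_indices
    h = cohort.haplotypes if loci is None else cohort.haplotypes[:, :, loci]
    return float((h[:, 0, :] != h[:, 1, :]).mean())


def _pairwise_r2(dose: np.ndarray) -> np.ndarray:
    """Squared correlation matrix of dosage columns (composite LD)."""
    d = dose.astype(np.float64)
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    d /= sd
    r = (d.T @ d) / d.shape[0]
    return r * r


def adjacent_snp_r2(
    varieties: list, panel: LocusPanel, maf_min: float = 0.05
) -> float:
    """Mean r^2 over consecutive SNP pairs within varieties.

    SNPs are filtered to within-variety MAF > ``maf_min``; adjacency is
    taken among the surviving SNPs within each chromosome.  The mean is
    over all pairs of all varieties.
    """
    snp = panel.snp_indices
    vals = []
    for v in varieties:
        dose = v.dosage(snp)
        freq = dose.mean(axis=0) / 2.0
        keep = np.minimum(freq, 1 - freq) > maf_min
        for c in range(panel.n_chromosomes):
            on_c = (panel.chrom[snp] == c) & keep
            idx = np.flatnonzero(on_c)
            if idx.size < 2:
                continue
            d = dose[:, idx].astype(np.float64)
            d -= d.mean(axis=0)
            d /= d.std(axis=0)
            r = np.einsum("ij,ij->j", d[:, :-1], d[:, 1:]) / d.shape[0]
            vals.append(r * r)
    if not vals:
        raise ValueError("no polymorphic adjacent SNP pairs")
    return float(np.concatenate(vals).mean())


def ld_decay(
    varieties: list,
    panel: LocusPanel,
    maf_min: float = 0.05,
    max_cm: float = 20.0,
    bin_cm: float = 1.0,
) -> pd.DataFrame:
    """Mean r^2 by distance bin (0..max_cm in bin_cm steps), across varieties.

    Empty bins are reported as NaN with n_pairs = 0, never as zero.
    """
    snp = panel.snp_indices
    n_bins = int(np.ceil(max_cm / bin_cm))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for v in varieties:
        dose = v.dosage(snp)
        freq = dose.mean(axis=0) / 2.0
        keep = np.minimum(freq, 1 - freq) > maf_min
        for c in range(panel.n_chromosomes):
            on_c = (panel.chrom[snp] == c) & keep
            idx = np.flatnonzero(on_c)
            if idx.size < 2:
                continue
            pos = panel.pos[snp[idx]]
            r2 = _pairwise_r2(dose[:, idx])
            dist = np.abs(pos[:, None] - pos[None, :])
            iu = np.triu_indices(idx.size, k=1)
            d = dist[iu]
            r2v = r2[iu]
            sel = d < max_cm
            b = (d[sel] / bin_cm).astype(np.int64)
            sums += np.bincount(b, weights=r2v[sel], minlength=n_bins)
            counts += np.bincount(b, minlength=n_bins)
    mean_r2 = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    return pd.DataFrame(
        {
            "bin_mid_cm": (np.arange(n_bins) + 0.5) * bin_cm,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def haldane_c(distance_cm: float) -> float:
    """Map distance (cM) to recombination fraction via Haldane's function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(distance_cm) / 100.0))


def expected_r2_sved(Ne: float, c: float, constant: float = 4.0) -> float:
    """Sved-type drift expectation E[r^2] = 1 / (1 + constant * Ne * c)."""
    Ne = np.asarray(Ne, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(Ne <= 0) or np.any(c < 0) or np.any(c > 0.5):
        raise ValueError("need Ne > 0 and 0 <= c <= 0.5")
    return 1.0 / (1.0 + constant * Ne * c)
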