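"""Genomic prediction: plot dosages, Bayesian ridge regression, GEBVs.

Family plots are genotyped as "proxy individuals": the genotype of a plot
is the mean allele dosage of 20 plants sampled from it, a real number in
[0, 2] per SNP.  Marker effects are estimated per trait with Bayesian
ridge regression (Gaussian iid marker prior, common variance) fitted by
Gibbs sampling; scaled-inverse-chi2 priors with 5 degrees of freedom get
their scales from the sample variance of the phenotypes, so that the prior
mode of the residual variance is var(y)/2 and the prior mode of the total
marker-explained variance is var(y)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import brr_gibbs
from .genome import Cohort, LocusPanel
from .params import ChainSpec

__all__ = [
    "ReferencePopulation",
    "MarkerEffectEstimate",
    "plot_dosage",
    "fit_brr",
    "compute_gebv",
    "effects_frame",
]


def effects_frame(estimates: dict) -> "pd.DataFrame":
    """Posterior-mean SNP effects per trait as a table (snp_id, a_hat_*).

    ``estimates`` maps a trait label to a MarkerEffectEstimate.
    """
    if not estimates:
        raise ValueError("no estimates given")
    first = next(iter(estimates.values()))
    data = {"snp_id": np.arange(first.a_hat.size)}
    for label, est in estimates.items():
        if est.a_hat.size != first.a_hat.size:
            raise ValueError("estimates cover different SNP panels")
        data[f"a_hat_{label}"] = est.a_hat
    return pd.DataFrame(data)


def plot_dosage(
    plot_members: Cohort,
    panel: LocusPanel,
    rng: np.random.Generator,
    n_sample: int = 20,
) -> np.ndarray:
    """Mean allele dosage of ``n_sample`` plants over the panel SNPs.

    Dosage = 2 x frequency of the counted allele among the sampled plants
    (a counted-allele frequency of 0.7 gives 1.4).  Sampling is without
    replacement, so the plot must hold at least ``n_sample`` plants.
    """
    if plot_members.n < n_sample:
        raise ValueError(f"plot has {plot_members.n} plants, need >= {n_sample}")
    idx = rng.choice(plot_members.n, size=n_sample, replace=False)
    g = plot_members.dosage(panel.snp_indices)[idx]
    return g.mean(axis=0, dtype=np.float64)


@dataclass
class ReferencePopulation:
    """Growing training set of plot records (X: mean dosages, y: phenotypes)."""

    n_snp: int
    n_traits: int = 4
    _X: list = field(default_factory=list)
    _y: list = field(default_factory=list)
    provenance: list = field(default_factory=list)  # dicts: stage, cycle, entry_year, record_id

    @property
    def n_records(self) -> int:
        return len(self._X)

    def add(self, X_rows: np.ndarray, y_rows: np.ndarray, stage: str, cycle: int, entry_year: int):
        """Append newly phenotyped+genotyped plots (append-only archive)."""
        X_rows = np.atleast_2d(np.asarray(X_rows, dtype=np.float32))
        y_rows = np.atleast_2d(np.asarray(y_rows, dtype=np.float64))
        if X_rows.shape[1] != self.n_snp:
            raise ValueError("SNP count mismatch in reference records")
        if X_rows.shape[0] != y_rows.shape[0]:
            raise ValueError("X and y record counts differ")
        start = self.n_records
        new_ids = {f"{stage}-c{cycle}-r{start + i}" for i in range(X_rows.shape[0])}
        existing = {p["record_id"] for p in self.provenance}
        if new_ids & existing:
            raise ValueError("duplicate record ids in reference population")
        for i in range(X_rows.shape[0]):
            self._X.append(X_rows[i])
            self._y.append(y_rows[i])
            self.provenance.append(
                {
                    "stage": stage,
                    "cycle": cycle,
                    "entry_year": entry_year,
                    "record_id": f"{stage}-c{cycle}-r{start + i}",
                }
            )

    def snapshot(self, max_entry_year: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) of all records with entry_year <= cutoff."""
        if max_entry_year is None:
            keep = range(self.n_records)
        else:
            keep = [
                i for i, p in enumerate(self.provenance) if p["entry_year"] <= max_entry_year
            ]
        X = np.array([self._X[i] for i in keep], dtype=np.float64)
        y = np.array([self._y[i] for i in keep], dtype=np.float64)
        return X, y

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.provenance)


# update_reference of the module surface: the append-only ReferencePopulation.add
update_reference = ReferencePopulation.add


@dataclass
class MarkerEffectEstimate:
    """Posterior means of intercept and per-SNP effects for one trait."""

    mu: float
    a_hat: np.ndarray  # (n_snp,)
    x_center: np.ndarray  # training column means, reapplied at prediction
    sigma2_e: float
    sigma2_marker: float
    chain_meta: dict

    def __post_init__(self):
        if not np.all(np.isfinite(self.a_hat)):
            raise ValueError("non-finite marker effect estimates")


def fit_brr(
    X: np.ndarray,
    y: np.ndarray,
    chain: ChainSpec,
    seed: int,
    fix_variances: tuple | None = None,
) -> MarkerEffectEstimate:
    """Fit Bayesian ridge regression for one trait.

    ``fix_variances=(sigma2_e, sigma2_marker)`` freezes the variance
    components (degenerate priors), under which the posterior mean of the
    effects is the closed-form ridge solution — used by the oracle tests.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_records, n_snp) matching y")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training records")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotypes in training data")
    center = X.mean(axis=0)
    vy = float(np.var(y))
    if vy == 0.0:
        warnings.warn("zero-variance phenotype vector: returning zero effects")
        return MarkerEffectEstimate(
            mu=float(y[0]),
            a_hat=np.zeros(X.shape[1]),
            x_center=center,
            sigma2_e=0.0,
            sigma2_marker=0.0,
            chain_meta={"n_iter": 0, "burn_in": 0, "seed": seed},
        )
    Xc = X - center
    XT = np.ascontiguousarray(Xc.T)
    x2 = np.einsum("ji,ji->j", XT, XT)
    msx = float(np.sum(np.var(Xc, axis=0)))
    df = chain.df_prior
    r2 = chain.r2_prior
    # scale choice: prior mode (S/(df+2)) sits at the R2-split of var(y)
    S_e = vy * (1.0 - r2) * (df + 2.0)
    msx = max(msx, 1e-12)
    S_a = vy * r2 / msx * (df + 2.0)
    if fix_variances is None:
        s2e0, s2a0 = vy * (1.0 - r2), vy * r2 / msx
        fix = False
    else:
        s2e0, s2a0 = map(float, fix_variances)
        fix = True
    a_hat, mu, s2e, s2a = brr_gibbs(
        XT, y, x2, chain.n_iter, chain.burn_in, S_e, df, S_a, df,
        int(seed) & 0x7FFFFFFF, fix, s2e0, s2a0,
    )
    return MarkerEffectEstimate(
        mu=float(mu),
        a_hat=a_hat,
        x_center=center,
        sigma2_e=float(s2e),
        sigma2_marker=float(s2a),
        chain_meta={"n_iter": chain.n_iter, "burn_in": chain.burn_in, "seed": int(seed)},
    )


def compute_gebv(genotype_or_dosage: np.ndarray, est: MarkerEffectEstimate) -> np.ndarray:
    """GEBV = sum_j x_ij a_hat_j over SNPs.

    Accepts integer genotypes (single plants) or mean dosages (plots), one
    row per candidate.  Training-column centering is reapplied; the
    intercept is excluded, a constant shift that cannot affect ranking.
    """
    x = np.atleast_2d(np.asarray(genotype_or_dosage, dtype=np.float64))
    if x.shape[1] != est.a_hat.size:
        raise ValueError("SNP count mismatch between genotypes and effect estimates")
    return np.squeeze((x - est.x_center) @ est.a_hat)
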