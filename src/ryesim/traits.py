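"""Trait architecture: pleiotropic QTL effects, TBVs, phenotypes.

All four traits share the same 700 QTL; allele-substitution effects are
multivariate normal with zero mean, unit variance per trait and a genetic
correlation of 0.7 between traits 3 and 4 (all other pairs uncorrelated).
The true breeding value of individual i for a trait is sum_j G_ij alpha_j
over QTL genotypes G in {0,1,2}; a plot's TBV is the mean TBV of its
members.  Residual variances are calibrated so that the plot heritability
var(plot TBV) / (var(plot TBV) + sigma_e^2) matches the targets
(0.3, 0.6, 0.4, 0.2); phenotypes add iid normal deviates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import Cohort, LocusPanel
from .params import TraitSpec

__all__ = [
    "TraitArchitecture",
    "sample_qtl_effects",
    "compute_tbv",
    "plot_tbv_from_members",
    "calibrate_to_plot_h2",
    "plot_phenotype",
    "single_plant_phenotype",
    "simulate_f2_calibration_plots",
    "architecture_frame",
]


@dataclass
class TraitArchitecture:
    alpha: np.ndarray  # (n_qtl, n_traits) allele-substitution effects
    effect_corr: np.ndarray  # (n_traits, n_traits)
    target_plot_h2: np.ndarray  # (n_traits,)
    sigma_e2: np.ndarray | None = None  # residual variances, set by calibration
    sigma_a2: np.ndarray | None = None  # plot-TBV variances in the calibration set

    @property
    def n_traits(self) -> int:
        return self.alpha.shape[1]

    def require_calibrated(self):
        if self.sigma_e2 is None:
            raise ValueError("architecture not calibrated: sigma_e2 unset")
        if np.any(self.sigma_e2 < 0):
            raise ValueError("negative residual variance")


def sample_qtl_effects(
    panel: LocusPanel,
    trait_spec: TraitSpec,
    rng: np.random.Generator,
) -> TraitArchitecture:
    """Draw iid MVN(0, effect_corr) effect rows for every QTL."""
    corr = trait_spec.effect_corr()
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError("effect correlation matrix is not positive semi-definite")
    n_qtl = panel.qtl_indices.size
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    z = rng.standard_normal((n_qtl, corr.shape[0]))
    return TraitArchitecture(
        alpha=z @ chol.T,
        effect_corr=corr,
        target_plot_h2=np.asarray(trait_spec.plot_h2, dtype=float),
    )


def compute_tbv(cohort: Cohort, panel: LocusPanel, arch: TraitArchitecture) -> np.ndarray:
    """(n, n_traits) TBV matrix; SNP loci contribute zero by construction."""
    qtl = panel.qtl_indices
    if qtl.size != arch.alpha.shape[0]:
        raise ValueError("QTL count mismatch between panel and effect matrix")
    g = cohort.dosage(qtl).astype(np.float64)
    return g @ arch.alpha


def plot_tbv_from_members(member_tbv: np.ndarray) -> np.ndarray:
    """Plot TBV = arithmetic mean of member TBVs (per trait)."""
    return member_tbv.mean(axis=0)


def calibrate_to_plot_h2(plot_tbvs: np.ndarray, arch: TraitArchitecture) -> TraitArchitecture:
    """Set residual variances from a calibration set of plot TBVs.

    Solved in one deterministic step per trait,
    sigma_e2 = var(plot TBV) * (1 - h2) / h2, which makes the realized plot
    heritability equal the target exactly in expectation.  Effects are left
    untouched, so effect correlations are preserved.
    """
    plot_tbvs = np.asarray(plot_tbvs, dtype=float)
    if plot_tbvs.ndim != 2 or plot_tbvs.shape[0] < 2:
        raise ValueError("need >= 2 calibration plots")
    va = plot_tbvs.var(axis=0, ddof=1)
    if np.any(va <= 0):
        raise ValueError("degenerate calibration set: zero plot-TBV variance")
    h2 = arch.target_plot_h2
    sigma_e2 = va * (1.0 - h2) / h2
    return replace(arch, sigma_e2=sigma_e2, sigma_a2=va)


def plot_phenotype(
    plot_tbv: np.ndarray, arch: TraitArchitecture, rng: np.random.Generator
) -> np.ndarray:
    """y = plot TBV + N(0, sigma_e2), independent per plot and per trait."""
    arch.require_calibrated()
    plot_tbv = np.asarray(plot_tbv, dtype=float)
    one_d = plot_tbv.ndim == 1
    plot_tbv = np.atleast_2d(plot_tbv)
    noise = rng.standard_normal(plot_tbv.shape) * np.sqrt(arch.sigma_e2)
    out = plot_tbv + noise
    return out[0] if one_d else out


def single_plant_phenotype(
    tbv: np.ndarray,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    trait: int | None = None,
) -> np.ndarray:
    """Individual phenotype with the plot-calibrated residual variance.

    Used for the heading-date grouping (trait 2); ``trait`` selects a
    single column of the TBV matrix.
    """
    arch.require_calibrated()
    tbv = np.asarray(tbv, dtype=float)
    if trait is None:
        return tbv + rng.standard_normal(tbv.shape) * np.sqrt(arch.sigma_e2)
    return tbv + rng.standard_normal(tbv.shape) * np.sqrt(arch.sigma_e2[trait])


def architecture_frame(panel: LocusPanel, arch: TraitArchitecture):
    """QTL effect table (id, chromosome, cM position, effect per trait),
    ready for ``.to_csv``."""
    import pandas as pd

    qtl = panel.qtl_indices
    data = {
        "qtl_id": qtl,
        "chromosome": panel.chrom[qtl] + 1,
        "pos_cm": panel.pos[qtl],
    }
    for t in range(arch.n_traits):
        data[f"alpha_trait{t + 1}"] = arch.alpha[:, t]
    return pd.DataFrame(data)


def simulate_f2_calibration_plots(
    varieties: list,
    panel: LocusPanel,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    n_plots: int = 250,
    family_size: int = 40,
    plot_size: int = 40,
) -> np.ndarray:
    """F2-style plot TBVs from the initial varieties, (n_plots, n_traits).

    Mirrors the production of F2 family plots: a pair cross between plants
    of two random varieties, one intermating generation, plot TBV = mean
    member TBV.  Deferred import keeps breeding_ops the single home of the
    crossing logic.
    """
    from .breeding import make_f1_families, intermate_family

    fams = make_f1_families(
        varieties, panel, rng, n_families=n_plots, family_size=family_size
    )
    out = np.empty((n_plots, arch.n_traits))
    for i, fam in enumerate(fams):
        f2 = intermate_family(fam, plot_size, panel, rng)
        out[i] = compute_tbv(f2.members, panel, arch).mean(axis=0)
    return out
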