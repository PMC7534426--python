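"""Run configuration, replicate orchestration, and result serialization.

A run simulates the historical population once (it is shared by all
replicates and scenarios), then re-draws everything from the initial
varieties onward independently per replicate: variety sampling, QTL
effects, calibration, and the whole breeding program per scenario.
Per-replicate and aggregated (mean and SD across replicates) metric tables
are written as tidy CSV.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import (
    FounderSet,
    build_locus_panel,
    create_initial_varieties,
    simulate_historical_population,
)
from .params import FAST_CHAIN, PAPER_CHAIN, BreedingSpec, GenomeSpec, TraitSpec
from .rng import substream, substream_seed
from .scenario import SCENARIOS, ScenarioConfig, run_scenario
from .traits import calibrate_to_plot_h2, sample_qtl_effects, simulate_f2_calibration_plots

__all__ = ["RunConfig", "load_config", "save_config", "run_replicates", "prepare_founders"]

_PROFILES = {"paper": PAPER_CHAIN, "fast": FAST_CHAIN}


@dataclass
class RunConfig:
    scenarios: list = field(default_factory=lambda: list(SCENARIOS))
    replicates: int = 50
    base_seed: int = 1
    profile: str = "paper"
    years: int = 36
    out_dir: str = "results"
    overwrite: bool = False
    calibration_plots: int = 250
    genome: dict = field(default_factory=dict)  # GenomeSpec overrides
    breeding: dict = field(default_factory=dict)  # BreedingSpec overrides
    traits: dict = field(default_factory=dict)  # TraitSpec overrides

    def __post_init__(self):
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}; valid: {sorted(SCENARIOS)}")
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown chain profile {self.profile!r}")
        if self.replicates < 1 or self.years < 12:
            raise ValueError("need replicates >= 1 and years >= 12")
        # surface typos in override blocks immediately
        self.genome_spec()
        self.breeding_spec()
        self.trait_spec()

    def genome_spec(self) -> GenomeSpec:
        return _build(GenomeSpec, self.genome)

    def breeding_spec(self) -> BreedingSpec:
        return _build(BreedingSpec, self.breeding)

    def trait_spec(self) -> TraitSpec:
        return _build(TraitSpec, self.traits)

    @property
    def chain(self):
        return _PROFILES[self.profile]


def _build(cls, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kw = {
        k: tuple(v) if isinstance(v, list) else v  # YAML lists -> tuples
        for k, v in overrides.items()
    }
    return cls(**kw)


def load_config(path: str) -> RunConfig:
    """Read a YAML run configuration; omitted keys take the study defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def prepare_founders(cfg: RunConfig):
    """Simulate the shared historical population and draw the locus panel."""
    spec = cfg.genome_spec()
    rng_hist = substream(cfg.base_seed, "history")
    cohort, pool = simulate_historical_population(spec, rng_hist)
    panel = build_locus_panel(cohort, pool, spec, rng_hist)
    base = cohort.subset_loci(panel._pool_indices)
    return panel, base


def _replicate_founders(cfg: RunConfig, panel, base, rep: int) -> FounderSet:
    b = cfg.breeding_spec()
    varieties = create_initial_varieties(
        base,
        panel,
        substream(cfg.base_seed, "varieties", rep),
        n_varieties=b.n_varieties,
        variety_size=b.variety_size,
    )
    return FounderSet(panel=panel, base=base, varieties=varieties)


def _replicate_architecture(cfg: RunConfig, founders: FounderSet, rep: int):
    b = cfg.breeding_spec()
    arch = sample_qtl_effects(
        founders.panel, cfg.trait_spec(), substream(cfg.base_seed, "effects", rep)
    )
    plot_tbvs = simulate_f2_calibration_plots(
        founders.varieties,
        founders.panel,
        arch,
        substream(cfg.base_seed, "calibration", rep),
        n_plots=cfg.calibration_plots,
        family_size=b.f1_family_size,
        plot_size=b.f2_plot_size,
    )
    return calibrate_to_plot_h2(plot_tbvs, arch)


def run_replicates(cfg: RunConfig, founders_cache=None) -> str:
    """Run all configured scenarios x replicates; return the output directory."""
    out = cfg.out_dir
    if os.path.exists(out) and os.listdir(out) and not cfg.overwrite:
        raise FileExistsError(f"output directory {out!r} not empty (set overwrite)")
    os.makedirs(out, exist_ok=True)
    panel, base = founders_cache if founders_cache is not None else prepare_founders(cfg)
    per_metric: dict[str, list] = {"gain": [], "accuracy": [], "variance": []}
    for rep in range(cfg.replicates):
        founders = _replicate_founders(cfg, panel, base, rep)
        arch = _replicate_architecture(cfg, founders, rep)
        for name in cfg.scenarios:
            scfg = ScenarioConfig(
                name=name, years=cfg.years, breeding=cfg.breeding_spec(), chain=cfg.chain
            )
            res = run_scenario(
                scfg, founders, arch, substream_seed(cfg.base_seed, "scenario", name, rep)
            )
            rep_dir = os.path.join(out, name, f"rep{rep:03d}")
            os.makedirs(rep_dir, exist_ok=True)
            for metric in ("gain", "accuracy", "variance", "reference_size", "audit"):
                getattr(res, metric).to_csv(os.path.join(rep_dir, f"{metric}.csv"), index=False)
            for metric in per_metric:
                df = getattr(res, metric).copy()
                df["scenario"] = name
                df["replicate"] = rep
                per_metric[metric].append(df)
    for metric, frames in per_metric.items():
        allf = pd.concat(frames, ignore_index=True)
        keys = [k for k in ("scenario", "cycle", "stage", "trait") if k in allf.columns]
        vals = [c for c in allf.columns if c not in keys + ["scenario", "replicate"]]
        agg = allf.groupby(keys)[vals].agg(["mean", "std"])
        agg.columns = ["_".join(col) for col in agg.columns]
        agg.reset_index().to_csv(os.path.join(out, f"aggregate_{metric}.csv"), index=False)
    return out
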