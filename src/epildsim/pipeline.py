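"""Scenario-grid orchestration: LD settings x effect sizes x pruning x replicates.

A scenario places the two causal loci (DSL 1 fixed; DSL 2 inside the same
block, in the middle of another block, at the edge of another block, or on
the other chromosome — settings A-D), expands the founder panel with
trajectory control, then for each interaction effect size draws replicate
case-control cohorts, optionally prunes them at each r2 threshold, screens
all SNP pairs with the H/L/O contrast test under maxT correction, and
aggregates exact sensitivity, signal sensitivity (per tag-set threshold) and
family-wise error into long-format tables.

Every replicate's seed derives deterministically from the master seed, so a
grid re-run reproduces its tables bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import founder_synth, ld_tools, mbmdr, metrics, popsim, sampler
from .disease_model import EpistasisModel, PopulationFreqs, build_table

__all__ = ["ScenarioConfig", "SETTING_ROLES", "build_scenario", "run_grid", "null_grid"]

#: DSL2 placement role per LD-block setting (DSL1 is always mid-block on the
#: second segment, the chr8-like one).
SETTING_ROLES = {
    "A": "same_block_as_partner",
    "B": "block_middle",
    "C": "block_edge",
    "D": "other_chromosome",
}

DSL1_SEGMENT = 1  # chr8-like segment


@dataclass
class ScenarioConfig:
    """Full grid configuration with reference-study defaults.

    The defaults mirror the reference conditions: 91 founders over 964 + 787
    sites expanded to 10,000 individuals in 500 generations; founder DSL MAFs
    0.09 (DSL 1) and 0.42/0.33/0.35/0.19 (DSL 2, settings A-D) steered to
    0.05 and 0.40; effect sizes beta3 in {0.50, 0.75, 0.90}; pruning at
    r2 <= {0.75, 0.60, 0.50, 0.20} plus unpruned; 100 replicates of 1000
    cases + 1000 controls; 999 permutations.  ``scaled()`` provides the
    desk-scale variant used by the analysis drivers and tests.
    """

    n_founders: int = 91
    segment_sites: tuple[int, int] = (964, 787)
    n_final: int = 10_000
    n_generations: int = 500
    settings: tuple[str, ...] = ("A", "B", "C", "D")
    dsl1_founder_maf: float = 0.09
    dsl2_founder_maf: dict = field(
        default_factory=lambda: {"A": 0.42, "B": 0.33, "C": 0.35, "D": 0.19}
    )
    dsl1_target_freq: float = 0.05
    dsl2_target_freq: float = 0.40
    beta3_values: tuple[float, ...] = (0.50, 0.75, 0.90)
    beta0: float = -5.0
    prune_thresholds: tuple[float | None, ...] = (None, 0.75, 0.60, 0.50, 0.20)
    tag_thresholds: tuple[float, ...] = (0.20, 0.45)
    replicates: int = 100
    permutations: int = 999
    n_cases: int = 1000
    n_controls: int = 1000
    alpha: float = 0.05
    alpha_cell: float = 0.1
    min_cell: int = 10
    sampling_mode: str = "standing"
    master_seed: int = 0

    @property
    def n_datasets(self) -> int:
        """Datasets scheduled by the grid: settings x effect sizes x replicates."""
        return len(self.settings) * len(self.beta3_values) * self.replicates

    @classmethod
    def scaled(cls, master_seed: int = 0) -> "ScenarioConfig":
        """Desk-scale study conditions (see docs/methods.md for the rationale)."""
        return cls(
            segment_sites=(100, 100),
            n_final=2000,
            n_generations=100,
            beta3_values=(1.2,),
            replicates=20,
            permutations=199,
            n_cases=500,
            n_controls=500,
            master_seed=master_seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("segment_sites", "beta3_values", "tag_thresholds", "settings"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "prune_thresholds" in raw:
            raw["prune_thresholds"] = tuple(
                None if v in (None, "none") else float(v) for v in raw["prune_thresholds"]
            )
        return cls(**raw)

    def seeds(self, *tags: int, n: int = 1) -> list[int]:
        """Deterministic child seeds (< 2^31) for a grid coordinate."""
        ss = np.random.SeedSequence([self.master_seed, *tags])
        return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class Scenario:
    """A built scenario: panel after QC, DSL sites, expanded population, tag sets."""

    name: str
    panel: founder_synth.FounderPanel
    dsl1: int
    dsl2: int
    population: popsim.Population
    tag_sets: dict  # (dsl, threshold) -> TagSet
    pop_dosages: np.ndarray


def build_scenario(config: ScenarioConfig, setting: str) -> Scenario:
    """Generate panel, QC, place DSLs, expand with trajectory control, tag."""
    if setting not in SETTING_ROLES:
        raise ValueError(f"unknown setting {setting!r}")
    tag = ord(setting)
    s_panel, s_place, s_evo = config.seeds(tag, n=3)
    specs = founder_synth.default_blockspecs(s_panel, segment_sites=config.segment_sites)
    panel = founder_synth.generate_panel(specs, config.n_founders, s_panel)
    keep = founder_synth.qc_filter(panel.founder_genotypes(), panel.sites)
    panel = panel.subset(keep)
    dsl1 = founder_synth.place_dsl(
        panel, "block_middle", config.dsl1_founder_maf, s_place, segment=DSL1_SEGMENT
    ).site_index
    role = SETTING_ROLES[setting]
    dsl2 = founder_synth.place_dsl(
        panel,
        role,
        config.dsl2_founder_maf[setting],
        s_place + 1,
        partner=dsl1,
        segment=None if role != "block_middle" and role != "block_edge" else DSL1_SEGMENT,
    ).site_index
    freqs = panel.minor_freqs()
    trajectories = [
        popsim.TrajectorySpec(dsl1, float(freqs[dsl1]), config.dsl1_target_freq),
        popsim.TrajectorySpec(dsl2, float(freqs[dsl2]), config.dsl2_target_freq),
    ]
    demo = popsim.DemographicModel(
        n_founders=config.n_founders,
        n_final=config.n_final,
        n_generations=config.n_generations,
    )
    pop = popsim.evolve(panel, demo, trajectories, s_evo)
    pop_dosages = popsim.materialize(pop, panel)
    tag_sets = {
        (dsl, thr): ld_tools.tag_set(pop_dosages, dsl, thr)
        for dsl in (dsl1, dsl2)
        for thr in config.tag_thresholds
    }
    return Scenario(
        name=setting,
        panel=panel,
        dsl1=dsl1,
        dsl2=dsl2,
        population=pop,
        tag_sets=tag_sets,
        pop_dosages=pop_dosages,
    )


def _scan_replicate(
    dataset: sampler.CaseControlDataset,
    config: ScenarioConfig,
    threshold: float | None,
    seed: int,
) -> mbmdr.ScanResult:
    dosages = dataset.dosages
    site_indices = np.arange(dosages.shape[1])
    if threshold is not None:
        keep = ld_tools.prune(
            dosages, dataset.sites, ld_tools.PruneConfig(threshold=threshold)
        )
        dosages = dosages[:, keep]
        site_indices = keep
    return mbmdr.scan_with_maxt(
        dosages,
        dataset.status,
        B=config.permutations,
        seed=seed,
        alpha_cell=config.alpha_cell,
        min_cell=config.min_cell,
        alpha=config.alpha,
        site_indices=site_indices,
    )


def run_grid(config: ScenarioConfig, verbose: bool = False) -> pd.DataFrame:
    """Run the full sensitivity grid; returns a long-format results table.

    One row per (setting, beta3, pruning threshold) with exact sensitivity
    and per-tag-threshold signal sensitivity across replicates.
    """
    rows = []
    for setting in config.settings:
        scen = build_scenario(config, setting)
        for beta3 in config.beta3_values:
            model = EpistasisModel(beta0=config.beta0, beta3=beta3)
            table = build_table(
                model,
                PopulationFreqs(config.dsl1_target_freq, 1.0 - config.dsl2_target_freq),
            )
            results: dict = {thr: [] for thr in config.prune_thresholds}
            for rep in range(config.replicates):
                s_rep = config.seeds(ord(setting), int(beta3 * 1000), rep, n=2)
                dataset = sampler.rejection_sample(
                    scen.population,
                    scen.panel,
                    table,
                    (scen.dsl1, scen.dsl2),
                    n_cases=config.n_cases,
                    n_controls=config.n_controls,
                    seed=s_rep[0],
                    mode=config.sampling_mode,
                )
                for thr in config.prune_thresholds:
                    results[thr].append(_scan_replicate(dataset, config, thr, s_rep[1]))
                if verbose:
                    print(f"[{setting} b3={beta3}] replicate {rep + 1}/{config.replicates}")
            for thr in config.prune_thresholds:
                ex, ex_se = metrics.exact_sensitivity(
                    results[thr], (scen.dsl1, scen.dsl2), config.alpha
                )
                row = {
                    "setting": setting,
                    "beta3": beta3,
                    "prune_threshold": np.nan if thr is None else thr,
                    "exact_sensitivity": ex,
                    "exact_se": ex_se,
                    "n_replicates": config.replicates,
                }
                for tt in config.tag_thresholds:
                    sig, sig_se = metrics.signal_sensitivity(
                        results[thr],
                        scen.tag_sets[(scen.dsl1, tt)],
                        scen.tag_sets[(scen.dsl2, tt)],
                        config.alpha,
                    )
                    row[f"signal_sensitivity_r2_{tt:g}"] = sig
                    row[f"signal_se_r2_{tt:g}"] = sig_se
                rows.append(row)
    return pd.DataFrame(rows)


def null_grid(
    config: ScenarioConfig,
    dataset: sampler.CaseControlDataset | None = None,
    setting: str = "A",
    verbose: bool = False,
) -> pd.DataFrame:
    """Family-wise type-I error under complete status randomisation.

    One genotype matrix is kept fixed across replicates (so all between-SNP
    correlations are preserved); affection status is re-randomised per
    replicate, the scan re-run per pruning threshold, and the fraction of
    replicates with any significant pair reported with a binomial CI.
    """
    if dataset is None:
        scen = build_scenario(config, setting)
        model = EpistasisModel(beta0=config.beta0, beta3=config.beta3_values[0])
        table = build_table(
            model, PopulationFreqs(config.dsl1_target_freq, 1.0 - config.dsl2_target_freq)
        )
        dataset = sampler.rejection_sample(
            scen.population,
            scen.panel,
            table,
            (scen.dsl1, scen.dsl2),
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            seed=config.seeds(ord(setting), 9999)[0],
            mode=config.sampling_mode,
        )
    rows = []
    base_status = dataset.status
    for thr in config.prune_thresholds:
        results = []
        for rep in range(config.replicates):
            s_perm, s_scan = config.seeds(17, 0 if thr is None else int(thr * 100), rep, n=2)
            rng = np.random.default_rng(s_perm)
            null_ds = sampler.CaseControlDataset(
                dosages=dataset.dosages,
                status=rng.permutation(base_status),
                sites=dataset.sites,
                causal_sites=dataset.causal_sites,
            )
            results.append(_scan_replicate(null_ds, config, thr, s_scan))
            if verbose:
                print(f"[null thr={thr}] replicate {rep + 1}/{config.replicates}")
        fwer, se = metrics.type1_fwer(results, config.alpha)
        k = int(round(fwer * config.replicates))
        lo, hi = metrics.binomial_ci(k, config.replicates)
        rows.append(
            {
                "prune_threshold": np.nan if thr is None else thr,
                "fwer": fwer,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "n_replicates": config.replicates,
            }
        )
    return pd.DataFrame(rows)
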