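"""Rejection sampling of balanced case-control cohorts from the expanded population.

Individuals are drawn uniformly (with replacement) from the final generation;
affection status is a Bernoulli draw with probability given by the penetrance
table cell of the individual's two-locus genotype at the causal sites; draws
are accepted into the case or control arm until both quotas are filled.  With
a ~1% prevalence, filling 1000 cases from a standing population of 10,000
requires replacement; a fresh-offspring mode that mates new individuals from
the final generation for every draw is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .disease_model import PenetranceTable
from .founder_synth import FounderPanel, SiteMeta
from .popsim import Population, materialize

__all__ = ["CaseControlDataset", "assign_status", "rejection_sample"]


@dataclass
class CaseControlDataset:
    """Unphased dosages plus binary affection status for n cases + n controls."""

    dosages: np.ndarray  # n_samples x n_sites, minor-allele dosage {0,1,2}
    status: np.ndarray  # 1 = case, 0 = control
    sites: list[SiteMeta]
    causal_sites: tuple[int, int]
    provenance: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())


def _risk_dosage(dosage: np.ndarray, risk_is_minor: bool) -> np.ndarray:
    """Risk-allele count from minor-allele dosage.

    In the reference scenario the DSL2 risk allele (A) is the *major* allele,
    so risk dosage = 2 - minor dosage.
    """
    return dosage if risk_is_minor else 2 - dosage


def assign_status(
    dsl1_dosage,
    dsl2_dosage,
    table: PenetranceTable,
    rng: np.random.Generator,
    dsl2_risk_is_minor: bool = False,
) -> np.ndarray:
    """Bernoulli(pi(G)) status draw for genotype dosages (vectorised)."""
    d1 = np.asarray(dsl1_dosage)
    d2 = _risk_dosage(np.asarray(dsl2_dosage), dsl2_risk_is_minor)
    pi = table.penetrance[d1, d2]
    return (rng.random(np.shape(pi)) < pi).astype(np.int8)


def rejection_sample(
    pop: Population,
    panel: FounderPanel,
    table: PenetranceTable,
    causal_sites: tuple[int, int],
    n_cases: int = 1000,
    n_controls: int = 1000,
    seed: int = 0,
    dsl2_risk_is_minor: bool = False,
    mode: str = "standing",
    max_draws: int = 10_000_000,
    batch: int = 20_000,
) -> CaseControlDataset:
    """Draw a balanced case-control cohort by rejection sampling.

    ``mode`` is ``"standing"`` (draw existing members of the final generation,
    with replacement) or ``"offspring"`` (mate fresh offspring from the final
    generation for every draw).  Raises if either quota cannot be filled
    within ``max_draws`` (a degenerate disease model).
    """
    if mode not in ("standing", "offspring"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    rng = np.random.default_rng(seed)
    c1, c2 = causal_sites
    causal = np.array([c1, c2])
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    need_cases, need_ctrls = n_cases, n_controls
    drawn = 0
    seg_pairs = None
    while (need_cases > 0 or need_ctrls > 0) and drawn < max_draws:
        k = min(batch, max_draws - drawn)
        drawn += k
        if mode == "standing":
            idx = rng.integers(pop.size, size=k)
            labels = [lab[idx] for lab in pop.labels]
        else:
            p1 = rng.integers(pop.size, size=k)
            p2 = (p1 + 1 + rng.integers(pop.size - 1, size=k)) % pop.size
            labels = []
            for lab in pop.labels:
                ca = lab[p1, rng.integers(2, size=k)]
                cb = lab[p2, rng.integers(2, size=k)]
                labels.append(np.column_stack([ca, cb]))
        if seg_pairs is None:
            seg_pairs = [panel.segment_of(int(s)) for s in causal]
        d = np.empty((k, 2), dtype=np.int8)
        for col, (site, seg) in enumerate(zip(causal, seg_pairs)):
            hap = panel.haplotypes[:, site]
            d[:, col] = hap[labels[seg][:, 0]] + hap[labels[seg][:, 1]]
        status = assign_status(d[:, 0], d[:, 1], table, rng, dsl2_risk_is_minor)
        sub = Population(labels=labels, generation=pop.generation)
        cases = np.flatnonzero(status == 1)[:need_cases]
        ctrls = np.flatnonzero(status == 0)[:need_ctrls]
        if cases.size:
            case_rows.append(materialize(sub, panel, individuals=cases))
            need_cases -= cases.size
        if ctrls.size:
            ctrl_rows.append(materialize(sub, panel, individuals=ctrls))
            need_ctrls -= ctrls.size
    if need_cases > 0 or need_ctrls > 0:
        raise RuntimeError(
            f"quota unreachable within max_draws={max_draws} "
            f"(missing {need_cases} cases, {need_ctrls} controls): degenerate model?"
        )
    dosages = np.vstack(case_rows + ctrl_rows)
    status = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return CaseControlDataset(
        dosages=dosages,
        status=status,
        sites=list(panel.sites),
        causal_sites=(int(c1), int(c2)),
        provenance={"seed": seed, "mode": mode, "draws": drawn},
    )
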