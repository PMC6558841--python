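"""Two-locus pure-epistasis disease model for case-control simulation.

The disease trait is Bernoulli with a logistic penetrance over two disease
susceptibility loci (DSLs),

    logit(pi) = beta0 + beta1*g1 + beta2*g2 + beta3*g1*g2,

where ``g1`` codes the DSL2 genotype as 1, 2 or 3 for 0, 1 or 2 copies of the
DSL2 risk allele, and ``g2`` is the DSL1 carrier indicator (0 if homozygous for
the DSL1 major allele, 1 otherwise).  With ``beta1 = beta2 = 0`` the model is
*pure* epistasis: neither locus has a marginal main effect on the logit scale,
and each extra DSL2 risk allele multiplies the odds of disease by exp(beta3),
but only in DSL1 carriers.  This mirrors the epistatic-recessive masking
pattern reported for HLA-B*27 and ERAP1 in Ankylosing Spondylitis, with a
population prevalence around 1% when beta0 = -5.

The 3x3 penetrance table, its Hardy-Weinberg cell frequencies, prevalence,
marginal penetrances, odds ratios and heritability are all derived from the
model in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "EpistasisModel",
    "PopulationFreqs",
    "PenetranceTable",
    "penetrance",
    "build_table",
    "prevalence",
    "marginals",
    "odds_ratios",
    "heritability",
    "heritability_genotypic",
]


@dataclass(frozen=True)
class EpistasisModel:
    """Logistic two-locus interaction model parameters.

    Defaults encode the pure-epistasis configuration: intercept fixed at -5
    (prevalence ~1%), no main effects, interaction strength ``beta3``.
    """

    beta0: float = -5.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.90

    @staticmethod
    def g1(dsl2_risk_count):
        """DSL2 genotype code: risk-allele dosage 0/1/2 -> 1/2/3."""
        return np.asarray(dsl2_risk_count) + 1

    @staticmethod
    def g2(dsl1_minor_count):
        """DSL1 carrier indicator: 0 for major homozygote, else 1."""
        return (np.asarray(dsl1_minor_count) >= 1).astype(int)


@dataclass(frozen=True)
class PopulationFreqs:
    """Risk-allele frequencies at the two DSLs.

    ``p1`` is the DSL1 minor (risk-enabling) allele frequency; ``p2`` is the
    DSL2 *risk* allele frequency.  In the reference scenario p1 = 0.05 and
    p2 = 0.60 (risk allele A is the major allele; the minor allele C has
    frequency 0.40).
    """

    p1: float
    p2: float

    def __post_init__(self):
        for p in (self.p1, self.p2):
            if not 0.0 < p < 1.0:
                raise ValueError(f"allele frequency {p} outside (0, 1)")

    @staticmethod
    def hwe_genotype_freqs(p: float) -> np.ndarray:
        """HWE genotype frequencies ((1-p)^2, 2p(1-p), p^2) for dosage 0/1/2."""
        q = 1.0 - p
        return np.array([q * q, 2.0 * p * q, p * p])


def penetrance(model: EpistasisModel, dsl1_minor_count, dsl2_risk_count):
    """Disease probability pi for a two-locus genotype (vectorised).

    Parameters are allele dosages: DSL1 minor-allele count in {0,1,2} and
    DSL2 risk-allele count in {0,1,2}.
    """
    g1 = model.g1(dsl2_risk_count)
    g2 = model.g2(dsl1_minor_count)
    eta = model.beta0 + model.beta1 * g1 + model.beta2 * g2 + model.beta3 * g1 * g2
    return expit(eta)


@dataclass(frozen=True)
class PenetranceTable:
    """3x3 penetrance table with HWE cell frequencies.

    ``penetrance[i, j]`` is P(disease | DSL1 minor dosage i, DSL2 risk dosage j)
    and ``cell_freqs[i, j]`` the HWE probability of that genotype combination.
    Although the table is stored 3x3, the nine cells are the nine expanded
    two-locus genotype combinations: the DSL1 heterozygote and minor-homozygote
    rows share penetrance values (both are carriers) but keep distinct
    frequencies.
    """

    penetrance: np.ndarray
    cell_freqs: np.ndarray
    model: EpistasisModel = field(repr=False)
    freqs: PopulationFreqs = field(repr=False)

    def __post_init__(self):
        assert self.penetrance.shape == (3, 3)
        assert self.cell_freqs.shape == (3, 3)


def build_table(model: EpistasisModel, freqs: PopulationFreqs) -> PenetranceTable:
    """Populate the nine-cell penetrance table under HWE."""
    i = np.arange(3)[:, None]  # DSL1 minor dosage
    j = np.arange(3)[None, :]  # DSL2 risk dosage
    pi = penetrance(model, i, j)
    f1 = PopulationFreqs.hwe_genotype_freqs(freqs.p1)
    f2 = PopulationFreqs.hwe_genotype_freqs(freqs.p2)
    cells = f1[:, None] * f2[None, :]
    return PenetranceTable(penetrance=pi, cell_freqs=cells, model=model, freqs=freqs)


def prevalence(table: PenetranceTable) -> float:
    """Population prevalence K = sum_i pi(G_i) p(G_i)."""
    return float(np.sum(table.penetrance * table.cell_freqs))


def marginals(table: PenetranceTable) -> tuple[np.ndarray, np.ndarray]:
    """Marginal penetrances per single-locus genotype.

    Returns ``(m_dsl1, m_dsl2)``: ``m_dsl1[i]`` is the penetrance of DSL1
    genotype i averaged over DSL2 genotypes (weighted by their HWE
    frequencies), and symmetrically for ``m_dsl2``.
    """
    f1 = PopulationFreqs.hwe_genotype_freqs(table.freqs.p1)
    f2 = PopulationFreqs.hwe_genotype_freqs(table.freqs.p2)
    m_dsl1 = table.penetrance @ f2
    m_dsl2 = f1 @ table.penetrance
    return m_dsl1, m_dsl2


def odds_ratios(model: EpistasisModel) -> tuple[np.ndarray, float]:
    """Per-genotype odds ratios vs the double-baseline cell, and exp(beta3).

    The baseline is the (DSL1 major homozygote, DSL2 zero risk alleles) cell;
    OR(cell) = exp(logit(pi_cell) - logit(pi_baseline)).
    """
    i = np.arange(3)[:, None]
    j = np.arange(3)[None, :]
    g1 = model.g1(j)
    g2 = model.g2(i)
    eta = model.beta0 + model.beta1 * g1 + model.beta2 * g2 + model.beta3 * g1 * g2
    return np.exp(eta - eta[0, 0]), float(np.exp(model.beta3))


def heritability(table: PenetranceTable) -> float:
    """Heritability of the binary trait, literal nine-cell form.

    Computed as

        h2 = sum_i [ pi(G_i) p(G_i) - K ]^2 / ( K (1 - K) )

    over the nine expanded two-locus genotype combinations, with the cell
    frequency *inside* the squared deviation.  This is the form the reference
    heritabilities (0.083 / 0.071 / 0.059 for beta3 = 0.90 / 0.75 / 0.50) are
    derived from; it is not the textbook genotypic-variance decomposition,
    which is available as :func:`heritability_genotypic`.
    """
    k = prevalence(table)
    if not 0.0 < k < 1.0:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    dev = table.penetrance * table.cell_freqs - k
    return float(np.sum(dev**2) / (k * (1.0 - k)))


def heritability_genotypic(table: PenetranceTable) -> float:
    """Broad-sense heritability on the observed (0/1) scale.

    Standard genotypic-variance form
    h2 = sum_i p(G_i) (pi(G_i) - K)^2 / (K (1 - K)).
    """
    k = prevalence(table)
    if not 0.0 < k < 1.0:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    var_g = np.sum(table.cell_freqs * (table.penetrance - k) ** 2)
    return float(var_g / (k * (1.0 - k)))
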