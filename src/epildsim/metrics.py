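"""Replicate-level performance criteria: exact sensitivity, signal sensitivity, FWER.

Exact sensitivity is the fraction of replicate datasets in which the exact
causal SNP pair reaches multiple-testing-corrected significance; signal
sensitivity widens "detection" to any significant pair whose members tag the
two causal sites (one member per tag set, under a one-to-one assignment);
the family-wise type-I error rate is the fraction of null replicates with any
significant pair at all.  All three are means of Bernoulli indicators and are
reported with binomial standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .ld_tools import TagSet
from .mbmdr import ScanResult

__all__ = [
    "SensitivityReport",
    "exact_sensitivity",
    "signal_sensitivity",
    "type1_fwer",
    "binomial_ci",
]


@dataclass(frozen=True)
class SensitivityReport:
    """Per-scenario sensitivity/FWER estimates (one row of the results table)."""

    scenario: str
    beta3: float
    prune_threshold: float | None
    exact_sensitivity: float
    exact_se: float
    signal_sensitivity: dict  # tag r2 threshold -> estimate
    signal_se: dict
    n_replicates: int


def _summarise(hits: list[bool]) -> tuple[float, float]:
    if not hits:
        raise ValueError("zero replicates")
    n = len(hits)
    p = float(np.mean(hits))
    return p, float(np.sqrt(p * (1.0 - p) / n))


def _significant_pairs(result: ScanResult, alpha: float) -> np.ndarray:
    if result.p_adjusted is None:
        raise ValueError("scan result carries no adjusted p-values")
    sig = result.p_adjusted <= alpha
    return result.global_pairs()[sig]


def exact_sensitivity(
    replicate_results: list[ScanResult],
    causal_pair: tuple[int, int],
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Fraction of replicates where the exact causal pair is significant.

    Pair indices are compared in original-panel coordinates, so a replicate
    whose scan ran on pruned data that lost a causal SNP counts as a miss.
    """
    want = frozenset(int(s) for s in causal_pair)
    hits = []
    for res in replicate_results:
        sig = _significant_pairs(res, alpha)
        hits.append(any(frozenset(map(int, row)) == want for row in sig))
    return _summarise(hits)


def signal_sensitivity(
    replicate_results: list[ScanResult],
    tagset1: TagSet,
    tagset2: TagSet,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Fraction of replicates where any tag pair of the causal pair is significant.

    A significant pair (a, b) qualifies when one member belongs to each tag
    set under a one-to-one assignment ((a in T1 and b in T2) or the reverse);
    tag sets must have been built on the complete, unpruned SNP panel.
    """
    t1, t2 = tagset1.members, tagset2.members
    hits = []
    for res in replicate_results:
        sig = _significant_pairs(res, alpha)
        hit = False
        for a, b in sig:
            a, b = int(a), int(b)
            if a == b:
                continue
            if (a in t1 and b in t2) or (a in t2 and b in t1):
                hit = True
                break
        hits.append(hit)
    return _summarise(hits)


def type1_fwer(
    null_replicate_results: list[ScanResult], alpha: float = 0.05
) -> tuple[float, float]:
    """Fraction of null replicates with at least one significant pair."""
    hits = []
    for res in null_replicate_results:
        if res.p_adjusted is None:
            raise ValueError("scan result carries no adjusted p-values")
        hits.append(bool(np.any(res.p_adjusted <= alpha)))
    return _summarise(hits)


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson (exact) binomial confidence interval for k successes of n."""
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n with n > 0")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
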