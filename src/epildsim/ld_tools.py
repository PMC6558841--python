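"""Genotypic r2, sliding-window LD pruning, and tag-SNP set construction.

r2 here is the squared Pearson correlation of unphased 0/1/2 dosage vectors
(the composite measure; no phase information is used), which serves both as
the pruning criterion and as the tagging criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founder_synth import MISSING, SiteMeta

__all__ = ["PruneConfig", "TagSet", "r2", "r2_with", "prune", "tag_set"]


@dataclass(frozen=True)
class PruneConfig:
    """Sliding-window pruning parameters: window size, shift, r2 threshold."""

    window: int = 10
    step: int = 2
    threshold: float = 0.75

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not 1 <= self.step < self.window:
            raise ValueError("step must satisfy 1 <= step < window")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")


@dataclass(frozen=True)
class TagSet:
    """All sites with r2 >= threshold to a causal site (the site included)."""

    causal_site: int
    threshold: float
    members: frozenset[int]

    def __contains__(self, site: int) -> bool:
        return site in self.members


def r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries (coded ``MISSING``) are dropped pairwise.  Returns NaN if
    either vector has zero variance over the complete observations (callers
    treating NaN as "no LD" should coerce it to 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("dosage vectors must have equal length >= 2")
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    vx = x - x.mean()
    vy = y - y.mean()
    den = np.sqrt((vx @ vx) * (vy @ vy))
    if den == 0.0:
        return float("nan")
    r = (vx @ vy) / den
    return float(r * r)


def r2_with(dosages: np.ndarray, site: int) -> np.ndarray:
    """r2 of one site against every column of a complete dosage matrix."""
    g = np.asarray(dosages, dtype=float)
    g = g - g.mean(axis=0)
    target = g[:, site]
    den = np.sqrt((target @ target) * np.einsum("ij,ij->j", g, g))
    num = target @ g
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r * r


def prune(
    dosages: np.ndarray, sites: list[SiteMeta], config: PruneConfig
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns surviving site indices.

    Windows of ``window`` consecutive SNPs are slid by ``step`` along each
    chromosome (never across a chromosome boundary).  Within each placement,
    surviving pairs are scanned in index order and whenever r2 exceeds the
    threshold the *later* member is removed; removed SNPs are skipped in all
    subsequent windows.  Deterministic and order-stable.
    """
    g = np.asarray(dosages)
    m = g.shape[1]
    if m != len(sites):
        raise ValueError("dosage columns and site metadata disagree")
    alive = np.ones(m, dtype=bool)
    cache: dict[tuple[int, int], float] = {}

    def _r2(i: int, j: int) -> float:
        key = (i, j)
        if key not in cache:
            val = r2(g[:, i], g[:, j])
            cache[key] = 0.0 if np.isnan(val) else val
        return cache[key]

    # chromosome groups in input order
    start = 0
    for end in range(1, m + 1):
        if end == m or sites[end].chromosome != sites[start].chromosome:
            idx = list(range(start, end))
            n_chr = len(idx)
            w0 = 0
            while True:
                win = [i for i in idx[w0 : w0 + config.window] if alive[i]]
                for a in range(len(win)):
                    i = win[a]
                    if not alive[i]:
                        continue
                    for b in range(a + 1, len(win)):
                        j = win[b]
                        if not alive[j]:
                            continue
                        if _r2(i, j) > config.threshold:
                            alive[j] = False
                if w0 + config.window >= n_chr:
                    break
                w0 += config.step
            start = end
    return np.flatnonzero(alive)


def tag_set(dosages: np.ndarray, causal_site: int, threshold: float) -> TagSet:
    """Tag-SNP set of a causal site on the complete (unpruned) SNP panel.

    Members are all sites with r2 >= threshold to the causal site, with no
    window restriction; the causal site itself always belongs (r2 = 1).
    """
    vals = r2_with(dosages, causal_site)
    members = set(np.flatnonzero(np.nan_to_num(vals, nan=0.0) >= threshold).tolist())
    members.add(int(causal_site))
    return TagSet(causal_site=int(causal_site), threshold=threshold, members=frozenset(members))
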