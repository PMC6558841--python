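"""MB-MDR-style exhaustive two-locus screen with Westfall-Young maxT p-values.

For every unordered SNP pair the 3x3 two-locus genotype cells are labelled
H (high risk), L (low risk) or O (no evidence) by comparing each cell's
case/control split against all remaining subjects with a 1-df Pearson
chi-square at ``alpha_cell`` (cells with fewer than ``min_cell`` subjects are
O).  The pair statistic is the 1-df chi-square of the pooled 2x2 table
(H vs L) x (case vs control), with O-labelled subjects excluded; a pair with
no H or no L cells scores 0.  No main-effect correction is applied (the
simulated signals are pure epistasis).

Family-wise significance comes from step-down maxT: the affection-status
vector is permuted B times with genotypes fixed, the full scan is recomputed
per permutation on one shared permutation stream, and adjusted p-values are
formed from successive maxima over the permutation null with monotonicity
enforced.  The whole (B+1) x pairs statistic matrix is built with a single
dense matrix product per pair chunk (status-vectors x cell-indicator
one-hots), which makes 199-999 permutations over thousands of pairs a matter
of seconds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "CellLabels",
    "PairResult",
    "ScanResult",
    "label_cells",
    "pair_statistic",
    "exhaustive_scan",
    "maxt_adjust",
    "scan_with_maxt",
    "top_k",
]

H, O, L = 1, 0, -1  # cell label codes


@dataclass(frozen=True)
class PairResult:
    """One SNP pair's labels, contrast statistic and p-values."""

    site_i: int
    site_j: int
    labels: np.ndarray  # 3x3 of {H, O, L}
    statistic: float
    p_raw: float | None = None
    p_adjusted: float | None = None


@dataclass
class ScanResult:
    """Exhaustive-scan output: pairs, statistics and (optionally) p-values."""

    pairs: np.ndarray  # (P, 2) site indices
    statistics: np.ndarray
    p_raw: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None
    site_indices: np.ndarray | None = None  # map scan columns -> original panel sites
    meta: dict = field(default_factory=dict)

    def global_pairs(self) -> np.ndarray:
        """Pairs expressed in original panel indices (if a map was provided)."""
        if self.site_indices is None:
            return self.pairs
        return self.site_indices[self.pairs]


def _cell_chi2_crit(alpha_cell: float) -> float:
    return float(chi2_dist.isf(alpha_cell, df=1))


def label_cells(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    alpha_cell: float = 0.1,
    min_cell: int = 10,
) -> np.ndarray:
    """H/L/O labels for a 3x3 (or flat 9) table of case/control cell counts."""
    a = np.asarray(case_counts, dtype=float).reshape(-1)
    b = np.asarray(control_counts, dtype=float).reshape(-1)
    if a.shape != (9,) or b.shape != (9,):
        raise ValueError("expected 3x3 case and control count tables")
    if a.sum() + b.sum() == 0:
        raise ValueError("all cells empty")
    labels = _label_cells_batch(
        a[None, None, :], (a + b)[None, :], a.sum(), a.sum() + b.sum(), alpha_cell, min_cell
    )[0, 0]
    return labels.reshape(3, 3)


def _label_cells_batch(case_counts, total_counts, n_cases, n_total, alpha_cell, min_cell):
    """Vectorised labelling over (..., cells) count arrays -> {H, O, L} codes."""
    a = case_counts  # cases in cell
    t = total_counts  # subjects in cell (broadcast against a)
    c = n_cases - a  # cases outside cell
    rest = n_total - t
    num = a * rest - c * t  # sign of (case prop in cell - case prop outside) * t * rest
    denom = t * rest * n_cases * (n_total - n_cases)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(denom > 0, n_total * (a * (rest - c) - (t - a) * c) ** 2 / denom, 0.0)
    crit = _cell_chi2_crit(alpha_cell)
    informative = (t >= min_cell) & (chi > crit)
    labels = np.zeros(np.broadcast(a, t).shape, dtype=np.int8)
    labels[informative & (num > 0)] = H
    labels[informative & (num < 0)] = L
    return labels


def pair_statistic(
    case_counts: np.ndarray, control_counts: np.ndarray, labels: np.ndarray
) -> float:
    """H-vs-L case/control contrast chi-square for one pair.

    Pools H cells and L cells into a 2x2 (H/L x case/control) table with
    O-cell subjects excluded; returns the 1-df Pearson chi-square, or 0 when
    no H or no L cell exists (or a margin is empty).
    """
    a = np.asarray(case_counts, dtype=float).reshape(-1)
    b = np.asarray(control_counts, dtype=float).reshape(-1)
    lab = np.asarray(labels).reshape(-1)
    hc, hn = a[lab == H].sum(), b[lab == H].sum()
    lc, ln = a[lab == L].sum(), b[lab == L].sum()
    n = hc + hn + lc + ln
    den = (hc + hn) * (lc + ln) * (hc + lc) * (hn + ln)
    if den == 0:
        return 0.0
    return float(n * (hc * ln - hn * lc) ** 2 / den)


def _pair_index_array(m: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(m), 2)), dtype=np.int64)


def _scan_statistics(
    dosages: np.ndarray,
    status_matrix: np.ndarray,
    alpha_cell: float,
    min_cell: int,
    pair_chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Statistics for all pairs under every status row.

    ``status_matrix`` is (R, n) of 0/1 vectors (row 0 is usually the observed
    status, the rest permutations).  Returns (pairs, stats) with stats of
    shape (R, P).
    """
    X = np.asarray(dosages)
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least two SNPs")
    if np.any(X < 0) or np.any(X > 2):
        raise ValueError("dosages must be complete and lie in {0, 1, 2}")
    pairs = _pair_index_array(m)
    R = status_matrix.shape[0]
    n_cases = float(status_matrix[0].sum())
    Y = np.ascontiguousarray(status_matrix, dtype=np.float32)
    stats = np.empty((R, len(pairs)), dtype=np.float64)
    crit = _cell_chi2_crit(alpha_cell)
    rows = np.arange(n)[:, None]
    for lo in range(0, len(pairs), pair_chunk):
        pc = pairs[lo : lo + pair_chunk]
        c = len(pc)
        cell = (3 * X[:, pc[:, 0]] + X[:, pc[:, 1]]).astype(np.int64)  # n x c
        onehot = np.zeros((n, c * 9), dtype=np.float32)
        onehot[rows, 9 * np.arange(c)[None, :] + cell] = 1.0
        counts_case = (Y @ onehot).astype(np.float64).reshape(R, c, 9)
        t = onehot.sum(axis=0).astype(np.float64).reshape(1, c, 9)
        a = counts_case
        cc = n_cases - a
        rest = n - t
        denom = t * rest * n_cases * (n - n_cases)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi = np.where(denom > 0, n * (a * (rest - cc) - (t - a) * cc) ** 2 / denom, 0.0)
        informative = (t >= min_cell) & (chi > crit)
        num = a * rest - cc * t
        h_mask = informative & (num > 0)
        l_mask = informative & (num < 0)
        hc = np.sum(a * h_mask, axis=2)
        ht = np.sum(t * h_mask, axis=2)
        lc = np.sum(a * l_mask, axis=2)
        lt = np.sum(t * l_mask, axis=2)
        hn = ht - hc
        ln_ = lt - lc
        npool = ht + lt
        den2 = ht * lt * (hc + lc) * (hn + ln_)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(den2 > 0, npool * (hc * ln_ - hn * lc) ** 2 / den2, 0.0)
        stats[:, lo : lo + c] = s
    return pairs, stats


def exhaustive_scan(
    dosages: np.ndarray,
    status: np.ndarray,
    alpha_cell: float = 0.1,
    min_cell: int = 10,
) -> ScanResult:
    """Evaluate the H/L contrast statistic for all C(M, 2) SNP pairs."""
    status = np.asarray(status).astype(np.int8)
    pairs, stats = _scan_statistics(dosages, status[None, :], alpha_cell, min_cell)
    return ScanResult(pairs=pairs, statistics=stats[0])


def maxt_adjust(observed: np.ndarray, null_stats: np.ndarray) -> np.ndarray:
    """Westfall-Young step-down maxT adjusted p-values.

    ``observed`` is (P,), ``null_stats`` (B, P) permutation statistics.
    Observed statistics are ordered descending; for each rank the successive
    maximum of the permutation statistics over that rank and all lower ranks
    is compared with the observed value; monotone nondecreasing p-values are
    enforced along the ordered list.
    """
    observed = np.asarray(observed, dtype=float)
    B = null_stats.shape[0]
    order = np.argsort(-observed, kind="stable")
    null_ord = null_stats[:, order]
    succ_max = np.maximum.accumulate(null_ord[:, ::-1], axis=1)[:, ::-1]
    exceed = (succ_max >= observed[order][None, :]).sum(axis=0)
    p_ord = (1.0 + exceed) / (B + 1.0)
    p_ord = np.maximum.accumulate(p_ord)
    p = np.empty_like(p_ord)
    p[order] = p_ord
    return p


def scan_with_maxt(
    dosages: np.ndarray,
    status: np.ndarray,
    B: int = 999,
    seed: int = 0,
    alpha_cell: float = 0.1,
    min_cell: int = 10,
    alpha: float = 0.05,
    site_indices: np.ndarray | None = None,
) -> ScanResult:
    """Exhaustive pair scan plus permutation-based raw and maxT-adjusted p-values.

    One shared permutation stream (B permutations of the status vector,
    genotypes fixed) serves all pairs, as step-down maxT requires.
    Zero-statistic pairs are assigned adjusted p = 1 outright.  Deterministic
    given ``seed``.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    if 1.0 / (B + 1) > alpha:
        import warnings

        warnings.warn(
            f"minimum attainable adjusted p {1.0 / (B + 1):.4g} exceeds alpha={alpha}",
            stacklevel=2,
        )
    status = np.asarray(status).astype(np.int8)
    rng = np.random.default_rng(seed)
    status_matrix = np.empty((B + 1, status.size), dtype=np.int8)
    status_matrix[0] = status
    for b in range(1, B + 1):
        status_matrix[b] = rng.permutation(status)
    pairs, stats = _scan_statistics(dosages, status_matrix, alpha_cell, min_cell)
    observed = stats[0]
    null_stats = stats[1:]
    p_raw = (1.0 + (null_stats >= observed[None, :]).sum(axis=0)) / (B + 1.0)
    p_adj = maxt_adjust(observed, null_stats)
    zero = observed == 0.0
    p_adj[zero] = 1.0
    p_raw[zero] = 1.0
    return ScanResult(
        pairs=pairs,
        statistics=observed,
        p_raw=p_raw,
        p_adjusted=p_adj,
        site_indices=None if site_indices is None else np.asarray(site_indices),
        meta={"B": B, "seed": seed, "alpha_cell": alpha_cell, "min_cell": min_cell},
    )


def top_k(result: ScanResult, k: int = 5000) -> ScanResult:
    """Retain the k best pairs: lowest adjusted p, ties by larger statistic,
    then lexicographic pair order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = result.p_adjusted
    if p is None:
        p = np.full(len(result.statistics), np.nan)
    order = sorted(
        range(len(result.statistics)),
        key=lambda i: (
            float(p[i]) if not np.isnan(p[i]) else np.inf,
            -float(result.statistics[i]),
            int(result.pairs[i, 0]),
            int(result.pairs[i, 1]),
        ),
    )[:k]
    order = np.array(order, dtype=int)
    return ScanResult(
        pairs=result.pairs[order],
        statistics=result.statistics[order],
        p_raw=None if result.p_raw is None else result.p_raw[order],
        p_adjusted=None if result.p_adjusted is None else result.p_adjusted[order],
        site_indices=result.site_indices,
        meta=dict(result.meta),
    )
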