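"""H/L/O labelling, contrast statistic, exhaustive scan and maxT adjustment."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from epildsim import mbmdr
from epildsim.disease_model import EpistasisModel, PopulationFreqs, build_table
from epildsim.sampler import assign_status
from tests.conftest import hwe_genotypes


def test_label_empty_cell_is_O():
    case = np.zeros((3, 3))
    ctrl = np.zeros((3, 3))
    case[1, 1] = 500
    ctrl[1, 1] = 500
    labels = mbmdr.label_cells(case, ctrl)
    assert labels[0, 0] == mbmdr.O


def test_label_case_enriched_cell_is_H():
    case = np.full((3, 3), 450 / 8)
    ctrl = np.full((3, 3), 500 / 8)
    case[0, 0], ctrl[0, 0] = 50, 0
    labels = mbmdr.label_cells(case, ctrl)
    # oracle: 2x2 chi-square of (cell vs rest) x (case vs control)
    chi = chi2_contingency([[50, 0], [450, 500]], correction=False)
    assert chi.pvalue < 0.1
    assert labels[0, 0] == mbmdr.H


def test_label_control_enriched_cell_is_L():
    case = np.full((3, 3), 500 / 8)
    ctrl = np.full((3, 3), 450 / 8)
    case[2, 2], ctrl[2, 2] = 0, 50
    assert mbmdr.label_cells(case, ctrl)[2, 2] == mbmdr.L


def test_label_balanced_cell_is_O():
    case = np.full((3, 3), 100.0)
    ctrl = np.full((3, 3), 100.0)
    assert (mbmdr.label_cells(case, ctrl) == mbmdr.O).all()


def test_label_min_cell_rule():
    case = np.full((3, 3), 100.0)
    ctrl = np.full((3, 3), 100.0)
    case[0, 0], ctrl[0, 0] = 9, 0  # wildly case-enriched but below min_cell
    assert mbmdr.label_cells(case, ctrl, min_cell=10)[0, 0] == mbmdr.O
    assert mbmdr.label_cells(case, ctrl, min_cell=5)[0, 0] == mbmdr.H


def test_pair_statistic_hand_value():
    """Pooled [[60,40],[40,60]] H/L table gives chi-square 8.0."""
    case = np.array([[60.0, 40, 0], [0, 0, 0], [0, 0, 0]])
    ctrl = np.array([[40.0, 60, 0], [0, 0, 0], [0, 0, 0]])
    labels = np.array([[mbmdr.H, mbmdr.L, 0], [0, 0, 0], [0, 0, 0]])
    assert mbmdr.pair_statistic(case, ctrl, labels) == pytest.approx(8.0)


def test_pair_statistic_zero_without_both_labels():
    case = np.full((3, 3), 10.0)
    ctrl = np.full((3, 3), 10.0)
    only_h = np.zeros((3, 3), dtype=int)
    only_h[0, 0] = mbmdr.H
    assert mbmdr.pair_statistic(case, ctrl, only_h) == 0.0
    assert mbmdr.pair_statistic(case, ctrl, np.zeros((3, 3), dtype=int)) == 0.0


def test_pair_statistic_equals_classic_chi2_single_h_single_l():
    case = np.zeros((3, 3))
    ctrl = np.zeros((3, 3))
    case[0, 0], ctrl[0, 0] = 70, 30
    case[2, 2], ctrl[2, 2] = 35, 65
    labels = np.zeros((3, 3), dtype=int)
    labels[0, 0], labels[2, 2] = mbmdr.H, mbmdr.L
    oracle = chi2_contingency([[70, 30], [35, 65]], correction=False).statistic
    assert mbmdr.pair_statistic(case, ctrl, labels) == pytest.approx(oracle)


def test_exhaustive_scan_pair_count_and_duplication(rng):
    X = hwe_genotypes(rng, 0.3, 300, 2)
    y = rng.integers(0, 2, 300)
    res = mbmdr.exhaustive_scan(X, y)
    assert len(res.pairs) == 1
    # duplicated columns -> identical statistics
    X4 = np.hstack([X, X])
    res4 = mbmdr.exhaustive_scan(X4, y)
    idx = {tuple(p): s for p, s in zip(map(tuple, res4.pairs), res4.statistics)}
    assert idx[(0, 1)] == pytest.approx(idx[(2, 3)])


def test_scan_matches_single_pair_statistic(rng):
    """Vectorised engine agrees with the scalar label/statistic path."""
    X = hwe_genotypes(rng, [0.2, 0.4, 0.3], 400, 3)
    y = rng.integers(0, 2, 400).astype(np.int8)
    res = mbmdr.exhaustive_scan(X, y)
    for (i, j), stat in zip(res.pairs, res.statistics):
        cell = 3 * X[:, i].astype(int) + X[:, j].astype(int)
        case = np.bincount(cell[y == 1], minlength=9).reshape(3, 3)
        ctrl = np.bincount(cell[y == 0], minlength=9).reshape(3, 3)
        labels = mbmdr.label_cells(case, ctrl)
        assert stat == pytest.approx(mbmdr.pair_statistic(case, ctrl, labels))


def test_planted_epistasis_pair_attains_max_statistic(rng):
    """Strong pure interaction (beta3=2) dominates the scan at n=2000."""
    table = build_table(EpistasisModel(beta0=-2.0, beta3=2.0), PopulationFreqs(0.3, 0.4))
    X = hwe_genotypes(rng, [0.3, 0.4] + [0.25] * 8, 2000, 10)
    y = assign_status(X[:, 0], 2 - X[:, 1], table, rng, dsl2_risk_is_minor=True)
    res = mbmdr.exhaustive_scan(X, y)
    best = res.pairs[np.argmax(res.statistics)]
    assert tuple(best) == (0, 1)


def test_allele_flip_invariance(rng):
    """Statistics are unchanged when a locus's dosage coding is flipped."""
    X = hwe_genotypes(rng, [0.2, 0.35, 0.45, 0.1], 500, 4)
    y = rng.integers(0, 2, 500).astype(np.int8)
    base = mbmdr.exhaustive_scan(X, y)
    flipped = X.copy()
    flipped[:, 2] = 2 - flipped[:, 2]
    alt = mbmdr.exhaustive_scan(flipped, y)
    assert np.allclose(base.statistics, alt.statistics)


def test_maxt_minimum_p_and_monotonicity(rng):
    table = build_table(EpistasisModel(beta0=-1.0, beta3=2.5), PopulationFreqs(0.3, 0.4))
    X = hwe_genotypes(rng, [0.3, 0.4] + [0.25] * 6, 1500, 8)
    y = assign_status(X[:, 0], 2 - X[:, 1], table, rng, dsl2_risk_is_minor=True)
    res = mbmdr.scan_with_maxt(X, y, B=99, seed=4)
    assert res.p_adjusted.min() >= 1.0 / 100.0
    order = np.argsort(-res.statistics, kind="stable")
    nonzero = res.statistics[order] > 0
    assert np.all(np.diff(res.p_adjusted[order][nonzero]) >= -1e-12)
    # strong planted pair reaches the smallest attainable p
    k = np.flatnonzero((res.pairs[:, 0] == 0) & (res.pairs[:, 1] == 1))[0]
    assert res.p_adjusted[k] == pytest.approx(1.0 / 100.0)


def test_maxt_zero_statistic_pairs_get_p_one(rng):
    X = hwe_genotypes(rng, 0.3, 100, 4)
    y = rng.integers(0, 2, 100).astype(np.int8)
    res = mbmdr.scan_with_maxt(X, y, B=19, seed=0, alpha=1.0)
    zero = res.statistics == 0.0
    if zero.any():
        assert np.all(res.p_adjusted[zero] == 1.0)


def test_maxt_same_seed_bit_reproducible(rng):
    X = hwe_genotypes(rng, [0.2, 0.3, 0.4], 300, 3)
    y = rng.integers(0, 2, 300).astype(np.int8)
    a = mbmdr.scan_with_maxt(X, y, B=49, seed=7)
    b = mbmdr.scan_with_maxt(X, y, B=49, seed=7)
    assert np.array_equal(a.p_adjusted, b.p_adjusted)
    assert np.array_equal(a.statistics, b.statistics)


def test_maxt_warns_when_B_too_small(rng):
    X = hwe_genotypes(rng, 0.3, 100, 2)
    y = rng.integers(0, 2, 100).astype(np.int8)
    with pytest.warns(UserWarning, match="alpha"):
        mbmdr.scan_with_maxt(X, y, B=5, seed=0, alpha=0.05)


def test_top_k_ordering_and_bounds(rng):
    X = hwe_genotypes(rng, [0.2, 0.3, 0.4, 0.25], 400, 4)
    y = rng.integers(0, 2, 400).astype(np.int8)
    res = mbmdr.scan_with_maxt(X, y, B=49, seed=3, alpha=1.0)
    allk = mbmdr.top_k(res, 100)
    assert len(allk.pairs) == len(res.pairs)  # k larger than #pairs
    one = mbmdr.top_k(res, 1)
    assert one.statistics[0] == res.statistics.max()
    assert np.all(np.diff(allk.p_adjusted) >= 0)
    with pytest.raises(ValueError):
        mbmdr.top_k(res, 0)
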