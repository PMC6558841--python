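"""Founder-panel generation, DSL placement, marker QC and PED/MAP round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from epildsim import founder_synth as fs

# ---------------------------------------------------------------------------
# panel generation


def test_default_panel_dimensions():
    specs = fs.default_blockspecs(0)
    panel = fs.generate_panel(specs, 91, 0)
    assert panel.haplotypes.shape == (182, 1751)
    assert panel.segment_lengths() == [964, 787]
    assert len(panel.sites) == 1751


def test_degenerate_pool_block_is_monomorphic():
    specs = [
        fs.BlockSpec(segment=0, span=(0, 10), pool_size=1, flip_rate=0.0),
        fs.BlockSpec(segment=0, span=(10, 20), pool_size=4, flip_rate=0.05),
    ]
    panel = fs.generate_panel(specs, 50, 3)
    col_var = panel.haplotypes[:, :10].std(axis=0)
    assert np.all(col_var == 0.0)
    keep = fs.qc_filter(panel.founder_genotypes(), panel.sites)
    assert np.all(keep >= 10)  # monomorphic block removed by QC


def test_cross_block_r2_near_zero(small_panel):
    g = small_panel.founder_genotypes().astype(float)
    off = small_panel.segment_offsets[1]
    corr = np.corrcoef(g.T)
    cross = corr[:off, off:] ** 2
    assert np.nanmean(cross) < 0.05


def test_generate_panel_deterministic():
    specs = fs.default_blockspecs(7, segment_sites=(30, 30))
    a = fs.generate_panel(specs, 20, 7)
    b = fs.generate_panel(specs, 20, 7)
    assert np.array_equal(a.haplotypes, b.haplotypes)
    assert a.sites == b.sites


def test_generate_panel_input_validation():
    with pytest.raises(ValueError):
        fs.generate_panel([], 10, 0)
    with pytest.raises(ValueError):
        fs.BlockSpec(segment=0, span=(0, 5), pool_size=2, flip_rate=0.6)
    with pytest.raises(ValueError):
        fs.BlockSpec(segment=0, span=(0, 5), pool_size=0, flip_rate=0.1)
    gapped = [
        fs.BlockSpec(segment=0, span=(0, 5), pool_size=2, flip_rate=0.1),
        fs.BlockSpec(segment=0, span=(6, 10), pool_size=2, flip_rate=0.1),
    ]
    with pytest.raises(ValueError):
        fs.generate_panel(gapped, 10, 0)


def test_sites_positions_strictly_increasing(small_panel):
    by_chrom = {}
    for s in small_panel.sites:
        by_chrom.setdefault(s.chromosome, []).append(s.position)
    for positions in by_chrom.values():
        assert np.all(np.diff(positions) > 0)


# ---------------------------------------------------------------------------
# DSL placement


def test_place_dsl_other_chromosome(small_panel):
    partner = small_panel.segment_offsets[1] + 5
    placement = fs.place_dsl(small_panel, "other_chromosome", 0.2, 5, partner=partner)
    assert small_panel.segment_of(placement.site_index) == 0


def test_place_dsl_block_edge(small_panel):
    placement = fs.place_dsl(small_panel, "block_edge", 0.3, 6)
    blk = small_panel.blocks[small_panel.block_of(placement.site_index)]
    lo, hi = small_panel.global_span(blk)
    assert placement.site_index < lo + 2 or placement.site_index >= hi - 2


def test_place_dsl_block_middle(small_panel):
    placement = fs.place_dsl(small_panel, "block_middle", 0.3, 6)
    blk = small_panel.blocks[small_panel.block_of(placement.site_index)]
    lo, hi = small_panel.global_span(blk)
    third = (hi - lo) // 3
    assert lo + third <= placement.site_index < hi - third


@pytest.mark.parametrize("seed", range(12))
def test_place_dsl_hits_target_maf(seed):
    """Realised founder MAF within +-0.03 of the 0.09 target, across seeds."""
    specs = fs.default_blockspecs(seed + 100, segment_sites=(60, 60))
    panel = fs.generate_panel(specs, 91, seed + 100)
    placement = fs.place_dsl(panel, "block_middle", 0.09, seed)
    maf = panel.minor_freqs()[placement.site_index]
    assert 0.06 <= maf <= 0.12


def test_place_dsl_same_block(small_panel):
    partner = small_panel.segment_offsets[1] + 10
    placement = fs.place_dsl(
        small_panel, "same_block_as_partner", 0.42, 8, partner=partner
    )
    assert placement.site_index != partner
    assert small_panel.block_of(placement.site_index) == small_panel.block_of(partner)


def test_place_dsl_requires_partner_or_segment(small_panel):
    with pytest.raises(ValueError):
        fs.place_dsl(small_panel, "same_block_as_partner", 0.1, 0)
    with pytest.raises(ValueError):
        fs.place_dsl(small_panel, "not_a_role", 0.1, 0)


# ---------------------------------------------------------------------------
# QC


def _hwe_oracle(n_het, n_hom_min, n_hom_maj):
    """Full enumeration via log-factorials (independent of the recurrence)."""
    n = n_het + n_hom_min + n_hom_maj
    n_a = 2 * min(n_hom_min, n_hom_maj) + n_het

    def logprob(h):
        r = (n_a - h) // 2
        c = n - h - r
        return (
            gammaln(n + 1)
            - gammaln(r + 1)
            - gammaln(h + 1)
            - gammaln(c + 1)
            + h * np.log(2)
            + gammaln(n_a + 1)
            + gammaln(2 * n - n_a + 1)
            - gammaln(2 * n + 1)
        )

    hs = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    lp = np.array([logprob(h) for h in hs])
    p = np.exp(lp - lp.max())
    p /= p.sum()
    obs = p[np.searchsorted(hs, n_het)]
    return p[p <= obs * (1 + 1e-12)].sum()


@pytest.mark.parametrize(
    "het,hom_min,hom_maj",
    [(10, 5, 85), (57, 14, 50), (0, 10, 90), (25, 0, 75), (3, 3, 3), (40, 1, 200)],
)
def test_hwe_exact_matches_enumeration_oracle(het, hom_min, hom_maj):
    assert fs.hwe_exact_p(het, hom_min, hom_maj) == pytest.approx(
        _hwe_oracle(het, hom_min, hom_maj), rel=1e-9
    )


@given(
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=60),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hwe_exact_is_a_probability(het, hom_min, hom_maj):
    if het + hom_min + hom_maj == 0:
        return
    p = fs.hwe_exact_p(het, hom_min, hom_maj)
    assert 0.0 < p <= 1.0


def test_qc_removes_monomorphic_site(rng):
    g = rng.integers(0, 3, size=(50, 3)).astype(np.int8)
    g[:, 1] = 0
    keep = fs.qc_filter(g)
    assert 1 not in keep


def test_qc_removes_high_missingness(rng):
    g = rng.integers(0, 2, size=(100, 2)).astype(np.int8)
    g[:15, 1] = fs.MISSING  # 15% missing
    keep = fs.qc_filter(g)
    assert 1 not in keep


def test_qc_removes_extreme_hwe_violation():
    """200 individuals all heterozygous: exact HWE p is far below 5e-15."""
    g = np.ones((200, 1), dtype=np.int8)
    assert _hwe_oracle(200, 0, 0) < 5e-15  # oracle confirms the rule applies
    assert fs.qc_filter(g).size == 0


def test_qc_is_idempotent(small_panel):
    g = small_panel.founder_genotypes()
    first = fs.qc_filter(g)
    second = first[fs.qc_filter(g[:, first])]
    assert np.array_equal(first, second)


def test_qc_rejects_empty_matrix():
    with pytest.raises(ValueError):
        fs.qc_filter(np.empty((0, 0), dtype=np.int8))


# ---------------------------------------------------------------------------
# PED/MAP


def _toy_dataset():
    sites = [
        fs.SiteMeta("7", 110_200_100, "ss7_1", ("A", "G")),
        fs.SiteMeta("8", 91_525_200, "ss8_1", ("C", "T")),
    ]
    dosages = np.array([[0, 2], [1, fs.MISSING], [2, 1]], dtype=np.int8)
    status = np.array([0, 1, 1], dtype=np.int8)
    return dosages, status, sites


def test_ped_map_round_trip(tmp_path):
    dosages, status, sites = _toy_dataset()
    prefix = tmp_path / "toy"
    fs.write_ped_map(prefix, dosages, status, sites, sample_ids=["a", "b", "c"])
    d2, s2, sites2, ids = fs.read_ped_map(prefix, sites=sites)
    assert np.array_equal(d2, dosages)
    assert np.array_equal(s2, status)
    assert sites2 == sites
    assert ids == ["a", "b", "c"]


def test_ped_missing_genotype_encoding(tmp_path):
    dosages, status, sites = _toy_dataset()
    prefix = tmp_path / "toy"
    fs.write_ped_map(prefix, dosages, status, sites)
    ped = (prefix.with_suffix(".ped")).read_text().splitlines()
    assert ped[1].split()[8:10] == ["0", "0"]  # sample b, SNP 2


def test_map_fields(tmp_path):
    dosages, status, sites = _toy_dataset()
    prefix = tmp_path / "toy"
    fs.write_ped_map(prefix, dosages, status, sites)
    rows = [line.split() for line in (prefix.with_suffix(".map")).read_text().splitlines()]
    assert rows[0] == ["7", "ss7_1", "0", "110200100"]
    assert rows[1] == ["8", "ss8_1", "0", "91525200"]


def test_ped_malformed_line_rejected(tmp_path):
    dosages, status, sites = _toy_dataset()
    prefix = tmp_path / "toy"
    fs.write_ped_map(prefix, dosages, status, sites)
    with open(prefix.with_suffix(".ped"), "a") as fh:
        fh.write("x x 0 0 0 1 A G\n")  # one SNP short
    with pytest.raises(ValueError, match="expected"):
        fs.read_ped_map(prefix)


def test_ped_unknown_allele_rejected(tmp_path):
    dosages, status, sites = _toy_dataset()
    prefix = tmp_path / "toy"
    fs.write_ped_map(prefix, dosages, status, sites)
    text = prefix.with_suffix(".ped").read_text().replace(" A ", " Z ", 1)
    prefix.with_suffix(".ped").write_text(text)
    with pytest.raises(ValueError, match="allele"):
        fs.read_ped_map(prefix, sites=sites)
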