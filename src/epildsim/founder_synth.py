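"""Synthetic founder haplotype panels with block-LD structure, QC, PED/MAP I/O.

The real study system is a small founder cohort (91 individuals) genotyped on
two 250-kbp chromosome segments (964 + 787 = 1751 bi-allelic SNPs) showing
LD blocks of varying size and correlation intensity.  This module emulates
that structure without any real data: each segment is tiled by blocks, and
within a block every founder haplotype is a copy of one of ``pool_size``
ancestral haplotypes with independent per-site allele flips at ``flip_rate``.
Small pools and low flip rates give tight blocks (high r2); large pools and
high flip rates dissolve them.  Blocks are generated independently, so
cross-block allelic correlation is zero in expectation.

Also provided: configurable placement of disease susceptibility loci (DSLs)
inside / at the edge of / across blocks at a target founder minor-allele
frequency, standard GWAS marker QC (MAF, missingness, Hardy-Weinberg exact
test), and PLINK text PED/MAP reading and writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SiteMeta",
    "BlockSpec",
    "FounderPanel",
    "DslPlacement",
    "generate_panel",
    "default_blockspecs",
    "place_dsl",
    "qc_filter",
    "hwe_exact_p",
    "write_ped_map",
    "read_ped_map",
]

MISSING = -1  # dosage code for a missing genotype

#: DSL placement roles relative to LD blocks.
ROLES = ("same_block_as_partner", "block_middle", "block_edge", "other_chromosome")


@dataclass(frozen=True)
class SiteMeta:
    """Marker metadata: chromosome label, bp position, id, (minor, major) alleles."""

    chromosome: str
    position: int
    id: str
    alleles: tuple[str, str]

    def __post_init__(self):
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError("a site needs exactly two distinct allele codes")


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: local site span within a segment, plus its LD 'knobs'.

    ``pool_size`` is the number of ancestral haplotypes founder haplotypes are
    copied from, ``flip_rate`` the per-site copy-error probability.
    """

    segment: int
    span: tuple[int, int]  # half-open, segment-local site indices
    pool_size: int
    flip_rate: float

    def __post_init__(self):
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0.0 <= self.flip_rate < 0.5:
            raise ValueError("flip_rate must lie in [0, 0.5)")
        if self.span[1] <= self.span[0]:
            raise ValueError("empty block span")


@dataclass
class FounderPanel:
    """Phased founder haplotypes over the two segments.

    ``haplotypes`` is (2 * n_founders) x n_sites, entries 1 = minor allele.
    Founder i owns rows 2i and 2i+1.  ``segment_offsets[s]`` is the global
    column index where segment s starts; block spans are segment-local.
    ``pool_assignments[b]`` records which ancestral haplotype each haplotype
    row copied in block b (used when a DSL column must be resampled to a
    target frequency).
    """

    haplotypes: np.ndarray
    sites: list[SiteMeta]
    blocks: list[BlockSpec]
    segment_offsets: tuple[int, ...]
    pool_assignments: list[np.ndarray] = field(default_factory=list)

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_segments(self) -> int:
        return len(self.segment_offsets)

    def segment_lengths(self) -> list[int]:
        bounds = list(self.segment_offsets) + [self.n_sites]
        return [bounds[s + 1] - bounds[s] for s in range(self.n_segments)]

    def segment_of(self, site: int) -> int:
        return int(np.searchsorted(self.segment_offsets, site, side="right") - 1)

    def global_span(self, block: BlockSpec) -> tuple[int, int]:
        off = self.segment_offsets[block.segment]
        return (off + block.span[0], off + block.span[1])

    def block_of(self, site: int) -> int:
        for b, blk in enumerate(self.blocks):
            lo, hi = self.global_span(blk)
            if lo <= site < hi:
                return b
        raise IndexError(f"site {site} not covered by any block")

    def founder_genotypes(self) -> np.ndarray:
        """Unphased minor-allele dosages, n_founders x n_sites."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def minor_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def subset(self, keep: np.ndarray) -> "FounderPanel":
        """Panel restricted to the given (sorted) global site indices.

        Block spans are remapped onto the retained index grid; blocks that
        lose all sites are dropped (their pool assignments with them).
        """
        keep = np.asarray(keep, dtype=int)
        sites = [self.sites[i] for i in keep]
        seg_ids = np.array([self.segment_of(i) for i in keep])
        new_offsets = tuple(int(np.searchsorted(seg_ids, s)) for s in range(self.n_segments))
        new_blocks, new_pools = [], []
        for blk, pool in zip(self.blocks, self.pool_assignments):
            lo, hi = self.global_span(blk)
            n_lo = int(np.searchsorted(keep, lo))
            n_hi = int(np.searchsorted(keep, hi))
            if n_hi > n_lo:
                off = new_offsets[blk.segment]
                new_blocks.append(replace(blk, span=(n_lo - off, n_hi - off)))
                new_pools.append(pool)
        return FounderPanel(
            haplotypes=self.haplotypes[:, keep].copy(),
            sites=sites,
            blocks=new_blocks,
            segment_offsets=new_offsets,
            pool_assignments=new_pools,
        )


@dataclass(frozen=True)
class DslPlacement:
    """A realised DSL placement: role, chosen site and its founder MAF target."""

    role: str
    site_index: int
    founder_maf: float


_SEGMENT_CHROMS = ("7", "8")
_SEGMENT_STARTS = (110_200_000, 91_525_000)
_SEGMENT_SPACING = (260, 318)
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G"))


def default_blockspecs(
    seed: int,
    segment_sites: tuple[int, int] = (964, 787),
    block_size_range: tuple[int, int] = (6, 40),
    pool_sizes: tuple[int, ...] = (2, 2, 3, 4, 6),
    flip_range: tuple[float, float] = (0.01, 0.08),
) -> list[BlockSpec]:
    """Tile both segments with blocks of random size/pool/flip intensity.

    Deterministic given ``seed``; the variety of pool sizes and flip rates is
    what produces blocks of differing LD intensity.
    """
    rng = np.random.default_rng(seed)
    specs: list[BlockSpec] = []
    for seg, n in enumerate(segment_sites):
        pos = 0
        while pos < n:
            size = int(rng.integers(block_size_range[0], block_size_range[1] + 1))
            size = min(size, n - pos)
            specs.append(
                BlockSpec(
                    segment=seg,
                    span=(pos, pos + size),
                    pool_size=int(rng.choice(pool_sizes)),
                    flip_rate=float(rng.uniform(*flip_range)),
                )
            )
            pos += size
    return specs


def _check_tiling(blockspecs: list[BlockSpec]) -> list[int]:
    """Validate that spans tile each segment contiguously; return lengths."""
    if not blockspecs:
        raise ValueError("empty blockspec list")
    n_seg = max(b.segment for b in blockspecs) + 1
    lengths = []
    for seg in range(n_seg):
        spans = sorted(b.span for b in blockspecs if b.segment == seg)
        if not spans or spans[0][0] != 0:
            raise ValueError(f"segment {seg} blocks do not start at 0")
        for (a0, a1), (b0, _) in zip(spans, spans[1:]):
            if a1 != b0:
                raise ValueError(f"segment {seg} blocks do not tile: gap/overlap at {a1}")
        lengths.append(spans[-1][1])
    return lengths


def _make_sites(lengths: list[int], rng: np.random.Generator) -> tuple[list[SiteMeta], tuple[int, ...]]:
    sites: list[SiteMeta] = []
    offsets = []
    for seg, n in enumerate(lengths):
        offsets.append(len(sites))
        chrom = _SEGMENT_CHROMS[seg % len(_SEGMENT_CHROMS)]
        start = _SEGMENT_STARTS[seg % len(_SEGMENT_STARTS)]
        spacing = _SEGMENT_SPACING[seg % len(_SEGMENT_SPACING)]
        gaps = rng.integers(1, 2 * spacing, size=n)
        positions = start + np.cumsum(gaps)
        for k in range(n):
            pair = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            sites.append(
                SiteMeta(
                    chromosome=chrom,
                    position=int(positions[k]),
                    id=f"ss{chrom}_{k + 1:05d}",
                    alleles=pair,
                )
            )
    return sites, tuple(offsets)


def generate_panel(
    blockspecs: list[BlockSpec], n_founders: int, seed: int
) -> FounderPanel:
    """Generate a founder haplotype panel from block specifications.

    Per block: ancestral site frequencies are drawn uniform on (0.05, 0.5),
    ``pool_size`` ancestral haplotypes are sampled from them, and each of the
    2 * n_founders haplotypes copies a uniformly chosen ancestral haplotype
    with independent per-site flips at ``flip_rate``.  Deterministic given
    ``seed``.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    lengths = _check_tiling(blockspecs)
    rng = np.random.default_rng(seed)
    sites, offsets = _make_sites(lengths, rng)
    n_hap = 2 * n_founders
    hap = np.zeros((n_hap, sum(lengths)), dtype=np.uint8)
    blocks = sorted(blockspecs, key=lambda b: (b.segment, b.span))
    pools: list[np.ndarray] = []
    for blk in blocks:
        lo = offsets[blk.segment] + blk.span[0]
        width = blk.span[1] - blk.span[0]
        p_site = rng.uniform(0.05, 0.5, size=width)
        ancestral = (rng.random((blk.pool_size, width)) < p_site).astype(np.uint8)
        assign = rng.integers(blk.pool_size, size=n_hap)
        flips = (rng.random((n_hap, width)) < blk.flip_rate).astype(np.uint8)
        hap[:, lo : lo + width] = ancestral[assign] ^ flips
        pools.append(assign)
    return FounderPanel(
        haplotypes=hap,
        sites=sites,
        blocks=blocks,
        segment_offsets=offsets,
        pool_assignments=pools,
    )


def _role_candidates(
    panel: FounderPanel,
    role: str,
    partner: int | None,
    segment: int | None,
) -> np.ndarray:
    """Global site indices compatible with a placement role."""
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    cands: list[int] = []
    if role == "same_block_as_partner":
        if partner is None:
            raise ValueError("same_block_as_partner requires a partner site")
        lo, hi = panel.global_span(panel.blocks[panel.block_of(partner)])
        cands = [i for i in range(lo, hi) if i != partner]
    elif role == "other_chromosome":
        if partner is None and segment is None:
            raise ValueError("other_chromosome requires a partner site or a segment")
        seg = segment if segment is not None else 1 - panel.segment_of(partner)
        bounds = list(panel.segment_offsets) + [panel.n_sites]
        cands = list(range(bounds[seg], bounds[seg + 1]))
    else:
        partner_block = panel.block_of(partner) if partner is not None else None
        for b, blk in enumerate(panel.blocks):
            if segment is not None and blk.segment != segment:
                continue
            if b == partner_block:
                continue
            lo, hi = panel.global_span(blk)
            width = hi - lo
            if role == "block_middle":
                third = width // 3
                if third == 0:
                    continue
                cands.extend(range(lo + third, hi - third))
            else:  # block_edge
                if width < 5:  # too small for a meaningful edge/interior split
                    continue
                cands.extend(range(lo, lo + 2))
                cands.extend(range(hi - 2, hi))
    if not cands:
        raise ValueError(f"no block compatible with role {role!r}")
    return np.array(sorted(set(cands)), dtype=int)


def _resample_column(
    panel: FounderPanel, site: int, target_maf: float, rng: np.random.Generator
) -> None:
    """Rewrite one site column to hit a target founder MAF, preserving block LD.

    The ancestral-pool carrier pattern at the site is re-chosen greedily so the
    expected minor count is as close as possible to the target, the column is
    regenerated through the stored pool assignment with the block's flip rate,
    and any residual is fixed by flipping a minimal random set of entries.
    """
    b = panel.block_of(site)
    blk = panel.blocks[b]
    assign = panel.pool_assignments[b]
    n_hap = panel.haplotypes.shape[0]
    target_count = int(round(target_maf * n_hap))
    pool_counts = np.bincount(assign, minlength=blk.pool_size).astype(float)
    f = blk.flip_rate
    # greedy carrier-subset choice: expected minor count if pool k carries the
    # minor allele is c_k (1 - f), otherwise c_k f
    carrier = np.zeros(blk.pool_size, dtype=bool)
    expected = float(np.sum(pool_counts * f))
    improved = True
    while improved:
        improved = False
        best_gain, best_k = 0.0, -1
        for k in np.flatnonzero(~carrier):
            delta = pool_counts[k] * (1.0 - 2.0 * f)
            gain = abs(expected - target_count) - abs(expected + delta - target_count)
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k >= 0:
            carrier[best_k] = True
            expected += pool_counts[best_k] * (1.0 - 2.0 * f)
            improved = True
    col = carrier[assign].astype(np.uint8)
    col ^= (rng.random(n_hap) < f).astype(np.uint8)
    # exact adjustment: flip a random subset towards the target count
    diff = int(col.sum()) - target_count
    if diff > 0:
        idx = rng.choice(np.flatnonzero(col == 1), size=diff, replace=False)
        col[idx] = 0
    elif diff < 0:
        idx = rng.choice(np.flatnonzero(col == 0), size=-diff, replace=False)
        col[idx] = 1
    panel.haplotypes[:, site] = col


def place_dsl(
    panel: FounderPanel,
    role: str,
    founder_maf: float,
    seed: int,
    partner: int | None = None,
    segment: int | None = None,
    tol: float = 0.03,
) -> DslPlacement:
    """Choose (and if needed re-shape) a site for a DSL under a placement role.

    Among sites compatible with ``role`` the one with founder MAF closest to
    ``founder_maf`` is selected; if none is within ``tol`` the nearest
    candidate's column is resampled through the block's ancestral pool to hit
    the target frequency exactly (mutating ``panel`` in place).
    """
    if not 0.0 < founder_maf < 0.5 + 1e-9:
        raise ValueError("founder_maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    cands = _role_candidates(panel, role, partner, segment)
    freqs = panel.minor_freqs()[cands]
    best = int(cands[np.argmin(np.abs(freqs - founder_maf))])
    if abs(panel.minor_freqs()[best] - founder_maf) > tol:
        _resample_column(panel, best, founder_maf, rng)
    return DslPlacement(role=role, site_index=best, founder_maf=founder_maf)


# ---------------------------------------------------------------------------
# Marker QC


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts (Levene/Haldane distribution, as in the standard SNP
    exact-test recurrence) and sums probabilities no larger than the observed
    one.  Monomorphic sites return 1.
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        raise ValueError("no genotypes")
    rare = 2 * min(n_hom_minor, n_hom_major) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0
    # probabilities over het counts with the parity of `rare`, via recurrence
    n_het_possible = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    probs = np.empty(len(n_het_possible), dtype=float)
    # start from the mode region: compute unnormalised probs recursively
    probs[0] = 1.0
    for k in range(1, len(n_het_possible)):
        h = n_het_possible[k]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # P(h) / P(h-2) = 4 * (hom_r + 1) * (hom_c + 1) / (h * (h - 1))
        probs[k] = probs[k - 1] * 4.0 * (hom_r + 1) * (hom_c + 1) / (h * (h - 1.0))
        if probs[k] > 1e250:  # rescale to avoid overflow
            probs /= probs[k]
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(n_het_possible, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def qc_filter(
    genotypes: np.ndarray,
    sites: list[SiteMeta] | None = None,
    maf_min: float = 0.01,
    miss_max: float = 0.10,
    hwe_alpha: float = 5e-15,
) -> np.ndarray:
    """Standard marker QC: returns indices of retained sites.

    Retains sites with minor allele frequency > ``maf_min``, missing-call
    fraction < ``miss_max`` and Hardy-Weinberg exact p >= ``hwe_alpha``.
    ``genotypes`` is samples x sites with dosages in {0, 1, 2} and -1 for
    missing.  Sites whose metadata is not bi-allelic are dropped (the dosage
    representation itself is bi-allelic; the check guards external input).
    """
    g = np.asarray(genotypes)
    if g.size == 0:
        raise ValueError("empty genotype matrix")
    n, m = g.shape
    keep = []
    for j in range(m):
        if sites is not None and len(set(sites[j].alleles)) != 2:
            continue
        col = g[:, j]
        valid = col >= 0
        n_valid = int(valid.sum())
        if n_valid == 0 or 1.0 - n_valid / n >= miss_max:
            continue
        col = col[valid]
        freq = col.sum() / (2.0 * n_valid)
        maf = min(freq, 1.0 - freq)
        if maf <= maf_min:
            continue
        n_het = int(np.sum(col == 1))
        n_hom_alt = int(np.sum(col == 2))
        n_hom_ref = n_valid - n_het - n_hom_alt
        if hwe_exact_p(n_het, min(n_hom_alt, n_hom_ref), max(n_hom_alt, n_hom_ref)) < hwe_alpha:
            continue
        keep.append(j)
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP

_PHENO_TO_STATUS = {"1": 0, "2": 1, "0": MISSING, "-9": MISSING}


def write_ped_map(
    prefix: str | Path,
    dosages: np.ndarray,
    status: np.ndarray,
    sites: list[SiteMeta],
    sample_ids: list[str] | None = None,
) -> None:
    """Write a dataset as PLINK text PED + MAP.

    PED columns: FID IID PAT MAT SEX PHENO then two allele codes per SNP;
    phenotype is 1 = control, 2 = case; missing genotype is "0 0".
    Dosages count the site's minor allele (``sites[j].alleles[0]``).
    """
    prefix = Path(prefix)
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    if m != len(sites):
        raise ValueError("dosage columns and site metadata disagree")
    if sample_ids is None:
        sample_ids = [f"ind{i + 1:05d}" for i in range(n)]
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in sites:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\n")
    geno_codes = np.empty((m, 4), dtype=object)
    for j, s in enumerate(sites):
        minor, major = s.alleles
        geno_codes[j] = [f"{major} {major}", f"{minor} {major}", f"{minor} {minor}", "0 0"]
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(n):
            pheno = {0: "1", 1: "2"}.get(int(status[i]), "0")
            fields = [sample_ids[i], sample_ids[i], "0", "0", "0", pheno]
            row = dosages[i]
            fields.extend(geno_codes[j][row[j] if row[j] >= 0 else 3] for j in range(m))
            fh.write(" ".join(fields) + "\n")


def read_ped_map(
    prefix: str | Path, sites: list[SiteMeta] | None = None
) -> tuple[np.ndarray, np.ndarray, list[SiteMeta], list[str]]:
    """Read PLINK text PED + MAP back into dosages/status/site metadata.

    If ``sites`` is given its allele orientation defines the dosage coding
    (guaranteeing a bit-exact round trip with :func:`write_ped_map`);
    otherwise the minor allele is inferred from the sample (ties broken
    alphabetically).  Returns (dosages, status, sites, sample_ids).
    """
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            chrom, snp_id, _, pos = line.split()
            map_rows.append((chrom, snp_id, int(pos)))
    m = len(map_rows)
    raw_alleles: list[list[tuple[str, str]]] = []
    statuses: list[int] = []
    ids: list[str] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(f"PED line {ln}: expected {6 + 2 * m} fields, got {len(parts)}")
            ids.append(parts[1])
            statuses.append(_PHENO_TO_STATUS.get(parts[5], MISSING))
            raw_alleles.append([(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)])
    n = len(raw_alleles)
    dosages = np.full((n, m), MISSING, dtype=np.int8)
    out_sites: list[SiteMeta] = []
    for j in range(m):
        col = [raw_alleles[i][j] for i in range(n)]
        observed = sorted({a for pair in col for a in pair if a != "0"})
        if len(observed) > 2:
            raise ValueError(f"site {map_rows[j][1]} has more than two allele codes")
        if sites is not None:
            minor, major = sites[j].alleles
        else:
            counts = {a: sum(pair.count(a) for pair in col) for a in observed}
            ordered = sorted(observed, key=lambda a: (counts[a], a))
            if len(ordered) == 1:
                minor, major = "N", ordered[0]  # monomorphic: orientation arbitrary
            else:
                minor, major = ordered[0], ordered[1]
        for i, (a, b) in enumerate(col):
            if a == "0" or b == "0":
                continue
            for al in (a, b):
                if al not in (minor, major):
                    raise ValueError(f"unknown allele code {al!r} at {map_rows[j][1]}")
            dosages[i, j] = (a == minor) + (b == minor)
        chrom, snp_id, pos = map_rows[j]
        out_sites.append(SiteMeta(chromosome=chrom, position=pos, id=snp_id, alleles=(minor, major)))
    return dosages, np.array(statuses, dtype=np.int8), out_sites, ids
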