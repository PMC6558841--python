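"""Forward-time expansion of a founder panel with allele-frequency trajectory control.

The founder cohort is expanded linearly (the same number of individuals added
each generation) to a target size under random mating, with no recombination,
no mutation, no migration and no selection.  Under those rules transmission is
pure label copying: every haplotype in every generation is one of the founder
haplotypes, so individuals are stored as pairs of founder-haplotype labels per
chromosome segment and genotypes are materialised on demand.  This keeps a
full 500-generation expansion to 10,000 individuals well inside desk scale.

Disease-predisposing-allele (DPA) frequencies at designated sites are steered
by trajectory control: each generation must keep every controlled frequency
inside a band around the straight-line path from the founder frequency to the
target; offending generations are redrawn, and a generation that exhausts its
redraw budget restarts the whole run on a fresh random substream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founder_synth import FounderPanel, hwe_exact_p

__all__ = [
    "DemographicModel",
    "TrajectorySpec",
    "Population",
    "TrajectoryError",
    "evolve",
    "allele_freq",
    "materialize",
    "hwe_check",
]


@dataclass(frozen=True)
class DemographicModel:
    """Linear population growth schedule."""

    n_founders: int = 91
    n_final: int = 10_000
    n_generations: int = 500

    def __post_init__(self):
        if self.n_final < self.n_founders:
            raise ValueError("n_final must be >= n_founders")

    def size_at(self, generation: int) -> int:
        """Population size at a generation, N0 + g * (Nf - N0) / G, rounded."""
        if self.n_generations == 0:
            return self.n_founders
        frac = generation / self.n_generations
        return int(round(self.n_founders + frac * (self.n_final - self.n_founders)))


@dataclass(frozen=True)
class TrajectorySpec:
    """Controlled allele-frequency path for one site.

    The acceptance band around the linear interpolation between ``start_freq``
    and ``target_freq`` is relative (``band_rel`` of the current path value)
    with an absolute floor ``band_floor``; ``max_restarts`` caps per-generation
    redraws before the whole run is restarted.
    """

    site_index: int
    start_freq: float
    target_freq: float
    band_rel: float = 0.20
    band_floor: float = 0.02
    max_restarts: int = 100

    def __post_init__(self):
        for f in (self.start_freq, self.target_freq):
            if not 0.0 < f < 1.0:
                raise ValueError("trajectory frequencies must lie in (0, 1)")
        if self.band_rel <= 0 and self.band_floor <= 0:
            raise ValueError("band must be positive")

    def path(self, generation: int, n_generations: int) -> float:
        frac = generation / n_generations if n_generations else 1.0
        return self.start_freq + frac * (self.target_freq - self.start_freq)

    def band(self, generation: int, n_generations: int) -> float:
        return max(self.band_rel * self.path(generation, n_generations), self.band_floor)


@dataclass
class Population:
    """Individuals as founder-haplotype label pairs, one (N, 2) array per segment."""

    labels: list[np.ndarray]
    generation: int = 0

    @property
    def size(self) -> int:
        return self.labels[0].shape[0]


class TrajectoryError(RuntimeError):
    """Raised when trajectory control cannot be satisfied."""


def founder_population(panel: FounderPanel) -> Population:
    n = panel.n_founders
    lab = np.empty((n, 2), dtype=np.int32)
    lab[:, 0] = 2 * np.arange(n)
    lab[:, 1] = 2 * np.arange(n) + 1
    return Population(labels=[lab.copy() for _ in range(panel.n_segments)], generation=0)


def _site_allele_vectors(panel: FounderPanel, trajectories) -> list[tuple[int, np.ndarray]]:
    out = []
    for t in trajectories:
        if not 0 <= t.site_index < panel.n_sites:
            raise IndexError(f"trajectory site {t.site_index} out of range")
        col = panel.haplotypes[:, t.site_index].astype(np.float64)
        if col.sum() == 0:
            raise TrajectoryError(f"target allele absent from founders at site {t.site_index}")
        out.append((panel.segment_of(t.site_index), col))
    return out


def evolve(
    panel: FounderPanel,
    demo: DemographicModel,
    trajectories: list[TrajectorySpec],
    seed: int,
    max_run_restarts: int = 50,
    freq_log: list | None = None,
) -> Population:
    """Run the expansion; returns the final-generation population.

    Each offspring draws two distinct parents uniformly (with replacement
    across offspring); per segment each parent transmits one of its two
    haplotype labels with probability 1/2, segments assorting independently.
    Deterministic given ``seed``.  If ``freq_log`` is a list it receives one
    ``(generation, size, controlled-frequency tuple)`` entry per accepted
    generation of the successful run.
    """
    site_info = _site_allele_vectors(panel, trajectories)
    ss = np.random.SeedSequence(seed)
    for attempt, child in enumerate(ss.spawn(max_run_restarts)):
        rng = np.random.default_rng(child)
        if freq_log is not None:
            freq_log.clear()
        try:
            return _run_once(panel, demo, trajectories, site_info, rng, freq_log)
        except TrajectoryError:
            if attempt == max_run_restarts - 1:
                raise TrajectoryError(
                    f"trajectory control failed after {max_run_restarts} full-run restarts"
                )
    raise AssertionError("unreachable")


def _run_once(panel, demo, trajectories, site_info, rng, freq_log=None) -> Population:
    pop = founder_population(panel)
    n_seg = panel.n_segments
    for g in range(1, demo.n_generations + 1):
        n_prev = pop.size
        n_next = demo.size_at(g)
        max_restarts = min((t.max_restarts for t in trajectories), default=1)
        for _ in range(max(1, max_restarts)):
            p1 = rng.integers(n_prev, size=n_next)
            p2 = (p1 + 1 + rng.integers(n_prev - 1, size=n_next)) % n_prev
            new_labels = []
            for s in range(n_seg):
                prev = pop.labels[s]
                c1 = prev[p1, rng.integers(2, size=n_next)]
                c2 = prev[p2, rng.integers(2, size=n_next)]
                new_labels.append(np.column_stack([c1, c2]))
            ok = True
            for spec, (seg, col) in zip(trajectories, site_info):
                freq = col[new_labels[seg]].mean()
                if abs(freq - spec.path(g, demo.n_generations)) > spec.band(
                    g, demo.n_generations
                ):
                    ok = False
                    break
            if ok:
                pop = Population(labels=new_labels, generation=g)
                if freq_log is not None:
                    freqs = tuple(
                        float(col[new_labels[seg]].mean()) for seg, col in site_info
                    )
                    freq_log.append((g, n_next, freqs))
                break
        else:
            raise TrajectoryError(f"generation {g}: redraw budget exhausted")
    return pop


def allele_freq(pop: Population, panel: FounderPanel, site: int) -> float:
    """Minor-allele frequency at a site: minor-allele count over 2N."""
    seg = panel.segment_of(site)
    col = panel.haplotypes[:, site].astype(np.float64)
    return float(col[pop.labels[seg]].mean())


def materialize(
    pop: Population,
    panel: FounderPanel,
    individuals: np.ndarray | None = None,
    sites: np.ndarray | None = None,
) -> np.ndarray:
    """Unphased dosage matrix for (a subset of) the population.

    Returns individuals x sites minor-allele dosages in {0, 1, 2}.
    """
    if sites is None:
        sites = np.arange(panel.n_sites)
    sites = np.asarray(sites, dtype=int)
    seg_of = np.array([panel.segment_of(s) for s in sites])
    n = pop.size if individuals is None else len(individuals)
    out = np.empty((n, len(sites)), dtype=np.int8)
    for s in range(panel.n_segments):
        cols = np.flatnonzero(seg_of == s)
        if cols.size == 0:
            continue
        lab = pop.labels[s] if individuals is None else pop.labels[s][individuals]
        hap = panel.haplotypes[:, sites[cols]]
        out[:, cols] = hap[lab[:, 0]] + hap[lab[:, 1]]
    return out


def hwe_check(pop: Population, panel: FounderPanel, sites: np.ndarray) -> np.ndarray:
    """Per-site exact HWE p-values for the current population (diagnostic)."""
    dos = materialize(pop, panel, sites=np.asarray(sites, dtype=int))
    pvals = np.empty(dos.shape[1])
    for j in range(dos.shape[1]):
        col = dos[:, j]
        n_het = int(np.sum(col == 1))
        n_hom_alt = int(np.sum(col == 2))
        n_hom_ref = col.shape[0] - n_het - n_hom_alt
        pvals[j] = hwe_exact_p(n_het, min(n_hom_alt, n_hom_ref), max(n_hom_alt, n_hom_ref))
    return pvals
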