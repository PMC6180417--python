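"""Neutral forward Wright-Fisher simulation of replicated diploid populations
with window-based recombination, per-generation single-migrant events, and
pooled-sequencing output.

Populations are N hermaphroditic diploids (selfing excluded), each a pair of
0/1 haplotypes over L biallelic loci with genomic coordinates.  Every
generation N offspring are produced by drawing two distinct parents uniformly
at random (neutral fitness), each contributing one recombinant gamete.
Crossover counts per 100-kb window are Poisson with half the female map rate
(males do not recombine, so every meiosis gets the sex-averaged rate), and
breakpoints fall uniformly within their window.  Migration replaces one
uniformly chosen resident with a migrant whose haplotypes are drawn at
linkage equilibrium from the opposite group's founding allele frequencies,
holding N fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .poolseq import SyncTable

__all__ = [
    "HaplotypePopulation", "RecombMap", "MigrationPlan", "ScenarioResult",
    "found_population", "next_generation", "apply_migration", "run_scenario",
    "pool_sequence",
]

WINDOW_BP = 100_000


@dataclass
class HaplotypePopulation:
    """N diploids as 2N haplotypes over L mapped biallelic loci."""

    chrom: np.ndarray       # (L,) str
    pos: np.ndarray         # (L,) int bp
    haplotypes: np.ndarray  # (2N, L) uint8 in {0, 1}

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] % 2:
            raise ValueError("need an even number of haplotypes")
        if self.haplotypes.shape[1] != len(self.pos):
            raise ValueError("haplotype length must match locus count")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def freq(self) -> np.ndarray:
        """Frequency of the '1' allele at each locus."""
        return self.haplotypes.mean(axis=0)

    def expected_het(self) -> np.ndarray:
        p = self.freq()
        return 2.0 * p * (1.0 - p)


@dataclass
class RecombMap:
    """Female crossover rates per 100-kb window; the applied per-meiosis rate
    is female/2 to average over the absence of male recombination."""

    windows: dict  # chrom -> (window_starts ascending, female rates), both arrays

    def __post_init__(self):
        clean = {}
        for ch, (starts, rates) in self.windows.items():
            starts = np.asarray(starts, dtype=np.int64)
            rates = np.asarray(rates, dtype=float)
            if (rates < 0).any():
                raise ValueError("recombination rates must be non-negative")
            clean[ch] = (starts, rates)
        self.windows = clean

    @classmethod
    def uniform(cls, chrom_lengths: dict, rate_per_window: float) -> "RecombMap":
        wins = {}
        for ch, ln in chrom_lengths.items():
            starts = np.arange(0, ln, WINDOW_BP, dtype=np.int64)
            wins[ch] = (starts, np.full(len(starts), rate_per_window))
        return cls(wins)

    def effective(self, ch):
        starts, rates = self.windows[ch]
        return starts, rates / 2.0


def found_population(freqs, chrom=None, pos=None, N: int = 1000, seed=None) -> HaplotypePopulation:
    """Found a population from per-locus allele frequencies.

    Per locus, exactly round(2N * p) copies (ties rounded up) of the '1'
    allele are dealt uniformly at random over the 2N haplotype slots and loci
    are independent — the pot-of-2N-alleles scheme, which fixes the founding
    count instead of drawing it binomially and founds at linkage equilibrium.
    """
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    L = len(freqs)
    if chrom is None:
        chrom = np.array(["sim"] * L, dtype=object)
    if pos is None:
        pos = np.arange(1, L + 1, dtype=np.int64) * 1000
    rng = np.random.default_rng(seed)
    k = np.floor(2 * N * freqs + 0.5).astype(np.int64)  # ties up
    hap = (np.arange(2 * N)[:, None] < k[None, :]).astype(np.uint8)
    hap = rng.permuted(hap, axis=0)
    return HaplotypePopulation(chrom=np.asarray(chrom, dtype=object),
                               pos=np.asarray(pos, dtype=np.int64), haplotypes=hap)


def _chrom_slices(chrom: np.ndarray):
    slices = []
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            slices.append((chrom[start], slice(start, i)))
            start = i
    return slices


def _gametes(pop: HaplotypePopulation, parent_idx: np.ndarray,
             rmap: RecombMap | None, rng) -> np.ndarray:
    """One gamete per listed parent.  Chromosomes assort independently; within
    a chromosome the starting strand is random and strands switch at each
    crossover breakpoint."""
    hap = pop.haplotypes
    n = len(parent_idx)
    out = np.empty((n, pop.n_loci), dtype=np.uint8)
    for ch, sl in _chrom_slices(pop.chrom):
        strand = rng.integers(0, 2, n)
        rows = hap[2 * parent_idx + strand, sl]
        if rmap is not None and ch in rmap.windows:
            starts, eff = rmap.effective(ch)
            lam = eff.sum()
            if lam > 0:
                kx = rng.poisson(lam, n)
                hot = np.nonzero(kx)[0]
                if len(hot):
                    rows = rows.copy()
                    probs = eff / lam
                    loc_pos = pop.pos[sl]
                    for i in hot:
                        widx = rng.choice(len(starts), size=kx[i], p=probs)
                        bps = starts[widx] + rng.random(kx[i]) * WINDOW_BP
                        sw = (np.searchsorted(np.sort(bps), loc_pos) % 2).astype(bool)
                        other = hap[2 * parent_idx[i] + 1 - strand[i], sl]
                        rows[i, sw] = other[sw]
        out[:, sl] = rows
    return out


def next_generation(pop: HaplotypePopulation, rmap: RecombMap | None = None,
                    seed=None, rng=None) -> HaplotypePopulation:
    """One non-overlapping Wright-Fisher generation: N offspring from
    uniformly drawn distinct parent pairs, one gamete per parent."""
    if pop.n < 2:
        raise ValueError("need at least 2 individuals to mate")
    if rng is None:
        rng = np.random.default_rng(seed)
    N = pop.n
    p1 = rng.integers(0, N, N)
    p2 = (p1 + 1 + rng.integers(0, N - 1, N)) % N  # distinct from p1, uniform
    g1 = _gametes(pop, p1, rmap, rng)
    g2 = _gametes(pop, p2, rmap, rng)
    hap = np.empty_like(pop.haplotypes)
    hap[0::2] = g1
    hap[1::2] = g2
    return HaplotypePopulation(chrom=pop.chrom, pos=pop.pos, haplotypes=hap)


def apply_migration(pop: HaplotypePopulation, source_freqs: np.ndarray,
                    n_migrants: int = 1, seed=None, rng=None) -> HaplotypePopulation:
    """Replace ``n_migrants`` uniformly chosen residents with migrants drawn
    per locus at linkage equilibrium from ``source_freqs``; N is unchanged."""
    if n_migrants == 0:
        return pop
    if rng is None:
        rng = np.random.default_rng(seed)
    source_freqs = np.asarray(source_freqs, dtype=float)
    hap = pop.haplotypes.copy()
    targets = rng.choice(pop.n, size=n_migrants, replace=False)
    for ind in targets:
        mig = (rng.random((2, pop.n_loci)) < source_freqs).astype(np.uint8)
        hap[2 * ind:2 * ind + 2] = mig
    return HaplotypePopulation(chrom=pop.chrom, pos=pop.pos, haplotypes=hap)


@dataclass
class MigrationPlan:
    """Per-generation migrant schedule for two groups of replicates.

    ``events_per_generation`` single-migrant events are split evenly between
    the groups; each group's receiving replicates are assigned by cycling
    deterministically through 1..n_replicates (or uniformly at random)."""

    events_per_generation: int = 0
    assignment: str = "cycle"

    def __post_init__(self):
        if self.events_per_generation % 2:
            raise ValueError("events must split evenly between the two groups")
        if self.assignment not in ("cycle", "random"):
            raise ValueError("assignment must be 'cycle' or 'random'")

    def receivers(self, generation: int, n_replicates: int, rng) -> np.ndarray:
        k = self.events_per_generation // 2
        if k == 0:
            return np.empty(0, dtype=int)
        if k >= n_replicates:
            return np.arange(n_replicates)
        if self.assignment == "cycle":
            return (generation * k + np.arange(k)) % n_replicates
        return rng.choice(n_replicates, size=k, replace=False)


@dataclass
class ScenarioResult:
    pops_a: list
    pops_b: list
    trajectory: "pd.DataFrame | None" = None


def run_scenario(founding_freqs_a, founding_freqs_b, N: int = 1000,
                 generations: int = 230, rmap: RecombMap | None = None,
                 plan: MigrationPlan | None = None, chrom=None, pos=None,
                 seed=None, record_every: int | None = None) -> ScenarioResult:
    """Simulate two groups of replicate populations forward in time.

    Each replicate is founded from its group's frequency vector; every
    generation applies reproduction then the migration plan.  Migrants into a
    group carry the *opposite* group's mean founding frequencies.  Frequency
    snapshots (mean over replicates, per group) are recorded every
    ``record_every`` generations when requested.
    """
    import pandas as pd

    plan = plan or MigrationPlan(0)
    ffa = [np.asarray(f, dtype=float) for f in founding_freqs_a]
    ffb = [np.asarray(f, dtype=float) for f in founding_freqs_b]
    src_into_a = np.mean(ffb, axis=0)  # group A receives group-B migrants
    src_into_b = np.mean(ffa, axis=0)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(ffa) + len(ffb) + 1)
    rngs = [np.random.default_rng(s) for s in child_seeds[:-1]]
    plan_rng = np.random.default_rng(child_seeds[-1])
    pops_a = [found_population(f, chrom, pos, N=N, seed=r)
              for f, r in zip(ffa, rngs[:len(ffa)])]
    pops_b = [found_population(f, chrom, pos, N=N, seed=r)
              for f, r in zip(ffb, rngs[len(ffa):])]
    rngs_a, rngs_b = rngs[:len(ffa)], rngs[len(ffa):]

    snaps = []

    def snapshot(gen):
        snaps.append({"generation": gen,
                      "freq_a": np.mean([p.freq() for p in pops_a], axis=0),
                      "freq_b": np.mean([p.freq() for p in pops_b], axis=0)})

    if record_every:
        snapshot(0)
    for gen in range(generations):
        for i in range(len(pops_a)):
            pops_a[i] = next_generation(pops_a[i], rmap, rng=rngs_a[i])
        for i in range(len(pops_b)):
            pops_b[i] = next_generation(pops_b[i], rmap, rng=rngs_b[i])
        for i in plan.receivers(gen, len(pops_a), plan_rng):
            pops_a[i] = apply_migration(pops_a[i], src_into_a, 1, rng=rngs_a[i])
        for i in plan.receivers(gen, len(pops_b), plan_rng):
            pops_b[i] = apply_migration(pops_b[i], src_into_b, 1, rng=rngs_b[i])
        if record_every and (gen + 1) % record_every == 0:
            snapshot(gen + 1)

    traj = None
    if snaps:
        rows = []
        for s in snaps:
            rows.append({"generation": s["generation"],
                         "mean_freq_a": float(s["freq_a"].mean()),
                         "mean_freq_b": float(s["freq_b"].mean()),
                         "mean_abs_gap": float(np.abs(s["freq_a"] - s["freq_b"]).mean())})
        traj = pd.DataFrame(rows)
    return ScenarioResult(pops_a=pops_a, pops_b=pops_b, trajectory=traj)


def pool_sequence(pops, depth: int = 50, seed=None, ref: str = "A") -> SyncTable:
    """Pooled sequencing of one or more populations at uniform ``depth``:
    per site the '1'-allele read count is Binomial(depth, population
    frequency).  The '1' allele is written as T, the '0' allele as A."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if isinstance(pops, HaplotypePopulation):
        pops = [pops]
    rng = np.random.default_rng(seed)
    first = pops[0]
    n_sites = first.n_loci
    counts = np.zeros((n_sites, len(pops), 6), dtype=np.int64)
    for j, p in enumerate(pops):
        minor = rng.binomial(depth, p.freq())
        counts[:, j, 1] = minor
        counts[:, j, 0] = depth - minor
    return SyncTable(chrom=first.chrom, pos=first.pos,
                     ref=np.array([ref] * n_sites, dtype=object), counts=counts)
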