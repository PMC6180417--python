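"""Pool-seq genomics: sync I/O, SNP calling, heterozygosity, F_ST and genome scans.

The sync format is the PoPoolation2 convention: one line per site with
``chrom  pos  ref  A:T:C:G:N:del`` count strings, one per population, with
1-based positions.  Downstream, sites are reduced to biallelic major/minor
counts and compared between two groups of replicate populations with either a
stratified Cochran-Mantel-Haenszel test (replicate *i* of one group paired
with replicate *i* of the other forms stratum *i*) or a per-site quasibinomial
GLM.  Genome-wide significance for the CMH scan comes from a permutation null
built from the minimum p-value across label-shuffled scans.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phenostats import cmh_counts

logger = logging.getLogger(__name__)

#: base order of the count sextet in a sync line
SYNC_BASES = ("A", "T", "C", "G", "N", "del")
#: alphabetical precedence of A/T/C/G used to break count ties (A<C<G<T)
_ALPHA_RANK = np.array([0, 3, 1, 2])


class SyncParseError(ValueError):
    """Raised when a sync line cannot be parsed; carries the 1-based line number."""


@dataclass
class SyncTable:
    """Per-site nucleotide counts for one or more pooled populations."""

    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray    # (n_sites,) int, 1-based
    ref: np.ndarray    # (n_sites,) str
    counts: np.ndarray  # (n_sites, n_pops, 6) int: A,T,C,G,N,del

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must have shape (n_sites, n_pops, 6)")
        if (self.counts < 0).any():
            raise ValueError("negative allele counts")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_pops(self) -> int:
        return self.counts.shape[1]


def read_sync(path) -> SyncTable:
    """Parse a sync file.  Malformed count strings raise :class:`SyncParseError`
    with the offending 1-based line number."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 4:
        raise SyncParseError("sync file needs chrom, pos, ref and >=1 count column")
    n_pops = df.shape[1] - 3
    counts = np.empty((len(df), n_pops, 6), dtype=np.int64)
    for j in range(n_pops):
        parts = df.iloc[:, 3 + j].str.split(":", expand=True)
        bad = parts.isna().any(axis=1) if parts.shape[1] == 6 else pd.Series(True, index=df.index)
        if parts.shape[1] != 6 or bad.any():
            line = int(bad.idxmax()) + 1 if parts.shape[1] == 6 else 1
            raise SyncParseError(f"malformed count string in population column {j + 1}, line {line}")
        try:
            counts[:, j, :] = parts.to_numpy(dtype=np.int64)
        except ValueError as exc:
            raise SyncParseError(f"non-integer count in population column {j + 1}: {exc}") from exc
    return SyncTable(
        chrom=df.iloc[:, 0].to_numpy(dtype=object),
        pos=df.iloc[:, 1].to_numpy(dtype=np.int64),
        ref=df.iloc[:, 2].to_numpy(dtype=object),
        counts=counts,
    )


def write_sync(table: SyncTable, path) -> None:
    """Write a :class:`SyncTable` in sync format (lossless round trip)."""
    with open(path, "w") as fh:
        for i in range(table.n_sites):
            cells = [":".join(str(c) for c in table.counts[i, j]) for j in range(table.n_pops)]
            fh.write(f"{table.chrom[i]}\t{table.pos[i]}\t{table.ref[i]}\t" + "\t".join(cells) + "\n")


@dataclass
class SNPTable:
    """Called biallelic sites with per-population major/minor allele counts."""

    chrom: np.ndarray
    pos: np.ndarray
    major: np.ndarray  # (n_sites,) base of the genome-wide major allele
    minor: np.ndarray
    major_counts: np.ndarray  # (n_sites, n_pops)
    minor_counts: np.ndarray
    triallelic: np.ndarray = None  # sites collapsed from >2 segregating alleles

    def __post_init__(self) -> None:
        if self.triallelic is None:
            self.triallelic = np.zeros(len(self.pos), dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_pops(self) -> int:
        return self.major_counts.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        return self.major_counts + self.minor_counts

    def minor_freq(self) -> np.ndarray:
        """Per-population minor-allele frequency, shape (n_sites, n_pops)."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.minor_counts / cov, np.nan)

    def pooled_maf(self) -> np.ndarray:
        tot = self.major_counts.sum(axis=1) + self.minor_counts.sum(axis=1)
        return self.minor_counts.sum(axis=1) / tot

    def subset(self, mask: np.ndarray) -> "SNPTable":
        return SNPTable(
            self.chrom[mask], self.pos[mask], self.major[mask], self.minor[mask],
            self.major_counts[mask], self.minor_counts[mask], self.triallelic[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                           "major": self.major, "minor": self.minor})
        for j in range(self.n_pops):
            df[f"maj{j}"] = self.major_counts[:, j]
            df[f"min{j}"] = self.minor_counts[:, j]
        return df


def call_snps(sync: SyncTable, min_cov: int = 30, max_cov: int = 200,
              min_maf: float = 0.02) -> SNPTable:
    """Call biallelic SNPs from a sync table.

    A site is retained when every population's A+T+C+G coverage lies in
    ``[min_cov, max_cov]`` and the pooled (summed over populations) minor
    allele frequency is at least ``min_maf``.  Major/minor alleles are decided
    from counts summed across populations; ties break alphabetically.  Sites
    with a third segregating allele are collapsed to the top two and flagged.
    """
    acgt = sync.counts[:, :, :4]
    cov = acgt.sum(axis=2)
    keep = ((cov >= min_cov) & (cov <= max_cov)).all(axis=1)

    totals = acgt.sum(axis=1)  # (n_sites, 4)
    # composite sort key: higher count wins, alphabetical on ties
    key = totals * 4 + (3 - _ALPHA_RANK)
    order = np.argsort(-key, axis=1, kind="stable")
    maj_idx, min_idx = order[:, 0], order[:, 1]
    rows = np.arange(len(totals))
    maj_tot = totals[rows, maj_idx]
    min_tot = totals[rows, min_idx]
    third_tot = totals.sum(axis=1) - maj_tot - min_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(maj_tot + min_tot > 0, min_tot / (maj_tot + min_tot), 0.0)
    keep &= maf >= min_maf
    keep &= min_tot > 0

    bases = np.array(["A", "T", "C", "G"], dtype=object)
    tri = (third_tot > 0) & keep
    if tri.any():
        logger.info("collapsed %d sites with >2 segregating alleles to top two", int(tri.sum()))
    return SNPTable(
        chrom=sync.chrom[keep],
        pos=sync.pos[keep],
        major=bases[maj_idx[keep]],
        minor=bases[min_idx[keep]],
        major_counts=acgt[rows[keep][:, None], np.arange(sync.n_pops)[None, :], maj_idx[keep][:, None]],
        minor_counts=acgt[rows[keep][:, None], np.arange(sync.n_pops)[None, :], min_idx[keep][:, None]],
        triallelic=(third_tot > 0)[keep],
    )


def rescale_coverage(snps: SNPTable, target: int = 50, min_cov: int = 50,
                     max_cov: int = 200) -> SNPTable:
    """Rescale every population's counts to a uniform ``target`` coverage.

    Sites where any population's major+minor coverage falls outside
    ``[min_cov, max_cov]`` are dropped.  The minor count is the frequency
    linearly scaled to ``target`` and rounded to the nearest integer (ties to
    even); major = target - minor, so frequency is preserved to within
    1/(2*target).
    """
    if target > min_cov:
        raise ValueError("target coverage must not exceed the minimum coverage filter")
    cov = snps.coverage
    keep = ((cov >= min_cov) & (cov <= max_cov)).all(axis=1)
    sub = snps.subset(keep)
    cov = sub.coverage
    minor = np.rint(target * sub.minor_counts / cov).astype(np.int64)
    return SNPTable(sub.chrom, sub.pos, sub.major, sub.minor,
                    target - minor, minor, sub.triallelic)


# ---------------------------------------------------------------------------
# heterozygosity and F_ST


def window_heterozygosity(snps: SNPTable, window: int = 150_000) -> pd.DataFrame:
    """Per-population mean expected heterozygosity 2p(1-p) in non-overlapping
    windows of ``window`` bp (0-based half-open; a 1-based site at ``pos``
    falls in window ``(pos-1)//window``).  Windows with no SNPs are omitted."""
    p = snps.minor_freq()
    het = 2.0 * p * (1.0 - p)
    win = (snps.pos - 1) // window
    df = pd.DataFrame({"chrom": snps.chrom, "win": win})
    for j in range(snps.n_pops):
        df[f"het{j}"] = het[:, j]
    out = df.groupby(["chrom", "win"], sort=True).agg(
        n_snps=("win", "size"), **{f"het{j}": (f"het{j}", "mean") for j in range(snps.n_pops)}
    ).reset_index()
    out["start"] = out["win"] * window
    out["end"] = (out["win"] + 1) * window
    cols = ["chrom", "start", "end", "n_snps"] + [f"het{j}" for j in range(snps.n_pops)]
    return out[cols]


def group_mean_het(snps: SNPTable, pops: Sequence[int]) -> np.ndarray:
    """Genome-wide mean expected heterozygosity for each listed population."""
    p = snps.minor_freq()[:, list(pops)]
    return np.nanmean(2.0 * p * (1.0 - p), axis=0)


def het_ttest(means_a: np.ndarray, means_b: np.ndarray) -> tuple[float, float]:
    """Two-sample t-test on per-population genome-wide mean heterozygosities."""
    t, p = stats.ttest_ind(means_a, means_b)
    return float(t), float(p)


def fst(snps: SNPTable, pops: Sequence[int]) -> tuple[np.ndarray, float]:
    """Per-site F_ST = (H_T - H_S)/H_T across the replicate populations ``pops``.

    H_T uses the unweighted mean minor-allele frequency across replicates;
    H_S is the mean of the per-replicate 2p(1-p).  Sites with H_T = 0 are
    skipped (NaN).  Returns (per-site values, mean over valid sites).
    """
    if len(pops) < 2:
        raise ValueError("need >=2 populations for F_ST")
    p = snps.minor_freq()[:, list(pops)]
    pbar = p.mean(axis=1)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p * (1.0 - p)).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(ht > 0, (ht - hs) / ht, np.nan)
    return per_site, float(np.nanmean(per_site))


# ---------------------------------------------------------------------------
# genome scans


@dataclass
class ScanResult:
    """Per-site p-values from a differentiation scan."""

    chrom: np.ndarray
    pos: np.ndarray
    p: np.ndarray
    test: str
    threshold: float | None = None       # permutation-derived genome-wide cutoff
    q: np.ndarray | None = None          # Storey q-values when computed
    sig: np.ndarray | None = None        # significant-site mask
    flags: np.ndarray | None = None      # per-site fit diagnostics

    def neglog10(self) -> np.ndarray:
        return -np.log10(self.p)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "p": self.p})
        if self.q is not None:
            df["q"] = self.q
        if self.sig is not None:
            df["sig"] = self.sig.astype(int)
        return df


def _paired_strata(snps: SNPTable, group_a: Sequence[int], group_b: Sequence[int]):
    a = snps.minor_counts[:, list(group_a)]
    b = snps.minor_counts[:, list(group_b)]
    c = snps.major_counts[:, list(group_a)]
    d = snps.major_counts[:, list(group_b)]
    return a, b, c, d


def cmh_scan(snps: SNPTable, group_a: Sequence[int], group_b: Sequence[int],
             continuity: bool = True) -> ScanResult:
    """Cochran-Mantel-Haenszel scan: at each site, replicate ``i`` of group A
    is paired with replicate ``i`` of group B to form stratum ``i`` of a
    (minor, major) x (group) table; the stratified statistic (with continuity
    correction by default) is referred to a chi-square with 1 df."""
    if len(group_a) != len(group_b):
        raise ValueError("groups must have equal size for paired strata")
    a, b, c, d = _paired_strata(snps, group_a, group_b)
    _, p = cmh_counts(a, b, c, d, continuity=continuity)
    return ScanResult(snps.chrom, snps.pos, p, test="cmh")


def _balanced_partitions(pops: Sequence[int]):
    pops = list(pops)
    k = len(pops) // 2
    seen = set()
    out = []
    for comb in itertools.combinations(pops, k):
        rest = tuple(sorted(set(pops) - set(comb)))
        key = frozenset((comb, rest))
        if key not in seen:
            seen.add(key)
            out.append((list(comb), list(rest)))
    return out


def permutation_threshold(snps: SNPTable, group_a: Sequence[int], group_b: Sequence[int],
                          n_perm: int = 1000, fwer: float = 0.05,
                          seed=None, continuity: bool = True) -> float:
    """Genome-wide p-value threshold at family-wise error ``fwer``.

    The pooled populations are repeatedly re-assigned at random to two
    balanced groups (sampling with replacement from all distinct balanced
    partitions, the original included); each shuffle records the smallest CMH
    p-value across sites, and the threshold is the ``fwer`` quantile of those
    minima.
    """
    pops = list(group_a) + list(group_b)
    k = len(pops) // 2
    if len(pops) % 2:
        raise ValueError("need an even number of populations")
    n_part = _n_balanced_partitions(len(pops))
    if n_part < 3:
        raise ValueError("fewer than 3 distinct balanced partitions; permutation null undefined")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable quantile")
    rng = np.random.default_rng(seed)
    minps = np.empty(n_perm)
    pops_arr = np.array(pops)
    for i in range(n_perm):
        perm = rng.permutation(pops_arr)
        res = cmh_scan(snps, perm[:k], perm[k:], continuity=continuity)
        minps[i] = res.p.min()
    return float(np.quantile(minps, fwer))


def _n_balanced_partitions(n: int) -> int:
    from math import comb
    return comb(n, n // 2) // 2


def glm_scan(snps: SNPTable, group_a: Sequence[int], group_b: Sequence[int]) -> ScanResult:
    """Quasibinomial GLM scan of minor-allele counts on group membership.

    Whenever a population has a zero count for either allele at a site, one is
    added to each of its two allele counts before fitting.  With a single
    binary covariate the quasibinomial fit has a closed form: the fitted
    group frequencies are the coverage-weighted pooled frequencies, the
    dispersion is the Pearson chi-square over its n_pops - 2 residual df, and
    the group contrast is tested with a dispersion-scaled t statistic on those
    df.  Uniform (rescaled) coverage is recommended upstream.
    """
    ga, gb = list(group_a), list(group_b)
    minor = snps.minor_counts[:, ga + gb].astype(float)
    major = snps.major_counts[:, ga + gb].astype(float)
    zero = (minor == 0) | (major == 0)
    minor = minor + zero
    major = major + zero
    cov = minor + major
    n_a = len(ga)
    n_pops = cov.shape[1]
    df_resid = n_pops - 2
    if df_resid <= 0:
        raise ValueError("need more than 2 populations for the quasibinomial scan")

    def pooled(sl):
        return minor[:, sl].sum(axis=1) / cov[:, sl].sum(axis=1)

    pa = pooled(slice(0, n_a))
    pb = pooled(slice(n_a, None))
    phat = np.concatenate([np.repeat(pa[:, None], n_a, axis=1),
                           np.repeat(pb[:, None], n_pops - n_a, axis=1)], axis=1)
    # Pearson dispersion over the 10 replicate observations, 2 fitted params
    y = minor / cov
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = ((y - phat) ** 2 * cov / (phat * (1 - phat))).sum(axis=1)
    # dispersion floored away from zero: a perfect within-group fit would
    # otherwise zero the SE even for a real contrast
    disp = np.maximum(pearson / df_resid, 1e-12)
    beta = np.log(pb / (1 - pb)) - np.log(pa / (1 - pa))
    wa = cov[:, :n_a].sum(axis=1) * pa * (1 - pa)
    wb = cov[:, n_a:].sum(axis=1) * pb * (1 - pb)
    var = disp * (1.0 / wa + 1.0 / wb)
    bad = ~np.isfinite(var) | (var <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / np.sqrt(var)
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    p = np.where(bad, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return ScanResult(snps.chrom, snps.pos, p, test="quasibinomial_glm", flags=bad)


# ---------------------------------------------------------------------------
# multiple testing and regions


def storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value vector")
    pi0 = min(1.0, (p > lam).sum() / ((1.0 - lam) * m))
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def correct(p: np.ndarray, method: str = "bonferroni", level: float = 0.05,
            lam: float = 0.5) -> tuple[np.ndarray, np.ndarray | None]:
    """Multiple-testing correction.

    ``bonferroni``: significant where p < level/m (returns (mask, None)).
    ``qvalue``: Storey q-values, significant where q <= level
    (returns (mask, qvalues)).
    """
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if method == "bonferroni":
        return p < level / len(p), None
    if method == "qvalue":
        q = storey_qvalues(p, lam=lam)
        return q <= level, q
    raise ValueError(f"unknown correction method: {method}")


def merge_regions(chrom: np.ndarray, pos: np.ndarray, max_gap: int = 50_000) -> pd.DataFrame:
    """Merge significant sites into regions: maximal runs of same-chromosome
    sites with inter-site gap <= ``max_gap``.  Returned as BED-style 0-based
    half-open intervals with the site count per region."""
    df = pd.DataFrame({"chrom": chrom, "pos": pos}).sort_values(["chrom", "pos"])
    regions = []
    for ch, sub in df.groupby("chrom", sort=True):
        ps = sub["pos"].to_numpy()
        start = ps[0]
        prev = ps[0]
        n = 1
        for x in ps[1:]:
            if x - prev > max_gap:
                regions.append((ch, int(start) - 1, int(prev), n))
                start, n = x, 0
            prev = x
            n += 1
        regions.append((ch, int(start) - 1, int(prev), n))
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_sites"])
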