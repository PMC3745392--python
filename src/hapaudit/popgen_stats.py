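"""Diversity statistics and frequency tests computed from first principles.

Haplotype diversity uses Nei's (1987) unbiased estimator with its
sampling variance::

    h   = n/(n-1) * (1 - sum p_i^2)
    V(h) = 2/(n(n-1)) * { 2(n-2)[sum p_i^3 - (sum p_i^2)^2]
                          + sum p_i^2 - (sum p_i^2)^2 }

Nucleotide diversity per site is the unbiased mean pairwise difference::

    pi = n/(n-1) * sum_{i<j} 2 p_i p_j d_ij / L

Its confidence interval uses the total (stochastic + sampling) variance
of Tajima (1983)::

    V_T(pi) = (n+1) pi / (3 (n-1) L) + 2 (n^2 + n + 3) pi^2 / (9 n (n-1))

the sampling-only component (first term) is exposed separately.  All
confidence intervals are 95% normal intervals truncated to the
statistic's natural range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from hapaudit.haplotyping import Haplotype
from hapaudit.io_formats import CountTable, SequenceRecord

Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)

_RESOLVED = frozenset("ACGT")


@dataclass(frozen=True)
class DiversityStats:
    """Per-population summary statistics (one Table-3-style row)."""

    label: str
    n: int
    k: int
    h: float
    v_h: float
    ci_h: tuple[float, float]
    pi: float
    v_pi_total: float
    v_pi_sampling: float
    ci_pi: tuple[float, float]
    s: int
    composition: dict[str, float]
    gc_percent: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def haplotype_diversity(counts) -> tuple[float, float, tuple[float, float]]:
    """Unbiased haplotype diversity, its variance and 95% CI.

    ``counts`` are per-haplotype individual counts for one population;
    zero entries are ignored.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError(f"need at least 2 individuals, got {int(n)}")
    p = c / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n / (n - 1) * (1 - s2)
    v = 2 / (n * (n - 1)) * (2 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    half = Z95 * np.sqrt(max(v, 0.0))
    ci = (max(0.0, h - half), min(1.0, h + half))
    return float(h), float(v), ci


def pairwise_diff_matrix(haplotypes: list[Haplotype]) -> np.ndarray:
    """Pairwise nucleotide differences between haplotype sequences.

    Positions where either sequence has an unresolved base (N, ambiguity
    code or gap) are pairwise-deleted.
    """
    seqs = [h.seq for h in haplotypes]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("haplotype sequences differ in length")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    resolved = np.isin(arr, [b"A", b"C", b"G", b"T"])
    k = len(seqs)
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            ok = resolved[i] & resolved[j]
            d[i, j] = d[j, i] = int(((arr[i] != arr[j]) & ok).sum())
    return d


def nucleotide_diversity(
    counts, d: np.ndarray, L: int
) -> tuple[float, float, float, tuple[float, float]]:
    """Per-site nucleotide diversity with Tajima total-variance CI.

    Returns ``(pi, v_total, v_sampling, (lo, hi))``.
    """
    c = np.asarray(counts, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.shape != (len(c), len(c)):
        raise ValueError(f"distance matrix {d.shape} does not match {len(c)} counts")
    if L <= 0:
        raise ValueError("L must be positive")
    n = c.sum()
    if n < 2:
        raise ValueError("need at least 2 individuals")
    p = c / n
    pi = float(n / (n - 1) * (p @ d @ p) / L)  # off-diagonal double sum
    v_sampling = (n + 1) * pi / (3 * (n - 1) * L)
    v_total = v_sampling + 2 * (n**2 + n + 3) * pi**2 / (9 * n * (n - 1))
    half = Z95 * np.sqrt(v_total)
    ci = (max(0.0, pi - half), pi + half)
    return pi, float(v_total), float(v_sampling), ci


def segregating_sites(haplotypes: list[Haplotype]) -> int:
    """Number of columns with >= 2 distinct resolved bases."""
    seqs = [h.seq for h in haplotypes]
    if not seqs:
        return 0
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences differ in length")
    s = 0
    for col in zip(*seqs):
        if len({b for b in col if b in _RESOLVED}) >= 2:
            s += 1
    return s


def base_composition(records) -> tuple[dict[str, float], float]:
    """Percent A/C/G/T over resolved bases only, plus GC percent."""
    tally = {b: 0 for b in "ACGT"}
    for rec in records:
        seq = rec.seq if isinstance(rec, (Haplotype, SequenceRecord)) else rec
        for b in seq:
            if b in tally:
                tally[b] += 1
    total = sum(tally.values())
    if total == 0:
        raise ValueError("no resolved bases")
    pct = {b: 100.0 * v / total for b, v in tally.items()}
    return pct, pct["G"] + pct["C"]


def chi_square_unique(table: CountTable) -> ChiSquareResult:
    """Pearson chi-square on unique vs non-unique haplotypes per site.

    For each site, haplotypes found only there are 'unique' and
    haplotypes found there and elsewhere are 'shared'; a haplotype
    contributes to every site where it occurs.  No continuity
    correction; df = number of sites - 1.
    """
    if len(table.site_ids) < 2:
        raise ValueError("need at least 2 sites")
    positive = table.counts > 0
    sampled = positive.any(axis=1)
    pos = positive[sampled]
    n_sites_of = pos.sum(axis=1)
    unique = ((pos & (n_sites_of[:, None] == 1)).sum(axis=0)).astype(int)
    present = pos.sum(axis=0).astype(int)
    if (present == 0).any():
        empty = [s for s, c in zip(table.site_ids, present) if c == 0]
        raise ValueError(f"site(s) with no haplotypes: {empty}")
    observed = np.vstack([unique, present - unique])
    return pearson_chi2(observed)


def pearson_chi2(observed) -> ChiSquareResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    observed = np.asarray(observed)
    statistic, p, df, expected = stats.chi2_contingency(observed, correction=False)
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        observed=observed,
        expected=expected,
    )


def compare_diversity(
    stat1: float, se1: float, stat2: float, se2: float, df: int
) -> tuple[float, float]:
    """Two-tailed t-test for a difference between two estimates.

    ``t = |stat1 - stat2| / sqrt(se1^2 + se2^2)`` with the caller's df.
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    pooled = np.hypot(se1, se2)
    if pooled == 0:
        raise ValueError("zero pooled standard error")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = abs(stat1 - stat2) / pooled
    p = 2 * stats.t.sf(t, df)
    return float(t), float(p)


def diversity_stats(
    label: str,
    haplotypes: list[Haplotype],
    counts,
    L: int | None = None,
) -> DiversityStats:
    """Bundle all per-population statistics for one sample.

    ``counts[i]`` is the number of individuals carrying ``haplotypes[i]``
    in this population; rows with zero count still inform nothing and are
    dropped internally.
    """
    counts = np.asarray(counts, dtype=int)
    keep = counts > 0
    haps = [h for h, k in zip(haplotypes, keep) if k]
    c = counts[keep]
    if L is None:
        L = len(haps[0].seq)
    h, v_h, ci_h = haplotype_diversity(c)
    d = pairwise_diff_matrix(haps)
    pi, v_t, v_s, ci_pi = nucleotide_diversity(c, d, L)
    expanded = [hap for hap, k in zip(haps, c) for _ in range(k)]
    comp, gc = base_composition(expanded)
    return DiversityStats(
        label=label,
        n=int(c.sum()),
        k=len(c),
        h=h,
        v_h=v_h,
        ci_h=ci_h,
        pi=pi,
        v_pi_total=v_t,
        v_pi_sampling=v_s,
        ci_pi=ci_pi,
        s=segregating_sites(haps),
        composition=comp,
        gc_percent=gc,
    )
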