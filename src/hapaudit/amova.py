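"""One-level analysis of molecular variance on haplotype sequences.

The total sum of squared deviations over individuals is decomposed into
among- and within-population components using squared pairwise sequence
distances (Excoffier-style)::

    SSD(total)  = (1/N)  sum_{i<j} delta2_ij
    SSD(within) = sum_g (1/n_g) sum_{i<j in g} delta2_ij
    SSD(among)  = SSD(total) - SSD(within)

    sigma_b^2 = SSD(within) / (N - P)
    sigma_a^2 = (SSD(among)/(P-1) - sigma_b^2) / n'
    n' = (N - sum n_g^2 / N) / (P - 1)

with ``delta2`` the number of pairwise nucleotide differences (the
default squared distance for haplotypic data).  Phi_ST is
``sigma_a^2 / (sigma_a^2 + sigma_b^2)``; a negative among-population
component is kept internally but clamped to 0 in the reported Phi_ST.
Significance comes from permuting individuals among populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hapaudit.io_formats import SequenceRecord
from hapaudit.popgen_stats import pairwise_diff_matrix
from hapaudit.haplotyping import Haplotype


@dataclass(frozen=True)
class AmovaResult:
    grouping: str
    n: int
    n_populations: int
    ssd_total: float
    ssd_among: float
    ssd_within: float
    sigma_a: float   # among-population variance component (may be negative)
    sigma_b: float   # within-population component
    phi_st: float    # raw ratio
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None

    @property
    def phi_st_reported(self) -> float:
        """Phi_ST clamped at zero, as printed in reports."""
        return max(self.phi_st, 0.0)


def _squared_distance_matrix(records: list[SequenceRecord]) -> np.ndarray:
    haps = [Haplotype(label=r.id, seq=r.seq, members=(r.id,)) for r in records]
    return pairwise_diff_matrix(haps).astype(float)


def _population_labels(records, grouping) -> np.ndarray:
    labels = []
    for rec in records:
        pop = grouping.get(rec.site, rec.site) if grouping else rec.site
        labels.append(pop)
    return np.asarray(labels)


def _components(d2: np.ndarray, labels: np.ndarray) -> dict:
    pops, inverse = np.unique(labels, return_inverse=True)
    n = len(labels)
    p = len(pops)
    if p < 2:
        raise ValueError("single population: AMOVA needs >= 2 populations")
    sizes = np.bincount(inverse)
    if (sizes < 2).any():
        small = [str(pops[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"population(s) with < 2 members: {small}")

    ssd_total = d2.sum() / (2 * n)
    ssd_within = 0.0
    for g in range(p):
        idx = np.flatnonzero(inverse == g)
        ssd_within += d2[np.ix_(idx, idx)].sum() / (2 * sizes[g])
    ssd_among = ssd_total - ssd_within

    sigma_b = ssd_within / (n - p)
    n_prime = (n - (sizes**2).sum() / n) / (p - 1)
    sigma_a = (ssd_among / (p - 1) - sigma_b) / n_prime
    denom = sigma_a + sigma_b
    phi = sigma_a / denom if denom != 0 else 0.0
    return {
        "n": n,
        "p": p,
        "ssd_total": float(ssd_total),
        "ssd_among": float(ssd_among),
        "ssd_within": float(ssd_within),
        "sigma_a": float(sigma_a),
        "sigma_b": float(sigma_b),
        "phi_st": float(phi),
    }


def amova_fst(
    records: list[SequenceRecord],
    grouping: dict[str, str] | None = None,
    label: str = "",
) -> AmovaResult:
    """Variance components and Phi_ST for sites mapped to populations.

    ``grouping`` maps site labels to population labels (identity when
    omitted), allowing pooled runs such as {BB: "BB-EST", EST: "BB-EST",
    STA: "STA"}.
    """
    d2 = _squared_distance_matrix(records)
    labels = _population_labels(records, grouping)
    c = _components(d2, labels)
    return AmovaResult(
        grouping=label or "/".join(sorted(set(labels))),
        n=c["n"],
        n_populations=c["p"],
        ssd_total=c["ssd_total"],
        ssd_among=c["ssd_among"],
        ssd_within=c["ssd_within"],
        sigma_a=c["sigma_a"],
        sigma_b=c["sigma_b"],
        phi_st=c["phi_st"],
    )


def permutation_test(
    records: list[SequenceRecord],
    grouping: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    label: str = "",
) -> AmovaResult:
    """AMOVA with a permutation P-value.

    Individuals are shuffled among populations holding sample sizes
    fixed; ``p = (1 + #{Phi_perm >= Phi_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = _squared_distance_matrix(records)
    labels = _population_labels(records, grouping)
    obs = _components(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _components(d2, perm)["phi_st"] >= obs["phi_st"] - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return AmovaResult(
        grouping=label or "/".join(sorted(set(labels))),
        n=obs["n"],
        n_populations=obs["p"],
        ssd_total=obs["ssd_total"],
        ssd_among=obs["ssd_among"],
        ssd_within=obs["ssd_within"],
        sigma_a=obs["sigma_a"],
        sigma_b=obs["sigma_b"],
        phi_st=obs["phi_st"],
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


def pooled_runs(
    records: list[SequenceRecord],
    pools: list[dict[str, str]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[AmovaResult]:
    """Run one AMOVA per site-to-population partition.

    Each pool must assign every site present in the records.
    """
    sites = {r.site for r in records}
    results = []
    for i, pool in enumerate(pools):
        missing = sites - set(pool)
        if missing:
            raise ValueError(f"pool #{i + 1} omits site(s) {sorted(missing)}")
        label = " vs ".join(sorted(set(pool.values())))
        results.append(
            permutation_test(records, pool, n_perm=n_perm, seed=seed + i, label=label)
        )
    return results
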