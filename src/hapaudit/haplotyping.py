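"""Zero-mismatch haplotype collapse and distribution summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from hapaudit.io_formats import CountTable, SequenceRecord

_RESOLVED = frozenset("ACGT")


@dataclass(frozen=True)
class Haplotype:
    """A group of records sharing one exact sequence."""

    label: str
    seq: str
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SharednessSummary:
    """How haplotypes distribute over sampling sites."""

    n_sites: int
    by_n_sites: dict[int, int]  # sites-present -> number of haplotypes
    unique_proportion_per_site: dict[str, float]
    top_frequencies: tuple[float, ...]  # haplotype totals / grand total, descending

    @property
    def n_unique(self) -> int:
        return self.by_n_sites.get(1, 0)

    @property
    def unique_percent(self) -> float:
        total = sum(self.by_n_sites.values())
        return 100.0 * self.n_unique / total if total else 0.0


def collapse(
    records: list[SequenceRecord], label_prefix: str = "HT"
) -> list[Haplotype]:
    """Partition records by exact sequence identity.

    Records containing ambiguity codes, N or gaps are excluded with a
    warning rather than wildcard-matched: a wildcard merge could join
    distinct haplotypes.  Labels are assigned by descending member count,
    ties broken by first appearance.
    """
    usable, ambiguous = [], []
    for rec in records:
        (usable if set(rec.seq) <= _RESOLVED else ambiguous).append(rec)
    if ambiguous:
        warnings.warn(
            f"excluding {len(ambiguous)} record(s) with unresolved positions: "
            + ", ".join(r.id for r in ambiguous[:5])
            + ("..." if len(ambiguous) > 5 else ""),
            stacklevel=2,
        )
    if usable:
        lengths = {len(r.seq) for r in usable}
        if len(lengths) > 1:
            raise ValueError(f"records have mixed lengths {sorted(lengths)}")

    order: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for rec in usable:
        if rec.seq not in order:
            order[rec.seq] = len(order)
            members[rec.seq] = []
        members[rec.seq].append(rec.id)

    ranked = sorted(order, key=lambda s: (-len(members[s]), order[s]))
    return [
        Haplotype(
            label=f"{label_prefix}{i}", seq=seq, members=tuple(members[seq])
        )
        for i, seq in enumerate(ranked, 1)
    ]


def build_count_table(
    haplotypes: list[Haplotype], site_of: dict[str, str]
) -> CountTable:
    """Tally haplotype members per site into a :class:`CountTable`.

    Haplotype rows keep the collapse ranking (descending total count,
    ties by first appearance); sites are ordered by first appearance in
    ``site_of`` to preserve the caller's column layout.
    """
    site_ids: list[str] = []
    for site in site_of.values():
        if site not in site_ids:
            site_ids.append(site)
    counts = np.zeros((len(haplotypes), len(site_ids)), dtype=int)
    for i, hap in enumerate(haplotypes):
        for member in hap.members:
            if member not in site_of:
                raise KeyError(f"no site known for record {member!r}")
            counts[i, site_ids.index(site_of[member])] += 1
    return CountTable(
        haplotype_ids=[h.label for h in haplotypes],
        site_ids=site_ids,
        counts=counts,
    )


def sharedness(table: CountTable) -> SharednessSummary:
    """Summarize how haplotypes are shared across sites.

    Only rows with a positive count somewhere enter the summary
    (auxiliary-only rows are distribution annotations, not sampled
    haplotypes).  The per-site unique proportion divides the haplotypes
    found only at that site by all haplotypes found there.
    """
    if not table.haplotype_ids:
        raise ValueError("empty table")
    positive = table.counts > 0
    sampled = positive.any(axis=1)
    sites_present = positive[sampled].sum(axis=1)

    by_n_sites: dict[int, int] = {}
    for k in sites_present:
        by_n_sites[int(k)] = by_n_sites.get(int(k), 0) + 1

    unique_prop: dict[str, float] = {}
    for j, site in enumerate(table.site_ids):
        here = positive[sampled][:, j]
        n_here = int(here.sum())
        n_unique = int((here & (sites_present == 1)).sum())
        unique_prop[site] = n_unique / n_here if n_here else 0.0

    totals = table.row_totals()[sampled]
    grand = table.grand_total
    top = tuple(sorted((t / grand for t in totals), reverse=True))
    return SharednessSummary(
        n_sites=len(table.site_ids),
        by_n_sites=by_n_sites,
        unique_proportion_per_site=unique_prop,
        top_frequencies=top,
    )
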