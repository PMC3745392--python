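"""Repository audit: deduplication, support classification, reconstruction.

The audit compares three haplotype sets: the deposited repository
entries, the haplotypes recovered from re-edited chromatograms, and an
auxiliary (unpublished) dataset.  Repository haplotypes are *supported*
when exactly identical to a re-edited haplotype, *auxiliary-supported*
when identical only to an auxiliary haplotype, and *unsupported*
otherwise; re-edited haplotypes absent from the repository are *novel*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from hapaudit.haplotyping import Haplotype, collapse
from hapaudit.io_formats import CountTable, SequenceRecord


@dataclass
class ReconciliationReport:
    duplicate_groups: list[tuple[str, ...]]
    n_repo_entries: int
    n_repo_distinct: int
    supported: set[str]
    aux_supported: set[str]
    unsupported: set[str]
    novel: set[str]
    reference_set: list[Haplotype] = field(default_factory=list)

    @property
    def n_redundant(self) -> int:
        """Entries beyond the first in each duplicate group."""
        return sum(len(g) - 1 for g in self.duplicate_groups)

    @property
    def support_rate(self) -> float:
        if not self.n_repo_distinct:
            return 0.0
        return (len(self.supported) + len(self.aux_supported)) / self.n_repo_distinct

    def summary(self) -> dict:
        return {
            "repo_entries": self.n_repo_entries,
            "duplicate_groups": len(self.duplicate_groups),
            "redundant_entries": self.n_redundant,
            "repo_distinct": self.n_repo_distinct,
            "supported": len(self.supported),
            "aux_supported": len(self.aux_supported),
            "unsupported": len(self.unsupported),
            "novel": len(self.novel),
            "reference_size": len(self.reference_set),
            "support_rate_percent": 100.0 * self.support_rate,
        }


def dedup_repository(
    records: list[SequenceRecord],
) -> tuple[list[tuple[str, ...]], list[Haplotype]]:
    """Find identity classes among repository entries.

    Returns the duplicate groups (size >= 2, member ids sorted, groups
    ordered by descending size then smallest member id) and one
    representative :class:`~hapaudit.haplotyping.Haplotype` per distinct
    sequence.
    """
    haplotypes = collapse(records, label_prefix="REPHT")
    groups = [
        tuple(sorted(h.members)) for h in haplotypes if len(h.members) >= 2
    ]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, haplotypes


def _window_key(seq: str, window: tuple[int, int] | None) -> str:
    if window is None:
        return seq
    offset, length = window
    if offset < 0 or offset + length > len(seq):
        raise ValueError(
            f"window ({offset},{length}) does not fit sequence of length {len(seq)}"
        )
    return seq[offset : offset + length]


def classify_support(
    repo: list[Haplotype],
    reedited: list[Haplotype],
    aux: list[Haplotype] | None = None,
    window: tuple[int, int] | None = None,
) -> ReconciliationReport:
    """Classify deduplicated repository haplotypes against two references.

    Comparison is exact identity.  When sequence sets differ in length, a
    ``window`` (offset, length on the longer sequences) must be supplied;
    it is applied to any sequence longer than ``length``.
    """
    aux = aux or []
    lengths = {len(h.seq) for h in [*repo, *reedited, *aux]}
    if len(lengths) > 1 and window is None:
        raise ValueError(
            f"sequence lengths differ {sorted(lengths)}; declare a comparison window"
        )

    def key(h: Haplotype) -> str:
        if window is not None and len(h.seq) > window[1]:
            return _window_key(h.seq, window)
        return h.seq

    reedited_keys = {key(h) for h in reedited}
    aux_keys = {key(h) for h in aux}
    supported, aux_supported, unsupported = set(), set(), set()
    aux_supported_haps: list[Haplotype] = []
    repo_keys = set()
    for h in repo:
        k = key(h)
        repo_keys.add(k)
        if k in reedited_keys:
            supported.add(h.label)
        elif k in aux_keys:
            aux_supported.add(h.label)
            aux_supported_haps.append(h)
        else:
            unsupported.add(h.label)

    novel = {h.label for h in reedited if key(h) not in repo_keys}
    reference = list(reedited) + aux_supported_haps

    dup_groups = [tuple(sorted(h.members)) for h in repo if len(h.members) >= 2]
    dup_groups.sort(key=lambda g: (-len(g), g[0]))
    n_entries = sum(len(h.members) for h in repo)
    return ReconciliationReport(
        duplicate_groups=dup_groups,
        n_repo_entries=n_entries,
        n_repo_distinct=len(repo),
        supported=supported,
        aux_supported=aux_supported,
        unsupported=unsupported,
        novel=novel,
        reference_set=reference,
    )


def build_erroneous(
    haplotype_list: list[Haplotype], distribution: CountTable
) -> list[SequenceRecord]:
    """Expand an ordinal-indexed distribution over a haplotype list.

    Row ``i`` of the distribution refers to ``haplotype_list[i]``; each
    (haplotype, site, count) cell becomes ``count`` individual records.
    Rows whose ordinal exceeds the list are skipped with a warning — the
    distribution may report more haplotypes than were ever deposited.
    """
    records: list[SequenceRecord] = []
    for i, (hap_id, row) in enumerate(
        zip(distribution.haplotype_ids, distribution.counts)
    ):
        if i >= len(haplotype_list):
            warnings.warn(
                f"distribution row {hap_id!r} (ordinal {i + 1}) has no "
                f"deposited haplotype (only {len(haplotype_list)} available); skipped",
                stacklevel=2,
            )
            continue
        hap = haplotype_list[i]
        for site, count in zip(distribution.site_ids, row):
            for k in range(1, int(count) + 1):
                records.append(
                    SequenceRecord(id=f"{hap_id}_{site}_{k}", seq=hap.seq, site=site)
                )
    return records
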