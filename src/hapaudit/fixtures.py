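"""Sequence-level realizations of the packaged distribution tables.

The packaged tables record *which* repository entries are duplicates and
*which* re-edited haplotype each repository haplotype corresponds to, but
not the sequences themselves.  :func:`build_audit_fixture` turns those
tables into a concrete, seeded sequence fixture on which the whole audit
(dedup -> support classification -> reference assembly) can run.
"""

from __future__ import annotations

from dataclasses import dataclass

from hapaudit.datasets import (
    N_REPOSITORY_ENTRIES,
    load_reedited_distribution,
    load_repository_duplicates,
    repository_accession,
)
from hapaudit.haplotyping import Haplotype
from hapaudit.io_formats import CountTable, SequenceRecord
from hapaudit.synthetic_data import SyntheticConfig, gen_haplotype_sequences


@dataclass
class AuditFixture:
    """A complete synthetic realization of the audit inputs."""

    table: CountTable
    reedited_records: list[SequenceRecord]  # one per sampled individual
    reedited_haplotypes: list[Haplotype]    # sampled rows, canonical sequences
    repo_records: list[SequenceRecord]      # deposited entries, accession ids
    aux_haplotypes: list[Haplotype]         # auxiliary-dataset haplotypes
    site_of: dict[str, str]


def _old_ordinals(old_id: str) -> list[int]:
    if not old_id or old_id.lower() == "new":
        return []
    return [int(x) for x in old_id.split(",")]


def build_audit_fixture(seed: int = 0, config: SyntheticConfig | None = None) -> AuditFixture:
    """Realize the packaged distribution and duplicate tables as sequences.

    Every table row gets a distinct sequence; repository entries whose
    ordinal appears in a row's old-id annotation carry that row's
    sequence (so annotated duplicates are exact duplicates and annotated
    matches are exact matches), and the remaining repository ordinals get
    distinct decoy sequences matching nothing.
    """
    if config is None:
        config = SyntheticConfig(seed=seed)
    table = load_reedited_distribution()

    sampled = table.baltic_rows()
    aux_rows = [h for h in table.haplotype_ids if table.aux_counts.get(h, 0) > 0]
    ordered = sampled + [h for h in table.haplotype_ids if h not in sampled]
    pool = gen_haplotype_sequences(
        len(ordered) + _n_unmapped(table), config, n_core=len(sampled)
    )
    seq_of = {h: s for h, s in zip(ordered, pool)}
    decoys = pool[len(ordered):]

    records: list[SequenceRecord] = []
    members: dict[str, list[str]] = {h: [] for h in table.haplotype_ids}
    for h, row in zip(table.haplotype_ids, table.counts):
        for site, count in zip(table.site_ids, row):
            for k in range(1, int(count) + 1):
                rec = SequenceRecord(id=f"{h}_{site}_{k}", seq=seq_of[h], site=site)
                records.append(rec)
                members[h].append(rec.id)

    reedited_haps = [
        Haplotype(label=h, seq=seq_of[h], members=tuple(members[h]))
        for h in sampled
    ]
    aux_haps = [Haplotype(label=h, seq=seq_of[h], members=()) for h in aux_rows]

    # repository: ordinal -> sequence via the old-id annotations
    ordinal_seq: dict[int, str] = {}
    for h in table.haplotype_ids:
        for ordinal in _old_ordinals(table.old_ids.get(h, "")):
            ordinal_seq[ordinal] = seq_of[h]
    decoy_iter = iter(decoys)
    repo_records = []
    for ordinal in range(1, N_REPOSITORY_ENTRIES + 1):
        seq = ordinal_seq.get(ordinal)
        if seq is None:
            seq = next(decoy_iter)
        repo_records.append(SequenceRecord(id=repository_accession(ordinal), seq=seq))

    # sanity: the fixture must realize the recorded duplicate groups
    for group in load_repository_duplicates():
        seqs = {repo_records[o - 1].seq for o in group["haplotype_ids"]}
        assert len(seqs) == 1, f"fixture violates duplicate group {group['group']}"

    site_of = {r.id: r.site for r in records}
    return AuditFixture(
        table=table,
        reedited_records=records,
        reedited_haplotypes=reedited_haps,
        repo_records=repo_records,
        aux_haplotypes=aux_haps,
        site_of=site_of,
    )


def _n_unmapped(table: CountTable) -> int:
    mapped = set()
    for h in table.haplotype_ids:
        mapped.update(_old_ordinals(table.old_ids.get(h, "")))
    return N_REPOSITORY_ENTRIES - len(mapped)
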