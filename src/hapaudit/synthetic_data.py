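"""Synthetic inputs for every pipeline stage.

The generators replace data that cannot be shipped: individual-level
sequence cohorts realizing a given haplotype distribution table,
dual-editor call-string pairs with injected disagreements, and
repositories containing exact-duplicate groups and corrupted variants.
All generators are pure functions of their inputs and an explicit seed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from hapaudit.io_formats import CountTable, SequenceRecord

BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters shared by the generators.

    ``L`` and ``S`` default to the dimensions of the re-edited dataset
    (435 bp fragments, 37 segregating sites).
    """

    L: int = 435
    S: int = 37
    seed: int = 0
    error_rate: float = 0.0
    duplicate_spec: tuple[int, ...] = ()
    disagreement_rate: float = 0.0
    poor_read_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.S <= self.L:
            raise ValueError(f"require 0 < S <= L, got S={self.S}, L={self.L}")
        for name in ("error_rate", "disagreement_rate", "poor_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if any(g < 2 for g in self.duplicate_spec):
            raise ValueError("duplicate groups must have size >= 2")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def gen_haplotype_sequences(
    n_haplotypes: int, config: SyntheticConfig, n_core: int | None = None
) -> list[str]:
    """``n_haplotypes`` distinct sequences linked by single-site mutations.

    Haplotypes are placed on a random attachment tree (each new haplotype
    is a one-or-more-step mutational neighbour of a uniformly chosen
    existing one), so any haplotype network built over them is connected.
    Each tree edge mutates at least one previously untouched site.
    Because every site mutates exactly once, all haplotypes are pairwise
    distinct.

    ``config.S`` sites are spread over the edges among the first
    ``n_core`` haplotypes (default: all of them), so that exactly ``S``
    columns segregate *within the core*; haplotypes beyond the core each
    add one fresh site.  A warning is attached when the realized core
    segregating-site count cannot equal ``config.S``.
    """
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if n_core is None:
        n_core = n_haplotypes
    if not 1 <= n_core <= n_haplotypes:
        raise ValueError(f"n_core={n_core} out of range 1..{n_haplotypes}")
    if n_core > 2 ** config.S:
        raise ValueError(
            f"{n_core} haplotypes cannot be built from {config.S} biallelic sites"
        )
    rng = config.rng(salt=1)
    background = "".join(rng.choice(list(BASES), size=config.L))
    if n_haplotypes == 1:
        if config.S > 0:
            warnings.warn(
                "single haplotype: realized segregating sites = 0, not "
                f"{config.S}", stacklevel=2,
            )
        return [background]

    core_edges = n_core - 1
    s_real = config.S
    if core_edges == 0:
        if config.S > 0:
            warnings.warn(
                "single core haplotype: realized core segregating sites = 0, "
                f"not {config.S}", stacklevel=2,
            )
        s_real = 0
    elif s_real < core_edges:
        warnings.warn(
            f"{n_core} distinct haplotypes need >= {core_edges} "
            f"segregating sites; realizing {core_edges} instead of {config.S}",
            stacklevel=2,
        )
        s_real = core_edges
    extra_edges = n_haplotypes - max(n_core, 1)
    if s_real + extra_edges > config.L:
        raise ValueError(
            f"cannot place {s_real + extra_edges} segregating sites in {config.L} bp"
        )

    sites = rng.choice(config.L, size=s_real + extra_edges, replace=False)
    # each core edge gets >=1 fresh site; surplus of the S pool at random
    per_edge = np.ones(core_edges, dtype=int)
    for _ in range(s_real - core_edges):
        per_edge[rng.integers(core_edges)] += 1
    per_edge = np.concatenate([per_edge, np.ones(extra_edges, dtype=int)])

    haplotypes = [list(background)]
    cursor = 0
    for edge in range(len(per_edge)):
        attach_pool = min(len(haplotypes), n_core) if edge < core_edges else len(haplotypes)
        parent = haplotypes[rng.integers(attach_pool)]
        child = list(parent)
        for _ in range(per_edge[edge]):
            pos = sites[cursor]
            cursor += 1
            alternatives = [b for b in BASES if b != background[pos]]
            child[pos] = alternatives[rng.integers(3)]
        haplotypes.append(child)
    return ["".join(h) for h in haplotypes]


def haplotype_pool(config: SyntheticConfig, table: CountTable) -> dict[str, str]:
    """Mapping haplotype id -> canonical sequence for every table row.

    Rows with a positive count somewhere form the generator core, so that
    exactly ``config.S`` columns segregate among the sampled haplotypes;
    zero-count (auxiliary-only) rows get distinct sequences one fresh
    mutation away from the core.
    """
    sampled = [h for h, row in zip(table.haplotype_ids, table.counts) if row.sum() > 0]
    aux_only = [h for h in table.haplotype_ids if h not in sampled]
    ordered = sampled + aux_only
    seqs = gen_haplotype_sequences(len(ordered), config, n_core=len(sampled) or None)
    return {h: s for h, s in zip(ordered, seqs)}


def gen_haplotypes(
    config: SyntheticConfig, table: CountTable
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Expand a count table into an individual-level sequence cohort.

    Returns one record per counted individual (ids ``<hap>_<site>_<k>``)
    and the individual-to-haplotype assignment.  Two individuals share a
    sequence iff they share a haplotype row; auxiliary-only rows receive a
    sequence in the underlying haplotype pool but contribute no records.
    """
    pool = haplotype_pool(config, table)
    records: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for hap, row in zip(table.haplotype_ids, table.counts):
        for site, count in zip(table.site_ids, row):
            for k in range(1, int(count) + 1):
                rec_id = f"{hap}_{site}_{k}"
                records.append(SequenceRecord(id=rec_id, seq=pool[hap], site=site))
                assignment[rec_id] = hap
    return records, assignment


def gen_editor_pair(
    truth: SequenceRecord, config: SyntheticConfig
) -> tuple[str, str]:
    """Simulate two independent editors' base calls for one read.

    Each position disagrees with probability ``disagreement_rate`` (one
    editor, chosen at random, records a different base or N).  With
    probability ``poor_read_fraction`` the read is made poor: at least a
    third of its positions are forced inconsistent.
    """
    rng = config.rng(salt=zlib.crc32(truth.id.encode()))
    L = len(truth.seq)
    a = list(truth.seq)
    b = list(truth.seq)

    disagree = rng.random(L) < config.disagreement_rate
    if rng.random() < config.poor_read_fraction:
        need = -(-L // 3)  # ceil(L/3)
        forced = rng.choice(L, size=need, replace=False)
        disagree[forced] = True

    for pos in np.flatnonzero(disagree):
        target = a if rng.random() < 0.5 else b
        true_base = truth.seq[pos]
        options = [x for x in "ACGTN" if x != true_base]
        target[pos] = options[rng.integers(len(options))]
    return "".join(a), "".join(b)


@dataclass
class RepositoryResult:
    """A synthetic repository plus the truth needed to audit it."""

    records: list[SequenceRecord]
    provenance: dict[str, str | None]  # record id -> source hap id (None if corrupted)
    duplicate_groups: list[list[str]] = field(default_factory=list)


def gen_repository(
    haplotypes: list[SequenceRecord], config: SyntheticConfig
) -> RepositoryResult:
    """Build a repository with exact-duplicate groups and corrupted entries.

    The first ``len(duplicate_spec)`` source haplotypes are deposited
    ``g`` times each (identical sequence, distinct accession-style ids);
    every other source is deposited once and, with probability
    ``error_rate``, corrupted by random substitutions so that it matches
    no input haplotype.
    """
    if len(config.duplicate_spec) > len(haplotypes):
        raise ValueError(
            f"{len(config.duplicate_spec)} duplicate groups requested but only "
            f"{len(haplotypes)} haplotypes available"
        )
    rng = config.rng(salt=2)
    truth_seqs = {h.seq for h in haplotypes}

    def corrupt(seq: str) -> str:
        for _ in range(100):
            out = list(seq)
            n_mut = int(rng.integers(1, 4))
            for pos in rng.choice(len(seq), size=n_mut, replace=False):
                options = [b for b in BASES if b != out[pos]]
                out[pos] = options[rng.integers(3)]
            cand = "".join(out)
            if cand not in truth_seqs:
                return cand
        raise RuntimeError("could not generate a corrupted variant")  # pragma: no cover

    records: list[SequenceRecord] = []
    provenance: dict[str, str | None] = {}
    groups: list[list[str]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"REP{counter:03d}"

    for g, source in zip(config.duplicate_spec, haplotypes):
        members = []
        for _ in range(g):
            rid = next_id()
            records.append(SequenceRecord(id=rid, seq=source.seq))
            provenance[rid] = source.id
            members.append(rid)
        groups.append(members)

    for source in haplotypes[len(config.duplicate_spec):]:
        rid = next_id()
        if rng.random() < config.error_rate:
            records.append(SequenceRecord(id=rid, seq=corrupt(source.seq)))
            provenance[rid] = None
        else:
            records.append(SequenceRecord(id=rid, seq=source.seq))
            provenance[rid] = source.id

    return RepositoryResult(records=records, provenance=provenance, duplicate_groups=groups)
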