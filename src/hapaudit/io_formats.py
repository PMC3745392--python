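"""Readers/writers for the formats the pipeline touches.

Sequences travel as FASTA with an ``id|site`` header convention (the site
label is optional); haplotype distribution tables are TSV with a
``haplotype`` key column, one column per breeding site, and optional
``aux`` (auxiliary-dataset count) and ``old_id`` annotation columns.
Lines starting with ``#`` are comments.  A final ``Total`` row, when
present, is checked against the column sums.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes plus gap.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

HEADER_SEP = "|"
FASTA_WRAP = 70


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad header or illegal character)."""


class TableFormatError(ValueError):
    """Raised for malformed or inconsistent count tables."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with an optional breeding-site label."""

    id: str
    seq: str
    site: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CountTable:
    """Haplotype-by-site count matrix with optional annotations.

    Rows with an all-zero count vector must carry a positive ``aux``
    annotation (auxiliary-only haplotypes); otherwise construction fails.
    """

    haplotype_ids: list[str]
    site_ids: list[str]
    counts: np.ndarray
    old_ids: dict[str, str] = field(default_factory=dict)
    aux_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.haplotype_ids), len(self.site_ids)):
            raise TableFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.haplotype_ids)} haplotypes x {len(self.site_ids)} sites"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(int)
            if not np.array_equal(as_int, self.counts):
                raise TableFormatError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise TableFormatError("counts must be non-negative")
        if len(set(self.haplotype_ids)) != len(self.haplotype_ids):
            raise TableFormatError("duplicate haplotype ids")
        for hap, row in zip(self.haplotype_ids, self.counts):
            if row.sum() == 0 and self.aux_counts.get(hap, 0) <= 0:
                raise TableFormatError(
                    f"haplotype {hap!r} has no counts and no auxiliary support"
                )

    # -- totals -------------------------------------------------------
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def row(self, haplotype_id: str) -> np.ndarray:
        return self.counts[self.haplotype_ids.index(haplotype_id)]

    def column(self, site_id: str) -> np.ndarray:
        return self.counts[:, self.site_ids.index(site_id)]

    def baltic_rows(self) -> list[str]:
        """Haplotype ids with at least one positive site count."""
        return [
            h for h, row in zip(self.haplotype_ids, self.counts) if row.sum() > 0
        ]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=self.haplotype_ids, columns=self.site_ids
        )
        df.index.name = "haplotype"
        if self.aux_counts:
            df["aux"] = [self.aux_counts.get(h, 0) for h in self.haplotype_ids]
        if self.old_ids:
            df["old_id"] = [self.old_ids.get(h, "") for h in self.haplotype_ids]
        return df


def _parse_header(header: str) -> tuple[str, str]:
    if HEADER_SEP in header:
        rec_id, site = header.split(HEADER_SEP, 1)
    else:
        rec_id, site = header, ""
    if not rec_id:
        raise FastaParseError(f"empty id in header {header!r}")
    return rec_id, site


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    Headers are ``id|site`` (site optional).  Sequences are uppercased and
    validated against the IUPAC nucleotide alphabet.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, entry in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = entry.description or entry.id
        rec_id, site = _parse_header(header)
        seq = str(entry.seq).upper()
        try:
            rec = SequenceRecord(id=rec_id, seq=seq, site=site)
        except ValueError as exc:
            raise FastaParseError(f"entry #{i} ({rec_id!r}): {exc}") from exc
        if rec_id in seen:
            raise FastaParseError(f"entry #{i}: duplicate id {rec_id!r}")
        seen.add(rec_id)
        records.append(rec)
    return records


def write_fasta(records, path) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    entries = []
    for rec in records:
        header = rec.id + (HEADER_SEP + rec.site if rec.site else "")
        entries.append(SeqRecord(Seq(rec.seq), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(entries)


def fasta_string(records) -> str:
    """FASTA serialization as a string (used for determinism checks)."""
    buf = io.StringIO()
    entries = [
        SeqRecord(
            Seq(r.seq),
            id=r.id + (HEADER_SEP + r.site if r.site else ""),
            description="",
        )
        for r in records
    ]
    SeqIO.FastaIO.FastaWriter(buf, wrap=FASTA_WRAP).write_file(entries)
    return buf.getvalue()


_ANNOTATION_COLS = ("aux", "old_id")
_TOTAL_LABEL = "total"


def read_count_table(path) -> CountTable:
    """Read a haplotype distribution TSV into a :class:`CountTable`.

    A ``Total`` row (and/or a ``Total`` column), when present, is verified
    against the computed sums; a mismatch is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0].lower() != "haplotype":
        raise TableFormatError(
            f"first column must be 'haplotype', got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)

    site_cols = [c for c in df.columns if c.lower() not in _ANNOTATION_COLS and c.lower() != _TOTAL_LABEL]
    total_col = next((c for c in df.columns if c.lower() == _TOTAL_LABEL), None)

    total_row = None
    hap_index = []
    for h in df.index:
        if h.lower() == _TOTAL_LABEL:
            total_row = h
        else:
            hap_index.append(h)

    def _cell(v) -> int:
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            return 0
        s = str(v).strip()
        try:
            x = float(s)
        except ValueError:
            raise TableFormatError(f"non-numeric count {s!r}") from None
        if x < 0 or x != int(x):
            raise TableFormatError(f"count {s!r} is not a non-negative integer")
        return int(x)

    counts = np.array(
        [[_cell(df.loc[h, c]) for c in site_cols] for h in hap_index], dtype=int
    )

    aux_counts: dict[str, int] = {}
    old_ids: dict[str, str] = {}
    for col in df.columns:
        if col.lower() == "aux":
            for h in hap_index:
                v = _cell(df.loc[h, col])
                if v:
                    aux_counts[h] = v
        elif col.lower() == "old_id":
            for h in hap_index:
                v = df.loc[h, col]
                if isinstance(v, str) and v.strip():
                    old_ids[h] = v.strip()

    table = CountTable(
        haplotype_ids=hap_index,
        site_ids=site_cols,
        counts=counts,
        old_ids=old_ids,
        aux_counts=aux_counts,
    )

    if total_row is not None:
        stated = np.array([_cell(df.loc[total_row, c]) for c in site_cols])
        if not np.array_equal(stated, table.col_totals()):
            raise TableFormatError(
                f"Total row {stated.tolist()} disagrees with column sums "
                f"{table.col_totals().tolist()}"
            )
    if total_col is not None:
        stated = np.array([_cell(df.loc[h, total_col]) for h in hap_index])
        if not np.array_equal(stated, table.row_totals()):
            raise TableFormatError("Total column disagrees with row sums")
    return table


def write_count_table(table: CountTable, path, comments: list[str] | None = None) -> None:
    """Write a :class:`CountTable` as TSV; inverse of :func:`read_count_table`.

    Zero cells in the count block are written as empty fields, matching how
    distribution tables are conventionally printed.
    """
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        cols = ["haplotype", *table.site_ids]
        if table.aux_counts:
            cols.append("aux")
        if table.old_ids:
            cols.append("old_id")
        fh.write("\t".join(cols) + "\n")
        for h, row in zip(table.haplotype_ids, table.counts):
            cells = [h] + [str(int(v)) if v else "" for v in row]
            if table.aux_counts:
                a = table.aux_counts.get(h, 0)
                cells.append(str(a) if a else "")
            if table.old_ids:
                cells.append(table.old_ids.get(h, ""))
            fh.write("\t".join(cells) + "\n")
        total_cells = ["Total"] + [str(int(v)) for v in table.col_totals()]
        if table.aux_counts:
            total_cells.append("")
        if table.old_ids:
            total_cells.append("")
        fh.write("\t".join(total_cells) + "\n")
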