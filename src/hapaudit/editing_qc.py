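"""Dual-editor consensus, the one-third inconsistency filter, and trimming.

Two editors' independent base calls for a read are merged into a
consensus; positions where the editors disagree receive the minimal IUPAC
code covering both calls.  Reads in which a third or more of the
positions could not be called consistently are discarded.  Retained reads
are trimmed to the maximal window free of terminal N-runs in every read.
"""

from __future__ import annotations

from dataclasses import dataclass

from hapaudit.io_formats import ALPHABET, SequenceRecord

# base -> set of concrete nucleotides it can represent
_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
_SET_TO_CODE = {frozenset(v): k for k, v in _IUPAC_SETS.items()}

POOR_READ_THRESHOLD = 1 / 3  # inconsistent_fraction >= this -> discarded


@dataclass(frozen=True)
class EditedRead:
    id: str
    calls_a: str
    calls_b: str
    consensus: str
    inconsistent_fraction: float

    @property
    def retained(self) -> bool:
        return self.inconsistent_fraction < POOR_READ_THRESHOLD


def _merge(a: str, b: str) -> str:
    if a == b:
        return a
    if a == "-" or b == "-":
        return "N"  # gap vs base cannot be reconciled
    return _SET_TO_CODE[frozenset(_IUPAC_SETS[a] | _IUPAC_SETS[b])]


def consensus_calls(calls_a: str, calls_b: str, read_id: str = "") -> EditedRead:
    """Merge two editors' calls into a consensus read.

    Agreeing positions copy the shared call; disagreeing positions get the
    minimal IUPAC code covering both calls (N when either call is N or a
    gap conflicts with a base) and count as inconsistent.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError(
            f"call strings differ in length ({len(calls_a)} vs {len(calls_b)})"
        )
    if not calls_a:
        raise ValueError("empty call strings")
    for name, calls in (("calls_a", calls_a), ("calls_b", calls_b)):
        bad = set(calls.upper()) - ALPHABET
        if bad:
            raise ValueError(f"{name}: illegal character(s) {sorted(bad)!r}")
    a, b = calls_a.upper(), calls_b.upper()
    consensus = []
    n_bad = 0
    for x, y in zip(a, b):
        if x == y:
            consensus.append(x)
        else:
            n_bad += 1
            consensus.append(_merge(x, y))
    return EditedRead(
        id=read_id,
        calls_a=a,
        calls_b=b,
        consensus="".join(consensus),
        inconsistent_fraction=n_bad / len(a),
    )


def filter_reads(reads) -> tuple[list[EditedRead], list[EditedRead]]:
    """Partition reads into (retained, discarded) by the 1/3 rule."""
    retained = [r for r in reads if r.retained]
    discarded = [r for r in reads if not r.retained]
    return retained, discarded


def _clean_window(seq: str) -> tuple[int, int]:
    """Half-open window of seq with leading/trailing N-runs stripped."""
    start, end = 0, len(seq)
    while start < end and seq[start] == "N":
        start += 1
    while end > start and seq[end - 1] == "N":
        end -= 1
    return start, end


def trim_common_window(reads) -> list[SequenceRecord]:
    """Trim retained reads to the intersection of their clean windows.

    All reads must share a coordinate system (equal length).  The output
    window is the widest interval inside every read's terminal-N-stripped
    span; the result is a set of equal-length records.
    """
    reads = list(reads)
    if not reads:
        return []
    lengths = {len(r.consensus) for r in reads}
    if len(lengths) > 1:
        raise ValueError(f"reads have mixed lengths {sorted(lengths)}")
    start, end = 0, lengths.pop()
    for r in reads:
        s, e = _clean_window(r.consensus)
        start, end = max(start, s), min(end, e)
    if start >= end:
        raise ValueError("empty window: no position is clean in every read")
    return [
        SequenceRecord(id=r.id or f"read{i}", seq=r.consensus[start:end])
        for i, r in enumerate(reads, 1)
    ]
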