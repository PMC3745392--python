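"""Access to the small tables packaged with hapaudit."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from hapaudit.io_formats import CountTable, read_count_table


def _data_path(name: str):
    return resources.files("hapaudit.data") / name


def load_reedited_distribution() -> CountTable:
    """Haplotype-by-site distribution of the re-edited dataset.

    35 haplotypes with Baltic counts (grand total 103 over sites BB, EST,
    STA) plus three auxiliary-only rows, with old-repository-id
    annotations.
    """
    with resources.as_file(_data_path("reedited_distribution.tsv")) as p:
        return read_count_table(p)


def load_repository_duplicates() -> list[dict]:
    """Duplicate groups among the 40 repository entries.

    Returns a list of dicts with keys ``group``, ``haplotype_ids`` (list of
    int ordinals) and ``accessions`` (list of accession strings), ordered
    by descending group size.
    """
    with resources.as_file(_data_path("repository_duplicates.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    groups = []
    for _, row in df.iterrows():
        groups.append(
            {
                "group": int(row["group"]),
                "haplotype_ids": [int(x) for x in row["haplotype_ids"].split(",")],
                "accessions": [x.strip() for x in row["accessions"].split(",")],
            }
        )
    return sorted(groups, key=lambda g: -len(g["haplotype_ids"]))


N_REPOSITORY_ENTRIES = 40
REPOSITORY_ACCESSION_PREFIX = "AM287"
REPOSITORY_ACCESSION_OFFSET = 214  # ordinal k -> AM287{214+k}


def repository_accession(ordinal: int) -> str:
    """Accession string for repository haplotype ordinal 1..40."""
    if not 1 <= ordinal <= N_REPOSITORY_ENTRIES:
        raise ValueError(f"repository ordinal {ordinal} out of range 1..40")
    return f"{REPOSITORY_ACCESSION_PREFIX}{REPOSITORY_ACCESSION_OFFSET + ordinal}"
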