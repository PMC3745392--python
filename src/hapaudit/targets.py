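"""Headline numbers recomputed from the packaged tables and fixtures.

Each target re-derives one figure of the reference analysis from scratch:
the diversity and sharedness targets need only the packaged distribution
table; the reconciliation targets run the full audit on a seeded
sequence-level realization of the packaged tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from hapaudit.datasets import load_reedited_distribution
from hapaudit.fixtures import build_audit_fixture
from hapaudit.haplotyping import sharedness
from hapaudit.popgen_stats import chi_square_unique, haplotype_diversity
from hapaudit.reconciliation import classify_support, dedup_repository

# Published reference values for the packaged dataset, at printed precision.
REFERENCE_VALUES = {
    "t1": 0.968,   # haplotype diversity, Bay of Bothnia (BB)
    "t2": 0.957,   # haplotype diversity, Estonia (EST)
    "t3": 0.939,   # haplotype diversity, Stockholm Archipelago (STA)
    "t4": 1.42,    # chi-square, unique vs shared haplotypes per site
    "t5": 54.3,    # % of haplotypes unique to a single site
    "t6": 42.9,    # % of STA haplotypes unique to STA
    "t7": 11.6,    # % frequency of the most common haplotype
    "t9": 31,      # distinct haplotypes among 40 repository entries
    "t10": 16,     # repository haplotypes supported by re-edited data
    "t11": 61.3,   # % repository haplotypes supported overall
    "t12": 38,     # corrected reference haplotype count
}


def round_half_up(x: float, digits: int) -> float:
    """Decimal rounding with ties away from zero (report convention)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def compute_targets(seed: int = 0) -> dict[str, dict]:
    """Recompute every target; returns id -> {value, n}."""
    table = load_reedited_distribution()
    out: dict[str, dict] = {}

    for tid, site in (("t1", "BB"), ("t2", "EST"), ("t3", "STA")):
        counts = table.column(site)
        h, _, _ = haplotype_diversity(counts)
        out[tid] = {"value": round_half_up(h, 3), "n": int(counts.sum())}

    chi = chi_square_unique(table)
    out["t4"] = {"value": round_half_up(chi.statistic, 2), "n": len(table.baltic_rows())}

    shared = sharedness(table)
    out["t5"] = {
        "value": round_half_up(shared.unique_percent, 1),
        "n": len(table.baltic_rows()),
    }
    out["t6"] = {
        "value": round_half_up(100 * shared.unique_proportion_per_site["STA"], 1),
        "n": int((table.column("STA") > 0).sum()),
    }
    out["t7"] = {
        "value": round_half_up(100 * shared.top_frequencies[0], 1),
        "n": table.grand_total,
    }

    fixture = build_audit_fixture(seed=seed)
    groups, repo_haps = dedup_repository(fixture.repo_records)
    out["t9"] = {"value": len(repo_haps), "n": len(fixture.repo_records)}

    report = classify_support(
        repo_haps, fixture.reedited_haplotypes, fixture.aux_haplotypes
    )
    out["t10"] = {"value": len(report.supported), "n": report.n_repo_distinct}
    out["t11"] = {
        "value": round_half_up(100 * report.support_rate, 1),
        "n": report.n_repo_distinct,
    }
    out["t12"] = {"value": len(report.reference_set), "n": report.n_repo_distinct}
    return out


def compare_to_reference(seed: int = 0) -> list[dict]:
    """Computed vs reference values with a one-ulp-of-print tolerance."""
    computed = compute_targets(seed=seed)
    rows = []
    for tid, ref in REFERENCE_VALUES.items():
        val = computed[tid]["value"]
        tol = _print_ulp(ref)
        rows.append(
            {
                "target": tid,
                "computed": val,
                "reference": ref,
                "tolerance": tol,
                "pass": abs(val - ref) <= tol + 1e-12,
            }
        )
    return rows


def _print_ulp(ref: float) -> float:
    """One unit in the last printed digit of the reference value."""
    s = repr(ref)
    if "." not in s:
        return 0.0
    return 10.0 ** -len(s.split(".")[1])
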