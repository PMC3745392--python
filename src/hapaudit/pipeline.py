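"""End-to-end orchestration: simulate -> collapse -> reconcile -> stats
-> AMOVA -> network, with a manifest recording every parameter."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from hapaudit import __version__
from hapaudit.amova import amova_fst, permutation_test, pooled_runs
from hapaudit.fixtures import build_audit_fixture
from hapaudit.haplotyping import Haplotype, build_count_table, collapse, sharedness
from hapaudit.io_formats import CountTable, write_count_table, write_fasta
from hapaudit.network import build_msn, compare_layers, layer_summary, write_graphml
from hapaudit.popgen_stats import (
    chi_square_unique,
    diversity_stats,
    pairwise_diff_matrix,
)
from hapaudit.reconciliation import classify_support, dedup_repository

log = logging.getLogger("hapaudit")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    permutations: int = 999
    window: tuple[int, int] | None = None
    verbose: bool = False


def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}f}"


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole reassessment on the packaged-table fixture.

    Emits ``table2.tsv`` (haplotype distribution), ``table3.tsv``
    (diversity statistics), ``table4.tsv`` (AMOVA), ``reconciliation.tsv``
    (audit counts), ``network.graphml`` and ``manifest.json`` under
    ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        fixture = build_audit_fixture(seed=config.seed)
        write_fasta(fixture.reedited_records, out / "reedited.fasta")
        write_fasta(fixture.repo_records, out / "repository.fasta")

        stage = "collapse"
        haps = collapse(fixture.reedited_records)
        table = build_count_table(haps, fixture.site_of)
        write_count_table(table, out / "table2.tsv", comments=["haplotype distribution"])

        stage = "stats"
        _write_stats(haps, table, out / "table3.tsv")

        stage = "reconcile"
        groups, repo_haps = dedup_repository(fixture.repo_records)
        report = classify_support(
            repo_haps,
            fixture.reedited_haplotypes,
            fixture.aux_haplotypes,
            window=config.window,
        )
        _write_reconciliation(report, out / "reconciliation.tsv")

        stage = "amova"
        _write_amova(fixture.reedited_records, config, out / "table4.tsv")

        stage = "network"
        _write_network(fixture, table, repo_haps, out / "network.graphml")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": {**asdict(config), "window": list(config.window) if config.window else None},
            "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _write_stats(haps, table: CountTable, path: Path) -> None:
    rows = []
    for site in table.site_ids:
        rows.append(diversity_stats(site, haps, table.column(site)))
    rows.append(diversity_stats("Pooled", haps, table.row_totals()))
    chi = chi_square_unique(table)
    shared = sharedness(table)
    with open(path, "w") as fh:
        fh.write(
            "population\tn\tk\th\th_ci_low\th_ci_high\tpi\tpi_ci_low\tpi_ci_high\t"
            "S\tpct_A\tpct_C\tpct_G\tpct_T\tpct_GC\n"
        )
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.label, str(r.n), str(r.k),
                        _fmt(r.h), _fmt(r.ci_h[0]), _fmt(r.ci_h[1]),
                        _fmt(r.pi), _fmt(r.ci_pi[0]), _fmt(r.ci_pi[1]),
                        str(r.s),
                    ]
                    + [_fmt(r.composition[b], 1) for b in "ACGT"]
                    + [_fmt(r.gc_percent, 1)]
                )
                + "\n"
            )
        fh.write(f"# chi_square_unique = {chi.statistic:.2f}, df = {chi.df}, "
                 f"P = {chi.p_value:.3f}\n")
        fh.write(f"# unique to one site: {shared.n_unique} "
                 f"({shared.unique_percent:.1f}%)\n")


def _write_reconciliation(report, path: Path) -> None:
    s = report.summary()
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in s.items():
            fh.write(f"{k}\t{v if not isinstance(v, float) else _fmt(v, 1)}\n")
        fh.write("\n# per-haplotype assignments\n")
        fh.write("haplotype\tcategory\tmembers\n")
        for cat in ("supported", "aux_supported", "unsupported"):
            for label in sorted(getattr(report, cat)):
                fh.write(f"{label}\t{cat}\t\n")
        for label in sorted(report.novel):
            fh.write(f"{label}\tnovel\t\n")


def _write_amova(records, config: RunConfig, path: Path) -> None:
    sites = sorted({r.site for r in records})
    runs = [permutation_test(records, None, config.permutations, config.seed, "overall")]
    pools = []
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            subset = [r for r in records if r.site in (a, b)]
            runs.append(
                permutation_test(
                    subset, None, config.permutations, config.seed, f"{a} vs {b}"
                )
            )
    if len(sites) == 3:
        for merged in ((0, 1), (0, 2), (1, 2)):
            pool = {
                s: ("-".join(sites[m] for m in merged) if j in merged else s)
                for j, s in enumerate(sites)
            }
            pools.append(pool)
        runs.extend(pooled_runs(records, pools, config.permutations, config.seed))
    with open(path, "w") as fh:
        fh.write("grouping\tn\tpopulations\tphi_st\tp_value\tpermutations\tseed\n")
        for r in runs:
            fh.write(
                f"{r.grouping}\t{r.n}\t{r.n_populations}\t"
                f"{_fmt(r.phi_st_reported)}\t{_fmt(r.p_value)}\t"
                f"{r.n_permutations}\t{r.seed}\n"
            )


def _write_network(fixture, table: CountTable, repo_haps, path: Path) -> None:
    # union node space over re-edited and repository sequences
    seq_nodes: dict[str, str] = {}
    for h in fixture.reedited_haplotypes:
        seq_nodes.setdefault(h.seq, h.label)
    for h in repo_haps:
        seq_nodes.setdefault(h.seq, h.label)
    nodes = [
        Haplotype(label=lbl, seq=seq, members=()) for seq, lbl in seq_nodes.items()
    ]
    d = pairwise_diff_matrix(nodes)
    net = build_msn(nodes, d)

    reedited_counts = CountTable(
        haplotype_ids=[h.label for h in fixture.reedited_haplotypes],
        site_ids=["total"],
        counts=[[h.count] for h in fixture.reedited_haplotypes],
    )
    repo_rows = [(seq_nodes[h.seq], len(h.members)) for h in repo_haps]
    repo_counts = CountTable(
        haplotype_ids=[r[0] for r in repo_rows],
        site_ids=["total"],
        counts=[[r[1]] for r in repo_rows],
    )
    annotated = compare_layers(
        net, reedited_counts, repo_counts, layer_names=("reedited", "repository")
    )
    log.info("network layers: %s", layer_summary(annotated, ("reedited", "repository")))
    write_graphml(annotated, path)
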