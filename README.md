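# hapaudit

Quality control and reanalysis tooling for mtDNA control-region haplotype
datasets: reconcile the haplotypes deposited in a public sequence
repository against re-edited chromatogram base calls, and recompute the
population-genetic summaries (diversity statistics, chi-square tests,
AMOVA, haplotype networks) from first principles.

The package implements the full audit workflow for a Baltic grey seal
mtDNA dataset (three breeding sites: Bay of Bothnia, Estonia, Stockholm
Archipelago; 103 individuals, 435 bp fragments, 35 haplotypes) whose
distribution and duplicate-group tables are shipped as plain-text data.
The underlying chromatograms and accessions are not required: a seeded
synthetic-data module realizes the tables as concrete sequence fixtures.

## Modules

| module | purpose |
|---|---|
| `io_formats` | FASTA (`id\|site` headers) and distribution-table TSV readers/writers |
| `synthetic_data` | seeded generators: cohorts matching a count table, dual-editor call pairs, repositories with duplicates and corrupted entries |
| `editing_qc` | dual-editor consensus (IUPAC merge), the one-third inconsistency filter, common-window trimming |
| `haplotyping` | zero-mismatch collapse, count tables, site-sharedness summaries |
| `reconciliation` | repository dedup, supported / auxiliary-supported / unsupported / novel classification, corrected-reference assembly |
| `popgen_stats` | Nei unbiased haplotype diversity (+variance, CI), nucleotide diversity (Tajima total-variance CI), segregating sites, base composition, Pearson chi-square, t comparison |
| `amova` | one-level AMOVA variance components, Phi_ST, permutation P-values, pooled runs |
| `network` | minimum spanning network (tie-inclusive Kruskal), two-layer comparison, GraphML/DOT export |
| `pipeline`, `cli` | end-to-end orchestration and the `hapaudit` command |

## CLI

```bash
hapaudit simulate --seed 1 --out cohort.fasta --truth truth.tsv
hapaudit edit --calls-a a.fasta --calls-b b.fasta --out edited.fasta --report qc.tsv
hapaudit collapse cohort.fasta --out table.tsv --haps haps.fasta
hapaudit reconcile --repo repo.fasta --reedited re.fasta --aux aux.fasta --out report.tsv
hapaudit stats cohort.fasta --out stats.tsv
hapaudit amova cohort.fasta --pools "BB,EST|STA" --perms 10000 --seed 42
hapaudit network haps.fasta --out net.graphml --dot net.dot
hapaudit run --out rundir --seed 1         # full pipeline on the packaged tables
hapaudit reproduce --seed 1                # recompute headline values, pass/fail
```

`hapaudit run` writes `table2.tsv` (haplotype distribution), `table3.tsv`
(diversity statistics), `table4.tsv` (AMOVA), `reconciliation.tsv`,
`network.graphml` and a `manifest.json`; identical seeds give identical
outputs.

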