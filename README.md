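# ogxpand

Hypothesis-driven detection of expanded orthologous groups (OGs) from
standard comparative-genomics outputs, with integration of
differential-expression evidence, discovery of the most similar additional
OGs via reciprocal best hits, and exact set-level / GO-term
over-representation statistics. Results land in an open, checksummed,
subsettable directory bundle of TSV files.

## What it consumes

| input | format |
| --- | --- |
| hierarchical orthogroups | Orthofinder-style `N0.tsv` (one species per column, `", "`-separated gene lists) |
| differential expression | per-species TSV with gene id, log2 fold change, p-value, adjusted p-value (DESeq2-style exports; extra columns ignored) |
| protein hits | BLAST/DIAMOND tabular, 12-column `-outfmt 6` |
| GO annotations | TSV `gene_id <TAB> GO:...,GO:...` plus an OBO 1.2 ontology |
| species table | TSV `species`, `ploidy`, optional GO map path |
| hypotheses table | TSV: index, name, `expanded_in` / `compared_to` (semicolon-separated), `Nmin_expanded_in`, `min_expansion_factor`, `min_expansion_difference` |
| peptides (optional) | FASTA, for longest-isoform filtering |
| species tree (optional) | newick, carried through opaquely |

A hypothesis declares a set of species expected to show gene-family
expansion against a set expected not to. A species *qualifies* for an OG
when its gene count is at least `min_expansion_factor` times — and at least
`min_expansion_difference` genes above — the count of every `compared_to`
species (`--comparison any` relaxes "every" to "at least one"). The OG is
called expanded when at least `Nmin_expanded_in` species qualify. Optional
ploidy normalisation (`count * 2 / ploidy`) is off by default.

## CLI

```sh
# generate complete synthetic inputs with planted, recoverable signal
ogxpand simulate --config sim.yaml --seed 7 --out fixtures/

# full pipeline: expansion -> summary -> neighborhoods -> GO enrichment
ogxpand run --config run.yaml

# individual stages
ogxpand expand --orthogroups N0.tsv --hypotheses hypotheses.tsv \
    --factor 2 --difference 1 --nmin 1 --out calls.tsv
ogxpand summarize --orthogroups N0.tsv --hypotheses hypotheses.tsv \
    --de-dir de/ --alpha 0.05 --out summaries/
ogxpand neighborhood --orthogroups N0.tsv --hits hits.tsv \
    --focal expanded_ids.txt -n 3 --out neighborhood.tsv
ogxpand goenrich --orthogroups N0.tsv --go-map go_map.tsv --obo go.obo \
    --study expanded_ids.txt --algorithm elim --top 10 --out enrichment.tsv

# one-question set statistics on a finished bundle
ogxpand settest --bundle out/ \
    --sample "expanded & deg[Hordeum_vulgare]>=1" \
    --success "any_deg>=1" --background "conserved"

# bookmark export: keep only selected OGs, bundle stays schema-valid
ogxpand subset --bundle out/ --ogs bookmarks.txt --out subset/
```

`run` reads a single YAML config (same keys as the flags; flags win).
Exit codes: 0 ok, 2 validation error, 3 stage failure. Logs go to stderr,
results to files.

The `settest` predicate language is a conjunction of atoms:
`expanded`, `conserved`, `all`, `deg[Species]>=m`, `count[Species]>c`,
`any_deg>=m`, `total>=c` joined with `&`.

## Results bundle

`run` writes a directory with `manifest.json` (tool/schema versions,
config hash, per-file sha256) plus TSV members: `og_genes`,
`expansion_calls.h<i>`, `og_summary.h<i>`, `membership_counts.h<i>`,
`neighborhood.h<i>`, `extended_hits.h<i>`, `go_enrichment.h<i>`,
`de_table`, `go_annotations`, `hypotheses`. Identical inputs and config
give byte-identical tables. `subset` keeps only rows referencing the
chosen OGs (gene-level tables are filtered through the `og_genes`
membership map) and revalidates checksums on load.

## Library layout

- `ogxpand.formats_io` — readers/writers, longest-isoform filter, bundle
- `ogxpand.expansion` — per-hypothesis expansion calling
- `ogxpand.summary` — OG summary rows, membership patterns, size histograms
- `ogxpand.neighborhood` — reciprocal best hits, most-similar additional OGs
- `ogxpand.set_stats` — exact hypergeometric / Fisher urn tests, predicates
- `ogxpand.go_enrichment` — DAG propagation, classic/elim tests, BH
- `ogxpand.simulate` — synthetic fixture generator with truth tables
- `ogxpand.cli` — orchestration and the `ogxpand` entry point
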