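# Interchange formats

All coordinates are 0-based, half-open. All tables are TSV with a header row.
FASTA is wrapped at 60 columns.

## Gene table (`genes.tsv`)

| column | type | notes |
|---|---|---|
| gene_id | string | unique |
| chrom | string | |
| strand | `+` / `-` | |
| body_start | int or empty | transcript extent, optional |
| body_end | int or empty | |
| coding_start | int | |
| tss | int or empty | must be 5' of `coding_start` on `strand` |
| disease_class | `disease` / `non_disease` | |
| stratum | string | e.g. `XAR`, `XCR` |

## TSS tag clusters (`tss_clusters.tsv`)

Columns: `chrom`, `start`, `end`, `strand`, `tag_count` (`end > start`,
`tag_count >= 1`). The representative position of a cluster is its 5'-most
base in transcript orientation (`start` on `+`, `end - 1` on `-`).

## Annotation term lists (`terms.tsv`)

Long form, one row per term-gene pair: `term`, `category`, `gene_id`.
`category` is one of `anatomical_site`, `biological_process`, `phenotype`,
`animal_model`. A term with no genes appears once with an empty `gene_id`.

## Contig BED

BED6. `name` is `profile:gene1,gene2,...` where profile is the class label
of the source genes.

## Oligomer table

Columns: `sequence`, `k`, `count_focal`, `count_other`, `freq_focal`,
`freq_other` (counts per megabase), `fold` (`inf` when absent from the other
subgenome), `perm_hits`, `perm_trials`, `significant` (0/1; empty before the
permutation test).

## Feature matrix

`fm.tsv`: genes x oligomers integer counts, first column `gene_id`.
`labels.tsv`: `gene_id`, `disease_class`.

## Pipeline config (JSON)

Keys: `distances_kb`, `kmer_sizes`, `criteria` (sub-object with `min_count`,
`min_fold`, `perm_trials`, `max_perm_hits`, `fragment_bp`, `normalize`),
`tau_grid`, `variance_kept`, `seed`.
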