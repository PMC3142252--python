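"""Readers, writers and validation for the pipeline's interchange formats.

All tables are TSV with documented headers; BED is strictly 0-based
half-open; FASTA is wrapped at 60 columns.  Writers are deterministic
(stable column order, fixed float formatting) so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationTerm, ValidationError
from .genome import Contig, GeneRecord, TssTagCluster
from .motifs import OligomerRecord, OverrepCriteria

logger = logging.getLogger(__name__)

GENE_COLUMNS = [
    "gene_id", "chrom", "strand", "body_start", "body_end",
    "coding_start", "tss", "disease_class", "stratum",
]
TAG_COLUMNS = ["chrom", "start", "end", "strand", "tag_count"]
TERM_COLUMNS = ["term", "category", "gene_id"]
OLIGOMER_COLUMNS = [
    "sequence", "k", "count_focal", "count_other", "freq_focal",
    "freq_other", "fold", "perm_hits", "perm_trials", "significant",
]


# ---------------------------------------------------------------- FASTA / BED

def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gene_bed(path, genes: Sequence[GeneRecord]) -> None:
    """Gene bodies as BED6 (name = gene id, score = 0)."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.body_interval()
            fh.write(f"{g.chrom}\t{s}\t{e}\t{g.id}\t0\t{g.strand}\n")


def write_contig_bed(path, contigs: Sequence[Contig]) -> None:
    """Contigs as BED6 (name = profile:gene ids)."""
    with open(path, "w") as fh:
        for c in contigs:
            name = f"{c.profile}:{','.join(c.source_genes)}"
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t0\t+\n")


def read_contig_bed(path, stratum: str = "ALL") -> List[Contig]:
    contigs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValidationError(f"{path}:{lineno}: expected >= 4 BED columns")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if end <= start:
            raise ValidationError(f"{path}:{lineno}: end {end} <= start {start}")
        profile, _, gene_part = name.partition(":")
        contigs.append(Contig(chrom, start, end, profile, gene_part.split(","), stratum=stratum))
    return contigs


# ------------------------------------------------------------------ gene table

def _parse_int(value: str, path, lineno: int, column: str) -> Optional[int]:
    if value == "" or value == ".":
        return None
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"{path}:{lineno}: column {column!r} is not an integer: {value!r}")


def read_gene_table(path) -> List[GeneRecord]:
    """Gene table TSV -> GeneRecords; malformed rows are reported with line numbers."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header != GENE_COLUMNS:
        raise ValidationError(
            f"{path}:1: header mismatch; expected {GENE_COLUMNS}, got {header}"
        )
    genes = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(GENE_COLUMNS):
            raise ValidationError(f"{path}:{lineno}: expected {len(GENE_COLUMNS)} columns")
        row = dict(zip(GENE_COLUMNS, fields))
        if row["strand"] not in ("+", "-"):
            raise ValidationError(f"{path}:{lineno}: unknown strand {row['strand']!r}")
        try:
            genes.append(
                GeneRecord(
                    id=row["gene_id"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    coding_start=_parse_int(row["coding_start"], path, lineno, "coding_start"),
                    tss=_parse_int(row["tss"], path, lineno, "tss"),
                    disease_class=row["disease_class"],
                    stratum=row["stratum"],
                    body_start=_parse_int(row["body_start"], path, lineno, "body_start"),
                    body_end=_parse_int(row["body_end"], path, lineno, "body_end"),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(path, genes: Sequence[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.id,
                        g.chrom,
                        g.strand,
                        "" if g.body_start is None else str(g.body_start),
                        "" if g.body_end is None else str(g.body_end),
                        str(g.coding_start),
                        "" if g.tss is None else str(g.tss),
                        g.disease_class,
                        g.stratum,
                    ]
                )
                + "\n"
            )


# ----------------------------------------------------------------- tag clusters

def read_tag_clusters(path) -> List[TssTagCluster]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    if lines[0].split("\t") != TAG_COLUMNS:
        raise ValidationError(f"{path}:1: header mismatch; expected {TAG_COLUMNS}")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(TAG_COLUMNS):
            raise ValidationError(f"{path}:{lineno}: expected {len(TAG_COLUMNS)} columns")
        chrom, start, end, strand, tags = fields
        if strand not in ("+", "-"):
            raise ValidationError(f"{path}:{lineno}: unknown strand {strand!r}")
        start_i, end_i = int(start), int(end)
        if end_i <= start_i:
            raise ValidationError(f"{path}:{lineno}: end {end_i} <= start {start_i}")
        out.append(TssTagCluster(chrom, start_i, end_i, strand, int(tags)))
    return out


def write_tag_clusters(path, clusters: Sequence[TssTagCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAG_COLUMNS) + "\n")
        for c in clusters:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.tag_count}\n")


# ------------------------------------------------------------------ term lists

def read_term_lists(path) -> List[AnnotationTerm]:
    """Long-form TSV (term, category, gene_id; one row per term-gene pair)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    if lines[0].split("\t") != TERM_COLUMNS:
        raise ValidationError(f"{path}:1: header mismatch; expected {TERM_COLUMNS}")
    seen: Dict[str, Dict] = {}
    order: List[str] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValidationError(f"{path}:{lineno}: expected 3 columns")
        term, category, gene = fields
        if term not in seen:
            seen[term] = {"category": category, "genes": set()}
            order.append(term)
        elif seen[term]["category"] != category:
            raise ValidationError(
                f"{path}:{lineno}: term {term!r} listed with conflicting categories"
            )
        if gene:
            seen[term]["genes"].add(gene)
    return [AnnotationTerm(t, seen[t]["category"], frozenset(seen[t]["genes"])) for t in order]


def write_term_lists(path, terms: Sequence[AnnotationTerm]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TERM_COLUMNS) + "\n")
        for t in terms:
            if not t.genes:
                fh.write(f"{t.name}\t{t.category}\t\n")
            for g in sorted(t.genes):
                fh.write(f"{t.name}\t{t.category}\t{g}\n")


def read_gene_list(path) -> List[str]:
    """Plain-text gene list (or first column of a BED-like file)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line.split("\t")[0])
    return out


# -------------------------------------------------------------------- oligomers

def write_oligomer_table(path, records: Sequence[OligomerRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(OLIGOMER_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.sequence,
                        str(r.k),
                        str(r.count_focal),
                        str(r.count_other),
                        f"{r.freq_focal:.6f}",
                        f"{r.freq_other:.6f}",
                        "inf" if r.fold == float("inf") else f"{r.fold:.6f}",
                        "" if r.perm_hits is None else str(r.perm_hits),
                        "" if r.perm_trials is None else str(r.perm_trials),
                        "" if r.significant is None else str(int(r.significant)),
                    ]
                )
                + "\n"
            )


def read_oligomer_table(path) -> List[OligomerRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, r in df.iterrows():
        records.append(
            OligomerRecord(
                sequence=r["sequence"],
                k=int(r["k"]),
                count_focal=int(r["count_focal"]),
                count_other=int(r["count_other"]),
                freq_focal=float(r["freq_focal"]),
                freq_other=float(r["freq_other"]),
                fold=float(r["fold"]),
                perm_hits=int(r["perm_hits"]) if r["perm_hits"] != "" else None,
                perm_trials=int(r["perm_trials"]) if r["perm_trials"] != "" else None,
                significant=bool(int(r["significant"])) if r["significant"] != "" else None,
            )
        )
    return records


# --------------------------------------------------------------- feature matrix

def write_feature_matrix(path_counts, path_labels, fm) -> None:
    df = pd.DataFrame(fm.counts.astype(int), index=fm.gene_ids, columns=fm.features)
    df.index.name = "gene_id"
    df.to_csv(path_counts, sep="\t")
    lab = pd.DataFrame({"gene_id": fm.gene_ids, "disease_class": fm.labels})
    lab.to_csv(path_labels, sep="\t", index=False)


def read_feature_matrix(path_counts, path_labels):
    from .discriminant import FeatureMatrix

    df = pd.read_csv(path_counts, sep="\t", index_col="gene_id")
    lab = pd.read_csv(path_labels, sep="\t", index_col="gene_id")
    labels = [lab.loc[g, "disease_class"] for g in df.index]
    return FeatureMatrix(list(df.index), labels, list(df.columns), df.to_numpy(dtype=float))


# ----------------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Shared run configuration echoed into logs for reproducibility."""

    distances_kb: List[int] = field(default_factory=lambda: [5, 10, 50, 100])
    kmer_sizes: List[int] = field(default_factory=lambda: [8, 12, 16, 20, 24])
    criteria: OverrepCriteria = field(default_factory=OverrepCriteria)
    tau_grid: List[float] = field(default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 20)])
    variance_kept: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.distances_kb):
            raise ValueError("distances must be positive")
        if any(k <= 0 for k in self.kmer_sizes):
            raise ValueError("k-mer sizes must be positive")


def load_config(path) -> PipelineConfig:
    import json

    raw = json.loads(Path(path).read_text())
    crit = OverrepCriteria(**raw.pop("criteria", {}))
    return PipelineConfig(criteria=crit, **raw)
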