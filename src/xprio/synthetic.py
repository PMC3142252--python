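"""Synthetic chromosomes, gene models, TSS tag tables and term lists.

Every pipeline stage can be exercised without external downloads: a random
chromosome at a configurable GC content carries planted gene models on
alternating strands, class-specific upstream motifs overwritten at a
configurable Poisson rate, TSS tag clusters (with single-tag decoys so the
exclusion rule is always exercised), and annotation term lists whose overlap
with the disease gene set is tunable.  All randomness flows from one seeded
generator, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import CATEGORIES, AnnotationTerm
from .genome import DISEASE, NON_DISEASE, GeneRecord, TssTagCluster

CHROM = "chrS"

_GENE_GAP = 500     # promoter gap between TSS and coding start
_BODY_LEN = 2500    # transcript extent from TSS


@dataclass
class SimConfig:
    seed: int = 0
    chrom_length: int = 800_000
    gc_content: float = 0.41
    n_disease: int = 10
    n_non_disease: int = 20
    strata_fractions: Dict[str, float] = field(default_factory=lambda: {"XAR": 1.0})
    planted_motifs: List[Tuple[str, str, float]] = field(default_factory=list)
    n_terms: int = 40
    p_match_disease: float = 0.5
    p_match_background: float = 0.1
    tss_jitter: int = 20
    min_intergenic: int = 12_000
    plant_window: int = 5_000

    def __post_init__(self):
        for p in (self.gc_content, self.p_match_disease, self.p_match_background):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_disease < 2 or self.n_non_disease < 2:
            raise ValueError("need at least 2 genes per class")
        for seq, cls, rate in self.planted_motifs:
            if cls not in (DISEASE, NON_DISEASE):
                raise ValueError(f"motif target class {cls!r} unknown")
            if rate < 0:
                raise ValueError("motif rate must be >= 0")


@dataclass
class GroundTruth:
    genes: List[GeneRecord]
    motif_positions: List[Tuple[str, str, int]]  # (motif, gene_id, genomic position)
    term_membership: Dict[str, List[str]]

    def to_json(self) -> str:
        payload = {
            "genes": [
                {
                    "id": g.id,
                    "strand": g.strand,
                    "tss": g.tss,
                    "coding_start": g.coding_start,
                    "disease_class": g.disease_class,
                    "stratum": g.stratum,
                }
                for g in self.genes
            ],
            "motif_positions": [list(t) for t in self.motif_positions],
            "term_membership": self.term_membership,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimDataset:
    config: SimConfig
    sequences: Dict[str, str]
    genes: List[GeneRecord]
    clusters: List[TssTagCluster]
    terms: List[AnnotationTerm]
    ground_truth: GroundTruth

    def write(self, out_dir) -> Dict[str, Path]:
        from . import io_utils

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "genome.fa",
            "genes": out_dir / "genes.tsv",
            "bed": out_dir / "genes.bed",
            "tss": out_dir / "tss_clusters.tsv",
            "terms": out_dir / "terms.tsv",
            "known": out_dir / "known.txt",
            "ground_truth": out_dir / "ground_truth.json",
        }
        io_utils.write_fasta(paths["fasta"], self.sequences)
        io_utils.write_gene_table(paths["genes"], self.genes)
        io_utils.write_gene_bed(paths["bed"], self.genes)
        io_utils.write_tag_clusters(paths["tss"], self.clusters)
        io_utils.write_term_lists(paths["terms"], self.terms)
        known = sorted(g.id for g in self.genes if g.disease_class == DISEASE)
        paths["known"].write_text("".join(f"{g}\n" for g in known))
        paths["ground_truth"].write_text(self.ground_truth.to_json() + "\n")
        return paths


def regime_preset(name: str) -> SimConfig:
    """Named configurations echoing the study's class sizes, plus a signal-free null.

    ``paper_like_XAR`` and ``paper_like_XCR`` plant strong disease-specific
    upstream motifs at desk scale (5 kb windows standing in for the largest
    distance regime); ``null`` has balanced classes and no planted signal.
    """
    motifs = [
        ("ACGGTCACGTTA", DISEASE, 10.0),
        ("TGCAAGGCTACA", DISEASE, 10.0),
    ]
    if name == "paper_like_XAR":
        return SimConfig(
            chrom_length=3_600_000,
            n_disease=25,
            n_non_disease=110,
            strata_fractions={"XAR": 1.0},
            planted_motifs=motifs,
            p_match_disease=0.5,
            p_match_background=0.12,
        )
    if name == "paper_like_XCR":
        return SimConfig(
            chrom_length=11_000_000,
            n_disease=56,
            n_non_disease=376,
            strata_fractions={"XCR": 1.0},
            planted_motifs=motifs,
            p_match_disease=0.5,
            p_match_background=0.12,
        )
    if name == "null":
        return SimConfig(
            chrom_length=1_100_000,
            n_disease=20,
            n_non_disease=20,
            planted_motifs=[],
            p_match_disease=0.2,
            p_match_background=0.2,
        )
    raise ValueError(f"unknown preset {name!r}; expected paper_like_XAR, paper_like_XCR or null")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(rng.choice(bases, size=length, p=p).tobytes())


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate a complete toy dataset with ground truth.

    Genes alternate strands along the chromosome at >= ``min_intergenic``
    body-to-body spacing; each gene gets a genuine multi-tag TSS cluster at
    the true TSS (jittered by up to ``tss_jitter``), a weaker same-strand
    decoy and a single-tag decoy; motifs are planted by overwriting sequence
    at Poisson(rate) positions within target-class upstream windows.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_disease + cfg.n_non_disease
    # each slot reserves room for the gene body, both flanking upstream
    # windows and the requested intergenic gap, so windows of adjacent genes
    # never collide regardless of strand orientation
    slot = cfg.min_intergenic + _BODY_LEN + 2 * cfg.plant_window
    margin = cfg.plant_window + 1000
    required = margin + n * slot + margin
    if cfg.chrom_length < required:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too short for {n} genes; need >= {required}"
        )

    seq = _random_sequence(rng, cfg.chrom_length, cfg.gc_content)

    labels = [DISEASE] * cfg.n_disease + [NON_DISEASE] * cfg.n_non_disease
    rng.shuffle(labels)

    strata = sorted(cfg.strata_fractions)
    weights = np.array([cfg.strata_fractions[s] for s in strata], dtype=float)
    weights = weights / weights.sum()

    genes: List[GeneRecord] = []
    clusters: List[TssTagCluster] = []
    for i, label in enumerate(labels):
        anchor = margin + i * slot + int(rng.integers(0, cfg.min_intergenic // 4))
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss = anchor
            coding_start = anchor + _GENE_GAP
            body = (tss, tss + _BODY_LEN)
        else:
            tss = anchor + _BODY_LEN - 1
            coding_start = tss - _GENE_GAP
            body = (anchor, tss + 1)
        stratum = strata[int(rng.choice(len(strata), p=weights))]
        gene = GeneRecord(
            id=f"G{i:04d}",
            chrom=CHROM,
            strand=strand,
            coding_start=coding_start,
            tss=tss,
            disease_class=label,
            stratum=stratum,
            body_start=body[0],
            body_end=body[1],
        )
        genes.append(gene)

        # genuine cluster: 5'-most base lands on the (jittered) true TSS
        jitter = int(rng.integers(-cfg.tss_jitter, cfg.tss_jitter + 1))
        width = int(rng.integers(5, 25))
        tags = int(rng.integers(10, 51))
        if strand == "+":
            start = tss + jitter
            clusters.append(TssTagCluster(CHROM, start, start + width, strand, tags))
        else:
            end = tss + jitter + 1
            clusters.append(TssTagCluster(CHROM, end - width, end, strand, tags))
        # weaker same-strand decoy further upstream (exercises the max-tag rule)
        off = int(rng.integers(300, 900))
        decoy_tags = int(rng.integers(2, 6))
        if strand == "+":
            clusters.append(TssTagCluster(CHROM, tss - off, tss - off + width, strand, decoy_tags))
        else:
            clusters.append(TssTagCluster(CHROM, tss + off, tss + off + width, strand, decoy_tags))
        # single-tag decoy (must be excluded by the one-tag rule)
        off2 = int(rng.integers(1000, 1500))
        if strand == "+":
            clusters.append(TssTagCluster(CHROM, tss - off2, tss - off2 + 10, strand, 1))
        else:
            clusters.append(TssTagCluster(CHROM, tss + off2, tss + off2 + 10, strand, 1))

    # plant motifs into target-class upstream windows (overwrite, keep coordinates)
    motif_positions: List[Tuple[str, str, int]] = []
    for motif, target, rate in cfg.planted_motifs:
        m = len(motif)
        mbytes = motif.encode()
        for g in genes:
            if g.disease_class != target:
                continue
            if g.strand == "+":
                lo, hi = g.tss - cfg.plant_window, g.tss - m
            else:
                lo, hi = g.tss + 1, g.tss + 1 + cfg.plant_window - m
            n_occ = int(rng.poisson(rate))
            placed: List[int] = []
            attempts = 0
            while len(placed) < n_occ and attempts < 50 * max(n_occ, 1):
                attempts += 1
                pos = int(rng.integers(lo, hi + 1))
                if any(abs(pos - q) < m for q in placed):
                    continue
                placed.append(pos)
            for pos in sorted(placed):
                seq[pos : pos + m] = mbytes
                motif_positions.append((motif, g.id, pos))

    # term lists
    terms: List[AnnotationTerm] = []
    membership: Dict[str, List[str]] = {}
    for t in range(cfg.n_terms):
        name = f"term{t:03d}"
        category = CATEGORIES[t % len(CATEGORIES)]
        members = []
        for g in genes:
            p = cfg.p_match_disease if g.disease_class == DISEASE else cfg.p_match_background
            if rng.random() < p:
                members.append(g.id)
        terms.append(AnnotationTerm(name, category, frozenset(members)))
        membership[name] = members

    truth = GroundTruth(genes=genes, motif_positions=motif_positions, term_membership=membership)
    return SimDataset(
        config=cfg,
        sequences={CHROM: seq.decode()},
        genes=genes,
        clusters=clusters,
        terms=terms,
        ground_truth=truth,
    )
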