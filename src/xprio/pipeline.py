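"""End-to-end orchestration: TSS selection -> contigs -> subgenomes -> motifs -> LDA."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence

from . import discriminant, genome, motifs
from .genome import DISEASE, NON_DISEASE, Contig, GeneRecord, Subgenome, TssTagCluster
from .motifs import OligomerRecord, OverrepCriteria

logger = logging.getLogger(__name__)


def assign_tss(
    genes: Sequence[GeneRecord],
    clusters: Sequence[TssTagCluster],
    max_distance: int = 5000,
) -> tuple[List[GeneRecord], List[str]]:
    """Replace each gene's TSS with its representative tag-cluster position.

    Only clusters whose 5'-most base lies within ``max_distance`` upstream of
    the gene's coding start are considered that gene's candidates; the
    selection rules (strand, 5' position, tag count, proximity) then pick the
    representative.  Genes with no surviving cluster keep ``tss=None`` and
    are listed in the second return value.
    """
    by_chrom: Dict[str, List[TssTagCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, []).append(c)
    out, no_tss = [], []
    for g in genes:
        nearby = [
            c
            for c in by_chrom.get(g.chrom, [])
            if abs(c.representative_position() - g.coding_start) <= max_distance
        ]
        pos = genome.select_representative_tss(g, nearby)
        if pos is None:
            no_tss.append(g.id)
            out.append(replace(g, tss=None))
        else:
            out.append(replace(g, tss=pos))
    return out, no_tss


@dataclass
class StratumAnalysis:
    """All artifacts of one (stratum, distance, k) discovery + classification run."""

    stratum: str
    distance_kb: int
    contigs: List[Contig]
    rejects: List[tuple]
    subgenomes: Dict[str, Subgenome]
    candidates: List[OligomerRecord]
    tested: List[OligomerRecord]
    oligomers: List[OligomerRecord]
    feature_matrix: Optional[discriminant.FeatureMatrix]
    excluded: List[tuple]


def analyze_stratum(
    genes: Sequence[GeneRecord],
    fasta: Mapping[str, str],
    stratum: str,
    distance_kb: int,
    k: int = 12,
    criteria: OverrepCriteria = OverrepCriteria(),
    seed: int = 0,
    merge: bool = True,
) -> StratumAnalysis:
    """Discover significant oligomers for one stratum/distance and featurize genes.

    Genes must already carry representative TSSs (see :func:`assign_tss`).
    """
    strat_genes = [g for g in genes if g.stratum == stratum]
    chrom_lengths = {name: len(seq) for name, seq in fasta.items()}
    contigs, rejects = genome.build_contigs(strat_genes, distance_kb, chrom_lengths)
    subgenomes = {
        sg.label[0]: sg for sg in genome.compile_subgenomes(contigs, fasta, distance_kb)
    }
    focal, other = subgenomes.get(DISEASE), subgenomes.get(NON_DISEASE)
    if focal is None or other is None:
        raise ValueError(
            f"stratum {stratum}: both classes need surviving contigs at {distance_kb} kb"
        )

    candidates = motifs.find_overrepresented(focal, other, k, criteria)
    tested = motifs.permutation_test(focal, other, candidates, criteria, seed=seed)
    significant = [r for r in tested if r.significant]
    oligomers = motifs.merge_oligomers(significant) if merge else significant

    fm = None
    excluded: List[tuple] = list(rejects)
    if oligomers:
        fm, excl = discriminant.build_feature_matrix(
            strat_genes, contigs, [r.sequence for r in oligomers], fasta
        )
        excluded += excl
    else:
        logger.warning(
            "stratum %s @ %dkb: no significant oligomer survived; no classifier built",
            stratum,
            distance_kb,
        )
    return StratumAnalysis(
        stratum=stratum,
        distance_kb=distance_kb,
        contigs=contigs,
        rejects=rejects,
        subgenomes=subgenomes,
        candidates=candidates,
        tested=tested,
        oligomers=oligomers,
        feature_matrix=fm,
        excluded=excluded,
    )


def classification_calls(cv: discriminant.CvResult) -> Dict[str, str]:
    """Per-gene X/NX calls from a CV result."""
    return {
        g: ("X" if pred == DISEASE else "NX") for g, (_, pred, _) in cv.per_gene.items()
    }
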