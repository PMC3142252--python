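"""Gene models, representative-TSS selection, and upstream subgenome assembly.

Coordinates are 0-based half-open throughout.  "Contigs" here are upstream
windows anchored at a gene's representative TSS, after merge/discard rules;
a "subgenome" pools the contigs sharing one (class, stratum, distance) label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

DISEASE = "disease"
NON_DISEASE = "non_disease"
PROFILES = (DISEASE, NON_DISEASE)


@dataclass(frozen=True)
class GeneRecord:
    """A gene with coordinates, class label and evolutionary stratum."""

    id: str
    chrom: str
    strand: str
    coding_start: int
    tss: Optional[int] = None
    disease_class: str = NON_DISEASE
    stratum: str = "ALL"
    body_start: Optional[int] = None
    body_end: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.disease_class not in PROFILES:
            raise ValueError(f"gene {self.id}: unknown class {self.disease_class!r}")
        if self.tss is not None:
            upstream_ok = self.tss < self.coding_start if self.strand == "+" else self.tss > self.coding_start
            if not upstream_ok:
                raise ValueError(
                    f"gene {self.id}: tss {self.tss} is not 5' of coding start "
                    f"{self.coding_start} on strand {self.strand}"
                )

    def body_interval(self) -> tuple[int, int]:
        """Widest available gene extent, used for the opposite-profile overlap rule."""
        pts = [self.coding_start]
        if self.tss is not None:
            pts.append(self.tss)
        start, end = min(pts), max(pts) + 1
        if self.body_start is not None:
            start = min(start, self.body_start)
        if self.body_end is not None:
            end = max(end, self.body_end)
        return start, end


@dataclass(frozen=True)
class TssTagCluster:
    """A strand-specific interval of 5'-capture tags evidencing a TSS."""

    chrom: str
    start: int
    end: int
    strand: str
    tag_count: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"tag cluster end {self.end} <= start {self.start}")
        if self.tag_count < 1:
            raise ValueError("tag_count must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def representative_position(self) -> int:
        """The 5'-most base of the cluster in transcript orientation."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Contig:
    """A merged upstream window labeled with its source genes' class profile."""

    chrom: str
    start: int
    end: int
    profile: str
    source_genes: list
    stratum: str = "ALL"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("contig end must exceed start")
        if not self.source_genes:
            raise ValueError("contig must have at least one source gene")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class Subgenome:
    """Contigs pooled under one (class, stratum, distance_kb) label, with sequence."""

    label: tuple
    contigs: list
    sequences: list

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # >= 1 shared base; touching half-open intervals do not overlap
    return a_start < b_end and b_start < a_end


def select_representative_tss(
    gene: GeneRecord,
    clusters: Sequence[TssTagCluster],
    evidence_intervals: Optional[Sequence[tuple[int, int]]] = None,
) -> Optional[int]:
    """Pick the representative TSS coordinate for a gene from its tag clusters.

    Filters, in order: same strand; entirely 5' of the coding start on that
    strand; more than one tag; overlapping a supplied evidence interval (if
    any are supplied).  Of the survivors the highest tag count wins, ties
    going to the cluster closest to the coding start.  Returns ``None`` when
    no cluster survives.
    """
    survivors = []
    for c in clusters:
        if c.chrom != gene.chrom or c.strand != gene.strand:
            continue
        if gene.strand == "+":
            if c.end > gene.coding_start:
                continue
        else:
            if c.start <= gene.coding_start:
                continue
        if c.tag_count < 2:
            continue
        if evidence_intervals is not None and not any(
            _overlaps(c.start, c.end, s, e) for s, e in evidence_intervals
        ):
            continue
        survivors.append(c)
    if not survivors:
        logger.info("gene %s: no surviving TSS tag cluster", gene.id)
        return None

    def distance(c: TssTagCluster) -> int:
        pos = c.representative_position()
        return abs(gene.coding_start - pos)

    best = min(survivors, key=lambda c: (-c.tag_count, distance(c), c.start))
    return best.representative_position()


def upstream_interval(
    gene: GeneRecord,
    distance: int,
    chrom_length: Optional[int] = None,
    include_downstream: bool = False,
) -> tuple[int, int]:
    """Raw window of ``distance`` bases immediately 5' of the gene's TSS.

    With ``include_downstream`` the window extends ``distance`` on both sides
    of the TSS.  Clamped to [0, chrom_length).
    """
    if gene.tss is None:
        raise ValueError(f"gene {gene.id} has no TSS")
    t = gene.tss
    if include_downstream:
        start, end = t - distance, t + distance + 1
    elif gene.strand == "+":
        start, end = t - distance, t
    else:
        start, end = t + 1, t + 1 + distance
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


def build_contigs(
    genes: Sequence[GeneRecord],
    distance_kb: int,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    include_downstream: bool = False,
) -> tuple[list[Contig], list[tuple[str, str]]]:
    """Build merged, conflict-filtered upstream contigs at one distance.

    Per gene, the window of ``distance_kb * 1000`` bases 5' of its TSS is
    taken (truncated at chromosome bounds); then (a) overlapping same-profile
    windows are merged, (b) contigs overlapping an opposite-profile contig
    are discarded pairwise (both sides), and (c) contigs overlapping any
    opposite-profile gene body are discarded.

    Returns ``(contigs, rejects)`` where rejects is a list of
    ``(gene_id or contig description, reason)`` pairs.
    """
    if distance_kb <= 0:
        raise ValueError("distance_kb must be positive")
    distance = distance_kb * 1000
    rejects: list[tuple[str, str]] = []

    raw: list[Contig] = []
    for g in genes:
        if g.tss is None:
            rejects.append((g.id, "no annotated TSS"))
            continue
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        start, end = upstream_interval(g, distance, clen, include_downstream)
        if end <= start:
            rejects.append((g.id, "empty window after truncation"))
            continue
        raw.append(
            Contig(g.chrom, start, end, g.disease_class, [g.id], stratum=g.stratum)
        )

    # (a) merge overlapping same-profile contigs, per chromosome
    merged: list[Contig] = []
    for profile in PROFILES:
        by_chrom: dict[str, list[Contig]] = {}
        for c in raw:
            if c.profile == profile:
                by_chrom.setdefault(c.chrom, []).append(c)
        for chrom, items in sorted(by_chrom.items()):
            items.sort(key=lambda c: (c.start, c.end))
            current = items[0]
            for nxt in items[1:]:
                if _overlaps(current.start, current.end, nxt.start, nxt.end):
                    current = Contig(
                        chrom,
                        current.start,
                        max(current.end, nxt.end),
                        profile,
                        sorted(set(current.source_genes) | set(nxt.source_genes)),
                        stratum=current.stratum,
                    )
                else:
                    merged.append(current)
                    current = nxt
            merged.append(current)

    # (b) discard both members of every opposite-profile overlapping pair
    doomed = set()
    for i, a in enumerate(merged):
        for j in range(i + 1, len(merged)):
            b = merged[j]
            if a.profile != b.profile and a.chrom == b.chrom and _overlaps(
                a.start, a.end, b.start, b.end
            ):
                doomed.add(i)
                doomed.add(j)
    kept = []
    for i, c in enumerate(merged):
        if i in doomed:
            rejects.append((",".join(c.source_genes), "overlaps opposite-profile contig"))
        else:
            kept.append(c)

    # (c) discard contigs overlapping any opposite-profile gene body
    final = []
    for c in kept:
        conflict = None
        for g in genes:
            if g.chrom != c.chrom or g.disease_class == c.profile:
                continue
            bs, be = g.body_interval()
            if _overlaps(c.start, c.end, bs, be):
                conflict = g.id
                break
        if conflict is None:
            final.append(c)
        else:
            rejects.append(
                (",".join(c.source_genes), f"overlaps opposite-profile gene body ({conflict})")
            )

    final.sort(key=lambda c: (c.chrom, c.start))
    return final, rejects


def compile_subgenomes(
    contigs: Sequence[Contig],
    fasta: Mapping[str, str],
    distance_kb: int,
) -> list[Subgenome]:
    """Group contigs by (profile, stratum) and attach reference-strand sequence.

    Sequences are taken from the plus strand without reverse-complementing;
    downstream k-mer counting is reverse-complement collapsed, so orientation
    is immaterial there.
    """
    groups: dict[tuple, list[Contig]] = {}
    for c in contigs:
        groups.setdefault((c.profile, c.stratum), []).append(c)
    out = []
    for (profile, stratum), items in sorted(groups.items()):
        seqs = []
        for c in items:
            if c.chrom not in fasta:
                raise ValueError(f"contig {c.chrom}:{c.start}-{c.end}: unknown sequence {c.chrom}")
            ref = fasta[c.chrom]
            if c.end > len(ref) or c.start < 0:
                raise ValueError(
                    f"contig {c.chrom}:{c.start}-{c.end} out of range for sequence of length {len(ref)}"
                )
            seqs.append(str(ref[c.start : c.end]).upper())
        out.append(Subgenome((profile, stratum, distance_kb), list(items), seqs))
    return out
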