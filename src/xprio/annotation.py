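"""Annotation-based candidate gene ranking.

Genes are scored against flat annotation-term gene lists on a binary
(present/absent) grid; the row sum is the gene's score and genes are ranked
by descending score.  A known-gene set can then be used to summarize
enrichment in the top of the ranking, to draw a cumulative coverage curve,
and to test the overlap of two prioritized sets with a hypergeometric tail
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: the four flat term categories, weighted equally
CATEGORIES = ("anatomical_site", "biological_process", "phenotype", "animal_model")


class ValidationError(ValueError):
    """Raised when an input table violates its documented schema."""


@dataclass(frozen=True)
class AnnotationTerm:
    """A named annotation term with the set of gene ids it selects."""

    name: str
    category: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.name:
            raise ValidationError("annotation term name must be nonempty")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown term category {self.category!r}; expected one of {CATEGORIES}"
            )
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class BinaryGrid:
    """Gene x term 0/1 membership matrix with per-gene scores and ranks.

    ``scores[i]`` is the row sum for ``genes[i]``; ``ranks[i]`` is its
    1-based rank, descending by score with ties broken lexicographically
    by gene id.
    """

    genes: list
    terms: list
    categories: list
    matrix: np.ndarray
    scores: np.ndarray
    ranks: np.ndarray

    def score_of(self, gene: str) -> int:
        return int(self.scores[self.genes.index(gene)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.genes, columns=self.terms)


@dataclass
class EnrichmentSummary:
    threshold: int
    n_top: int
    n_top_known: int
    frac_top_known: float
    n_all: int
    n_all_known: int
    frac_all_known: float
    fold: float


def build_binary_grid(genes: Sequence[str], terms: Sequence[AnnotationTerm]) -> BinaryGrid:
    """Build the binary evaluation grid for ``genes`` against ``terms``.

    Entry (g, t) is 1 iff gene g appears in term t's gene list.  Scores are
    row sums; ranks are descending by score, ties broken by gene id.
    """
    genes = list(genes)
    seen: set = set()
    for g in genes:
        if g in seen:
            raise ValidationError(f"duplicate gene id: {g!r}")
        seen.add(g)
    seen.clear()
    for t in terms:
        if t.name in seen:
            raise ValidationError(f"duplicate term name: {t.name!r}")
        seen.add(t.name)

    matrix = np.zeros((len(genes), len(terms)), dtype=np.int8)
    for j, term in enumerate(terms):
        for i, g in enumerate(genes):
            if g in term.genes:
                matrix[i, j] = 1
    scores = matrix.sum(axis=1).astype(int)

    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    ranks = np.empty(len(genes), dtype=int)
    for rank0, i in enumerate(order):
        ranks[i] = rank0 + 1

    return BinaryGrid(
        genes=genes,
        terms=[t.name for t in terms],
        categories=[t.category for t in terms],
        matrix=matrix,
        scores=scores,
        ranks=ranks,
    )


def enrichment_summary(
    grid: BinaryGrid, known: Iterable[str], threshold: int
) -> EnrichmentSummary:
    """Summarize enrichment of ``known`` genes among genes scoring >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if len(grid.genes) == 0:
        raise ValueError("empty grid")
    known = set(known)
    top = [g for g, s in zip(grid.genes, grid.scores) if s >= threshold]
    if not top:
        raise ValueError("no genes pass threshold")
    n_top = len(top)
    n_top_known = sum(1 for g in top if g in known)
    n_all = len(grid.genes)
    n_all_known = sum(1 for g in grid.genes if g in known)
    frac_top = n_top_known / n_top
    frac_all = n_all_known / n_all
    if frac_all == 0:
        raise ValueError("no known genes in grid; fold enrichment undefined")
    return EnrichmentSummary(
        threshold=threshold,
        n_top=n_top,
        n_top_known=n_top_known,
        frac_top_known=frac_top,
        n_all=n_all,
        n_all_known=n_all_known,
        frac_all_known=frac_all,
        fold=frac_top / frac_all,
    )


def enrichment_from_counts(
    n_top: int, n_top_known: int, n_all: int, n_all_known: int, threshold: int = 0
) -> EnrichmentSummary:
    """Enrichment arithmetic from pre-tabulated counts (no grid required)."""
    if n_top == 0:
        raise ValueError("no genes pass threshold")
    frac_top = n_top_known / n_top
    frac_all = n_all_known / n_all
    if frac_all == 0:
        raise ValueError("fold enrichment undefined when frac_all_known = 0")
    return EnrichmentSummary(threshold, n_top, n_top_known, frac_top, n_all, n_all_known, frac_all, frac_top / frac_all)


def coverage_curve(grid: BinaryGrid, known: Iterable[str]) -> pd.DataFrame:
    """Cumulative coverage of ``known`` genes by descending score level.

    Returns one row per distinct score level (descending) with columns
    ``score_level``, ``cumulative_known_coverage`` (fraction of in-grid known
    genes with score >= level) and ``pct_known_within_level`` (fraction of
    the genes at exactly that level that are known).
    """
    known = set(known)
    in_grid = known & set(grid.genes)
    dropped = known - in_grid
    if dropped:
        logger.warning(
            "%d known gene ids absent from grid ignored: %s",
            len(dropped),
            sorted(dropped)[:10],
        )
    if not in_grid:
        raise ValueError("no known gene intersects the grid")

    scores = {g: int(s) for g, s in zip(grid.genes, grid.scores)}
    levels = sorted(set(scores.values()), reverse=True)
    rows = []
    cum_known = 0
    for level in levels:
        at_level = [g for g in grid.genes if scores[g] == level]
        known_at_level = sum(1 for g in at_level if g in in_grid)
        cum_known += known_at_level
        rows.append(
            {
                "score_level": level,
                "cumulative_known_coverage": cum_known / len(in_grid),
                "pct_known_within_level": known_at_level / len(at_level),
            }
        )
    return pd.DataFrame(rows)


def hypergeometric_overlap(
    k: int, N: int, m: int, n: int, inclusive: bool = True
) -> float:
    """Upper-tail hypergeometric overlap probability.

    With ``inclusive`` (the standard over-representation convention) this is
    P(X >= k) for X ~ Hypergeometric(N, m, n): the probability of drawing at
    least ``k`` of the ``m`` marked genes when sampling ``n`` of ``N``.
    ``inclusive=False`` gives the strict tail P(X > k), which some tools
    report instead.
    """
    if m > N or n > N:
        raise ValueError("m and n must not exceed N")
    if k < 0 or N < 0 or m < 0 or n < 0:
        raise ValueError("all arguments must be non-negative")
    cut = k - 1 if inclusive else k
    return float(hypergeom.sf(cut, N, m, n))


def per_category_matches(grid: BinaryGrid) -> pd.DataFrame:
    """Per-gene match counts broken down by term category."""
    data = {}
    cats = np.asarray(grid.categories)
    for cat in CATEGORIES:
        cols = np.flatnonzero(cats == cat)
        data[cat] = grid.matrix[:, cols].sum(axis=1) if cols.size else np.zeros(len(grid.genes), int)
    return pd.DataFrame(data, index=grid.genes)


def ranking_table(grid: BinaryGrid, known: Iterable[str] = ()) -> pd.DataFrame:
    """Full ranking as a table: gene, score, rank, per-category counts, known flag."""
    known = set(known)
    df = pd.DataFrame(
        {
            "gene_id": grid.genes,
            "score": grid.scores,
            "rank": grid.ranks,
        }
    )
    df = df.join(per_category_matches(grid).reset_index(drop=True))
    df["known"] = [int(g in known) for g in grid.genes]
    return df.sort_values("rank").reset_index(drop=True)
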