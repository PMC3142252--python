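"""Oligomer-count feature matrices and linear discriminant classification.

The predictor dimension (one column per discovered oligomer) typically far
exceeds the number of genes, so counts are first projected onto principal
components retaining a configurable variance fraction (capped at n - 2
components); a two-class Gaussian LDA with pooled covariance and empirical
priors is fit in the reduced space.  The tuning parameter ``tau`` is the
posterior-probability decision threshold for the disease class: a gene is
called disease when P(disease | x) >= tau.  Evaluation is by leave-one-out
cross-validation with the PCA refit inside every fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import DISEASE, NON_DISEASE, Contig, GeneRecord
from .motifs import canonical, revcomp

logger = logging.getLogger(__name__)

CLASSES = (DISEASE, NON_DISEASE)


@dataclass
class FeatureMatrix:
    """Genes x oligomers count matrix with class labels."""

    gene_ids: list
    labels: list
    features: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.features)):
            raise ValueError("counts shape does not match gene/feature lists")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")

    def subset(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            [self.gene_ids[i] for i in idx],
            [self.labels[i] for i in idx],
            list(self.features),
            self.counts[idx],
        )


@dataclass
class LdaModel:
    """PCA basis + reduced-space class Gaussians + decision threshold tau."""

    center: np.ndarray
    components: np.ndarray  # (n_components, p)
    class_means: Dict[str, np.ndarray]
    pooled_covariance: np.ndarray
    priors: Dict[str, float]
    tau: float
    features: list

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) @ self.components.T

    def posterior_disease(self, X: np.ndarray) -> np.ndarray:
        """P(disease | x) for each row of the raw count matrix X."""
        Z = self.transform(X)
        scores = {}
        cov = self.pooled_covariance
        # solve via cholesky; covariance was regularized at fit time
        L = np.linalg.cholesky(cov)
        for cls in CLASSES:
            d = Z - self.class_means[cls]
            sol = np.linalg.solve(L, d.T)
            maha = np.sum(sol**2, axis=0)
            scores[cls] = -0.5 * maha + np.log(self.priors[cls])
        a, b = scores[DISEASE], scores[NON_DISEASE]
        m = np.maximum(a, b)
        ea, eb = np.exp(a - m), np.exp(b - m)
        return ea / (ea + eb)

    def predict(self, X: np.ndarray) -> List[str]:
        post = self.posterior_disease(X)
        return [DISEASE if p >= self.tau else NON_DISEASE for p in post]


@dataclass
class CvResult:
    """Per-gene predictions and per-class success percentages."""

    per_gene: Dict[str, tuple]  # gene -> (true, predicted, posterior_disease)
    success_disease: float
    success_non_disease: float
    tau: float

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.success_disease + self.success_non_disease)


def count_occurrences(text: str, pattern: str) -> int:
    """Occurrences of ``pattern`` or its reverse complement in ``text`` (overlaps allowed)."""
    text = text.upper()
    total = 0
    for pat in {pattern, revcomp(pattern)}:
        i = text.find(pat)
        while i != -1:
            total += 1
            i = text.find(pat, i + 1)
    return total


def build_feature_matrix(
    genes: Sequence[GeneRecord],
    contigs: Sequence[Contig],
    oligomers: Sequence[str],
    fasta: Mapping[str, str],
) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """Count each oligomer in each gene's own upstream contig.

    A gene in a merged multi-gene contig receives that whole contig's counts.
    Genes without a surviving contig are excluded and reported in the second
    return value as ``(gene_id, reason)`` pairs.
    """
    if not oligomers:
        raise ValueError("oligomer list is empty")
    contig_of: Dict[str, Contig] = {}
    for c in contigs:
        for g in c.source_genes:
            contig_of[g] = c

    gene_ids, labels, rows = [], [], []
    excluded = []
    seq_cache: Dict[int, str] = {}
    for g in genes:
        c = contig_of.get(g.id)
        if c is None:
            excluded.append((g.id, "no surviving contig"))
            continue
        key = id(c)
        if key not in seq_cache:
            seq_cache[key] = str(fasta[c.chrom][c.start : c.end]).upper()
        seq = seq_cache[key]
        rows.append([count_occurrences(seq, o) for o in oligomers])
        gene_ids.append(g.id)
        labels.append(g.disease_class)
    fm = FeatureMatrix(gene_ids, labels, list(oligomers), np.array(rows, dtype=float))
    if excluded:
        logger.info("%d genes excluded from feature matrix", len(excluded))
    return fm, excluded


def _pca_basis(X: np.ndarray, variance_kept: float, max_components: int):
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    if var.sum() == 0:
        raise ValueError("zero-variance feature matrix")
    ratio = np.cumsum(var) / var.sum()
    ncomp = int(np.searchsorted(ratio, variance_kept - 1e-12) + 1)
    rank = int(np.sum(s > s[0] * 1e-10))
    ncomp = max(1, min(ncomp, max_components, rank))
    return center, Vt[:ncomp]


def train_lda(fm: FeatureMatrix, tau: float = 0.5, variance_kept: float = 0.95) -> LdaModel:
    """Fit the PCA-reduced two-class LDA on the full feature matrix."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must lie in (0, 1]")
    labels = np.asarray(fm.labels)
    n = len(labels)
    for cls in CLASSES:
        if np.sum(labels == cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 genes")

    center, components = _pca_basis(fm.counts, variance_kept, max_components=n - 2)
    Z = (fm.counts - center) @ components.T
    d = Z.shape[1]

    means, priors = {}, {}
    scatter = np.zeros((d, d))
    for cls in CLASSES:
        Zc = Z[labels == cls]
        means[cls] = Zc.mean(axis=0)
        priors[cls] = len(Zc) / n
        dev = Zc - means[cls]
        scatter += dev.T @ dev
    cov = scatter / (n - 2)
    # ridge keeps the pooled covariance invertible when folds get degenerate
    ridge = max(np.trace(cov) / d, 1.0) * 1e-9
    cov = cov + ridge * np.eye(d)

    return LdaModel(center, components, means, cov, priors, tau, list(fm.features))


def _prior_only_posterior(labels: Sequence[str]) -> float:
    n = len(labels)
    return sum(1 for l in labels if l == DISEASE) / n


def loocv(fm: FeatureMatrix, tau: float = 0.5, variance_kept: float = 0.95) -> CvResult:
    """Leave-one-out cross-validation with PCA refit per fold."""
    n = len(fm.gene_ids)
    if n < 3:
        raise ValueError("need at least 3 genes for LOOCV")
    posteriors = np.empty(n)
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        sub = fm.subset(rest)
        counts = {cls: sub.labels.count(cls) for cls in CLASSES}
        if min(counts.values()) < 2:
            logger.warning("fold %d: class vanished; predicting with prior only", i)
            posteriors[i] = _prior_only_posterior(sub.labels)
            continue
        model = train_lda(sub, tau=tau, variance_kept=variance_kept)
        posteriors[i] = model.posterior_disease(fm.counts[i : i + 1])[0]
    return _threshold_result(fm, posteriors, tau)


def _threshold_result(fm: FeatureMatrix, posteriors: np.ndarray, tau: float) -> CvResult:
    per_gene = {}
    correct = {cls: 0 for cls in CLASSES}
    total = {cls: 0 for cls in CLASSES}
    for gid, true, post in zip(fm.gene_ids, fm.labels, posteriors):
        pred = DISEASE if post >= tau else NON_DISEASE
        per_gene[gid] = (true, pred, float(post))
        total[true] += 1
        if pred == true:
            correct[true] += 1
    return CvResult(
        per_gene=per_gene,
        success_disease=100.0 * correct[DISEASE] / total[DISEASE] if total[DISEASE] else float("nan"),
        success_non_disease=100.0 * correct[NON_DISEASE] / total[NON_DISEASE] if total[NON_DISEASE] else float("nan"),
        tau=tau,
    )


def loocv_posteriors(fm: FeatureMatrix, variance_kept: float = 0.95) -> np.ndarray:
    """LOOCV disease posteriors; training is threshold-free so one pass serves every tau."""
    result = loocv(fm, tau=0.5, variance_kept=variance_kept)
    return np.array([result.per_gene[g][2] for g in fm.gene_ids])


def sweep_tau(
    fm: FeatureMatrix, grid: Sequence[float], variance_kept: float = 0.95
) -> tuple[List[CvResult], CvResult]:
    """LOOCV success rates over a tau grid and the balanced-accuracy optimum.

    The LOOCV posteriors do not depend on tau (tau only thresholds them), so
    they are computed once and re-thresholded per grid point.  Ties in
    balanced accuracy resolve to the larger tau.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("tau grid is empty")
    if any(not 0 < t < 1 for t in grid):
        raise ValueError("tau grid values must lie in (0, 1)")
    posteriors = loocv_posteriors(fm, variance_kept=variance_kept)
    results = [_threshold_result(fm, posteriors, t) for t in sorted(grid)]
    best = max(results, key=lambda r: (r.balanced_accuracy, r.tau))
    return results, best


def cross_predict(model: LdaModel, fm_other: FeatureMatrix) -> CvResult:
    """Apply a trained model to a foreign gene set featurized on the model's oligomers."""
    if list(fm_other.features) != list(model.features):
        raise ValueError(
            "feature mismatch: re-featurize the foreign set on the model's oligomer list"
        )
    posteriors = model.posterior_disease(fm_other.counts)
    return _threshold_result(fm_other, posteriors, model.tau)


def combined_report(
    ranking: pd.DataFrame,
    predictions: Mapping[int, Mapping[str, str]],
    contig_lengths: Mapping[str, int],
    known: Iterable[str] = (),
    min_score: int = 10,
    min_distances_for_candidate: int = 2,
) -> pd.DataFrame:
    """Join the annotation ranking with per-distance classifier calls.

    ``ranking`` needs columns ``gene_id`` and ``score``; ``predictions`` maps
    distance_kb -> {gene_id -> 'X' | 'NX'}.  Genes scoring >= ``min_score``
    are reported with: an exclusion reason when no classifier call exists
    ('no annotated TSS' / 'short contig'), the call at each distance, whether
    the calls agree with prior knowledge ("correctly classified"), and a
    candidate flag for genes not in ``known`` called X at at least
    ``min_distances_for_candidate`` distances.
    """
    known = set(known)
    distances = sorted(predictions)
    rows = []
    for _, r in ranking.iterrows():
        gid, score = r["gene_id"], int(r["score"])
        if score < min_score:
            continue
        calls = {d: predictions[d].get(gid) for d in distances}
        row = {"gene_id": gid, "score": score, "known": int(gid in known)}
        if all(v is None for v in calls.values()):
            row["excluded"] = (
                "no annotated TSS" if gid not in contig_lengths else "short contig"
            )
            for d in distances:
                row[f"call_{d}kb"] = ""
            row["correctly_classified"] = ""
            row["candidate"] = False
        else:
            row["excluded"] = ""
            made = {d: v for d, v in calls.items() if v is not None}
            for d in distances:
                row[f"call_{d}kb"] = calls[d] or ""
            expected = "X" if gid in known else "NX"
            row["correctly_classified"] = all(v == expected for v in made.values())
            n_x = sum(1 for v in made.values() if v == "X")
            row["candidate"] = gid not in known and n_x >= min_distances_for_candidate
        rows.append(row)
    return pd.DataFrame(rows)
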