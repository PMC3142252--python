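"""Canonical k-mer counting, overrepresentation screening and permutation testing.

A k-mer and its reverse complement are pooled under a canonical key (the
lexicographic minimum of the two).  Overrepresentation in a focal subgenome
relative to another is screened with a minimum-occurrence and a
fold-enrichment criterion, then confirmed by a fragment-shuffling permutation
test that rebuilds size-matched pseudo-subgenomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import inf
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .genome import Subgenome

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass
class OverrepCriteria:
    """Screening thresholds for calling an oligomer overrepresented."""

    min_count: int = 10
    min_fold: float = 5.0
    perm_trials: int = 1000
    max_perm_hits: int = 50
    fragment_bp: int = 2000
    normalize: bool = True  # length-normalized frequencies; False = raw-count ratio

    def __post_init__(self):
        if min(self.min_count, self.perm_trials, self.max_perm_hits, self.fragment_bp) <= 0:
            raise ValueError("all criteria must be positive")
        if self.min_fold <= 0:
            raise ValueError("min_fold must be positive")
        if self.max_perm_hits >= self.perm_trials:
            raise ValueError("max_perm_hits must be < perm_trials")


@dataclass
class OligomerRecord:
    """A canonical oligomer with counts, frequencies and permutation outcome."""

    sequence: str
    k: int
    count_focal: int
    count_other: int
    freq_focal: float  # occurrences per megabase of focal subgenome
    freq_other: float
    fold: float
    perm_hits: Optional[int] = None
    perm_trials: Optional[int] = None
    significant: Optional[bool] = None


def _count_in_sequence(seq: str, k: int, counts: Dict[str, int]) -> None:
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return
    rc = revcomp(seq)
    # prefix sums of non-ACGT positions let us skip ambiguous windows cheaply
    bad = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_bad = ~np.isin(bad, np.frombuffer(b"ACGT", dtype=np.uint8))
    pref = np.concatenate([[0], np.cumsum(is_bad)])
    for i in range(n - k + 1):
        if pref[i + k] - pref[i]:
            continue
        fwd = seq[i : i + k]
        rev = rc[n - i - k : n - i]
        key = fwd if fwd <= rev else rev
        counts[key] = counts.get(key, 0) + 1


def count_oligomers(subgenome: Subgenome | Iterable[str], k: int) -> Dict[str, int]:
    """Canonical k-mer counts over a subgenome (or bare sequence iterable).

    Windows never span contig boundaries; windows containing non-ACGT
    characters are skipped; each occurrence of a k-mer or its reverse
    complement increments the canonical key once.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = subgenome.sequences if isinstance(subgenome, Subgenome) else list(subgenome)
    counts: Dict[str, int] = {}
    for seq in seqs:
        _count_in_sequence(seq, k, counts)
    if not counts:
        logger.warning("no window of width %d fits in any contig; empty count map", k)
    return counts


def _frequency(count: int, length: int, normalize: bool) -> float:
    return count / length if normalize else float(count)


def find_overrepresented(
    focal: Subgenome | Iterable[str],
    other: Subgenome | Iterable[str],
    k: int,
    criteria: OverrepCriteria = OverrepCriteria(),
) -> List[OligomerRecord]:
    """Canonical k-mers passing the occurrence and fold-enrichment criteria.

    A k-mer is retained when it occurs at least ``min_count`` times in the
    focal subgenome and its (length-normalized) frequency there is at least
    ``min_fold`` times its frequency in the other subgenome; absence from the
    other subgenome gives fold = +inf and passes the fold criterion.
    """
    focal_counts = count_oligomers(focal, k)
    other_counts = count_oligomers(other, k)
    len_f = focal.total_length if isinstance(focal, Subgenome) else sum(len(s) for s in focal)
    len_o = other.total_length if isinstance(other, Subgenome) else sum(len(s) for s in other)

    records = []
    for kmer in sorted(focal_counts):
        cf = focal_counts[kmer]
        if cf < criteria.min_count:
            continue
        co = other_counts.get(kmer, 0)
        ff = _frequency(cf, len_f, criteria.normalize)
        fo = _frequency(co, len_o, criteria.normalize)
        fold = ff / fo if fo > 0 else inf
        if fold < criteria.min_fold:
            continue
        records.append(
            OligomerRecord(
                sequence=kmer,
                k=k,
                count_focal=cf,
                count_other=co,
                freq_focal=cf / len_f * 1e6,
                freq_other=co / len_o * 1e6,
                fold=fold,
            )
        )
    return records


def significance_call(perm_hits: int, criteria: OverrepCriteria) -> bool:
    """Strictly-fewer-than rule: qualifying in max_perm_hits trials is NOT significant."""
    return perm_hits < criteria.max_perm_hits


def _fragment_sequences(seqs: Sequence[str], fragment_bp: int) -> List[str]:
    """Cut each contig sequence into non-overlapping pieces, keeping the remainder."""
    frags = []
    for seq in seqs:
        for i in range(0, len(seq), fragment_bp):
            piece = seq[i : i + fragment_bp]
            if piece:
                frags.append(piece)
    return frags


def permutation_test(
    focal: Subgenome,
    other: Subgenome,
    candidates: Sequence[OligomerRecord],
    criteria: OverrepCriteria = OverrepCriteria(),
    seed: int = 0,
) -> List[OligomerRecord]:
    """Fragment-shuffling significance test for candidate oligomers.

    Both subgenomes are pooled, cut into ``fragment_bp`` fragments (terminal
    remainders kept), and per trial the shuffled fragments are dealt to a
    pseudo-focal subgenome until it first reaches the true focal size, the
    rest forming the pseudo-other.  Both screening criteria are re-applied in
    the pseudo split; ``perm_hits`` counts qualifying trials and a candidate
    is ``significant`` when ``perm_hits < max_perm_hits``.
    """
    if not candidates:
        return []
    k = candidates[0].k
    frags = _fragment_sequences(list(focal.sequences) + list(other.sequences), criteria.fragment_bp)
    total_len = sum(len(f) for f in frags)
    if total_len < 2 * criteria.fragment_bp:
        raise ValueError("pooled subgenomes shorter than two fragments; cannot permute")

    cand_seqs = [c.sequence for c in candidates]
    col = {s: j for j, s in enumerate(cand_seqs)}
    n_frag, n_cand = len(frags), len(cand_seqs)

    # per-fragment candidate count matrix: one scan of the pooled sequence
    M = np.zeros((n_frag, n_cand), dtype=np.int32)
    for i, frag in enumerate(frags):
        local: Dict[str, int] = {}
        _count_in_sequence(frag, k, local)
        for s, c in local.items():
            j = col.get(s)
            if j is not None:
                M[i, j] = c
    lens = np.array([len(f) for f in frags], dtype=np.int64)
    total_counts = M.sum(axis=0)

    rng = np.random.default_rng(seed)
    hits = np.zeros(n_cand, dtype=np.int64)
    target = focal.total_length
    for _ in range(criteria.perm_trials):
        perm = rng.permutation(n_frag)
        cum = np.cumsum(lens[perm])
        nf = int(np.searchsorted(cum, target, side="left")) + 1
        nf = min(nf, n_frag - 1) or 1  # both pseudo subgenomes stay nonempty
        pf = perm[:nf]
        len_f = int(cum[nf - 1])
        len_o = total_len - len_f
        cf = M[pf].sum(axis=0)
        co = total_counts - cf
        if criteria.normalize:
            ff = cf / len_f
            fo = co / len_o
        else:
            ff = cf.astype(float)
            fo = co.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            qualifies = (cf >= criteria.min_count) & (
                (fo == 0) | (ff >= criteria.min_fold * fo)
            )
        hits += qualifies

    out = []
    for rec, h in zip(candidates, hits):
        out.append(
            replace(
                rec,
                perm_hits=int(h),
                perm_trials=criteria.perm_trials,
                significant=significance_call(int(h), criteria),
            )
        )
    return out


def _best_merge(a: str, b: str, min_overlap: int) -> Optional[tuple[int, str]]:
    """Best (overlap_length, merged_sequence) joining a and b in any orientation."""
    best: Optional[tuple[int, str]] = None

    def consider(ov: int, merged: str):
        nonlocal best
        merged = canonical(merged)
        if best is None or ov > best[0] or (ov == best[0] and merged < best[1]):
            best = (ov, merged)

    for b_or in (b, revcomp(b)):
        if b_or in a:
            consider(len(b_or), a)
            continue
        if a in b_or:
            consider(len(a), b_or)
            continue
        top = min(len(a), len(b_or)) - 1
        for ov in range(top, min_overlap - 1, -1):
            if a.endswith(b_or[:ov]):
                consider(ov, a + b_or[ov:])
                break
        for ov in range(top, min_overlap - 1, -1):
            if b_or.endswith(a[:ov]):
                consider(ov, b_or + a[ov:])
                break
    if best is not None and best[0] >= min_overlap:
        return best
    return None


def merge_oligomers(
    records: Sequence[OligomerRecord], min_overlap: Optional[int] = None
) -> List[OligomerRecord]:
    """Greedy single-linkage assembly of overlapping oligomers into longer ones.

    Two oligomers merge when a suffix of one matches a prefix of the other
    (in either orientation) over at least ``min_overlap`` bases, or one
    contains the other; merging repeats to a fixpoint, largest overlaps
    first, ties broken lexicographically.  ``min_overlap`` defaults to half
    the shortest candidate length.
    """
    if not records:
        return []
    if min_overlap is None:
        min_overlap = max(1, min(r.k for r in records) // 2)

    # deduplicate canonical sequences, pooling counts
    pool: Dict[str, OligomerRecord] = {}
    for r in records:
        key = canonical(r.sequence)
        if key in pool:
            p = pool[key]
            pool[key] = replace(
                p,
                count_focal=p.count_focal + r.count_focal,
                count_other=p.count_other + r.count_other,
                significant=(p.significant or r.significant),
            )
        else:
            pool[key] = replace(r, sequence=key)

    def merge_pass(items: Dict[str, OligomerRecord]) -> bool:
        seqs = sorted(items)
        best = None  # (overlap, merged_seq, sa, sb)
        for i, sa in enumerate(seqs):
            for sb in seqs[i + 1 :]:
                m = _best_merge(sa, sb, min_overlap)
                if m is None:
                    continue
                ov, merged = m
                cand = (ov, merged, sa, sb)
                if best is None or ov > best[0] or (ov == best[0] and merged < best[1]):
                    best = cand
        if best is None:
            return False
        ov, merged, sa, sb = best
        ra, rb = items.pop(sa), items.pop(sb)
        logger.debug("merged %s + %s -> %s (overlap %d)", sa, sb, merged, ov)
        new = OligomerRecord(
            sequence=merged,
            k=len(merged),
            count_focal=ra.count_focal + rb.count_focal,
            count_other=ra.count_other + rb.count_other,
            freq_focal=ra.freq_focal + rb.freq_focal,
            freq_other=ra.freq_other + rb.freq_other,
            fold=max(ra.fold, rb.fold),
            perm_hits=None,
            perm_trials=ra.perm_trials,
            significant=(ra.significant or rb.significant),
        )
        if merged in items:
            ex = items[merged]
            new = replace(
                new,
                count_focal=ex.count_focal + new.count_focal,
                count_other=ex.count_other + new.count_other,
                significant=(ex.significant or new.significant),
            )
        items[merged] = new
        return True

    while merge_pass(pool):
        pass
    return [pool[s] for s in sorted(pool)]
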