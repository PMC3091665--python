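"""Ungapped 33-mer tag alignment by exact-seed lookup and Hamming verification.

Reads are first collapsed to unique sequences with read counts; sequences
containing 'N' are counted but excluded from alignment. Alignment splits a
tag into max_mismatches+1 disjoint seeds: by pigeonhole, any placement with
at most max_mismatches differences leaves at least one seed exact, so
seed-and-verify finds every qualifying ungapped placement on either strand.

Mapping quality is a declared proxy (no realigner is reproduced here):
40 for a unique best placement with no alternative within the mismatch
budget, 25 when a strictly worse alternative exists, 0 for ties — only the
threshold semantics (ambiguous vs trusted) matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .enzymes import revcomp
from .io import FastqRead

MAX_MQ = 40
SECOND_BEST_MQ = 25


@dataclass
class UniqueTag:
    sequence: str
    read_count: int
    has_N: bool
    #: per-base mean Phred quality over the collapsed reads
    mean_quals: Optional[np.ndarray] = None

    @property
    def mean_qual(self) -> float:
        return float(self.mean_quals.mean()) if self.mean_quals is not None else 30.0


@dataclass
class TagAlignment:
    sequence: str
    chrom: str
    position: int       # 0-based leftmost reference coordinate
    strand: str         # '+' or '-'
    n_mismatches: int
    n_best_hits: int
    mapping_quality: int


def collapse_unique(
    reads: Iterable[FastqRead],
) -> Tuple[List[UniqueTag], Dict[str, float]]:
    """Collapse reads into unique sequences with counts and a class summary.

    The summary partitions unique sequences into three classes — with-N
    (any undetermined base), single-read, multi-read — whose percentages
    sum to 100. N-containing sequences are excluded from alignment input
    downstream, mirroring the discard-any-read-with-N rule.
    """
    counts: Dict[str, int] = {}
    qual_sums: Dict[str, np.ndarray] = {}
    length: Optional[int] = None
    for r in reads:
        if length is None:
            length = len(r.sequence)
        elif len(r.sequence) != length:
            raise ValueError(
                f"non-uniform read length: {len(r.sequence)} != {length}"
            )
        if r.sequence in counts:
            counts[r.sequence] += 1
            qual_sums[r.sequence] += r.phred
        else:
            counts[r.sequence] = 1
            qual_sums[r.sequence] = r.phred.astype(np.int64).copy()
    tags = [
        UniqueTag(
            sequence=seq,
            read_count=c,
            has_N="N" in seq,
            mean_quals=qual_sums[seq] / c,
        )
        for seq, c in counts.items()
    ]
    n = len(tags)
    if n == 0:
        summary = {"pct_single_read": 0.0, "pct_multi_read": 0.0, "pct_with_N": 0.0}
    else:
        n_with_n = sum(t.has_N for t in tags)
        n_single = sum(1 for t in tags if not t.has_N and t.read_count == 1)
        n_multi = n - n_with_n - n_single
        summary = {
            "pct_single_read": 100.0 * n_single / n,
            "pct_multi_read": 100.0 * n_multi / n,
            "pct_with_N": 100.0 * n_with_n / n,
        }
    return tags, summary


class KmerIndex:
    """Exact k-mer lookup over the forward strand of a reference."""

    def __init__(self, reference: Dict[str, str], k: int = 11):
        if not reference:
            raise ValueError("empty reference")
        self.k = k
        self.chroms: List[str] = list(reference)
        self._order = {c: i for i, c in enumerate(self.chroms)}
        self.seqs = {c: s.upper() for c, s in reference.items()}
        self.arrs = {
            c: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            for c, s in self.seqs.items()
        }
        index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((chrom, i))
        self._index = index

    def lookup(self, kmer: str) -> Sequence[Tuple[str, int]]:
        return self._index.get(kmer, ())

    def chrom_order(self, chrom: str) -> int:
        return self._order[chrom]


def build_index(reference: Dict[str, str], k: int = 11) -> KmerIndex:
    return KmerIndex(reference, k)


def align_tag(
    sequence: str, index: KmerIndex, max_mismatches: int = 2
) -> Optional[TagAlignment]:
    """Best ungapped placement of a tag on either strand, or None.

    All placements within the mismatch budget are enumerated (pigeonhole
    over max_mismatches+1 disjoint seeds of the index k-mer length);
    n_best_hits counts distinct loci tied at the minimum mismatch count.
    Ties report the lowest locus (chromosome order, then coordinate) with
    mapping quality 0.
    """
    L = len(sequence)
    k = index.k
    n_seeds = max_mismatches + 1
    if k * n_seeds > L:
        raise ValueError(
            f"tag length {L} too short for {n_seeds} seeds of length {k}"
        )
    sequence = sequence.upper()
    hits: Dict[Tuple[str, int], Tuple[int, str]] = {}  # locus -> (mismatches, strand)
    for strand, query in (("+", sequence), ("-", revcomp(sequence))):
        qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        seen: set = set()
        for s in range(n_seeds):
            off = s * k
            for chrom, pos in index.lookup(query[off : off + k]):
                start = pos - off
                if start < 0 or (chrom, start) in seen:
                    continue
                seen.add((chrom, start))
                ref = index.arrs[chrom]
                if start + L > ref.size:
                    continue
                mm = int((ref[start : start + L] != qarr).sum())
                if mm <= max_mismatches:
                    prev = hits.get((chrom, start))
                    # same locus on both strands (palindromic tag): keep the
                    # better mismatch count, prefer '+' on ties
                    if prev is None or mm < prev[0]:
                        hits[(chrom, start)] = (mm, strand)
    if not hits:
        return None
    best_mm = min(mm for mm, _ in hits.values())
    best = sorted(
        (index.chrom_order(c), p, c) for (c, p), (mm, _) in hits.items() if mm == best_mm
    )
    _, position, chrom = best[0]
    strand = hits[(chrom, position)][1]
    n_best = len(best)
    if n_best > 1:
        mq = 0
    elif len(hits) > n_best:
        mq = SECOND_BEST_MQ
    else:
        mq = MAX_MQ
    return TagAlignment(
        sequence=sequence,
        chrom=chrom,
        position=position,
        strand=strand,
        n_mismatches=best_mm,
        n_best_hits=n_best,
        mapping_quality=mq,
    )


def align_tags(
    tags: Iterable[UniqueTag], index: KmerIndex, max_mismatches: int = 2
) -> List[Tuple[UniqueTag, Optional[TagAlignment]]]:
    """Align N-free unique tags; N-containing tags are dropped up front."""
    out: List[Tuple[UniqueTag, Optional[TagAlignment]]] = []
    for t in tags:
        if t.has_N:
            continue
        out.append((t, align_tag(t.sequence, index, max_mismatches)))
    return out


def alignment_rate(
    aligned: Sequence[Tuple[UniqueTag, Optional[TagAlignment]]]
) -> float:
    """Percent of N-free unique tags with a placement; NaN when none exist."""
    n = len(aligned)
    if n == 0:
        return float("nan")
    return 100.0 * sum(1 for _, a in aligned if a is not None) / n
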