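"""Descriptive analyses: coverage histograms, sliding-window sequence
characteristics vs read coverage, SNP-in-read position distributions, and
the clone-QC / validation-rate accounting.

Percentages are computed exactly and rounded half-up only at the reported
precision; partitions always sum to their totals before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._intervals import GenomeIntervals
from .align import TagAlignment, UniqueTag
from .snpcall import SNPCandidate


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    repetitive_fraction: float
    gc_fraction: float
    read_count: int


@dataclass
class RateSummary:
    n_tested: int
    n_positive: int
    rate_pct: float

    def __post_init__(self):
        if not 0 <= self.n_positive <= self.n_tested:
            raise ValueError(
                f"n_positive {self.n_positive} outside [0, {self.n_tested}]"
            )


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def rate(n_positive: int, n_tested: int, decimals: int = 0) -> RateSummary:
    """Validation-rate arithmetic: rate_pct = round(100*positive/tested)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return RateSummary(
        n_tested=n_tested,
        n_positive=n_positive,
        rate_pct=_round_half_up(100.0 * n_positive / n_tested, decimals),
    )


def classify_counts(
    n_locus_specific: int, n_multi_hit: int, n_no_hit: int, decimals: int = 1
) -> Tuple[RateSummary, RateSummary, RateSummary]:
    """Clone-QC percentages from the three class counts (a partition)."""
    n_good = n_locus_specific + n_multi_hit + n_no_hit
    if n_good <= 0:
        raise ValueError("empty clone set")
    return tuple(
        rate(n, n_good, decimals) for n in (n_locus_specific, n_multi_hit, n_no_hit)
    )


def classify_clone_hits(
    hit_counts: Sequence[int], decimals: int = 1
) -> Tuple[RateSummary, RateSummary, RateSummary]:
    """Classify per-clone best-hit counts into locus-specific (=1 hit),
    multi-hit (>1) and no-hit (=0) fractions of the good clones."""
    counts = list(hit_counts)
    if any(c < 0 for c in counts):
        raise ValueError("negative hit count")
    n1 = sum(1 for c in counts if c == 1)
    nm = sum(1 for c in counts if c > 1)
    n0 = sum(1 for c in counts if c == 0)
    return classify_counts(n1, nm, n0, decimals)


def coverage_histogram(
    tags: Iterable[UniqueTag] | Sequence[int], min_count: int = 3
) -> pd.Series:
    """Probability histogram (bin width 1) of read counts >= min_count."""
    counts = np.asarray(
        [t.read_count if isinstance(t, UniqueTag) else int(t) for t in tags],
        dtype=np.int64,
    )
    counts = counts[counts >= min_count]
    if counts.size == 0:
        return pd.Series(dtype=float, name="probability")
    vals, freq = np.unique(counts, return_counts=True)
    s = pd.Series(freq / counts.size, index=vals, name="probability")
    s.index.name = "read_count"
    return s


def window_stats(
    reference: Dict[str, str],
    repeats: GenomeIntervals,
    alignments: Sequence[Tuple[UniqueTag, Optional[TagAlignment]]],
    window: int = 10_000,
) -> List[WindowStat]:
    """Non-overlapping tiling windows with repeat fraction, GC fraction and
    mapped read count (reads assigned by leftmost mapped coordinate,
    weighted by read count; 'N' bases are excluded from the GC denominator).
    """
    per_window_reads: Dict[Tuple[str, int], int] = {}
    for tag, aln in alignments:
        if aln is None:
            continue
        key = (aln.chrom, aln.position // window)
        per_window_reads[key] = per_window_reads.get(key, 0) + tag.read_count
    out: List[WindowStat] = []
    for chrom, seq in reference.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for wi, start in enumerate(range(0, len(seq), window)):
            end = min(start + window, len(seq))
            sub = arr[start:end]
            n_gc = int(((sub == ord("G")) | (sub == ord("C"))).sum())
            n_known = int((sub != ord("N")).sum())
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=start,
                    end=end,
                    repetitive_fraction=repeats.overlap_bases(chrom, start, end)
                    / (end - start),
                    gc_fraction=(n_gc / n_known if n_known else 0.0),
                    read_count=per_window_reads.get((chrom, wi), 0),
                )
            )
    return out


def window_stats_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in stats],
            "start": [w.start for w in stats],
            "end": [w.end for w in stats],
            "repetitive_fraction": [w.repetitive_fraction for w in stats],
            "gc_fraction": [w.gc_fraction for w in stats],
            "read_count": [w.read_count for w in stats],
        }
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN sentinel when either variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def high_coverage_repeat_enrichment(
    alignments: Sequence[Tuple[UniqueTag, Optional[TagAlignment]]],
    repeats: GenomeIntervals,
    threshold: int = 200,
) -> Tuple[float, float]:
    """(% repetitive among tags with > threshold reads,
        % repetitive among tags with < threshold reads).

    A mapped tag is repetitive when its best-placement footprint overlaps
    the repeat annotation by at least one base (the point-in-repeat rule
    of the SNP filters, extended to the 33-bp footprint). Tags exactly at
    the threshold belong to neither class, matching the "more than" /
    "less than" phrasing the classes are reported with.
    """
    above = [0, 0]  # [repetitive, total]
    below = [0, 0]
    for tag, aln in alignments:
        if aln is None:
            continue
        L = len(tag.sequence)
        is_rep = repeats.overlaps(aln.chrom, aln.position, aln.position + L)
        if tag.read_count > threshold:
            above[1] += 1
            above[0] += int(is_rep)
        elif tag.read_count < threshold:
            below[1] += 1
            below[0] += int(is_rep)
    pct_above = 100.0 * above[0] / above[1] if above[1] else 0.0
    pct_below = 100.0 * below[0] / below[1] if below[1] else 0.0
    return pct_above, pct_below


def snp_read_position_distribution(
    candidates: Sequence[SNPCandidate],
    alignments_by_seq: Dict[str, TagAlignment],
    read_length: int = 33,
) -> np.ndarray:
    """Counts of (candidate, supporting read) pairs per 1-based read position.

    For each candidate, every alt-supporting tag contributes its read count
    at the position the variant occupies in the read as sequenced (reverse-
    strand alignments index from the read's 3' reference end).
    """
    bins = np.zeros(read_length, dtype=np.int64)
    for c in candidates:
        for seq, n_reads in c.tags:
            aln = alignments_by_seq.get(seq)
            if aln is None or aln.chrom != c.chrom:
                continue
            offset = c.position - aln.position
            if not 0 <= offset < read_length:
                continue
            read_pos = offset if aln.strand == "+" else read_length - 1 - offset
            bins[read_pos] += n_reads
    return bins
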