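"""Pileup construction, candidate SNP calling, and the two filter ladders.

Candidates are called from per-column allele counts of aligned unique tags
(each tag contributes its read count at every covered base). Two nested
stringency tiers are then applied:

lenient
    alt-supporting reads >= 3; position not in a repeat interval; no 10-bp
    reference window holds 3 or more candidates (all candidates of a
    violating window are removed).

stringent (applied on top of lenient)
    no indel within 3 bp; covering reads (depth) >= 10; some covering read
    with mapping quality >= 40; consensus quality >= 10; the 10-bp window
    rule again.

Consensus quality is a declared Phred-scaled score: the one-sided binomial
tail probability of seeing at least the observed alt count out of the depth
if every read were wrong independently with the column's mean base-error
rate. Only the >= 10 threshold semantics are contractually meaningful.

A final cross-assembly step realigns each candidate's supporting tag to a
second (newer) assembly and drops candidates that place ambiguously there
or cannot be placed on its repeat-masked sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from ._intervals import GenomeIntervals
from .align import TagAlignment, UniqueTag, align_tag, build_index
from .enzymes import revcomp

_ALLELES = ("A", "C", "G", "T")

TIER_ORDER = {"none": 0, "candidate": 1, "lenient": 2, "stringent": 3}


@dataclass
class PileupColumn:
    chrom: str
    position: int
    ref_base: str
    counts: Dict[str, int] = field(default_factory=dict)
    qual_sums: Dict[str, float] = field(default_factory=dict)
    max_mq: int = 0
    has_multimap: bool = False
    #: alt allele -> [(tag sequence, read count)] of contributing tags
    alt_tags: Dict[str, List[Tuple[str, int]]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def mean_qual(self) -> float:
        d = self.depth
        return sum(self.qual_sums.values()) / d if d else 0.0


@dataclass
class SNPCandidate:
    chrom: str
    position: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    consensus_quality: int
    max_mq: int
    #: alt-supporting unique tags as (sequence, read_count)
    tags: List[Tuple[str, int]] = field(default_factory=list)
    flags: Dict[str, bool] = field(default_factory=dict)
    audit: Dict[str, bool] = field(default_factory=dict)
    tier: str = "candidate"


def build_pileup(
    alignments: Sequence[Tuple[UniqueTag, Optional[TagAlignment]]],
    reference: Dict[str, str],
) -> List[PileupColumn]:
    """Columns over every covered reference base, sorted by locus.

    Multi-hit (mapping quality 0) alignments contribute to depth but set
    the column's has_multimap flag so repeat analyses can see them.
    Total depth equals read length x mapped read count, summed.
    """
    columns: Dict[Tuple[str, int], PileupColumn] = {}
    for tag, aln in alignments:
        if aln is None:
            continue
        ref_seq = reference[aln.chrom]
        L = len(tag.sequence)
        if aln.position + L > len(ref_seq):
            raise ValueError(
                f"alignment at {aln.chrom}:{aln.position} extends past chromosome end"
            )
        if aln.strand == "+":
            oriented = tag.sequence
            quals = tag.mean_quals
        else:
            oriented = revcomp(tag.sequence)
            quals = tag.mean_quals[::-1] if tag.mean_quals is not None else None
        for j, base in enumerate(oriented):
            pos = aln.position + j
            key = (aln.chrom, pos)
            col = columns.get(key)
            if col is None:
                col = PileupColumn(aln.chrom, pos, ref_seq[pos])
                columns[key] = col
            col.counts[base] = col.counts.get(base, 0) + tag.read_count
            q = float(quals[j]) if quals is not None else 30.0
            col.qual_sums[base] = col.qual_sums.get(base, 0.0) + q * tag.read_count
            col.max_mq = max(col.max_mq, aln.mapping_quality)
            if aln.mapping_quality == 0:
                col.has_multimap = True
            if base != col.ref_base and base in _ALLELES:
                col.alt_tags.setdefault(base, []).append((tag.sequence, tag.read_count))
    order = {c: i for i, c in enumerate(reference)}
    return sorted(columns.values(), key=lambda c: (order[c.chrom], c.position))


def consensus_quality(alt_count: int, depth: int, mean_qual: float) -> int:
    """Phred-scaled binomial-tail confidence, capped at 40."""
    if depth <= 0 or alt_count <= 0:
        return 0
    e = min(0.75, 10.0 ** (-mean_qual / 10.0))
    p = float(stats.binom.sf(alt_count - 1, depth, e))
    if p <= 0.0:
        return 40
    return min(40, int(round(-10.0 * math.log10(p))))


def call_candidates(
    pileup: Sequence[PileupColumn], min_alt_reads: int = 1
) -> List[SNPCandidate]:
    """One candidate per column whose best non-reference allele has support.

    The single best-supported alt allele is considered (two-inbred pooled
    design implies biallelic sites); count ties break alphabetically for
    determinism.
    """
    out: List[SNPCandidate] = []
    for col in pileup:
        if col.ref_base not in _ALLELES:
            continue
        best_alt, best_n = None, 0
        for a in _ALLELES:
            n = col.counts.get(a, 0)
            if a != col.ref_base and n > best_n:
                best_alt, best_n = a, n
        if best_alt is None or best_n < min_alt_reads:
            continue
        out.append(
            SNPCandidate(
                chrom=col.chrom,
                position=col.position,
                ref=col.ref_base,
                alt=best_alt,
                depth=col.depth,
                alt_count=best_n,
                consensus_quality=consensus_quality(best_n, col.depth, col.mean_qual),
                max_mq=col.max_mq,
                tags=list(col.alt_tags.get(best_alt, ())),
            )
        )
    return out


def dense_window_positions(
    positions: Sequence[int], window: int = 10, min_count: int = 3
) -> Set[int]:
    """Positions lying in any length-``window`` interval holding >= min_count.

    Windows are every reference interval [p, p+window): positions 100 and
    109 co-occupy a 10-bp window, 100 and 110 do not. Every position of
    every violating window is returned.
    """
    pos = sorted(set(positions))
    removed: Set[int] = set()
    j = 0
    for i in range(len(pos)):
        while pos[i] - pos[j] > window - 1:
            j += 1
        if i - j + 1 >= min_count:
            removed.update(pos[j : i + 1])
    return removed


def filter_lenient(
    candidates: Sequence[SNPCandidate],
    repeats: GenomeIntervals,
    min_alt_reads: int = 3,
    window: int = 10,
    window_min_count: int = 3,
) -> List[SNPCandidate]:
    """Lenient tier: support, repeat-region and dense-window rules.

    (The companion rule — discard reads containing 'N' — is enforced
    upstream at unique-sequence collapse.) The window census runs over the
    candidates that meet the support rule: isolated single-error-read
    columns are not credible variant sites and must not trigger the purge
    of a genuine neighbour. All censused candidates of a violating window
    are removed.
    """
    dense: Set[Tuple[str, int]] = set()
    by_chrom: Dict[str, List[int]] = {}
    for c in candidates:
        if c.alt_count >= min_alt_reads:
            by_chrom.setdefault(c.chrom, []).append(c.position)
    for chrom, poss in by_chrom.items():
        for p in dense_window_positions(poss, window, window_min_count):
            dense.add((chrom, p))
    kept: List[SNPCandidate] = []
    for c in candidates:
        ok_support = c.alt_count >= min_alt_reads
        in_repeat = repeats.covers(c.chrom, c.position)
        in_dense = (c.chrom, c.position) in dense
        c.flags["repeat_region"] = in_repeat
        c.flags["dense_window"] = in_dense
        c.audit["lenient_min_alt_reads"] = ok_support
        c.audit["lenient_not_repeat"] = not in_repeat
        c.audit["lenient_window"] = not in_dense
        if ok_support and not in_repeat and not in_dense:
            c.tier = "lenient"
            kept.append(c)
    return kept


def filter_stringent(
    candidates: Sequence[SNPCandidate],
    indel_positions: Dict[str, Sequence[int]] | None = None,
    min_support: int = 10,
    mq_min: int = 40,
    cq_min: int = 10,
    indel_flank: int = 3,
    window: int = 10,
    window_min_count: int = 3,
) -> List[SNPCandidate]:
    """Stringent tier, applied on top of the lenient set (tiers nest).

    ``min_support`` is the total covering-read requirement (depth);
    ``indel_positions`` is the declared indel track (truth indels in
    simulation, a user BED otherwise). A candidate within ``indel_flank``
    bp of an indel position is discarded (inclusive boundary).
    """
    indel_sorted = {
        c: np.asarray(sorted(p), dtype=np.int64)
        for c, p in (indel_positions or {}).items()
    }
    dense: Set[Tuple[str, int]] = set()
    by_chrom: Dict[str, List[int]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c.position)
    for chrom, poss in by_chrom.items():
        for p in dense_window_positions(poss, window, window_min_count):
            dense.add((chrom, p))
    kept: List[SNPCandidate] = []
    for c in candidates:
        if TIER_ORDER[c.tier] < TIER_ORDER["lenient"]:
            continue
        near_indel = False
        arr = indel_sorted.get(c.chrom)
        if arr is not None and arr.size:
            i = int(np.searchsorted(arr, c.position))
            for j in (i - 1, i):
                if 0 <= j < arr.size and abs(int(arr[j]) - c.position) <= indel_flank:
                    near_indel = True
        ok_support = c.depth >= min_support
        ok_mq = c.max_mq >= mq_min
        ok_cq = c.consensus_quality >= cq_min
        in_dense = (c.chrom, c.position) in dense
        c.flags["near_indel"] = near_indel
        c.audit["stringent_not_near_indel"] = not near_indel
        c.audit["stringent_min_support"] = ok_support
        c.audit["stringent_mq"] = ok_mq
        c.audit["stringent_cq"] = ok_cq
        c.audit["stringent_window"] = not in_dense
        if not near_indel and ok_support and ok_mq and ok_cq and not in_dense:
            c.tier = "stringent"
            kept.append(c)
    return kept


def cross_assembly_filter(
    candidates: Sequence[SNPCandidate],
    second_reference: Dict[str, str],
    second_repeats: GenomeIntervals | None = None,
    max_mismatches: int = 2,
    k: int = 11,
) -> List[SNPCandidate]:
    """Drop candidates whose tag is ambiguous or unplaceable on a second assembly.

    For each candidate the best-supported alt-carrying tag is realigned:
    excluded when its best placement on the second assembly is non-unique,
    or when it has no placement at all on the repeat-masked second
    assembly. The second assembly may equal the first.
    """
    index = build_index(second_reference, k)
    if second_repeats is not None and second_repeats.total_bases:
        masked = {
            chrom: _mask(seq, second_repeats.get(chrom))
            for chrom, seq in second_reference.items()
        }
        masked_index = build_index(masked, k)
    else:
        masked_index = index
    kept: List[SNPCandidate] = []
    for c in candidates:
        if not c.tags:
            c.audit["cross_assembly"] = False
            c.flags["multi_position"] = False
            continue
        tag_seq = max(c.tags, key=lambda t: t[1])[0]
        full = align_tag(tag_seq, index, max_mismatches)
        multi = full is None or full.n_best_hits > 1
        on_masked = align_tag(tag_seq, masked_index, max_mismatches)
        unplaced = on_masked is None
        c.flags["multi_position"] = multi
        c.flags["unplaced_masked"] = unplaced
        c.audit["cross_assembly"] = not (multi or unplaced)
        if not (multi or unplaced):
            kept.append(c)
    return kept


def _mask(seq: str, intervals) -> str:
    arr = bytearray(seq.encode("ascii"))
    for s, e in intervals:
        arr[s:e] = b"N" * (e - s)
    return arr.decode("ascii")


@dataclass
class FlankContext:
    candidate: SNPCandidate
    context: str           # left flank + [ref/alt] + right flank
    left_truncated: bool
    right_truncated: bool


def extract_flanks(
    candidate: SNPCandidate, reference: Dict[str, str], flank: int = 60
) -> FlankContext:
    """Flanking context for assay design: 60 bp each side, alleles bracketed.

    Flanks are truncated (and flagged) at chromosome ends.
    """
    seq = reference[candidate.chrom]
    p = candidate.position
    left = seq[max(0, p - flank) : p]
    right = seq[p + 1 : p + 1 + flank]
    return FlankContext(
        candidate=candidate,
        context=f"{left}[{candidate.ref}/{candidate.alt}]{right}",
        left_truncated=len(left) < flank,
        right_truncated=len(right) < flank,
    )


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(
    candidates: Sequence[SNPCandidate],
    reference: Dict[str, str],
    path,
    extra_header: Sequence[str] = (),
) -> None:
    """Write candidates as VCF 4.2 (1-based positions; FILTER encodes tier)."""
    order = {c: i for i, c in enumerate(reference)}
    keys = [(order[c.chrom], c.position) for c in candidates]
    if keys != sorted(keys):
        raise ValueError("candidates must be sorted by chromosome and position")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rrsnp\n")
        for line in extra_header:
            fh.write(f"##{line}\n")
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Covering reads">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt-supporting reads">\n')
        fh.write('##INFO=<ID=CQ,Number=1,Type=Integer,Description="Consensus quality">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Integer,Description="Max mapping quality">\n')
        fh.write('##INFO=<ID=TIER,Number=1,Type=String,Description="Filter tier reached">\n')
        fh.write('##FILTER=<ID=lenient,Description="Lenient tier only">\n')
        fh.write('##FILTER=<ID=candidate,Description="Raw candidate, no tier passed">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in candidates:
            filt = "PASS" if c.tier == "stringent" else c.tier
            info = (
                f"DP={c.depth};AC={c.alt_count};CQ={c.consensus_quality};"
                f"MQ={c.max_mq};TIER={c.tier}"
            )
            fh.write(
                f"{c.chrom}\t{c.position + 1}\t.\t{c.ref}\t{c.alt}\t"
                f"{c.consensus_quality}\t{filt}\t{info}\n"
            )
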