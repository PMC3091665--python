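import numpy as np
import pysam
import pytest

from rrsnp import (GenomeIntervals, SNPCandidate, build_index, build_pileup,
                   call_candidates, collapse_unique, consensus_quality,
                   cross_assembly_filter, dense_window_positions,
                   extract_flanks, filter_lenient, filter_stringent, write_vcf)
from rrsnp.align import TagAlignment, UniqueTag, align_tags
from rrsnp.enzymes import revcomp
from rrsnp.io import FastqRead

from conftest import random_seq


def _tag(seq, count=1, quals=30.0):
    return UniqueTag(seq, count, "N" in seq, np.full(len(seq), quals))


def _aln(seq, chrom, pos, strand="+", mm=0, best=1, mq=40):
    return TagAlignment(seq, chrom, pos, strand, mm, best, mq)


def _cand(pos, chrom="c", ref="A", alt="G", depth=20, alt_count=10, cq=40,
          mq=40, tier="candidate"):
    return SNPCandidate(chrom, pos, ref, alt, depth, alt_count, cq, mq, tier=tier)


class TestPileup:
    def test_single_unique_read_gives_depth_one_columns(self, rng):
        ref = {"c": random_seq(rng, 200)}
        seq = ref["c"][50:83]
        cols = build_pileup([(_tag(seq), _aln(seq, "c", 50))], ref)
        assert len(cols) == 33
        assert all(c.depth == 1 for c in cols)
        assert cols[0].position == 50 and cols[-1].position == 82

    def test_read_count_multiplies_depth(self, rng):
        ref = {"c": random_seq(rng, 100)}
        seq = ref["c"][10:43]
        cols = build_pileup([(_tag(seq, count=2), _aln(seq, "c", 10))], ref)
        assert all(c.depth == 2 for c in cols)

    def test_reverse_strand_bases_in_reference_orientation(self, rng):
        ref = {"c": random_seq(rng, 100)}
        seq = revcomp(ref["c"][10:43])
        cols = build_pileup([(_tag(seq), _aln(seq, "c", 10, strand="-"))], ref)
        for col in cols:
            assert col.counts == {ref["c"][col.position]: 1}

    def test_depth_conservation(self, rng):
        ref = {"c": random_seq(rng, 2000)}
        alns = []
        total_reads = 0
        for _ in range(50):
            p = int(rng.integers(0, 2000 - 33))
            n = int(rng.integers(1, 5))
            seq = ref["c"][p : p + 33]
            alns.append((_tag(seq, count=n), _aln(seq, "c", p)))
            total_reads += n
        cols = build_pileup(alns, ref)
        assert sum(c.depth for c in cols) == 33 * total_reads

    def test_past_end_alignment_rejected(self, rng):
        ref = {"c": random_seq(rng, 40)}
        seq = random_seq(rng, 33)
        with pytest.raises(ValueError, match="past"):
            build_pileup([(_tag(seq), _aln(seq, "c", 20))], ref)

    def test_multimap_contributes_depth_and_flags(self, rng):
        ref = {"c": random_seq(rng, 100)}
        seq = ref["c"][10:43]
        cols = build_pileup([(_tag(seq), _aln(seq, "c", 10, best=2, mq=0))], ref)
        assert all(c.has_multimap and c.max_mq == 0 for c in cols)


class TestCalling:
    def test_no_alt_no_candidate(self, rng):
        ref = {"c": random_seq(rng, 100)}
        seq = ref["c"][0:33]
        cols = build_pileup([(_tag(seq, count=10), _aln(seq, "c", 0))], ref)
        assert call_candidates(cols) == []

    def test_pooled_heterozygous_pattern(self, rng):
        ref = {"c": random_seq(rng, 100)}
        ref_seq = ref["c"][0:33]
        alt_base = "A" if ref_seq[16] != "A" else "G"
        alt_seq = ref_seq[:16] + alt_base + ref_seq[17:]
        cols = build_pileup(
            [
                (_tag(ref_seq, count=5), _aln(ref_seq, "c", 0)),
                (_tag(alt_seq, count=5), _aln(alt_seq, "c", 0, mm=1)),
            ],
            ref,
        )
        cands = call_candidates(cols)
        assert len(cands) == 1
        c = cands[0]
        assert (c.position, c.alt, c.alt_count, c.depth) == (16, alt_base, 5, 10)
        assert c.consensus_quality == 40
        assert c.tags == [(alt_seq, 5)]

    def test_min_alt_reads_threshold_monotone(self, rng):
        ref = {"c": random_seq(rng, 100)}
        ref_seq = ref["c"][0:33]
        alt_base = "A" if ref_seq[5] != "A" else "G"
        alt_seq = ref_seq[:5] + alt_base + ref_seq[6:]
        cols = build_pileup(
            [
                (_tag(ref_seq, count=8), _aln(ref_seq, "c", 0)),
                (_tag(alt_seq, count=2), _aln(alt_seq, "c", 0, mm=1)),
            ],
            ref,
        )
        assert len(call_candidates(cols, min_alt_reads=1)) == 1
        assert len(call_candidates(cols, min_alt_reads=2)) == 1
        assert call_candidates(cols, min_alt_reads=3) == []


def test_consensus_quality_monotone_in_support():
    qs = [consensus_quality(a, 20, 30.0) for a in range(0, 6)]
    assert qs == sorted(qs)
    assert consensus_quality(0, 20, 30.0) == 0
    assert consensus_quality(10, 20, 30.0) == 40
    # high error rate -> low confidence
    assert consensus_quality(2, 20, 3.0) < 10


class TestWindowRule:
    def test_examples(self):
        # 100,105,109 span a 10 bp window; 100,105,110 do not
        assert dense_window_positions([100, 105, 109]) == {100, 105, 109}
        assert dense_window_positions([100, 105, 110]) == set()
        assert dense_window_positions([1, 2]) == set()

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(200):
            pos = sorted(set(rng.integers(0, 300, size=rng.integers(2, 40)).tolist()))
            got = dense_window_positions(pos, window=10, min_count=3)
            expected = set()
            for w in range(0, 301):
                inside = [p for p in pos if w <= p < w + 10]
                if len(inside) >= 3:
                    expected.update(inside)
            assert got == expected


class TestFilterLadders:
    def test_lenient_rules(self):
        reps = GenomeIntervals({"c": [(500, 600)]})
        weak = _cand(10, alt_count=2)
        ok = _cand(100, alt_count=3)
        in_rep = _cand(550, alt_count=9)
        kept = filter_lenient([weak, ok, in_rep], reps)
        assert kept == [ok]
        assert ok.tier == "lenient"
        assert weak.audit["lenient_min_alt_reads"] is False
        assert in_rep.flags["repeat_region"] is True

    def test_lenient_window_purge(self):
        reps = GenomeIntervals.empty()
        cluster = [_cand(p, alt_count=5) for p in (100, 105, 109)]
        lone = _cand(300, alt_count=5)
        kept = filter_lenient(cluster + [lone], reps)
        assert kept == [lone]
        assert all(c.flags["dense_window"] for c in cluster)

    def test_stringent_boundaries(self):
        def lenient(c):
            c.tier = "lenient"
            return c

        shallow = lenient(_cand(10, depth=9))
        deep = lenient(_cand(100, depth=10))
        near = lenient(_cand(200))
        far = lenient(_cand(300))
        low_cq = lenient(_cand(400, cq=9))
        edge_cq = lenient(_cand(500, cq=10))
        low_mq = lenient(_cand(600, mq=25))
        indels = {"c": [203, 304]}  # |200-203|=3 removed, |300-304|=4 kept
        kept = filter_stringent(
            [shallow, deep, near, far, low_cq, edge_cq, low_mq], indels
        )
        assert kept == [deep, far, edge_cq]
        assert all(c.tier == "stringent" for c in kept)
        assert near.flags["near_indel"] and not far.flags["near_indel"]
        assert shallow.audit["stringent_min_support"] is False
        assert low_mq.audit["stringent_mq"] is False

    def test_stringent_requires_lenient_tier(self):
        c = _cand(10)  # tier "candidate": never promoted
        assert filter_stringent([c], {}) == []

    def test_nesting_invariant(self, rng):
        cands = [
            _cand(int(p), alt_count=int(a), depth=int(d), cq=int(q))
            for p, a, d, q in zip(
                rng.choice(5000, 100, replace=False),
                rng.integers(1, 8, 100),
                rng.integers(1, 30, 100),
                rng.integers(0, 41, 100),
            )
        ]
        lenient = filter_lenient(cands, GenomeIntervals.empty())
        stringent = filter_stringent(lenient, {})
        assert set(id(c) for c in stringent) <= set(id(c) for c in lenient)
        assert set(id(c) for c in lenient) <= set(id(c) for c in cands)


class TestCrossAssembly:
    def test_identity_reference_keeps_unique_candidate(self, rng):
        ref = {"c": random_seq(rng, 1000)}
        tag = ref["c"][100:133]
        c = _cand(116, tier="stringent")
        c.tags = [(tag, 5)]
        assert cross_assembly_filter([c], ref) == [c]

    def test_duplicated_locus_excluded(self, rng):
        seg = random_seq(rng, 200)
        second = {"c": random_seq(rng, 300) + seg + random_seq(rng, 300) + seg}
        c = _cand(50, tier="stringent")
        c.tags = [(seg[:33], 5)]
        assert cross_assembly_filter([c], second) == []
        assert c.flags["multi_position"]

    def test_deleted_region_excluded(self, rng):
        c = _cand(50, tier="stringent")
        c.tags = [(random_seq(rng, 33), 5)]
        second = {"c": random_seq(rng, 1000)}
        assert cross_assembly_filter([c], second) == []

    def test_repeat_masked_unalignable_excluded(self, rng):
        ref = {"c": random_seq(rng, 1000)}
        tag = ref["c"][100:133]
        c = _cand(116, tier="stringent")
        c.tags = [(tag, 5)]
        masked = GenomeIntervals({"c": [(90, 140)]})
        assert cross_assembly_filter([c], ref, masked) == []
        assert c.flags["unplaced_masked"]


class TestFlanks:
    def test_long_chromosome_center(self, rng):
        ref = {"c": random_seq(rng, 3000)}
        c = _cand(1000, ref=ref["c"][1000], alt="A" if ref["c"][1000] != "A" else "C")
        f = extract_flanks(c, ref)
        assert len(f.context) == 121 + 4  # 60+60 flanks + "[X/Y]"
        assert not f.left_truncated and not f.right_truncated
        stripped = f.context[:60] + c.ref + f.context[-60:]
        assert stripped == ref["c"][940:1061]

    def test_truncated_at_chrom_start(self, rng):
        ref = {"c": random_seq(rng, 200)}
        c = _cand(10, ref=ref["c"][10], alt="A" if ref["c"][10] != "A" else "C")
        f = extract_flanks(c, ref)
        assert f.left_truncated and not f.right_truncated
        assert f.context.startswith(ref["c"][:10] + "[")


class TestVcf:
    def test_roundtrip_with_pysam(self, tmp_path, rng):
        ref = {"c1": random_seq(rng, 500), "c2": random_seq(rng, 500)}
        cands = []
        for chrom, pos, tier in (("c1", 10, "stringent"), ("c1", 50, "lenient"),
                                 ("c2", 5, "candidate")):
            ref_base = ref[chrom][pos]
            c = _cand(pos, chrom=chrom, ref=ref_base,
                      alt="A" if ref_base != "A" else "T", tier=tier)
            cands.append(c)
        path = tmp_path / "out.vcf"
        write_vcf(cands, ref, path)
        recs = list(pysam.VariantFile(str(path)))
        assert len(recs) == 3
        r = recs[0]
        assert (r.chrom, r.pos, r.ref) == ("c1", 11, cands[0].ref)
        assert r.alts == (cands[0].alt,)
        assert r.info["DP"] == 20 and r.info["AC"] == 10
        assert r.info["TIER"] == "stringent"
        assert list(recs[0].filter) == ["PASS"]
        assert list(recs[1].filter) == ["lenient"]

    def test_empty_set_header_only(self, tmp_path, rng):
        ref = {"c": random_seq(rng, 100)}
        path = tmp_path / "empty.vcf"
        write_vcf([], ref, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        assert all(l.startswith("#") for l in lines)

    def test_unsorted_rejected(self, tmp_path, rng):
        ref = {"c": random_seq(rng, 100)}
        cands = [_cand(50, ref=ref["c"][50]), _cand(10, ref=ref["c"][10])]
        with pytest.raises(ValueError, match="sorted"):
            write_vcf(cands, ref, tmp_path / "x.vcf")


def test_monotonicity_removing_reads_never_adds_calls(rng):
    """Deleting a tag's reads can only shrink the lenient call set."""
    ref = {"c": random_seq(rng, 400)}
    reads = []
    for p in (0, 60, 120, 180):
        seq = ref["c"][p : p + 33]
        alt_seq = seq[:10] + ("A" if seq[10] != "A" else "G") + seq[11:]
        reads += [FastqRead(f"r{p}{i}", seq, "?" * 33) for i in range(5)]
        reads += [FastqRead(f"a{p}{i}", alt_seq, "?" * 33) for i in range(4)]
    index = build_index(ref)

    def call(read_list):
        tags, _ = collapse_unique(read_list)
        alns = align_tags(tags, index)
        cands = call_candidates(build_pileup(alns, ref))
        return {(c.chrom, c.position) for c in filter_lenient(cands, GenomeIntervals.empty())}

    full = call(reads)
    assert len(full) == 4
    reduced = call([r for r in reads if not r.name.startswith("a0")])
    assert reduced <= full
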