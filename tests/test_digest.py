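import re
import warnings

import numpy as np
import pytest
from intervaltree import IntervalTree

from rrsnp import (BUILTIN_ENZYMES, GenomeIntervals, compute_digest_report,
                   digest, extract_tags, scan_cut_positions, size_select,
                   tag_repeat_fraction)
from rrsnp.digest import Fragment, Tag, tags_of
from rrsnp.enzymes import IUPAC_CODES

from conftest import random_seq


def regex_cut_oracle(seq, enzyme):
    """Independent oracle: overlapping regex scan of the expanded pattern."""
    pat = "".join(f"[{IUPAC_CODES[c]}]" for c in enzyme.recognition)
    n = len(seq)
    cuts = [
        m.start() + enzyme.cut_offset
        for m in re.finditer(f"(?=({pat}))", seq.upper())
    ]
    return [c for c in cuts if 0 < c < n]


def test_scan_single_and_double_site(cviri):
    assert scan_cut_positions("AAATGCAAAA", cviri) == [5]
    assert scan_cut_positions("TGCATGCA", cviri) == [2, 6]


def test_scan_repeated_alui_site_matches_regex_oracle():
    alui = BUILTIN_ENZYMES["AluI"]
    seq = "AGCT" * 1000
    cuts = scan_cut_positions(seq, alui)
    assert len(cuts) == 1000
    assert cuts == regex_cut_oracle(seq, alui)


def test_n_bases_never_match(cviri):
    assert scan_cut_positions("AATGNA" + "TGCA".replace("G", "N") + "AA", cviri) == []
    assert scan_cut_positions("TGCN" * 50, cviri) == []


@pytest.mark.parametrize("enzyme", list(BUILTIN_ENZYMES.values()), ids=lambda e: e.name)
def test_scan_agrees_with_regex_oracle_on_random_sequence(enzyme, rng):
    seq = random_seq(rng, 50_000)
    assert scan_cut_positions(seq, enzyme) == regex_cut_oracle(seq, enzyme)


def test_degenerate_cvij_sites_each_cut(rng):
    cvij = BUILTIN_ENZYMES["CviJI"]  # RGCY: overlapping occurrences possible
    seq = "AGCCGGCTA"  # AGCC (R=A,Y=C) at 0 and GGCT at 4; GGCC-like overlap inside
    assert scan_cut_positions(seq, cvij) == regex_cut_oracle(seq, cvij)


def test_digest_forced_cut(cviri):
    frags = digest({"c": "AAATGCAAAA"}, cviri)
    assert [(f.sequence, f.start, f.end) for f in frags] == [
        ("AAATG", 0, 5),
        ("CAAAA", 5, 10),
    ]
    assert all(f.terminal for f in frags)


def test_digest_no_sites_gives_whole_chromosome(cviri):
    frags = digest({"c": "AAAA" * 10}, cviri)
    assert len(frags) == 1
    assert (frags[0].start, frags[0].end, frags[0].terminal) == (0, 40, True)


def test_digest_is_a_partition(cviri, rng):
    seq = random_seq(rng, 100_000)
    frags = digest({"chr1": seq}, cviri)
    assert sum(len(f) for f in frags) == 100_000
    assert frags[0].start == 0 and frags[-1].end == 100_000
    for a, b in zip(frags[:-1], frags[1:]):
        assert a.end == b.start  # sorted, disjoint, gap-free
    assert "".join(f.sequence for f in frags) == seq


def test_size_select_inclusive_bounds_and_idempotence(rng):
    frags = [
        Fragment("c", 0, n, "A" * n) for n in (50, 70, 200, 201)
    ]
    kept = size_select(frags, 70, 200)
    assert [len(f) for f in kept] == [70, 200]
    assert all(f.selected for f in kept)
    assert size_select(kept, 70, 200) == kept  # idempotent
    assert size_select([], 70, 200) == []
    with pytest.raises(ValueError):
        size_select(frags, 200, 70)


def test_size_select_matches_filter_oracle(rng):
    lengths = rng.integers(1, 500, size=10_000)
    frags = [Fragment("c", 0, int(n), "A" * int(n)) for n in lengths]
    kept = size_select(frags, 70, 200)
    oracle = [f for f in frags if 70 <= len(f) <= 200]
    assert [(f.start, f.end) for f in kept] == [(f.start, f.end) for f in oracle]


def test_extract_tags_coordinates():
    frag = Fragment("c", 1000, 1200, "A" * 100 + "C" * 100)
    five, three = extract_tags(frag)
    assert (five.start, five.end, five.side) == (1000, 1033, "5p")
    assert (three.start, three.end, three.side) == (1167, 1200, "3p")
    assert five.sequence == "A" * 33 and three.sequence == "C" * 33

    frag70 = Fragment("c", 0, 70, "A" * 70)
    t5, t3 = extract_tags(frag70)
    assert (t5.start, t5.end) == (0, 33)
    assert (t3.start, t3.end) == (37, 70)  # overlap only below 66 bp

    frag33 = Fragment("c", 0, 33, "G" * 33)
    tags = extract_tags(frag33)
    assert len(tags) == 1 and tags[0].collapsed


def test_tag_repeat_fraction():
    reps = GenomeIntervals({"c": [(20, 40)]})
    tag = Tag("c", 0, 33, "5p", "A" * 33)
    assert tag_repeat_fraction(tag, reps) == pytest.approx(13 / 33)
    assert tag_repeat_fraction(Tag("c", 100, 133, "5p", "A" * 33), reps) == 0.0
    assert tag_repeat_fraction(Tag("c", 22, 55, "5p", "A" * 33), GenomeIntervals({"c": [(0, 100)]})) == 1.0


def test_overlap_bases_matches_intervaltree_oracle(rng):
    ivals = []
    p = 0
    for _ in range(200):
        p += int(rng.integers(1, 50))
        q = p + int(rng.integers(1, 40))
        ivals.append((p, q))
        p = q
    gi = GenomeIntervals({"c": ivals})
    tree = IntervalTree.from_tuples(ivals)
    for _ in range(300):
        s = int(rng.integers(0, p))
        e = s + int(rng.integers(1, 100))
        expected = sum(
            min(e, iv.end) - max(s, iv.begin) for iv in tree.overlap(s, e)
        )
        assert gi.overlap_bases("c", s, e) == expected
        assert gi.covers("c", s) == bool(tree.overlap(s, s + 1))


def test_report_zero_selected_warns_and_zeroes():
    frags = [Fragment("c", 0, 10, "A" * 10)]
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        rep = compute_digest_report(frags, 1000, None, enzyme_name="x")
    assert any("selected" in str(x.message) for x in w)
    assert rep.n_selected_fragments == 0
    assert rep.complexity_reduction_pct == 0.0
    assert rep.coverage_per_run == 0.0
    assert rep.predicted_snps == 0.0


def test_report_internal_consistency(cviri, rng):
    seq = random_seq(rng, 100_000)
    frags = digest({"chr1": seq}, cviri)
    rep = compute_digest_report(frags, 100_000, None, enzyme_name="CviRI")
    selected = size_select(frags, 70, 200)
    assert rep.n_total_fragments == len(frags)
    assert rep.n_selected_fragments == len(selected)
    assert rep.total_selected_length == sum(len(f) for f in selected)
    assert rep.pct_selected_portion == pytest.approx(
        100 * len(selected) / len(frags), abs=0.005
    )
    assert rep.complexity_reduction_pct == pytest.approx(
        100 * rep.total_selected_length / 100_000
    )
    assert rep.n_repetitive_selected == 0
    assert rep.pct_repetitive_selected == 0.0
    assert 0 <= rep.pct_selected_portion <= 100


def test_repetitive_fragment_threshold_rule(rng):
    # selected fragment whose 5' tag is >= 50% inside a repeat counts as repetitive
    seq = random_seq(rng, 1000)
    frag = Fragment("c", 100, 200, seq[100:200], selected=True)
    reps_hi = GenomeIntervals({"c": [(100, 120)]})   # 20/33 of the 5' tag
    reps_lo = GenomeIntervals({"c": [(100, 110)]})   # 10/33
    rep_hi = compute_digest_report([frag], 1000, reps_hi, min_len=70, max_len=200)
    rep_lo = compute_digest_report([frag], 1000, reps_lo, min_len=70, max_len=200)
    assert rep_hi.n_repetitive_selected == 1
    assert rep_lo.n_repetitive_selected == 0


def test_tags_of_sets_fragment_indices(cviri, rng):
    seq = random_seq(rng, 20_000)
    frags = size_select(digest({"c": seq}, cviri), 70, 200)
    tags = tags_of(frags)
    assert len(tags) == 2 * len(frags)
    for t in tags:
        frag = frags[t.fragment_index]
        assert frag.start <= t.start and t.end <= frag.end
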