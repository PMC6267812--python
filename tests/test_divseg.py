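"""divSEG categorisation and tandem-repeat detection."""

import numpy as np
import pytest

from segdiff.divseg import (
    DivSegCall,
    annotate_internal_repeats,
    classify,
    classify_all,
    detect_tandem_unit,
)
from segdiff.segmenter import DivSeg, segment_genomes
from segdiff.synthetic import MutationSpec, generate_ancestor, mutate_pair
from tests.conftest import random_dna


def test_clean_indel_category():
    """b-side empty, a-side 1.2 kb with clean breakpoints -> indel in a."""
    rng = np.random.default_rng(0)
    flank = random_dna(rng, 500)
    ins = random_dna(rng, 1200)
    a = flank + ins + flank
    b = flank + flank
    seg = DivSeg(500, 1700, 500, 500)
    call = classify(seg, a, b)
    assert call.category == "indel"
    assert call.carrier == "a"


def test_approximate_insert_category():
    """a-side 7 bp vs b-side 900 bp: an insert positioned only to within
    the 10 bp unaligned-base tolerance."""
    rng = np.random.default_rng(1)
    flank = random_dna(rng, 400)
    a = flank + random_dna(rng, 7) + flank
    b = flank + random_dna(rng, 900) + flank
    call = classify(DivSeg(400, 407, 400, 1300), a, b)
    assert call.category == "approximate_insert"
    assert call.carrier == "b"


def test_replacement_fallback_reports_identity():
    rng = np.random.default_rng(2)
    flank = random_dna(rng, 300)
    ra = random_dna(rng, 500)
    rb = random_dna(rng, 480)
    a = flank + ra + flank
    b = flank + rb + flank
    call = classify(DivSeg(300, 800, 300, 780), a, b)
    assert call.category == "replacement"
    assert 0.0 <= call.homology_identity < 0.7


def test_high_homology_replacement_warned():
    rng = np.random.default_rng(3)
    flank = random_dna(rng, 300)
    ra = random_dna(rng, 500)
    rb = list(ra)
    for p in rng.choice(500, size=10, replace=False):
        rb[p] = "ACGT"[("ACGT".index(rb[p]) + 1) % 4]
    a = flank + ra + flank
    b = flank + "".join(rb) + flank
    call = classify(DivSeg(300, 800, 300, 800), a, b)
    assert call.category == "replacement"
    assert call.homology_identity >= 0.95
    assert "HighHomology" in call.tags


def test_tandem_cnv_category_with_copy_counts():
    """12 bp unit, 12 copies in a vs 20 in b -> tandem_cnv(12, 20)."""
    rng = np.random.default_rng(4)
    unit = "GATCCTGAAGCT"
    flank1, flank2 = random_dna(rng, 300), random_dna(rng, 300)
    a = flank1 + unit * 12 + flank2
    b = flank1 + unit * 20 + flank2
    # divSEG as the left-shifted placement of the extra copies in b
    seg = DivSeg(300, 300, 300, 300 + 8 * 12)
    call = classify(seg, a, b)
    assert call.category == "tandem_cnv"
    assert (call.a_copies, call.b_copies) == (12, 20)
    assert len(call.unit) == 12


def test_tandem_cnv_symmetric():
    rng = np.random.default_rng(5)
    unit = "CCTGAATG"
    flank1, flank2 = random_dna(rng, 200), random_dna(rng, 200)
    a = flank1 + unit * 10 + flank2
    b = flank1 + unit * 15 + flank2
    fwd = classify(DivSeg(200, 200, 200, 240), a, b)
    rev = classify(DivSeg(200, 240, 200, 200), b, a)
    assert fwd.category == rev.category == "tandem_cnv"
    assert (fwd.a_copies, fwd.b_copies) == (rev.b_copies, rev.a_copies)


# ---------------------------------------------------------------------------
# detect_tandem_unit


def test_unit_below_floor_rejected():
    assert detect_tandem_unit("ATGATGATGATG") is None


def test_exact_8bp_unit_47_copies():
    unit = "GTACCGAT"
    got = detect_tandem_unit(unit * 47)
    assert got is not None
    assert got == (unit, 47)


def test_noisy_array_recovered():
    """10-copy array with 5% random noise outside the first copy still
    yields the unit and the copy count."""
    rng = np.random.default_rng(6)
    unit = "GTTCAGACGGAT"  # 12 bp
    arr = list(unit * 10)
    n_noise = int(0.05 * len(arr))
    for p in rng.choice(np.arange(len(unit), len(arr)), size=n_noise,
                        replace=False):
        arr[p] = "ACGT"[("ACGT".index(arr[p]) + 1) % 4]
    got = detect_tandem_unit("".join(arr))
    assert got == (unit, 10)


def test_exhaustive_unit_scan_oracle():
    """detect_tandem_unit agrees with a brute-force scan over every unit
    length and phase on clean arrays."""
    rng = np.random.default_rng(7)
    for ulen in (7, 9, 11, 13, 16):
        unit = random_dna(rng, ulen)
        from segdiff.mapper import _minimal_period
        if _minimal_period(unit) < 7:
            continue
        s = unit * 6
        # oracle: smallest L in bounds such that s[i] == s[i+L] throughout
        oracle = next(
            (L for L in range(7, 17)
             if len(s) >= 2 * L and all(s[i] == s[i + L]
                                        for i in range(len(s) - L))),
            None,
        )
        got = detect_tandem_unit(s)
        assert (got is not None) == (oracle is not None)
        if got:
            assert len(got[0]) == oracle
            assert got[1] == len(s) // oracle


# ---------------------------------------------------------------------------
# internal repeats and end-to-end classification


def test_internal_repeat_tagging():
    rng = np.random.default_rng(8)
    dup = random_dna(rng, 400)
    uniq = random_dna(rng, 400)
    genome_a = (random_dna(rng, 2000) + dup + random_dna(rng, 2000)
                + dup + random_dna(rng, 1000) + uniq + random_dna(rng, 1000))
    genome_b = ""  # not used for "a"-carried inserts
    seg_dup = DivSeg(2000 + 400 + 2000, 2000 + 400 + 2000 + 400, 0, 0)
    call = DivSegCall("indel", seg_dup.a_start, seg_dup.a_end, 0, 0, carrier="a")
    tags = annotate_internal_repeats(seg_dup, call, genome_a, genome_b)
    assert "InternallyRepeated" in tags

    off = 2000 + 400 + 2000 + 400 + 1000
    seg_uniq = DivSeg(off, off + 400, 0, 0)
    call2 = DivSegCall("indel", seg_uniq.a_start, seg_uniq.a_end, 0, 0, carrier="a")
    assert "InternallyRepeated" not in annotate_internal_repeats(
        seg_uniq, call2, genome_a, genome_b)


def test_classify_all_duplicated_vs_unique_inserts():
    """3 duplicated + 3 unique seeded inserts: exactly the duplicated ones
    are tagged InternallyRepeated."""
    rng = np.random.default_rng(9)
    anc = random_dna(rng, 60_000)
    dup_src = [anc[i * 9000 + 100 : i * 9000 + 600] for i in range(3)]
    inserts = dup_src + [random_dna(rng, 500) for _ in range(3)]
    positions = sorted(rng.choice(np.arange(2000, 58_000, 700), size=6,
                                  replace=False))
    b = anc
    for p, ins in zip(sorted(positions, reverse=True),
                      inserts[::-1]):
        b = b[:p] + ins + b[p:]
    res = segment_genomes(anc, b)
    calls = classify_all(res, anc, b)
    tagged = sum("InternallyRepeated" in c.tags for c in calls)
    assert len(calls) == 6
    assert tagged == 3


def test_every_divseg_gets_exactly_one_category(structural_pair):
    _, ga, gb, _ = structural_pair
    res = segment_genomes(ga, gb)
    calls = classify_all(res, ga, gb)
    assert len(calls) == len(res.divsegs())
    valid = {"indel", "approximate_insert", "replacement", "tandem_cnv"}
    assert all(c.category in valid for c in calls)
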