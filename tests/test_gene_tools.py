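"""CDS mutation typing, rRNA comparison, MITE census, in-silico PCR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segdiff.divstats import build_position_map
from segdiff.gene_tools import (
    compare_cds,
    compare_rrna_sets,
    consensus_from_copies,
    insilico_pcr,
    mite_census,
)
from segdiff.io import FeatureRecord, GenomeRecord, revcomp
from segdiff.segmenter import segment_genomes
from segdiff.synthetic import DEFAULT_MITE
from tests.conftest import random_dna


def _gene(n_codons=50, seed=0):
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    body = []
    while len(body) < n_codons - 2:
        c = random_dna(rng, 3)
        if c not in stops:
            body.append(c)
    return "ATG" + "".join(body) + "TAA"


def test_identical_cds():
    g = _gene()
    cmp = compare_cds(g, g)
    assert (cmp.n_point_mutations, cmp.n_silent, cmp.n_nonsilent) == (0, 0, 0)
    assert cmp.aa_replacements == []


def test_synonymous_change_at_codon_10():
    g = _gene(seed=1)
    # force codon 10 to CTG (Leu) vs CTA (Leu): synonymous third-base change
    i = 9 * 3
    a = g[:i] + "CTG" + g[i + 3:]
    b = g[:i] + "CTA" + g[i + 3:]
    cmp = compare_cds(a, b)
    assert (cmp.n_point_mutations, cmp.n_silent, cmp.n_nonsilent) == (1, 1, 0)


def test_nonsynonymous_replacement_label():
    g = _gene(seed=2)
    i = 4 * 3  # codon 5
    a = g[:i] + "CAT" + g[i + 3:]  # His
    b = g[:i] + "TAT" + g[i + 3:]  # Tyr
    cmp = compare_cds(a, b)
    assert cmp.n_point_mutations == 1
    assert cmp.aa_replacements == ["H5Y"]
    # symmetric up to label direction
    rev = compare_cds(b, a)
    assert rev.aa_replacements == ["Y5H"]
    assert rev.n_silent == cmp.n_silent


def test_mixed_mutations_conserve_counts():
    g = _gene(n_codons=200, seed=3)
    rng = np.random.default_rng(4)
    b = list(g)
    pos = rng.choice(np.arange(3, len(g) - 3), size=9, replace=False)
    for p in pos:
        b[p] = "ACGT"[("ACGT".index(b[p]) + 1 + rng.integers(3)) % 4]
    b = "".join(b)
    cmp = compare_cds(g, b)
    assert cmp.n_point_mutations == cmp.n_silent + cmp.n_nonsilent
    assert cmp.n_point_mutations <= 9  # same-codon hits may coincide


def test_non_codon_length_rejected():
    with pytest.raises(ValueError):
        compare_cds("ATGAA", "ATGAA")


# ---------------------------------------------------------------------------
# rRNA comparison


def _with_rrna(seq, positions, length=1500, prefix="rrs"):
    feats = [FeatureRecord(f"{prefix}{i}", "rRNA", p, p + length, "+",
                           product_name="16S ribosomal RNA")
             for i, p in enumerate(positions)]
    return GenomeRecord(id=prefix, sequence=seq, features=feats)


def test_identical_rrna_sets_zero_differences():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 40_000)
    g = _with_rrna(seq, [5000, 20_000])
    pm = build_position_map(segment_genomes(g, g))
    df = compare_rrna_sets(g, g, pm)
    assert list(df.n_differences) == [0, 0]


def test_seeded_16s_snps_counted():
    """3 SNPs in one operon -> that pair reports 3 differences, the other
    pair 0."""
    rng = np.random.default_rng(6)
    seq = random_dna(rng, 40_000)
    b = list(seq)
    for p in (20_100, 20_600, 21_000):
        b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
    b = "".join(b)
    ga = _with_rrna(seq, [5000, 20_000], prefix="a")
    gb = _with_rrna(b, [5000, 20_000], prefix="b")
    pm = build_position_map(segment_genomes(ga, gb))
    df = compare_rrna_sets(ga, gb, pm)
    assert sorted(df.n_differences) == [0, 3]


# ---------------------------------------------------------------------------
# MITE census and consensus


def test_single_embedded_consensus_found_exactly():
    rng = np.random.default_rng(7)
    cons = DEFAULT_MITE.sequence
    seq = random_dna(rng, 5000) + cons + random_dna(rng, 5000)
    census = mite_census(seq, cons)
    assert census.n_complete == 1
    c = census.copies[0]
    assert (c.start, c.end) == (5000, 5000 + len(cons))
    assert c.identity == 1.0


def test_implanted_copies_with_mutations_recovered():
    """10 implanted copies, each with up to 3 substitutions, on both
    strands: all 10 found, non-overlapping, thresholds met."""
    rng = np.random.default_rng(8)
    cons = DEFAULT_MITE.sequence
    L = len(cons)
    seq = random_dna(rng, 2000)
    truth = []
    for i in range(10):
        copy = list(cons)
        for p in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
            copy[p] = "ACGT"[("ACGT".index(copy[p]) + 1) % 4]
        copy = "".join(copy)
        if i % 2:
            copy = revcomp(copy)
        truth.append(len(seq))
        seq += "TA" + copy + "TA" + random_dna(rng, 1500)
    census = mite_census(seq, cons)
    assert census.n_complete == 10
    starts = [c.start for c in census.copies]
    assert starts == sorted(starts)
    for c in census.copies:
        assert c.identity >= 0.8
        assert c.length >= 0.9 * L
        assert c.tsd
    # non-overlap
    for c1, c2 in zip(census.copies, census.copies[1:]):
        assert c1.end <= c2.start
    assert census.modal_length == L


def test_consensus_majority_and_tiebreak():
    assert consensus_from_copies(["ACGT", "ACGT"])[0] == "ACGT"
    # column 2: G,G,T -> majority G; column 3: ties A vs T -> A (A<C<G<T)
    cons, freq = consensus_from_copies(["AAGA", "AAGT", "AATA", "AATT"])
    assert cons[2] == "G"
    assert cons[3] == "A"
    assert freq.loc[2, "G"] == 2 and freq.loc[2, "T"] == 2


def test_consensus_recovers_ancestor_at_2pct_noise():
    rng = np.random.default_rng(9)
    anc = random_dna(rng, 123)
    copies = []
    for _ in range(100):
        c = list(anc)
        for p in range(len(c)):
            if rng.random() < 0.02:
                c[p] = "ACGT"[int(rng.integers(4))]
        copies.append("".join(c))
    cons, freq = consensus_from_copies(copies)
    assert cons == anc
    assert freq.values.sum() == 100 * 123


def test_unequal_copy_lengths_rejected():
    with pytest.raises(ValueError):
        consensus_from_copies(["ACGT", "ACG"])


# ---------------------------------------------------------------------------
# in-silico PCR


def test_amplicon_arithmetic():
    """template N3 + F(20) + 100 bp + rc(R)(20) + N3 -> product 140."""
    rng = np.random.default_rng(10)
    fwd = random_dna(rng, 20)
    rev = random_dna(rng, 20)
    template = "AAA" + fwd + random_dna(rng, 100) + revcomp(rev) + "AAA"
    pred = insilico_pcr(template, fwd, rev, "t1")
    assert pred.products == [140]
    assert pred.product_length == 140


def test_absent_primer_no_product():
    rng = np.random.default_rng(11)
    template = random_dna(rng, 2000)
    pred = insilico_pcr(template, "ACGTACGTACGTACGTACGT", "TTTTGGGGCCCCAAAATTTT")
    assert pred.products == []
    assert pred.product_length is None


def test_mirrored_orientation_found():
    rng = np.random.default_rng(12)
    fwd = random_dna(rng, 20)
    rev = random_dna(rng, 20)
    template = "CC" + fwd + random_dna(rng, 60) + revcomp(rev) + "CC"
    flipped = revcomp(template)
    assert insilico_pcr(flipped, fwd, rev).products == [20 + 60 + 20]


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.integers(0, 900))
def test_amplicon_length_law(seed, gap):
    """Implanting primers D bp apart always yields the closed-form product
    length len(F) + D + len(R), checked against direct string arithmetic."""
    rng = np.random.default_rng(seed)
    fwd = random_dna(rng, int(rng.integers(15, 36)))
    rev = random_dna(rng, int(rng.integers(15, 36)))
    mid = random_dna(rng, gap)
    template = random_dna(rng, 50) + fwd + mid + revcomp(rev) + random_dna(rng, 50)
    expected = len(fwd) + gap + len(rev)
    assert expected in insilico_pcr(template, fwd, rev).products


def test_primer_length_validated():
    with pytest.raises(ValueError):
        insilico_pcr("ACGT" * 100, "ACGT", "ACGTACGTACGTACGTACGT")
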