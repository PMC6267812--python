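"""ORF correlation, start-codon reconciliation, disrupted and
strain-specific gene calling."""

from collections import Counter

import numpy as np
import pytest

from segdiff.divstats import build_position_map
from segdiff.io import FeatureRecord, GenomeRecord, revcomp
from segdiff.orfmap import (
    correlate_orfs,
    find_disrupted,
    protein_identity,
    strain_specific_filter,
    translate_cds,
    verify_sequence_identity,
)
from segdiff.segmenter import segment_genomes
from segdiff.synthetic import MutationSpec, generate_ancestor, mutate_pair
from tests.conftest import random_dna


def _grid_genome(seed=1, length=40_000):
    spec = MutationSpec(genome_length=length, gene_grid=True, n_snp=0,
                        n_1bp_indel=0, seed=seed)
    return generate_ancestor(spec)


def test_identity_all_perfect():
    g = _grid_genome()
    res = segment_genomes(g, g)
    pm = build_position_map(res)
    corr = correlate_orfs(g, g, pm)
    assert len(corr) == len(g.cds_features())
    assert all(c.status == "perfect" for c in corr)
    assert all(c.name_match for c in corr)


def test_each_cds_in_exactly_one_correlation(annotated_pair, annotated_segmentation):
    _, ga, gb, _ = annotated_pair
    _, pm = annotated_segmentation
    corr = correlate_orfs(ga, gb, pm)
    a_seen = [c.a_locus for c in corr if c.a_locus]
    b_seen = [c.b_locus for c in corr if c.b_locus]
    assert sorted(a_seen) == sorted(f.locus_tag for f in ga.cds_features())
    assert sorted(b_seen) == sorted(f.locus_tag for f in gb.cds_features())
    assert len(a_seen) == len(set(a_seen))
    assert len(b_seen) == len(set(b_seen))


def test_correlation_symmetric(annotated_pair, annotated_segmentation):
    _, ga, gb, _ = annotated_pair
    res, pm = annotated_segmentation
    fwd = {(c.a_locus, c.b_locus) for c in correlate_orfs(ga, gb, pm)
           if c.a_locus and c.b_locus}
    res_rev = segment_genomes(gb, ga)
    pm_rev = build_position_map(res_rev)
    rev = {(c.b_locus, c.a_locus) for c in correlate_orfs(gb, ga, pm_rev)
           if c.a_locus and c.b_locus}
    assert fwd == rev


def test_cds_inside_divseg_is_strain_specific(annotated_pair, annotated_segmentation):
    _, ga, gb, truth = annotated_pair
    _, pm = annotated_segmentation
    corr = {c.a_locus or c.b_locus: c for c in correlate_orfs(ga, gb, pm)}
    for row in truth.of_type("strain_gene").itertuples(index=False):
        assert corr[row.target_locus].status == "strain_specific"


def test_unperturbed_genes_all_perfect(annotated_pair, annotated_segmentation):
    _, ga, gb, truth = annotated_pair
    _, pm = annotated_segmentation
    corr = correlate_orfs(ga, gb, pm)
    touched = set(truth.table.target_locus) | {
        t + s for t in truth.table.target_locus for s in ("_1", "_2")
    }
    imperfect = [c for c in corr
                 if c.status != "perfect"
                 and (c.a_locus or c.b_locus) not in touched
                 and (c.b_locus or c.a_locus) not in touched]
    assert imperfect == []


# ---------------------------------------------------------------------------
# sequence verification


def _one_gene_genome(gene_nt: str, locus="g1", start=100, product="p"):
    rng = np.random.default_rng(99)
    seq = random_dna(rng, start) + gene_nt + random_dna(rng, 100)
    feat = FeatureRecord(locus, "CDS", start, start + len(gene_nt), "+",
                         product_name=product)
    return GenomeRecord(id=locus, sequence=seq, features=[feat]), feat


def test_verify_identical_cds():
    gene = "ATG" + "GCTTAC" * 20 + "TAA"
    ga, fa = _one_gene_genome(gene)
    gb, fb = _one_gene_genome(gene)
    ok, recon = verify_sequence_identity(ga, fa, gb, fb)
    assert ok is True
    assert recon.conversion_applied is False


def test_verify_downstream_gtg_start_with_met_conversion():
    """b starts 30 codons downstream at a GTG; genome a's residue there is
    Val, converted to Met before comparison."""
    body = "GCTTAC" * 14  # 28 codons
    gene_a = "ATG" + body + "GTG" + "GCTTAC" * 20 + "TAA"
    ga, fa = _one_gene_genome(gene_a)
    # same genome, but annotate the CDS from the internal GTG onwards
    offset = 3 + len(body)
    fb = FeatureRecord("g2", "CDS", fa.start + offset, fa.end, "+",
                       product_name="p")
    gb = GenomeRecord(id="g2", sequence=ga.sequence, features=[fb])
    ok, recon = verify_sequence_identity(ga, fa, gb, fb)
    assert ok is True
    assert recon.shorter_start_codon == "GTG"
    assert recon.conversion_applied is True


def test_verify_false_on_nonsynonymous_snp():
    gene = "ATG" + "GCTTAC" * 20 + "TAA"
    mutated = gene[:10] + ("C" if gene[10] != "C" else "G") + gene[11:]
    ga, fa = _one_gene_genome(gene)
    gb, fb = _one_gene_genome(mutated)
    assert translate_cds(ga, fa) != translate_cds(gb, fb)
    ok, _ = verify_sequence_identity(ga, fa, gb, fb)
    assert ok is False


def test_untranslatable_cds_flagged():
    gene = "ATG" + "GCTTAC" * 20 + "TAA"
    broken = gene[:-4] + gene[-3:]  # length not a codon multiple
    ga, fa = _one_gene_genome(gene)
    gb, fb = _one_gene_genome(broken)
    ok, recon = verify_sequence_identity(ga, fa, gb, fb)
    assert ok is None and recon is None


# ---------------------------------------------------------------------------
# disrupted genes


def test_seeded_frameshifts_become_disrupted_pairs(annotated_pair, annotated_segmentation):
    _, ga, gb, truth = annotated_pair
    _, pm = annotated_segmentation
    corr = correlate_orfs(ga, gb, pm)
    pairs = find_disrupted(corr, ga, gb, pm)
    split = {p.regular_locus for p in pairs if p.reason == "split"}
    assert split == set(truth.of_type("frameshift").target_locus)
    by_locus = {}
    for c in corr:
        for locus in (c.a_locus, c.b_locus):
            if locus:
                by_locus[locus] = c
    for locus in split:
        assert by_locus[locus].status == "disrupted_pair"


def test_identical_annotations_no_disruption():
    g = _grid_genome(seed=2)
    res = segment_genomes(g, g)
    pm = build_position_map(res)
    corr = correlate_orfs(g, g, pm)
    assert find_disrupted(corr, g, g, pm) == []


def test_pseudo_on_both_sides_excluded():
    spec = MutationSpec(genome_length=20_000, gene_grid=True, n_snp=0,
                        n_1bp_indel=0, seed=3)
    g = generate_ancestor(spec)
    feats = [FeatureRecord(f.locus_tag, f.kind, f.start, f.end, f.strand,
                           pseudo=True, product_name=f.product_name)
             for f in g.features]
    gp = GenomeRecord(id=g.id, sequence=g.sequence, features=feats)
    res = segment_genomes(gp, gp)
    pm = build_position_map(res)
    corr = correlate_orfs(gp, gp, pm)
    assert find_disrupted(corr, gp, gp, pm) == []


# ---------------------------------------------------------------------------
# strain-specific filtering


def test_homolog_filter_retains_exactly_unique_genes(annotated_pair, annotated_segmentation):
    """5 seeded unique genes are retained; the 2 near-duplicates (~90%
    identity to a core gene) are removed by the 75% homolog filter."""
    _, ga, gb, truth = annotated_pair
    _, pm = annotated_segmentation
    corr = correlate_orfs(ga, gb, pm)
    out = strain_specific_filter(corr, ga, gb)
    retained = sorted(out["retained"]["a"] + out["retained"]["b"])
    assert retained == sorted(truth.of_type("strain_gene").target_locus)
    excluded = {**out["excluded"]["a"], **out["excluded"]["b"]}
    for locus in truth.of_type("strain_gene_dup").target_locus:
        assert excluded[locus].startswith("homolog_")


def test_keyword_category_exclusion(annotated_pair, annotated_segmentation):
    _, ga, gb, truth = annotated_pair
    _, pm = annotated_segmentation
    target = truth.of_type("strain_gene").iloc[0]
    feats = []
    for f in (ga if target.carrier == "a" else gb).features:
        if f.locus_tag == target.target_locus:
            f = FeatureRecord(f.locus_tag, f.kind, f.start, f.end, f.strand,
                              product_name="IS630 family transposase")
        feats.append(f)
    g_mod = GenomeRecord(
        id="mod", sequence=(ga if target.carrier == "a" else gb).sequence,
        features=feats)
    pair = (g_mod, gb) if target.carrier == "a" else (ga, g_mod)
    corr = correlate_orfs(*pair, pm)
    out = strain_specific_filter(corr, *pair)
    assert out["excluded"][target.carrier][target.target_locus] == "category"


def test_protein_identity_measures():
    assert protein_identity("MKLVA", "MKLVA") == 1.0
    assert protein_identity("MKLVAMKLVA", "MKLVAMKLVV") == pytest.approx(0.9)
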