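"""Shared fixtures: small synthetic genome pairs and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from segdiff.synthetic import MutationSpec, generate_ancestor, mutate_pair

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def gotoh_score(a: str, b: str, match=1, mismatch=-2, open_=-5, extend=-1) -> float:
    """Independent full-matrix affine-gap global alignment score (Gotoh).

    A gap run of length L costs open + (L-1)*extend; gap switches between
    rows pay a fresh open.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend,
                          Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend,
                          X[i, j - 1] + open_)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def naive_column_counts(row_a: str, row_b: str) -> tuple[int, int, int, int]:
    """Brute-force m/mm/go/ge scan, formulated independently: gap opens are
    counted as the number of maximal gap runs per row."""
    assert len(row_a) == len(row_b)
    import re

    runs = [mo for row in (row_a, row_b) for mo in re.finditer(r"-+", row)]
    gap_cols = sum(mo.end() - mo.start() for mo in runs)
    go = len(runs)
    ge = gap_cols - go
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    m = sum(1 for x, y in pairs if x == y and x != "N")
    mm = len(pairs) - m
    return m, mm, go, ge


def leftmost_indel(seq_with: str, s: int, e: int) -> tuple[int, int]:
    """Canonical (leftmost) placement of an inserted interval [s, e) within
    its carrier sequence — insertions in repetitive context are only defined
    up to rotation."""
    while s > 0 and seq_with[s - 1] == seq_with[e - 1]:
        s -= 1
        e -= 1
    return s, e


@pytest.fixture(scope="session")
def snp_indel_pair():
    """100 kb pair with 25 SNPs and 5 one-base indels (the canonical
    near-identical comparison scenario)."""
    spec = MutationSpec(genome_length=100_000, n_snp=25, n_1bp_indel=5, seed=42)
    anc = generate_ancestor(spec)
    ga, gb, truth = mutate_pair(anc, spec)
    return spec, ga, gb, truth


@pytest.fixture(scope="session")
def structural_pair():
    """200 kb pair with the full zoo of structural events."""
    spec = MutationSpec(
        genome_length=200_000, n_snp=10, n_1bp_indel=3, n_inversion=2,
        n_tandem_cnv=2, n_mge_insertion=3, n_block_indel=3,
        block_length_range=(101, 4000), seed=7,
    )
    anc = generate_ancestor(spec)
    ga, gb, truth = mutate_pair(anc, spec)
    return spec, ga, gb, truth


@pytest.fixture(scope="session")
def annotated_pair():
    """Gene-grid pair with frameshifts and strain-specific genes."""
    spec = MutationSpec(
        genome_length=150_000, gene_grid=True, n_snp=10, n_frameshift=2,
        n_strain_gene=5, n_strain_gene_dup=2, seed=9,
    )
    anc = generate_ancestor(spec)
    ga, gb, truth = mutate_pair(anc, spec)
    return spec, ga, gb, truth


@pytest.fixture(scope="session")
def annotated_segmentation(annotated_pair):
    from segdiff.divstats import build_position_map
    from segdiff.segmenter import segment_genomes

    _, ga, gb, _ = annotated_pair
    res = segment_genomes(ga, gb)
    return res, build_position_map(res)
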