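"""Gene-level diagnostics: CDS point-mutation typing, position-correlated
rRNA comparison, MITE census/consensus, and in-silico PCR strain typing.

``compare_cds`` types the point mutations between two orthologous coding
sequences codon by codon (genetic code 11) into silent and non-silent
changes, reporting amino-acid replacements like ``H526Y`` numbered on the
first genome's protein.  ``mite_census`` finds all non-overlapping copies of
a mobile-element consensus on both strands, with completeness thresholds
and a length histogram; ``consensus_from_copies`` derives a majority-rule
consensus and a base-frequency matrix from equal-length copies.
``insilico_pcr`` predicts amplicon lengths for a primer pair, the basis for
PCR-based strain discrimination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .divstats import PositionCorrelationMap
from .io import GenomeRecord, revcomp

__all__ = [
    "CdsComparison",
    "MiteCensus",
    "MiteCopy",
    "AmpliconPrediction",
    "compare_cds",
    "compare_rrna_sets",
    "mite_census",
    "consensus_from_copies",
    "insilico_pcr",
]

MAX_AMPLICON = 5000


# ---------------------------------------------------------------------------
# CDS comparison


@dataclass
class CdsComparison:
    n_point_mutations: int
    n_silent: int
    n_nonsilent: int
    aa_replacements: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_silent + self.n_nonsilent != self.n_point_mutations:
            raise ValueError("silent + nonsilent must equal point mutations")


def compare_cds(a_cds: str, b_cds: str) -> CdsComparison:
    """Codon-aligned comparison of two CDSs (indel-free expected).

    Counts per-base point mutations, classifies each affected codon as
    silent or non-silent, and reports replacements as <refAA><pos><altAA>
    with 1-based residue numbering on the genome-a protein.
    """
    for name, s in (("a", a_cds), ("b", b_cds)):
        if len(s) % 3:
            raise ValueError(f"CDS {name} length is not a multiple of 3")
    flagged = []
    if len(a_cds) != len(b_cds):
        # orthologous CDSs are expected indel-free; compare the common
        # prefix codon-wise and flag the length difference
        flagged.append("length_difference")
        n = min(len(a_cds), len(b_cds))
        n -= n % 3
        a_cds, b_cds = a_cds[:n], b_cds[:n]
    aa_a = _translate_initiator(a_cds, flagged, "a")
    _translate_initiator(b_cds, flagged, "b")
    n_pm = n_silent = n_nonsilent = 0
    replacements = []
    for ci in range(0, len(a_cds), 3):
        ca = a_cds[ci : ci + 3]
        cb = b_cds[ci : ci + 3]
        diffs = sum(1 for x, y in zip(ca, cb) if x != y)
        if diffs == 0:
            continue
        pos = ci // 3 + 1  # 1-based residue on the genome-a protein
        n_pm += diffs
        ra = aa_a[pos - 1] if pos - 1 < len(aa_a) else "?"
        rb = "M" if ci == 0 else str(Seq(cb).translate(table=11))
        if ra == rb:
            n_silent += diffs
        else:
            n_nonsilent += diffs
            replacements.append(f"{ra}{pos}{rb}")
    return CdsComparison(n_pm, n_silent, n_nonsilent, replacements, flagged)


def _translate_initiator(cds: str, flagged: list, name: str) -> str:
    nt = cds.replace("-", "")
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        flagged.append(f"internal_stop_{name}")
    return "M" + aa[1:] if aa else aa


# ---------------------------------------------------------------------------
# rRNA operon comparison


def compare_rrna_sets(
    a: GenomeRecord,
    b: GenomeRecord,
    posmap: PositionCorrelationMap,
    product_filter: str = "16S",
) -> pd.DataFrame:
    """Pair rRNA genes through the position map and count base differences.

    Operons are paired by mapping the midpoint of each a-side rRNA into b
    and picking the b-side rRNA containing it; leftovers on either side are
    listed unpaired with a difference count of -1.
    """
    sel = lambda g: [
        f for f in g.rrna_features()
        if not product_filter or product_filter.lower() in f.product_name.lower()
    ]
    a_rrna, b_rrna = sel(a), sel(b)
    rows = []
    used_b = set()
    for fa in a_rrna:
        mid = (fa.start + fa.end) // 2
        partner = None
        for off in range(0, (fa.end - fa.start) // 2, 50):
            for pos in (mid + off, mid - off):
                if 0 <= pos < len(a.sequence):
                    p = posmap.map_a_to_b(pos)
                    if p is not None:
                        partner = p
                        break
            if partner is not None:
                break
        fb = None
        if partner is not None:
            for cand in b_rrna:
                if cand.locus_tag not in used_b and cand.start <= partner < cand.end:
                    fb = cand
                    break
        if fb is None:
            rows.append({"a_locus": fa.locus_tag, "b_locus": "",
                         "n_differences": -1})
            continue
        used_b.add(fb.locus_tag)
        sa = a.feature_sequence(fa)
        sb = b.feature_sequence(fb)
        d = edlib.align(sa, sb, task="distance")["editDistance"]
        rows.append({"a_locus": fa.locus_tag, "b_locus": fb.locus_tag,
                     "n_differences": int(d)})
    for fb in b_rrna:
        if fb.locus_tag not in used_b:
            rows.append({"a_locus": "", "b_locus": fb.locus_tag,
                         "n_differences": -1})
    return pd.DataFrame(rows, columns=["a_locus", "b_locus", "n_differences"])


# ---------------------------------------------------------------------------
# MITE census


@dataclass
class MiteCopy:
    start: int
    end: int
    strand: str
    length: int
    identity: float
    tsd: bool  # flanked by a TA target-site duplication


@dataclass
class MiteCensus:
    family: str
    copies: list[MiteCopy]
    length_histogram: dict[int, int]

    @property
    def n_complete(self) -> int:
        return len(self.copies)

    @property
    def modal_length(self) -> int | None:
        if not self.copies:
            return None
        return max(self.length_histogram.items(), key=lambda kv: (kv[1], -kv[0]))[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "start": c.start, "end": c.end, "strand": c.strand,
            "length": c.length, "identity": round(c.identity, 4),
            "tsd": c.tsd,
        } for c in self.copies])


def _seed_candidates(seq: str, consensus: str, k: int = 14) -> set[int]:
    """Approximate start positions suggested by exact k-mer seeds."""
    idx: dict[str, list[int]] = {}
    for i in range(len(consensus) - k + 1):
        idx.setdefault(consensus[i : i + k], []).append(i)
    starts: set[int] = set()
    step = max(1, k // 2)
    for j in range(0, len(seq) - k + 1):
        km = seq[j : j + k]
        offs = idx.get(km)
        if offs:
            for off in offs:
                starts.add(j - off)
    return starts


def mite_census(
    genome: GenomeRecord | str,
    consensus: str,
    family: str = "MITE",
    min_length_frac: float = 0.9,
    min_identity: float = 0.8,
) -> MiteCensus:
    """Census of all non-overlapping copies of a consensus element.

    A copy is *complete* when its aligned span is at least
    ``min_length_frac`` of the consensus length at ``min_identity``
    identity; both strands are searched and a flanking TA target-site
    duplication is recorded when present.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    consensus = consensus.upper()
    L = len(consensus)
    if L < 50:
        raise ValueError("consensus must be at least 50 bp")
    margin = max(10, int(L * 0.2))
    hits: list[tuple[int, int, str, float]] = []
    for strand, cons in (("+", consensus), ("-", revcomp(consensus))):
        cands = sorted(_seed_candidates(seq, cons))
        merged: list[tuple[int, int]] = []
        for s in cands:
            w0 = max(0, s - margin)
            w1 = min(len(seq), s + L + margin)
            if merged and w0 <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], w1))
            else:
                merged.append((w0, w1))
        k_dist = int(L * (1 - min_identity))
        for w0, w1 in merged:
            window = seq[w0:w1]
            while True:
                res = edlib.align(cons, window, mode="HW", task="locations",
                                  k=k_dist)
                if res["editDistance"] == -1 or not res["locations"]:
                    break
                s_loc, e_loc = res["locations"][0]
                span = e_loc - s_loc + 1
                ident = 1.0 - res["editDistance"] / max(span, L)
                if span >= min_length_frac * L and ident >= min_identity:
                    s_best, e_best, id_best = s_loc, e_loc + 1, ident
                    if span < L:
                        # a mismatching terminal base makes the local hit
                        # short; snap back to full element length if the
                        # identity allows
                        for cs in (s_loc, e_loc + 1 - L):
                            if cs < 0 or cs + L > len(window):
                                continue
                            sl = window[cs : cs + L]
                            if "#" in sl:
                                continue
                            d = edlib.align(cons, sl, task="distance")["editDistance"]
                            cid = 1.0 - d / L
                            if cid >= min_identity and cid >= id_best - 1e-9:
                                s_best, e_best, id_best = cs, cs + L, cid
                                break
                    hits.append((w0 + s_best, w0 + e_best, strand, id_best))
                    s_loc, e_loc = s_best, e_best - 1
                # blank out the found copy and rescan the window remainder
                window = (window[:s_loc] + "#" * (e_loc + 1 - s_loc)
                          + window[e_loc + 1 :])
    # non-overlapping selection, best identity first, then leftmost
    hits.sort(key=lambda h: (-h[3], h[0]))
    chosen: list[tuple[int, int, str, float]] = []
    occupied: list[tuple[int, int]] = []
    for h in hits:
        if any(h[0] < e and s < h[1] for s, e in occupied):
            continue
        chosen.append(h)
        occupied.append((h[0], h[1]))
    chosen.sort(key=lambda h: h[0])
    copies = []
    for s, e, strand, ident in chosen:
        tsd = seq[max(0, s - 2) : s] == "TA" and seq[e : e + 2] == "TA"
        copies.append(MiteCopy(s, e, strand, e - s, ident, tsd))
    hist = dict(sorted(Counter(c.length for c in copies).items()))
    return MiteCensus(family, copies, hist)


def consensus_from_copies(copies: list[str]) -> tuple[str, pd.DataFrame]:
    """Majority-rule consensus of equal-length copies plus the per-column
    base-frequency matrix (ties broken by the fixed order A < C < G < T)."""
    if len(copies) < 2:
        raise ValueError("need at least two copies")
    n = len(copies[0])
    if any(len(c) != n for c in copies):
        raise ValueError("copies must have equal length (pre-filter to the "
                         "modal length)")
    arr = np.frombuffer("".join(c.upper() for c in copies).encode(),
                        dtype=np.uint8).reshape(len(copies), n)
    bases = "ACGT"
    freqs = np.stack([(arr == ord(x)).sum(axis=0) for x in bases])
    # argmax takes the first maximum, i.e. the A<C<G<T order on ties
    cons = "".join(bases[i] for i in freqs.argmax(axis=0))
    mat = pd.DataFrame(freqs.T, columns=list(bases))
    mat.index.name = "position"
    return cons, mat


# ---------------------------------------------------------------------------
# in-silico PCR


@dataclass
class AmpliconPrediction:
    primer_id: str
    products: list[int]  # all product lengths found, ascending

    @property
    def product_length(self) -> int | None:
        return self.products[0] if self.products else None


def _find_sites(seq: str, primer: str, max_mismatches: int) -> list[int]:
    """Start positions where primer matches with <= max_mismatches and the
    3'-terminal base (last base of the primer) matching exactly."""
    hits = []
    if max_mismatches == 0:
        start = 0
        while True:
            i = seq.find(primer, start)
            if i < 0:
                break
            hits.append(i)
            start = i + 1
        return hits
    n = len(primer)
    for i in range(len(seq) - n + 1):
        window = seq[i : i + n]
        if window[-1] != primer[-1]:
            continue
        mm = sum(1 for x, y in zip(window, primer) if x != y)
        if mm <= max_mismatches:
            hits.append(i)
    return hits


def insilico_pcr(
    genome: GenomeRecord | str,
    fwd: str,
    rev: str,
    primer_id: str = "pair",
    max_mismatches: int = 0,
    max_product: int = MAX_AMPLICON,
) -> AmpliconPrediction:
    """Predict amplicons for a primer pair.

    The forward primer is located on the plus strand and the reverse
    primer's reverse complement downstream of it (and the mirrored
    orientation); the product spans from the forward primer's 5' base to
    the far end of the reverse-primer site, inclusive.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    fwd, rev = fwd.upper(), rev.upper()
    for p in (fwd, rev):
        if not 15 <= len(p) <= 35:
            raise ValueError("primers must be 15-35 nt")
    if max_mismatches > 3:
        raise ValueError("at most 3 mismatches supported")
    products = set()
    for left, right in ((fwd, rev), (rev, fwd)):
        # 3' mismatch must stay disallowed on the rc-site too: the reverse
        # primer's 3' base is the first base of its reverse complement
        lsites = _find_sites(seq, left, max_mismatches)
        rc = revcomp(right)
        rsites = _find_sites_rc(seq, rc, max_mismatches)
        for ls in lsites:
            for rs in rsites:
                end = rs + len(rc)
                length = end - ls
                if len(left) <= length <= max_product:
                    products.add(length)
    return AmpliconPrediction(primer_id, sorted(products))


def _find_sites_rc(seq: str, rc_primer: str, max_mismatches: int) -> list[int]:
    """Sites of a reverse-complemented primer; the primer's 3' end is the
    first base of the site and must match exactly."""
    if max_mismatches == 0:
        hits = []
        start = 0
        while True:
            i = seq.find(rc_primer, start)
            if i < 0:
                break
            hits.append(i)
            start = i + 1
        return hits
    n = len(rc_primer)
    hits = []
    for i in range(len(seq) - n + 1):
        window = seq[i : i + n]
        if window[0] != rc_primer[0]:
            continue
        mm = sum(1 for x, y in zip(window, rc_primer) if x != y)
        if mm <= max_mismatches:
            hits.append(i)
    return hits
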