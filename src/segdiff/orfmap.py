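"""Correlation of protein-coding genes between two annotated genomes.

ORFs are paired positionally through the per-base position-correlation map:
the C-terminal position is tried first, then (for ORFs whose C-terminus
fails) the N-terminal position; a correlation is possible only if at least
one terminus lies inside a matchSEG.  A pair whose two termini both map to
equivalent positions in the same segment and whose product names are
identical is a *perfect* correlation.  ORFs inside divSEGs are candidate
strain-specific genes; candidates with a close homolog (>= 75% protein
identity) in the other proteome, or in excluded product categories
(transposases, phage proteins, ...), are filtered out.  Genes regular in
one strain but pseudo-flagged or split into fragments in the other are
reported as disrupted pairs.

Terminus positions are strand-aware: the C-terminus is the last transcribed
base (``end-1`` on the forward strand, ``start`` on the reverse strand) and
equivalence means the position map pairs one coordinate exactly with the
other (no slack).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .divstats import MAPPED, STRAIN_SPECIFIC, PositionCorrelationMap
from .io import FeatureRecord, GenomeRecord

__all__ = [
    "OrfCorrelation",
    "StartReconciliation",
    "DisruptedPair",
    "correlate_orfs",
    "verify_sequence_identity",
    "find_disrupted",
    "strain_specific_filter",
    "translate_cds",
    "protein_identity",
]

STATUSES = (
    "perfect",
    "c_term_only",
    "n_term_only",
    "unmapped",
    "strain_specific",
    "disrupted_pair",
    "spurious_candidate",
)

DEFAULT_EXCLUDE_KEYWORDS = ("transposase", "integrase", "phage", "prophage")
SPURIOUS_MAX_NT = 150


@dataclass
class OrfCorrelation:
    a_locus: str | None
    b_locus: str | None
    status: str
    name_match: bool = False
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    def to_row(self) -> dict:
        return {
            "a_locus": self.a_locus or "",
            "b_locus": self.b_locus or "",
            "status": self.status,
            "name_match": self.name_match,
            "identity": round(self.identity, 4) if self.identity is not None else "",
        }


@dataclass(frozen=True)
class StartReconciliation:
    shorter_start_codon: str  # ATG, GTG or TTG
    conversion_applied: bool  # internal Val/Leu -> Met substitution used


@dataclass
class DisruptedPair:
    regular_genome: str  # "a" or "b"
    regular_locus: str
    fragment_loci: tuple[str, ...]
    reason: str  # "pseudo_flag" or "split"


# ---------------------------------------------------------------------------
# translation helpers (bacterial code, table 11)


def translate_cds(genome: GenomeRecord, feat: FeatureRecord) -> str | None:
    """Protein sequence of a CDS (genetic code 11, initiator always Met).

    Returns None for untranslatable CDSs (length not a codon multiple,
    missing stop, or internal stop) — callers treat those as flagged.
    """
    nt = genome.feature_sequence(feat)
    if len(nt) % 3 or len(nt) < 6:
        return None
    aa = str(Seq(nt).translate(table=11))
    if not aa.endswith("*"):
        return None
    aa = aa[:-1]
    if "*" in aa:
        return None
    return "M" + aa[1:]


def start_codon(genome: GenomeRecord, feat: FeatureRecord) -> str:
    return genome.feature_sequence(feat)[:3]


def _c_term(feat: FeatureRecord) -> int:
    return feat.end - 1 if feat.strand == "+" else feat.start


def _n_term(feat: FeatureRecord) -> int:
    return feat.start if feat.strand == "+" else feat.end - 1


# ---------------------------------------------------------------------------
# positional correlation


def correlate_orfs(
    a: GenomeRecord,
    b: GenomeRecord,
    posmap: PositionCorrelationMap,
) -> list[OrfCorrelation]:
    """Pair every CDS of both genomes positionally; each CDS appears in
    exactly one OrfCorrelation."""
    a_cds = a.cds_features()
    b_cds = b.cds_features()
    b_by_cterm = {(_c_term(f), f.strand): f for f in b_cds}
    b_by_nterm = {(_n_term(f), f.strand): f for f in b_cds}

    consumed_b: set[str] = set()
    paired: dict[str, tuple[FeatureRecord, str]] = {}  # a_locus -> (fb, via)

    # first pass: C-terminal correlation for every ORF
    for fa in a_cds:
        ac = _c_term(fa)
        if posmap.a_category[ac] != MAPPED:
            continue
        cand = b_by_cterm.get((int(posmap.a_partner[ac]), fa.strand))
        if cand is not None and cand.locus_tag not in consumed_b:
            consumed_b.add(cand.locus_tag)
            paired[fa.locus_tag] = (cand, "c")
    # second pass: N-terminal correlation for the remainder
    for fa in a_cds:
        if fa.locus_tag in paired:
            continue
        an = _n_term(fa)
        if posmap.a_category[an] != MAPPED:
            continue
        cand = b_by_nterm.get((int(posmap.a_partner[an]), fa.strand))
        if cand is not None and cand.locus_tag not in consumed_b:
            consumed_b.add(cand.locus_tag)
            paired[fa.locus_tag] = (cand, "n")

    out: list[OrfCorrelation] = []
    for fa in a_cds:
        hit = paired.get(fa.locus_tag)
        if hit is None:
            out.append(OrfCorrelation(fa.locus_tag, None,
                                      _unpaired_status(fa, posmap, "a")))
            continue
        fb, via = hit
        names_equal = bool(fa.product_name) and fa.product_name == fb.product_name
        if via == "c":
            ac, an = _c_term(fa), _n_term(fa)
            n_equiv = (
                posmap.a_category[an] == MAPPED
                and int(posmap.a_partner[an]) == _n_term(fb)
            )
            same_seg = (
                posmap.a_segment[ac] == posmap.a_segment[an]
                if n_equiv else False
            )
            status = ("perfect" if n_equiv and same_seg and names_equal
                      else "c_term_only")
        else:
            status = "n_term_only"
        out.append(OrfCorrelation(fa.locus_tag, fb.locus_tag, status,
                                  name_match=names_equal))
    for fb in b_cds:
        if fb.locus_tag in consumed_b:
            continue
        out.append(OrfCorrelation(None, fb.locus_tag,
                                  _unpaired_status(fb, posmap, "b")))
    return out


def _unpaired_status(
    feat: FeatureRecord, posmap: PositionCorrelationMap, genome: str
) -> str:
    cat = posmap.a_category if genome == "a" else posmap.b_category
    if (cat[feat.start : feat.end] == STRAIN_SPECIFIC).all():
        return "strain_specific"
    return "unmapped"


# ---------------------------------------------------------------------------
# sequence-level verification with start-codon reconciliation


def verify_sequence_identity(
    a: GenomeRecord, fa: FeatureRecord,
    b: GenomeRecord, fb: FeatureRecord,
) -> tuple[bool | None, StartReconciliation | None]:
    """Check that a correlated ORF pair encodes the same protein.

    Equal-length proteins must be identical.  With inconsistent start-codon
    assignments the C-terminal fragments must be identical over the length
    of the shorter protein; when the shorter ORF starts with GTG or TTG the
    internal Val/Leu of the longer protein is converted to Met first.
    Untranslatable CDSs yield (None, None) — flagged, excluded.
    """
    pa = translate_cds(a, fa)
    pb = translate_cds(b, fb)
    if pa is None or pb is None:
        return None, None
    if pa == pb:
        return True, StartReconciliation(start_codon(a, fa), False)
    if len(pa) == len(pb):
        return False, StartReconciliation(start_codon(a, fa), False)
    if len(pa) < len(pb):
        shorter, longer = pa, pb
        sc = start_codon(a, fa)
    else:
        shorter, longer = pb, pa
        sc = start_codon(b, fb)
    frag = longer[-len(shorter):]
    if sc == "ATG":
        return frag == shorter, StartReconciliation(sc, False)
    if sc in ("GTG", "TTG") and frag and frag[0] in "VL":
        frag = "M" + frag[1:]
        return frag == shorter, StartReconciliation(sc, True)
    return frag == shorter, StartReconciliation(sc, False)


# ---------------------------------------------------------------------------
# disrupted genes


def find_disrupted(
    correlations: list[OrfCorrelation],
    a: GenomeRecord,
    b: GenomeRecord,
    posmap: PositionCorrelationMap,
) -> list[DisruptedPair]:
    """Genes regular in one strain and disrupted in the other.

    A pair is reported when one genome carries a pseudo-flagged CDS whose
    partner is regular, or when two/three CDS fragments of one genome map
    inside the span of a single regular CDS of the other (a split gene
    annotated without a pseudo flag).  The statuses of the correlations
    involved are updated to ``disrupted_pair``.
    """
    a_feats = {f.locus_tag: f for f in a.cds_features()}
    b_feats = {f.locus_tag: f for f in b.cds_features()}
    by_a = {c.a_locus: c for c in correlations if c.a_locus}
    by_b = {c.b_locus: c for c in correlations if c.b_locus}
    pairs: list[DisruptedPair] = []

    # pseudo flag on exactly one side of a correlated pair
    for c in correlations:
        if not (c.a_locus and c.b_locus):
            continue
        fa, fb = a_feats[c.a_locus], b_feats[c.b_locus]
        if fa.pseudo == fb.pseudo:
            continue
        regular = "a" if fb.pseudo else "b"
        pairs.append(DisruptedPair(
            regular_genome=regular,
            regular_locus=c.a_locus if regular == "a" else c.b_locus,
            fragment_loci=(c.b_locus if regular == "a" else c.a_locus,),
            reason="pseudo_flag",
        ))
        c.status = "disrupted_pair"

    # split genes: several fragments of one genome inside one partner span
    def splits(host: GenomeRecord, host_feats, guest_feats, guest_to_host,
               host_name: str, by_host, by_guest):
        for hf in host.cds_features():
            if hf.pseudo:
                continue
            frags = []
            for gf in guest_feats.values():
                pts = []
                for coord in (_c_term(gf), _n_term(gf)):
                    partner = guest_to_host(coord)
                    if partner is not None:
                        pts.append(partner)
                if pts and all(hf.start <= p < hf.end for p in pts):
                    frags.append(gf)
            frags = [g for g in frags if not g.pseudo]
            if len(frags) < 2 or len(frags) > 3:
                continue
            pairs.append(DisruptedPair(
                regular_genome=host_name,
                regular_locus=hf.locus_tag,
                fragment_loci=tuple(g.locus_tag for g in frags),
                reason="split",
            ))
            host_corr = by_host.get(hf.locus_tag)
            if host_corr is not None:
                host_corr.status = "disrupted_pair"
            for g in frags:
                gc = by_guest.get(g.locus_tag)
                if gc is not None:
                    gc.status = "disrupted_pair"

    splits(a, a_feats, b_feats, posmap.map_b_to_a, "a", by_a, by_b)
    splits(b, b_feats, a_feats, posmap.map_a_to_b, "b", by_b, by_a)
    return pairs


# ---------------------------------------------------------------------------
# strain-specific gene filtering


def protein_identity(x: str, y: str) -> float:
    """Global-alignment identity: matches / aligned length, terminal gaps
    excluded."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(x, y)[0]
    ax, ay = [], []
    px = py = 0
    for (sx, ex), (sy, ey) in zip(aln.aligned[0], aln.aligned[1]):
        if sx > px:
            ax.append(x[px:sx])
            ay.append("-" * (sx - px))
        if sy > py:
            ax.append("-" * (sy - py))
            ay.append(y[py:sy])
        ax.append(x[sx:ex])
        ay.append(y[sy:ey])
        px, py = ex, ey
    if px < len(x):
        ax.append(x[px:])
        ay.append("-" * (len(x) - px))
    if py < len(y):
        ax.append("-" * (len(y) - py))
        ay.append(y[py:])
    rx, ry = "".join(ax), "".join(ay)
    # trim terminal gap columns
    start = 0
    end = len(rx)
    while start < end and (rx[start] == "-" or ry[start] == "-"):
        start += 1
    while end > start and (rx[end - 1] == "-" or ry[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    matches = sum(1 for i in range(start, end) if rx[i] == ry[i] != "-")
    return matches / (end - start)


def _kmers(s: str, k: int = 5) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def strain_specific_filter(
    correlations: list[OrfCorrelation],
    a: GenomeRecord,
    b: GenomeRecord,
    min_homolog_identity: float = 0.75,
    exclude_keywords: tuple[str, ...] = DEFAULT_EXCLUDE_KEYWORDS,
) -> dict:
    """Filter strain-specific gene candidates.

    Removes candidates with a cross-proteome homolog at or above
    ``min_homolog_identity``, candidates in excluded product-name
    categories, and rates short candidates without any cross-proteome hit
    as spurious.  Returns retained/excluded locus lists per genome and
    logs the reason for every exclusion.
    """
    feats = {"a": {f.locus_tag: f for f in a.cds_features()},
             "b": {f.locus_tag: f for f in b.cds_features()}}
    genomes = {"a": a, "b": b}
    proteomes = {
        g: {
            tag: translate_cds(genomes[g], f)
            for tag, f in feats[g].items()
            if translate_cds(genomes[g], f) is not None
        }
        for g in ("a", "b")
    }
    kmer_index = {
        g: {tag: _kmers(p) for tag, p in proteomes[g].items()}
        for g in ("a", "b")
    }

    retained = {"a": [], "b": []}
    excluded = {"a": {}, "b": {}}
    for c in correlations:
        if c.status != "strain_specific":
            continue
        g = "a" if c.a_locus else "b"
        other = "b" if g == "a" else "a"
        tag = c.a_locus or c.b_locus
        feat = feats[g][tag]
        name = feat.product_name.lower()
        if any(kw in name for kw in exclude_keywords):
            excluded[g][tag] = "category"
            continue
        prot = proteomes[g].get(tag)
        if prot is None:
            excluded[g][tag] = "untranslatable"
            continue
        mine = _kmers(prot)
        best = 0.0
        hit_any = False
        for otag, okms in kmer_index[other].items():
            if not (mine & okms):
                continue
            hit_any = True
            ident = protein_identity(prot, proteomes[other][otag])
            best = max(best, ident)
            if best >= min_homolog_identity:
                break
        c.identity = best if hit_any else None
        if best >= min_homolog_identity:
            excluded[g][tag] = f"homolog_{best:.2f}"
            continue
        if not hit_any and feat.length < SPURIOUS_MAX_NT:
            c.status = "spurious_candidate"
            excluded[g][tag] = "spurious"
            continue
        retained[g].append(tag)
    return {"retained": retained, "excluded": excluded}


def correlations_to_frame(correlations: list[OrfCorrelation]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in correlations])
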