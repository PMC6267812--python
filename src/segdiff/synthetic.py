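"""Synthetic genome pairs with exhaustive ground truth.

The generator emulates the difference structure seen between closely
related bacterial chromosomes: point mutations, 1-base frameshift indels,
mobile-element insertions flanked by a target-site duplication (TSD),
long inversions bounded by inverted repeats, tandem-repeat copy-number
variations with 7-16 bp units, and prophage-like strain-specific blocks.
An ancestral sequence (optionally carrying a regular grid of protein-coding
genes, genetic code 11) is mutated into two descendants; every event is
applied to exactly one descendant and recorded in a truth table with its
coordinates in the ancestor and in both derived genomes.

Events are placed at least 200 bp apart by default so that each falls into
its own connector/divSEG and recovery by the comparison pipeline is exact.
Randomness comes from numpy's PCG64 generator seeded explicitly, so fixtures
are reproducible bit for bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .io import FeatureRecord, GenomeRecord, revcomp

__all__ = [
    "MutationSpec",
    "MutationTruthTable",
    "MobileElement",
    "DEFAULT_MITE",
    "generate_ancestor",
    "mutate_pair",
    "emit_fixture",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_START_CODONS = ("ATG", "GTG", "TTG")


@dataclass(frozen=True)
class MobileElement:
    name: str
    sequence: str
    tsd_length: int = 2


# A MITE-like element: 25 bp terminal inverted repeats around a 73 bp core,
# 123 bp in total, inserted at TA target sites with a TA duplication.
_MITE_TIR = "TAGGCTGATCCAACGCGTTAGGCTA"
_MITE_CORE = (
    "ACCTTGAGCGATTACGGCATCAATGCTTGGTCAGGAACGTTCCATGATTGCCGTAAGCTTACGGATCCATTGA"
)
DEFAULT_MITE = MobileElement(
    "synMITE1", _MITE_TIR + _MITE_CORE + revcomp(_MITE_TIR), tsd_length=2
)


@dataclass
class MutationSpec:
    """Event counts and geometry for one synthetic genome pair."""

    genome_length: int = 500_000
    gc_content: float = 0.43  # enterobacterial
    n_snp: int = 25
    n_1bp_indel: int = 5
    n_inversion: int = 0
    n_tandem_cnv: int = 0
    n_mge_insertion: int = 0
    n_block_indel: int = 0
    n_frameshift: int = 0  # 1-bp indels targeted at planted CDSs
    #: strain-specific gene insertions (a novel CDS inside an inserted block)
    n_strain_gene: int = 0
    #: like n_strain_gene, but the inserted CDS is a close (~90% identity)
    #: copy of an existing core gene, so the homolog filter removes it
    n_strain_gene_dup: int = 0
    strain_gene_length: int = 600  # multiple of 3
    strain_gene_pad: int = 150  # unannotated flank inside the inserted block
    block_length_range: tuple[int, int] = (500, 5000)
    inversion_length_range: tuple[int, int] = (1000, 4000)
    inverted_repeat_range: tuple[int, int] = (35, 84)
    mge_library: tuple[MobileElement, ...] = (DEFAULT_MITE,)
    tandem_unit_range: tuple[int, int] = (7, 16)
    tandem_copy_range: tuple[int, int] = (10, 49)
    min_spacing: int = 200
    gene_grid: bool = False
    gene_length: int = 900  # multiple of 3
    gene_spacing: int = 2400  # distance between gene starts
    start_codon_props: tuple[float, float, float] = (0.8, 0.15, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_snp, self.n_1bp_indel, self.n_inversion,
                  self.n_tandem_cnv, self.n_mge_insertion,
                  self.n_block_indel, self.n_frameshift)
        if any(c < 0 for c in counts):
            raise ValueError("event counts must be >= 0")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be a fraction in (0, 1)")
        if self.gene_length % 3:
            raise ValueError("gene_length must be a codon multiple")


@dataclass
class MutationTruthTable:
    """Ground truth: one row per event, the oracle for recovery tests."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def of_type(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["type"] == kind]

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n codons without stop codons (gene bodies stay open)."""
    out = []
    while len(out) < n:
        cod = _random_dna(rng, 3, gc)
        if cod not in _STOPS and cod not in _START_CODONS:
            out.append(cod)
    return "".join(out)


def generate_ancestor(spec: MutationSpec) -> GenomeRecord:
    """Random ancestor genome, optionally with a regular grid of CDSs."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    seq = list(_random_dna(rng, spec.genome_length, spec.gc_content))
    features: list[FeatureRecord] = []
    if spec.gene_grid:
        gi = 0
        pos = spec.gene_spacing // 2
        while pos + spec.gene_length + 3 <= spec.genome_length:
            gi += 1
            start_codon = _START_CODONS[
                rng.choice(3, p=np.asarray(spec.start_codon_props))
            ]
            body = _random_codons(rng, spec.gene_length // 3 - 2, spec.gc_content)
            stop = _STOPS[rng.integers(3)]
            gene = start_codon + body + stop
            strand = "+" if rng.random() < 0.5 else "-"
            placed = gene if strand == "+" else revcomp(gene)
            seq[pos : pos + len(gene)] = placed
            features.append(
                FeatureRecord(
                    locus_tag=f"SYN_{gi:04d}",
                    kind="CDS",
                    start=pos,
                    end=pos + len(gene),
                    strand=strand,
                    product_name=f"hypothetical protein {gi:04d}",
                )
            )
            pos += spec.gene_spacing
    return GenomeRecord(
        id=f"synthetic_{spec.seed}", sequence="".join(seq), circular=False,
        features=features,
        description=f"synthetic ancestor length={spec.genome_length} seed={spec.seed}",
    )


@dataclass
class _Event:
    kind: str
    carrier: str  # "a" or "b"
    anc_start: int
    anc_end: int
    repl_a: str
    repl_b: str
    payload: str = ""
    detail: str = ""
    target_locus: str = ""
    #: CDS planted inside the carrier's inserted material:
    #: (offset within repl, length, strand, locus_tag, product_name)
    new_cds: tuple | None = None


def _pick_position(
    rng: np.random.Generator,
    reserved: list[tuple[int, int]],
    footprint: int,
    genome_length: int,
    spacing: int,
    forbidden: list[tuple[int, int]] | None = None,
) -> int:
    for _ in range(2000):
        p = int(rng.integers(spacing, genome_length - footprint - spacing))
        lo, hi = p - spacing, p + footprint + spacing
        if any(s < hi and lo < e for s, e in reserved):
            continue
        if forbidden and any(s < p + footprint and p < e for s, e in forbidden):
            continue
        reserved.append((p, p + footprint))
        return p
    raise ValueError(
        "infeasible packing: cannot place an event of footprint "
        f"{footprint} with spacing {spacing} in length {genome_length}"
    )


def _random_unit(rng: np.random.Generator, length: int, gc: float) -> str:
    from .mapper import _minimal_period

    while True:
        u = _random_dna(rng, length, gc)
        if _minimal_period(u) >= 7:
            return u


def mutate_pair(
    ancestor: GenomeRecord, spec: MutationSpec
) -> tuple[GenomeRecord, GenomeRecord, MutationTruthTable]:
    """Apply the specified events, each to one descendant, with ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    anc = ancestor.sequence
    n = len(anc)
    reserved: list[tuple[int, int]] = []
    cds = [f for f in ancestor.features if f.kind == "CDS"]
    cds_intervals = [(f.start, f.end) for f in cds]
    events: list[_Event] = []

    def coin() -> str:
        return "a" if rng.random() < 0.5 else "b"

    # structural events are kept out of planted genes so that untouched genes
    # stay perfectly correlated
    for _ in range(spec.n_block_indel):
        lo, hi = spec.block_length_range
        length = int(rng.integers(lo, hi + 1))
        p = _pick_position(rng, reserved, 0, n, spec.min_spacing, cds_intervals)
        block = _random_dna(rng, length, spec.gc_content)
        c = coin()
        events.append(_Event(
            "block_indel", c, p, p,
            repl_a=block if c == "a" else "",
            repl_b=block if c == "b" else "",
            payload=block, detail=f"len={length}",
        ))

    strain_gene_no = 0
    for kind_count, duplicate in ((spec.n_strain_gene, False),
                                  (spec.n_strain_gene_dup, True)):
        for _ in range(kind_count):
            strain_gene_no += 1
            pad = spec.strain_gene_pad
            if duplicate:
                if not cds:
                    raise ValueError("n_strain_gene_dup needs gene_grid genes")
                donor = cds[int(rng.integers(len(cds)))]
                gene = ancestor.feature_sequence(donor)
                codons = [gene[i : i + 3] for i in range(0, len(gene), 3)]
                n_mut = max(1, len(codons) // 10)
                idx = rng.choice(np.arange(1, len(codons) - 1), size=n_mut,
                                 replace=False)
                for i in idx:
                    codons[int(i)] = _random_codons(rng, 1, spec.gc_content)
                gene = "".join(codons)
            else:
                gene = ("ATG"
                        + _random_codons(rng, spec.strain_gene_length // 3 - 2,
                                         spec.gc_content)
                        + _STOPS[int(rng.integers(3))])
            block = (_random_dna(rng, pad, spec.gc_content) + gene
                     + _random_dna(rng, pad, spec.gc_content))
            p = _pick_position(rng, reserved, 0, n, spec.min_spacing,
                               cds_intervals)
            c = coin()
            tag = f"SYNS_{strain_gene_no:04d}"
            kind = "strain_gene_dup" if duplicate else "strain_gene"
            events.append(_Event(
                kind, c, p, p,
                repl_a=block if c == "a" else "",
                repl_b=block if c == "b" else "",
                payload=block, detail=f"gene_len={len(gene)}",
                target_locus=tag,
                new_cds=(pad, len(gene), "+", tag,
                         f"strain-specific protein {strain_gene_no:04d}"),
            ))

    for _ in range(spec.n_mge_insertion):
        elem = spec.mge_library[int(rng.integers(len(spec.mge_library)))]
        t = elem.tsd_length
        p = _pick_position(rng, reserved, t, n, spec.min_spacing, cds_intervals)
        tsd = anc[p : p + t]
        ins = tsd + elem.sequence + tsd
        c = coin()
        events.append(_Event(
            "mge_insertion", c, p, p + t,
            repl_a=ins if c == "a" else tsd,
            repl_b=ins if c == "b" else tsd,
            payload=elem.sequence, detail=f"element={elem.name};tsd={tsd}",
        ))

    for _ in range(spec.n_inversion):
        lo, hi = spec.inversion_length_range
        length = int(rng.integers(lo, hi + 1))
        irlen = int(rng.integers(*spec.inverted_repeat_range))
        p = _pick_position(rng, reserved, length, n, spec.min_spacing, cds_intervals)
        ir = _random_dna(rng, irlen, spec.gc_content)
        core = anc[p + irlen : p + length - irlen]
        region = ir + core + revcomp(ir)
        c = coin()
        inverted = revcomp(region)
        events.append(_Event(
            "inversion", c, p, p + length,
            repl_a=inverted if c == "a" else region,
            repl_b=inverted if c == "b" else region,
            payload=region, detail=f"len={length};ir_len={irlen}",
        ))

    for _ in range(spec.n_tandem_cnv):
        ulen = int(rng.integers(spec.tandem_unit_range[0],
                                spec.tandem_unit_range[1] + 1))
        unit = _random_unit(rng, ulen, spec.gc_content)
        lo, hi = spec.tandem_copy_range
        p_copies = int(rng.integers(lo, hi + 1))
        q_copies = int(rng.integers(lo, hi + 1))
        while q_copies == p_copies:
            q_copies = int(rng.integers(lo, hi + 1))
        foot = ulen * p_copies
        p = _pick_position(rng, reserved, foot, n, spec.min_spacing, cds_intervals)
        c = coin()
        base_arr = unit * p_copies
        var_arr = unit * q_copies
        a_copies = q_copies if c == "a" else p_copies
        b_copies = q_copies if c == "b" else p_copies
        events.append(_Event(
            "tandem_cnv", c, p, p + foot,
            repl_a=var_arr if c == "a" else base_arr,
            repl_b=var_arr if c == "b" else base_arr,
            payload=unit,
            detail=f"unit_len={ulen};a_copies={a_copies};b_copies={b_copies}",
        ))

    for _ in range(spec.n_frameshift):
        free = [f for f in cds if not any(
            s < f.end and f.start < e for s, e in reserved)]
        if not free:
            raise ValueError("infeasible packing: no unreserved CDS left")
        feat = free[int(rng.integers(len(free)))]
        # interior position, away from the termini
        p = int(rng.integers(feat.start + 60, feat.end - 60))
        reserved.append((feat.start - spec.min_spacing,
                         feat.end + spec.min_spacing))
        c = coin()
        if rng.random() < 0.5:  # 1-base deletion
            ev = _Event("frameshift", c, p, p + 1,
                        repl_a="" if c == "a" else anc[p : p + 1],
                        repl_b="" if c == "b" else anc[p : p + 1],
                        payload=anc[p : p + 1], detail="del",
                        target_locus=feat.locus_tag)
        else:
            base = "ACGT"[int(rng.integers(4))]
            ev = _Event("frameshift", c, p, p,
                        repl_a=base if c == "a" else "",
                        repl_b=base if c == "b" else "",
                        payload=base, detail="ins",
                        target_locus=feat.locus_tag)
        events.append(ev)

    for _ in range(spec.n_1bp_indel):
        p = _pick_position(rng, reserved, 1, n, spec.min_spacing, cds_intervals)
        c = coin()
        if rng.random() < 0.5:
            ev = _Event("one_base_indel", c, p, p + 1,
                        repl_a="" if c == "a" else anc[p : p + 1],
                        repl_b="" if c == "b" else anc[p : p + 1],
                        payload=anc[p : p + 1], detail="del")
        else:
            base = "ACGT"[int(rng.integers(4))]
            ev = _Event("one_base_indel", c, p, p,
                        repl_a=base if c == "a" else "",
                        repl_b=base if c == "b" else "",
                        payload=base, detail="ins")
        events.append(ev)

    for _ in range(spec.n_snp):
        p = _pick_position(rng, reserved, 1, n, spec.min_spacing)
        old = anc[p]
        alts = [x for x in "ACGT" if x != old]
        new = alts[int(rng.integers(3))]
        c = coin()
        events.append(_Event(
            "snp", c, p, p + 1,
            repl_a=new if c == "a" else old,
            repl_b=new if c == "b" else old,
            payload=new, detail=f"{old}>{new}",
        ))

    events.sort(key=lambda e: (e.anc_start, e.anc_end))

    # build both descendants in one sweep, recording derived coordinates
    pieces_a: list[str] = []
    pieces_b: list[str] = []
    rows = []
    extra_feats: dict[str, list[FeatureRecord]] = {"a": [], "b": []}
    ca = cb = 0
    prev = 0
    shifts: list[tuple[int, int, int]] = []  # (anc_end, shift_a, shift_b)
    for ev in events:
        keep = anc[prev : ev.anc_start]
        pieces_a.append(keep)
        pieces_b.append(keep)
        ca += len(keep)
        cb += len(keep)
        rows.append({
            "type": ev.kind, "carrier": ev.carrier,
            "anc_start": ev.anc_start, "anc_end": ev.anc_end,
            "a_start": ca, "a_end": ca + len(ev.repl_a),
            "b_start": cb, "b_end": cb + len(ev.repl_b),
            "payload": ev.payload, "detail": ev.detail,
            "target_locus": ev.target_locus,
        })
        if ev.new_cds is not None:
            off, glen, strand, tag, product = ev.new_cds
            gstart = (ca if ev.carrier == "a" else cb) + off
            extra_feats[ev.carrier].append(FeatureRecord(
                locus_tag=tag, kind="CDS", start=gstart, end=gstart + glen,
                strand=strand, product_name=product,
            ))
        pieces_a.append(ev.repl_a)
        pieces_b.append(ev.repl_b)
        ca += len(ev.repl_a)
        cb += len(ev.repl_b)
        prev = ev.anc_end
        shifts.append((ev.anc_end, ca - prev, cb - prev))
    tail = anc[prev:]
    pieces_a.append(tail)
    pieces_b.append(tail)
    seq_a = "".join(pieces_a)
    seq_b = "".join(pieces_b)

    def lift(x: int, genome: str) -> int:
        shift = 0
        for anc_end, sh_a, sh_b in shifts:
            if anc_end <= x:
                shift = sh_a if genome == "a" else sh_b
            else:
                break
        return x + shift

    feats_a, feats_b = _lift_features(ancestor, events, lift)
    feats_a = sorted(feats_a + extra_feats["a"], key=lambda f: (f.start, f.end))
    feats_b = sorted(feats_b + extra_feats["b"], key=lambda f: (f.start, f.end))
    truth = MutationTruthTable(pd.DataFrame(
        rows, columns=["type", "carrier", "anc_start", "anc_end", "a_start",
                       "a_end", "b_start", "b_end", "payload", "detail",
                       "target_locus"],
    ))
    ga = GenomeRecord(id=f"{ancestor.id}_A", sequence=seq_a, features=feats_a,
                      description=f"{ancestor.description} descendant A")
    gb = GenomeRecord(id=f"{ancestor.id}_B", sequence=seq_b, features=feats_b,
                      description=f"{ancestor.description} descendant B")
    _check_truth(ga, gb, truth)
    return ga, gb, truth


def _lift_features(ancestor, events, lift):
    """Carry the ancestor annotation onto both descendants.  A frameshifted
    CDS is replaced in the carrier by two fragment features (no pseudo flag),
    the way an annotation pipeline would call the pieces."""
    frameshifts = {e.target_locus: e for e in events if e.kind == "frameshift"}
    out = {"a": [], "b": []}
    for f in ancestor.features:
        ev = frameshifts.get(f.locus_tag)
        for g in ("a", "b"):
            s, e = lift(f.start, g), lift(f.end, g)
            if ev is None or ev.carrier != g:
                out[g].append(FeatureRecord(
                    locus_tag=f.locus_tag, kind=f.kind, start=s, end=e,
                    strand=f.strand, pseudo=f.pseudo,
                    product_name=f.product_name,
                ))
                continue
            # split the carrier copy into two in-frame fragments at the indel
            p = lift(ev.anc_start, g)
            cut1 = s + 3 * ((p - s) // 3)
            rest = e - (p + 1)
            cut2 = e - 3 * (rest // 3)
            if cut2 <= cut1:
                cut2 = cut1 + 3
            out[g].append(FeatureRecord(
                locus_tag=f"{f.locus_tag}_1", kind="CDS", start=s, end=cut1,
                strand=f.strand, product_name=f.product_name,
            ))
            out[g].append(FeatureRecord(
                locus_tag=f"{f.locus_tag}_2", kind="CDS", start=cut2, end=e,
                strand=f.strand, product_name=f.product_name,
            ))
    return out["a"], out["b"]


def _check_truth(ga, gb, truth: MutationTruthTable) -> None:
    """Every recorded payload must sit verbatim at its derived coordinates."""
    for row in truth.table.itertuples(index=False):
        seq = ga.sequence if row.carrier == "a" else gb.sequence
        s = row.a_start if row.carrier == "a" else row.b_start
        e = row.a_end if row.carrier == "a" else row.b_end
        if row.type == "snp":
            if seq[s:e] != row.payload:
                raise AssertionError("truth table SNP payload mismatch")
        elif row.type in ("one_base_indel", "frameshift") and row.detail == "ins":
            if seq[s:e] != row.payload:
                raise AssertionError("truth table indel payload mismatch")
        elif row.type in ("block_indel", "strain_gene", "strain_gene_dup"):
            if seq[s:e] != row.payload:
                raise AssertionError("truth table block payload mismatch")
        elif row.type == "mge_insertion":
            if row.payload not in seq[s:e]:
                raise AssertionError("truth table element payload mismatch")
        elif row.type == "inversion":
            region = seq[s:e]
            if region not in (row.payload, revcomp(row.payload)):
                raise AssertionError("truth table inversion payload mismatch")


# ---------------------------------------------------------------------------
# fixture emission


def _to_seqrecord(g: GenomeRecord) -> SeqRecord:
    rec = SeqRecord(Seq(g.sequence), id=g.id, description=g.description)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if g.circular else "linear"
    rec.annotations["date"] = "01-JAN-2000"  # fixed for byte-identical output
    for f in g.features:
        quals = {"locus_tag": [f.locus_tag]}
        if f.product_name:
            quals["product"] = [f.product_name]
        if f.pseudo:
            quals["pseudo"] = [""]
        rec.features.append(SeqFeature(
            FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
            type=f.kind, qualifiers=quals,
        ))
    return rec


def emit_fixture(
    pair: tuple[GenomeRecord, GenomeRecord, MutationTruthTable],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + GenBank for both genomes and the truth TSV."""
    ga, gb, truth = pair
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, g in (("a", ga), ("b", gb)):
        rec = _to_seqrecord(g)
        fa = out / f"genome_{tag}.fasta"
        gbk = out / f"genome_{tag}.gb"
        SeqIO.write([rec], str(fa), "fasta")
        SeqIO.write([rec], str(gbk), "genbank")
        paths[f"fasta_{tag}"] = fa
        paths[f"genbank_{tag}"] = gbk
    tsv = out / "truth.tsv"
    truth.table.to_csv(tsv, sep="\t", index=False, lineterminator="\n")
    paths["truth"] = tsv
    return paths
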