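"""Reading and writing the standard formats the pipeline touches.

All coordinates are 0-based half-open on the forward strand of the
linearised sequence.  Circular genomes are linearised at the record's given
origin and the comparison never wraps across it.  Conversion to 1-based
inclusive coordinates (GenBank, GFF3) happens only at the format boundary.

Sequences are upper-cased on read; IUPAC ambiguity codes other than N are
mapped to N, and N always counts as a mismatch downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeRecord",
    "FeatureRecord",
    "read_genome",
    "read_genomes",
    "read_table",
    "write_report",
    "write_tsv",
    "write_bed",
    "write_gff3",
    "read_primer_table",
]

_VALID = set("ACGTN")
_AMBIG = re.compile(r"[^ACGTN]")


class ParseError(ValueError):
    """Raised when an input file does not parse under the named standard."""


@dataclass(frozen=True)
class FeatureRecord:
    """A CDS/rRNA/other feature in 0-based half-open genome coordinates."""

    locus_tag: str
    kind: str  # "CDS", "rRNA" or "other"
    start: int
    end: int
    strand: str  # "+" or "-"
    pseudo: bool = False
    product_name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.locus_tag}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One genome sequence with optional annotation."""

    id: str
    sequence: str
    circular: bool = False
    features: list[FeatureRecord] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id}: empty sequence")
        seq = self.sequence.upper()
        seq = _AMBIG.sub("N", seq)
        self.sequence = seq
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"genome {self.id}: duplicate locus tags {dup[:5]}")
        for f in self.features:
            if f.end > len(seq):
                raise ValueError(
                    f"genome {self.id}: feature {f.locus_tag} exceeds length {len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_features(self) -> list[FeatureRecord]:
        return [f for f in self.features if f.kind == "CDS"]

    def rrna_features(self) -> list[FeatureRecord]:
        return [f for f in self.features if f.kind == "rRNA"]

    def feature_sequence(self, feat: FeatureRecord) -> str:
        """Feature sequence 5'->3' (reverse-complemented for minus strand)."""
        s = self.sequence[feat.start : feat.end]
        return revcomp(s) if feat.strand == "-" else s


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _features_from_seqrecord(rec) -> list[FeatureRecord]:
    feats: list[FeatureRecord] = []
    seen: set[str] = set()
    anon = 0
    for f in rec.features:
        if f.type not in ("CDS", "rRNA"):
            continue
        quals = f.qualifiers
        tag = quals.get("locus_tag", [None])[0]
        if tag is None:
            anon += 1
            tag = f"{f.type}_{anon:05d}"
        if tag in seen:  # compound annotations can repeat a tag; keep first
            continue
        seen.add(tag)
        loc = f.location
        if loc is None:
            continue
        strand = "-" if loc.strand == -1 else "+"
        feats.append(
            FeatureRecord(
                locus_tag=tag,
                kind=f.type,
                start=int(loc.start),
                end=int(loc.end),
                strand=strand,
                pseudo="pseudo" in quals or "pseudogene" in quals,
                product_name=quals.get("product", [""])[0],
            )
        )
    feats.sort(key=lambda f: (f.start, f.end, f.locus_tag))
    return feats


def read_genomes(path: str | Path, format: str = "fasta") -> list[GenomeRecord]:
    """Read every sequence record in *path* (``fasta`` or ``genbank``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format: {format!r}")
    try:
        recs = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # biopython raises assorted ValueErrors
        raise ParseError(f"{path}: cannot parse as {format}: {exc}") from exc
    if not recs:
        raise ParseError(f"{path}: no records found (format {format})")
    out = []
    for rec in recs:
        seq = str(rec.seq)
        if len(seq) == 0:
            raise ParseError(f"{path}: record {rec.id} has an empty sequence")
        circular = rec.annotations.get("topology", "") == "circular"
        out.append(
            GenomeRecord(
                id=rec.id,
                sequence=seq,
                circular=circular,
                features=_features_from_seqrecord(rec),
                description=rec.description,
            )
        )
    return out


def read_genome(path: str | Path, format: str = "fasta") -> GenomeRecord:
    """Read a single-genome file; error if the file holds several records."""
    recs = read_genomes(path, format)
    if len(recs) != 1:
        raise ParseError(f"{path}: expected one record, found {len(recs)}")
    return recs[0]


def read_primer_table(path: str | Path) -> pd.DataFrame:
    """Primer TSV with columns id, forward_seq, reverse_seq."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "forward_seq", "reverse_seq"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: primer table lacks columns {sorted(missing)}")
    for col in ("forward_seq", "reverse_seq"):
        df[col] = df[col].str.upper()
    return df


# ---------------------------------------------------------------------------
# report writing


def _to_frame(result) -> pd.DataFrame:
    """Coerce a pipeline result into a DataFrame via its to_frame() or as-is."""
    if isinstance(result, pd.DataFrame):
        return result
    if hasattr(result, "to_frame"):
        return result.to_frame()
    if isinstance(result, Iterable):
        rows = list(result)
        if rows and hasattr(rows[0], "to_row"):
            return pd.DataFrame([r.to_row() for r in rows])
        return pd.DataFrame(rows)
    raise TypeError(f"cannot serialise {type(result).__name__}")


def write_tsv(result, path: str | Path) -> None:
    """Deterministic TSV: stable column order, '\\n' endings, no index."""
    df = _to_frame(result)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.4f")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: Sequence[tuple[str, int, int]] | pd.DataFrame,
              path: str | Path, names: Sequence[str] | None = None) -> None:
    """BED (0-based half-open) — internal convention, written as-is."""
    if isinstance(intervals, pd.DataFrame):
        rows = [tuple(r) for r in intervals.itertuples(index=False)]
    else:
        rows = [tuple(r) for r in intervals]
    rows.sort(key=lambda r: (str(r[0]), int(r[1]), int(r[2])))
    with open(path, "w") as fh:
        for i, row in enumerate(rows):
            chrom, start, end = row[:3]
            name = names[i] if names is not None else (row[3] if len(row) > 3 else ".")
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{name}\n")


def write_gff3(features: Sequence[tuple], path: str | Path) -> None:
    """GFF3 (1-based inclusive). Rows: (seqid, type, start0, end0, strand, attrs)."""
    rows = sorted(features, key=lambda r: (str(r[0]), int(r[2]), int(r[3])))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start0, end0, strand, attrs in rows:
            fh.write(
                f"{seqid}\tsegdiff\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"
            )


def write_report(result, path: str | Path, format: str = "tsv") -> None:
    """Write a finished pipeline product in the requested report format."""
    if format == "tsv":
        write_tsv(result, path)
    elif format == "bed":
        write_bed(result, path)
    elif format == "gff3":
        write_gff3(result, path)
    else:
        raise ValueError(f"unsupported report format: {format!r}")


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (report boundary only)."""
    return start0 + 1, end0


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    return start1 - 1, end1
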