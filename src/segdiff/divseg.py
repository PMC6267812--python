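"""Categorisation of divergent segments (divSEGs).

Each divSEG between two matchSEGs is assigned exactly one of four
categories, tested in this order:

* ``tandem_cnv`` — the extra material is a whole number of copies of a
  7-16 bp tandem-repeat unit that tiles the locus in both genomes with
  differing copy counts;
* ``indel`` — one side is empty: the inserted sequence can be pinpointed
  to an exact position in the carrier genome;
* ``approximate_insert`` — an insert whose position is resolved only up to
  10 unaligned bases on the other side;
* ``replacement`` — dissimilar sequence on both sides at an equivalent
  position (the fallback).  The aligned identity of the two sides is
  reported; sides above 95% identity are tagged, since such a segment may
  belong in a matchSEG instead.

Inserts that match elsewhere in their own genome are tagged
``InternallyRepeated`` (genome-internal duplications).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from .io import GenomeRecord
from .mapper import TANDEM_UNIT_MAX, TANDEM_UNIT_MIN, _minimal_period, _try_tandem_cnv
from .segmenter import DivSeg, SegmentationResult

__all__ = [
    "DivSegCall",
    "TandemRepeatCNV",
    "classify",
    "classify_all",
    "detect_tandem_unit",
    "annotate_internal_repeats",
]

APPROX_INSERT_TOLERANCE = 10
HIGH_HOMOLOGY_WARN = 0.95
INTERNAL_REPEAT_MIN_IDENTITY = 0.90
INTERNAL_REPEAT_MIN_COVERAGE = 0.80


@dataclass
class TandemRepeatCNV:
    unit: str
    a_copies: int
    b_copies: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    def __post_init__(self) -> None:
        if not TANDEM_UNIT_MIN <= len(self.unit) <= TANDEM_UNIT_MAX:
            raise ValueError("tandem unit length out of bounds")
        if max(self.a_copies, self.b_copies) < 2:
            raise ValueError("a tandem CNV needs >= 2 copies on one side")


@dataclass
class DivSegCall:
    category: str  # indel | approximate_insert | replacement | tandem_cnv
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    carrier: str | None = None  # genome carrying the insert, for inserts
    homology_identity: float | None = None
    unit: str | None = None
    a_copies: int | None = None
    b_copies: int | None = None
    tags: set = field(default_factory=set)

    def to_row(self) -> dict:
        return {
            "category": self.category,
            "a_start": self.a_start, "a_end": self.a_end,
            "b_start": self.b_start, "b_end": self.b_end,
            "carrier": self.carrier or "",
            "unit": self.unit or "",
            "a_copies": self.a_copies if self.a_copies is not None else "",
            "b_copies": self.b_copies if self.b_copies is not None else "",
            "homology_identity": (
                round(self.homology_identity, 4)
                if self.homology_identity is not None else ""
            ),
            "tags": ",".join(sorted(self.tags)),
        }


def _seq(g: GenomeRecord | str) -> str:
    return g.sequence if isinstance(g, GenomeRecord) else g


def detect_tandem_unit(
    s: str, min_unit: int = TANDEM_UNIT_MIN, max_unit: int = TANDEM_UNIT_MAX
) -> tuple[str, int] | None:
    """Smallest tandem unit (within bounds) whose concatenation covers the
    string with at most 10% mismatching positions; returns (unit, copies).

    Units that are themselves periodic with a period below ``min_unit`` are
    rejected, so e.g. a poly-ATG array is not reported as a 9-mer repeat.
    """
    if not s:
        raise ValueError("empty sequence")
    n = len(s)
    for L in range(min_unit, max_unit + 1):
        if n < 2 * L:
            break
        unit = s[:L]
        if _minimal_period(unit) < min_unit:
            continue
        tiled = (unit * (n // L + 1))[:n]
        mism = sum(1 for x, y in zip(s, tiled) if x != y)
        if mism <= 0.10 * n:
            return unit, n // L
    return None


def _identity_global(x: str, y: str) -> float:
    if not x or not y:
        return 0.0
    d = edlib.align(x, y, task="distance")["editDistance"]
    return 1.0 - d / max(len(x), len(y))


def classify(
    seg: DivSeg, a: GenomeRecord | str, b: GenomeRecord | str
) -> DivSegCall:
    """Assign one category to a divSEG (decision order: tandem_cnv, indel,
    approximate_insert, replacement)."""
    sa, sb = _seq(a), _seq(b)
    la, lb = seg.a_length, seg.b_length
    coords = dict(a_start=seg.a_start, a_end=seg.a_end,
                  b_start=seg.b_start, b_end=seg.b_end)

    cnv = _try_tandem_cnv(seg, sa, sb)
    if cnv is not None:
        unit, na, nb = cnv
        return DivSegCall("tandem_cnv", **coords,
                          carrier="a" if na > nb else "b",
                          unit=unit, a_copies=na, b_copies=nb)
    if la == 0 or lb == 0:
        return DivSegCall("indel", **coords, carrier="a" if la else "b")
    if min(la, lb) <= APPROX_INSERT_TOLERANCE:
        return DivSegCall("approximate_insert", **coords,
                          carrier="a" if la > lb else "b")
    ident = _identity_global(sa[seg.a_start : seg.a_end],
                             sb[seg.b_start : seg.b_end])
    call = DivSegCall("replacement", **coords, homology_identity=ident)
    if ident >= HIGH_HOMOLOGY_WARN:
        call.tags.add("HighHomology")
    return call


def annotate_internal_repeats(
    seg: DivSeg, call: DivSegCall, genome_a: GenomeRecord | str,
    genome_b: GenomeRecord | str,
) -> set:
    """Tag the call ``InternallyRepeated`` when the insert sequence occurs
    elsewhere in its own genome (>= 90% identity over >= 80% of its length)."""
    if call.carrier == "a":
        own, start, end = _seq(genome_a), seg.a_start, seg.a_end
    elif call.carrier == "b":
        own, start, end = _seq(genome_b), seg.b_start, seg.b_end
    else:
        return call.tags
    insert = own[start:end]
    if len(insert) < 20:
        return call.tags
    rest = own[:start] + own[end:]
    core = insert[
        int(len(insert) * (1 - INTERNAL_REPEAT_MIN_COVERAGE) / 2):
        int(len(insert) * (1 + INTERNAL_REPEAT_MIN_COVERAGE) / 2)
    ]
    for query in (insert, core):
        if not query:
            continue
        k = int((1 - INTERNAL_REPEAT_MIN_IDENTITY) * len(query))
        res = edlib.align(query, rest, mode="HW", task="distance", k=k)
        if res["editDistance"] != -1:
            call.tags.add("InternallyRepeated")
            break
    return call.tags


def classify_all(
    seg_result: SegmentationResult,
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    tag_internal_repeats: bool = True,
) -> list[DivSegCall]:
    """Classify every divSEG of a finished segmentation, in genome order."""
    seg_result.validate()
    calls = []
    for s in seg_result.divsegs():
        call = classify(s, a, b)
        if tag_internal_repeats and call.category in ("indel", "approximate_insert"):
            annotate_internal_repeats(s, call, a, b)
        s.category = call.category
        s.tags = call.tags
        calls.append(call)
    return calls


def calls_to_frame(calls: list[DivSegCall]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in calls])
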