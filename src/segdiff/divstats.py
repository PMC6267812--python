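"""Alignment column statistics, the divergence measure, and per-base
position-correlation maps between two segmented genomes.

Every alignment column is classified as exactly one of match (m), mismatch
(mm), gap open (go) or gap extension (ge); the first column of each maximal
gap run in either row is the go column, subsequent ones are ge.  N bases
always count as mismatch.  Divergence is (mm + go) / (m + mm + go): gap
extensions never enter the statistic, so a long indel counts once however
long it is.  Cumulative statistics over many segments are obtained by
summing counts, never by averaging per-segment fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import PairwiseAlignment

__all__ = [
    "ColumnStats",
    "classify_columns",
    "divergence",
    "PositionCorrelationMap",
    "build_position_map",
    "MAPPED",
    "GAP",
    "STRAIN_SPECIFIC",
]

# position-map category codes
MAPPED = 0
GAP = 1
STRAIN_SPECIFIC = 2
_CATEGORY_NAMES = {MAPPED: "mapped", GAP: "gap", STRAIN_SPECIFIC: "strain_specific"}


@dataclass
class ColumnStats:
    m: int = 0
    mm: int = 0
    go: int = 0
    ge: int = 0

    def __post_init__(self) -> None:
        if min(self.m, self.mm, self.go, self.ge) < 0:
            raise ValueError("column counts must be non-negative")

    def __add__(self, other: "ColumnStats") -> "ColumnStats":
        return ColumnStats(
            self.m + other.m, self.mm + other.mm,
            self.go + other.go, self.ge + other.ge,
        )

    @property
    def total(self) -> int:
        return self.m + self.mm + self.go + self.ge


def classify_columns(aln: PairwiseAlignment) -> ColumnStats:
    """Count m/mm/go/ge columns of an alignment."""
    a, b = aln.a_aligned, aln.b_aligned
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    m = mm = go = ge = 0
    gap_a = gap_b = False
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            raise ValueError("column with gaps in both rows")
        if x == "-":
            if gap_a:
                ge += 1
            else:
                go += 1
            gap_a, gap_b = True, False
        elif y == "-":
            if gap_b:
                ge += 1
            else:
                go += 1
            gap_a, gap_b = False, True
        else:
            gap_a = gap_b = False
            if x == y and x != "N":
                m += 1
            else:
                mm += 1
    return ColumnStats(m, mm, go, ge)


def divergence(stats: ColumnStats) -> float:
    """(mm + go) / (m + mm + go); gap extensions are excluded."""
    denom = stats.m + stats.mm + stats.go
    if denom <= 0:
        raise ValueError("divergence undefined: no m/mm/go columns")
    return (stats.mm + stats.go) / denom


@dataclass
class PositionCorrelationMap:
    """Per-base classification of both genomes with partner coordinates.

    ``a_category``/``b_category`` hold MAPPED/GAP/STRAIN_SPECIFIC codes;
    ``a_partner``/``b_partner`` hold the coordinate in the other genome for
    mapped positions and -1 otherwise; ``a_segment``/``b_segment`` hold the
    index of the segment each position belongs to.
    """

    a_category: np.ndarray
    a_partner: np.ndarray
    a_segment: np.ndarray
    b_category: np.ndarray
    b_partner: np.ndarray
    b_segment: np.ndarray

    def category_counts(self, genome: str) -> dict[str, int]:
        cat = self.a_category if genome == "a" else self.b_category
        return {
            name: int((cat == code).sum()) for code, name in _CATEGORY_NAMES.items()
        }

    def map_a_to_b(self, pos: int) -> int | None:
        p = int(self.a_partner[pos])
        return p if p >= 0 else None

    def map_b_to_a(self, pos: int) -> int | None:
        p = int(self.b_partner[pos])
        return p if p >= 0 else None

    def to_frame(self) -> pd.DataFrame:
        """Two-column coordinate liftover (mapped positions only)."""
        idx = np.nonzero(self.a_category == MAPPED)[0]
        return pd.DataFrame({"pos_a": idx, "pos_b": self.a_partner[idx]})

    def strain_specific_intervals(self, genome: str) -> list[tuple[int, int]]:
        cat = self.a_category if genome == "a" else self.b_category
        mask = cat == STRAIN_SPECIFIC
        out: list[tuple[int, int]] = []
        pos = np.nonzero(mask)[0]
        if pos.size == 0:
            return out
        start = prev = int(pos[0])
        for p in pos[1:]:
            p = int(p)
            if p != prev + 1:
                out.append((start, prev + 1))
                start = p
            prev = p
        out.append((start, prev + 1))
        return out


def matchseg_event_counts(seg_result) -> dict[str, int]:
    """Point-mutation and frameshift totals over all matchSEG alignments.

    Point mutations are mismatch columns; frameshifts are internal gap runs
    whose length is not a multiple of 3 (indels that disrupt the reading
    frame, overwhelmingly 1-base runs in closely related genomes).
    """
    import re

    pm = fs = 0
    for s in seg_result.matchsegs():
        pm += s.stats.mm
        for row in (s.alignment.a_aligned, s.alignment.b_aligned):
            for mo in re.finditer(r"-+", row):
                if (mo.end() - mo.start()) % 3:
                    fs += 1
    return {"point_mutations": pm, "frameshifts": fs}


def build_position_map(seg) -> PositionCorrelationMap:
    """Build the per-base correlation map from a SegmentationResult.

    Positions inside matchSEGs are mapped (or gap, when opposite a gap in
    the alignment); positions inside divSEGs are strain-specific.
    """
    seg.validate()
    la, lb = seg.a_length, seg.b_length
    a_cat = np.full(la, STRAIN_SPECIFIC, dtype=np.int8)
    b_cat = np.full(lb, STRAIN_SPECIFIC, dtype=np.int8)
    a_par = np.full(la, -1, dtype=np.int64)
    b_par = np.full(lb, -1, dtype=np.int64)
    a_seg = np.full(la, -1, dtype=np.int64)
    b_seg = np.full(lb, -1, dtype=np.int64)

    for idx, s in enumerate(seg.segments):
        a_seg[s.a_start : s.a_end] = idx
        b_seg[s.b_start : s.b_end] = idx
        aln = getattr(s, "alignment", None)
        if aln is None:  # divSEG: already strain-specific
            continue
        i, j = s.a_start, s.b_start
        for x, y in zip(aln.a_aligned, aln.b_aligned):
            if x != "-" and y != "-":
                a_cat[i] = MAPPED
                b_cat[j] = MAPPED
                a_par[i] = j
                b_par[j] = i
                i += 1
                j += 1
            elif x == "-":
                b_cat[j] = GAP
                j += 1
            else:
                a_cat[i] = GAP
                i += 1
        if i != s.a_end or j != s.b_end:
            raise ValueError("segment alignment inconsistent with its intervals")

    pm = PositionCorrelationMap(a_cat, a_par, a_seg, b_cat, b_par, b_seg)
    _check_monotone(pm)
    return pm


def _check_monotone(pm: PositionCorrelationMap) -> None:
    mapped = pm.a_partner[pm.a_partner >= 0]
    if mapped.size and not np.all(np.diff(mapped) > 0):
        raise AssertionError("mapped positions are not strictly increasing")
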