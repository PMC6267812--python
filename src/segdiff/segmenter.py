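"""Segmentation of a moderately diverged genome pair into matchSEGs/divSEGs.

The comparison runs in three passes.  Pass 1 aligns the genomes in 200 kb
chunks, each new chunk starting at the beginning of the last matching
stretch of the previous one, so the chunks jointly traverse both
chromosomes.  Pass 2 extracts draft matching segments from the chunk
alignments: a matchSEG is extended until an indel longer than 100 bp or a
significant rise in local divergence (a sliding 1 kb window above 5%)
terminates it, and its boundaries are trimmed so that the first and last
alignment column is an identical base pair.  Pass 3 re-aligns every
matchSEG, splits those containing indels over 100 bp, fuses those separated
by fewer than 100 bp in both genomes, and flags matchSEGs above 1%
divergence for review.  Every genome position ends up in exactly one
segment; the gaps between matchSEGs are the divSEGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignParams, PairwiseAlignment, align_pair
from .divstats import ColumnStats, classify_columns, divergence
from .io import GenomeRecord

__all__ = [
    "SegmentParams",
    "MatchSeg",
    "DivSeg",
    "SegmentationResult",
    "ChunkAlignment",
    "first_pass",
    "extract_segments",
    "refine",
    "segment_genomes",
]

_DASH = ord("-")
_N = ord("N")


@dataclass(frozen=True)
class SegmentParams:
    chunk: int = 200_000
    max_internal_indel: int = 100
    fuse_below: int = 100
    window: int = 1000
    window_max_divergence: float = 0.05
    #: matchSEGs above this divergence are flagged for review
    flag_divergence: float = 0.01
    #: demote flagged matchSEGs to divSEGs instead of keeping them
    convert_flagged: bool = False
    align: AlignParams = field(default_factory=AlignParams)


@dataclass
class MatchSeg:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    alignment: PairwiseAlignment
    stats: ColumnStats

    @property
    def divergence(self) -> float:
        return divergence(self.stats)

    @property
    def a_length(self) -> int:
        return self.a_end - self.a_start

    @property
    def b_length(self) -> int:
        return self.b_end - self.b_start


@dataclass
class DivSeg:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    category: str | None = None
    tags: set = field(default_factory=set)

    @property
    def a_length(self) -> int:
        return self.a_end - self.a_start

    @property
    def b_length(self) -> int:
        return self.b_end - self.b_start


@dataclass
class SegmentationResult:
    segments: list
    a_length: int
    b_length: int
    a_id: str = "a"
    b_id: str = "b"

    def matchsegs(self) -> list[MatchSeg]:
        return [s for s in self.segments if isinstance(s, MatchSeg)]

    def divsegs(self) -> list[DivSeg]:
        return [s for s in self.segments if isinstance(s, DivSeg)]

    def validate(self) -> None:
        """Partition invariant: segments tile both genomes without overlap."""
        pa = pb = 0
        for s in self.segments:
            if s.a_start != pa or s.b_start != pb:
                raise ValueError(
                    f"segment does not abut previous one at a={pa}, b={pb}"
                )
            if s.a_end < s.a_start or s.b_end < s.b_start:
                raise ValueError("segment with negative extent")
            if isinstance(s, DivSeg) and s.a_length == 0 and s.b_length == 0:
                raise ValueError("empty divSEG")
            pa, pb = s.a_end, s.b_end
        if pa != self.a_length or pb != self.b_length:
            raise ValueError(
                f"segments cover a:[0,{pa}) b:[0,{pb}) of "
                f"a:{self.a_length} b:{self.b_length}"
            )

    def cumulative_stats(self) -> ColumnStats:
        total = ColumnStats()
        for s in self.matchsegs():
            total = total + s.stats
        return total

    def coverage(self) -> dict:
        ma = sum(s.a_length for s in self.matchsegs())
        mb = sum(s.b_length for s in self.matchsegs())
        return {
            "matchseg_count": len(self.matchsegs()),
            "divseg_count": len(self.divsegs()),
            "a_matchseg_bases": ma,
            "b_matchseg_bases": mb,
            "a_matchseg_fraction": ma / self.a_length,
            "b_matchseg_fraction": mb / self.b_length,
            "a_divseg_bases": self.a_length - ma,
            "b_divseg_bases": self.b_length - mb,
        }

    def flagged(self, threshold: float = 0.01) -> list[MatchSeg]:
        return [s for s in self.matchsegs() if s.divergence > threshold]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments:
            if isinstance(s, MatchSeg):
                rows.append({
                    "type": "matchSEG",
                    "a_start": s.a_start, "a_end": s.a_end,
                    "b_start": s.b_start, "b_end": s.b_end,
                    "m": s.stats.m, "mm": s.stats.mm,
                    "go": s.stats.go, "ge": s.stats.ge,
                    "divergence": round(s.divergence, 4),
                })
            else:
                rows.append({
                    "type": "divSEG",
                    "a_start": s.a_start, "a_end": s.a_end,
                    "b_start": s.b_start, "b_end": s.b_end,
                    "m": 0, "mm": 0, "go": 0, "ge": 0,
                    "divergence": float("nan"),
                })
        return pd.DataFrame(rows)


@dataclass
class ChunkAlignment:
    a_start: int
    b_start: int
    alignment: PairwiseAlignment
    #: column index where the next chunk takes over (None for the last chunk)
    restart_col: int | None = None


# ---------------------------------------------------------------------------
# pass 1


def _seq(g: GenomeRecord | str) -> str:
    return g.sequence if isinstance(g, GenomeRecord) else g


def _last_match_stretch_start(
    aln: PairwiseAlignment, min_len: int = 50
) -> tuple[int, int, int] | None:
    """(column, a_offset, b_offset) of the start of the last maximal run of
    identical aligned bases at least ``min_len`` long, or None.

    The length floor keeps the restart anchor out of the spurious 1-2 base
    matches a global aligner scatters through unrelated window tails.
    """
    a, b = aln.a_aligned, aln.b_aligned
    last_start = None
    run_start = None
    run_len = 0
    ai = bi = 0
    for col, (x, y) in enumerate(zip(a, b)):
        is_match = x == y and x != "-" and x != "N"
        if is_match:
            if run_len == 0:
                run_start = (col, ai, bi)
            run_len += 1
            if run_len >= min_len:
                last_start = run_start
        else:
            run_len = 0
        ai += x != "-"
        bi += y != "-"
    return last_start


def first_pass(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    chunk: int = 200_000,
    params: SegmentParams | None = None,
) -> list[ChunkAlignment]:
    """Chunked traversal of both genomes with the restart rule.

    Each chunk is aligned and the next chunk starts at the beginning of the
    last matching stretch of the current one; if that stretch starts at the
    chunk start (the chunk matched end to end) the next chunk starts at the
    chunk end instead, and the continuing segment is fused later.
    """
    params = params or SegmentParams()
    sa, sb = _seq(a), _seq(b)
    la, lb = len(sa), len(sb)
    chunks: list[ChunkAlignment] = []
    pa = pb = 0
    while True:
        wa = sa[pa : pa + chunk]
        wb = sb[pb : pb + chunk]
        aln = align_pair(wa, wb, params.align)
        ca = ChunkAlignment(pa, pb, aln)
        chunks.append(ca)
        if pa + len(wa) >= la and pb + len(wb) >= lb:
            break
        stretch = _last_match_stretch_start(aln)
        if stretch is None or (stretch[1] == 0 and stretch[2] == 0):
            ca.restart_col = len(aln)
            pa, pb = pa + len(wa), pb + len(wb)
        else:
            col, aoff, boff = stretch
            ca.restart_col = col
            pa, pb = pa + aoff, pb + boff
    return chunks


# ---------------------------------------------------------------------------
# pass 2


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def extract_segments(
    chunks: list[ChunkAlignment],
    params: SegmentParams | None = None,
) -> SegmentationResult:
    """Draft segmentation from the pass-1 chunk alignments."""
    params = params or SegmentParams()
    row_a = "".join(
        c.alignment.a_aligned[: c.restart_col] if c.restart_col is not None
        else c.alignment.a_aligned
        for c in chunks
    )
    row_b = "".join(
        c.alignment.b_aligned[: c.restart_col] if c.restart_col is not None
        else c.alignment.b_aligned
        for c in chunks
    )
    a_len = len(row_a) - row_a.count("-")
    b_len = len(row_b) - row_b.count("-")

    xa = np.frombuffer(row_a.encode(), dtype=np.uint8)
    xb = np.frombuffer(row_b.encode(), dtype=np.uint8)
    gap_a = xa == _DASH
    gap_b = xb == _DASH
    gap = gap_a | gap_b
    match = ~gap & (xa == xb) & (xa != _N)
    mismatch = ~gap & ~match

    # gap-open columns: first column of each maximal gap run in either row
    go = np.zeros(xa.size, dtype=bool)
    for g in (gap_a, gap_b):
        for s, _ in _runs_of(g):
            go[s] = True

    # columns belonging to an indel longer than the threshold
    long_gap = np.zeros(xa.size, dtype=bool)
    for s, e in _runs_of(gap):
        if e - s > params.max_internal_indel:
            long_gap[s:e] = True

    # columns inside any sliding window above the divergence ceiling
    countable = (match | mismatch | go).astype(np.int64)
    divpoint = (mismatch | go).astype(np.int64)
    bad = np.zeros(xa.size, dtype=bool)
    w = params.window
    if xa.size >= w:
        c_cum = np.concatenate([[0], np.cumsum(countable)])
        d_cum = np.concatenate([[0], np.cumsum(divpoint)])
        wins_c = c_cum[w:] - c_cum[:-w]
        wins_d = d_cum[w:] - d_cum[:-w]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(wins_c >= 100, wins_d / np.maximum(wins_c, 1), 0.0)
        bad_start = np.nonzero(frac > params.window_max_divergence)[0]
        for s in bad_start:
            bad[s : s + w] = True

    div_col = long_gap | bad
    matchsegs = []
    for s, e in _runs_of(~div_col):
        m_idx = np.nonzero(match[s:e])[0]
        if m_idx.size == 0:
            continue
        c0 = s + int(m_idx[0])
        c1 = s + int(m_idx[-1]) + 1
        matchsegs.append(_build_matchseg(row_a, row_b, gap_a, gap_b, c0, c1, params))
    return _assemble(matchsegs, a_len, b_len)


def _build_matchseg(
    row_a: str, row_b: str, gap_a: np.ndarray, gap_b: np.ndarray,
    c0: int, c1: int, params: SegmentParams,
) -> MatchSeg:
    a_start = int((~gap_a[:c0]).sum())
    b_start = int((~gap_b[:c0]).sum())
    a_end = a_start + int((~gap_a[c0:c1]).sum())
    b_end = b_start + int((~gap_b[c0:c1]).sum())
    sub = PairwiseAlignment(row_a[c0:c1], row_b[c0:c1], 0.0)
    return MatchSeg(a_start, a_end, b_start, b_end, sub, classify_columns(sub))


def _assemble(matchsegs: list[MatchSeg], a_len: int, b_len: int,
              a_id: str = "a", b_id: str = "b") -> SegmentationResult:
    """Alternate matchSEGs with the divSEGs that fill the gaps between them."""
    segments: list = []
    pa = pb = 0
    for m in matchsegs:
        if m.a_start > pa or m.b_start > pb:
            segments.append(DivSeg(pa, m.a_start, pb, m.b_start))
        segments.append(m)
        pa, pb = m.a_end, m.b_end
    if pa < a_len or pb < b_len:
        segments.append(DivSeg(pa, a_len, pb, b_len))
    res = SegmentationResult(segments, a_len, b_len, a_id, b_id)
    res.validate()
    return res


# ---------------------------------------------------------------------------
# pass 3


def _trim_to_match(aln: PairwiseAlignment) -> tuple[int, int, int, int, PairwiseAlignment] | None:
    """Trim an alignment to its first/last identical base pair.

    Returns (a_trim_left, a_trim_right, b_trim_left, b_trim_right, trimmed)
    or None when no column matches.
    """
    a, b = aln.a_aligned, aln.b_aligned
    first = last = None
    for i, (x, y) in enumerate(zip(a, b)):
        if x == y and x != "-" and x != "N":
            if first is None:
                first = i
            last = i
    if first is None:
        return None
    atl = first - a[:first].count("-")
    btl = first - b[:first].count("-")
    atr = (len(a) - last - 1) - a[last + 1 :].count("-")
    btr = (len(b) - last - 1) - b[last + 1 :].count("-")
    sub = PairwiseAlignment(a[first : last + 1], b[first : last + 1], 0.0)
    return atl, atr, btl, btr, sub


def _realign_matchseg(
    m: MatchSeg, sa: str, sb: str, params: SegmentParams
) -> list[MatchSeg]:
    """Re-align a matchSEG, split at internal indels over the threshold and
    trim every piece to identical-base boundaries."""
    aln = align_pair(sa[m.a_start : m.a_end], sb[m.b_start : m.b_end], params.align)
    xa = np.frombuffer(aln.a_aligned.encode(), dtype=np.uint8)
    xb = np.frombuffer(aln.b_aligned.encode(), dtype=np.uint8)
    gap = (xa == _DASH) | (xb == _DASH)
    cuts = [(s, e) for s, e in _runs_of(gap) if e - s > params.max_internal_indel]
    pieces: list[tuple[int, int]] = []
    prev = 0
    for s, e in cuts:
        if s > prev:
            pieces.append((prev, s))
        prev = e
    if prev < len(aln):
        pieces.append((prev, len(aln)))
    out: list[MatchSeg] = []
    for c0, c1 in pieces:
        sub = PairwiseAlignment(aln.a_aligned[c0:c1], aln.b_aligned[c0:c1], 0.0)
        trim = _trim_to_match(sub)
        if trim is None:
            continue
        atl, atr, btl, btr, trimmed = trim
        a0 = m.a_start + (c0 - aln.a_aligned[:c0].count("-")) + atl
        b0 = m.b_start + (c0 - aln.b_aligned[:c0].count("-")) + btl
        a1 = a0 + len(trimmed.a_aligned) - trimmed.a_aligned.count("-")
        b1 = b0 + len(trimmed.b_aligned) - trimmed.b_aligned.count("-")
        stats = classify_columns(trimmed)
        if stats.m == 0:
            continue
        out.append(MatchSeg(a0, a1, b0, b1, trimmed, stats))
    return out


def refine(
    draft: SegmentationResult,
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    params: SegmentParams | None = None,
) -> SegmentationResult:
    """Pass 3: re-align, split on >100 bp indels, fuse <100 bp separations."""
    params = params or SegmentParams()
    sa, sb = _seq(a), _seq(b)
    draft.validate()
    matchsegs = list(draft.matchsegs())

    for _ in range(10):
        # re-align and split
        split: list[MatchSeg] = []
        for m in matchsegs:
            split.extend(_realign_matchseg(m, sa, sb, params))
        # fuse neighbours separated by < fuse_below in both genomes
        fused: list[MatchSeg] = []
        changed = False
        for m in split:
            if fused:
                p = fused[-1]
                da = m.a_start - p.a_end
                db = m.b_start - p.b_end
                if 0 <= da < params.fuse_below and 0 <= db < params.fuse_below:
                    merged = MatchSeg(
                        p.a_start, m.a_end, p.b_start, m.b_end,
                        align_pair(sa[p.a_start : m.a_end],
                                   sb[p.b_start : m.b_end], params.align),
                        ColumnStats(),
                    )
                    merged.stats = classify_columns(merged.alignment)
                    fused[-1] = merged
                    changed = True
                    continue
            fused.append(m)
        stable = not changed and [
            (m.a_start, m.a_end, m.b_start, m.b_end) for m in fused
        ] == [(m.a_start, m.a_end, m.b_start, m.b_end) for m in matchsegs]
        matchsegs = fused
        if stable:
            break

    if params.convert_flagged:
        matchsegs = [
            m for m in matchsegs if m.divergence <= params.flag_divergence
        ]

    a_id = a.id if isinstance(a, GenomeRecord) else "a"
    b_id = b.id if isinstance(b, GenomeRecord) else "b"
    return _assemble(matchsegs, len(sa), len(sb), a_id, b_id)


def segment_genomes(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    params: SegmentParams | None = None,
) -> SegmentationResult:
    """Full 3-pass segmentation of a genome pair."""
    params = params or SegmentParams()
    chunks = first_pass(a, b, params.chunk, params)
    draft = extract_segments(chunks, params)
    return refine(draft, a, b, params)
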