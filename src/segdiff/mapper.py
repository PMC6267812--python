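"""Exact-match "run / connector" decomposition for near-identical genome pairs.

The two sequences are split into an alternating series of *runs* (shared
subsequences that are completely identical in both genomes) and *connectors*
(the divergent material between runs).  Runs are found as unique exact k-mer
matches chained colinearly (longest increasing chain, leftmost-in-a on ties),
maximally extended, and trimmed so that consecutive runs never overlap.
Connectors are then typed into difference categories: point mutations,
one-base indels, few-base differences, tandem-repeat copy-number variations,
inversions and long indels.

Interleaving the a-side (resp. b-side) pieces in order reconstructs each
input byte-exactly; this invariant is asserted after every decomposition.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from .io import GenomeRecord, revcomp

__all__ = ["Run", "Connector", "DiffRecord", "decompose", "type_differences"]

DIFF_CATEGORIES = (
    "point_mutation",
    "one_base_indel",
    "few_base_difference",
    "copy_number_variation",
    "inversion",
    "long_indel",
)

#: one side empty and longer than this -> long_indel
LONG_INDEL_MIN = 50
#: minimum aligned identity for calling a connector an inversion
INVERSION_MIN_IDENTITY = 0.90
#: a run shorter than this between two connectors may be absorbed when the
#: merged connector forms a single complex event (inversion)
MERGE_RUN_MAX = 100

TANDEM_UNIT_MIN = 7
TANDEM_UNIT_MAX = 16


@dataclass(frozen=True)
class Run:
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    def __post_init__(self) -> None:
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise ValueError("run sides must have equal length")
        if self.length <= 0:
            raise ValueError("run must be non-empty")


@dataclass(frozen=True)
class Connector:
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def a_length(self) -> int:
        return self.a_end - self.a_start

    @property
    def b_length(self) -> int:
        return self.b_end - self.b_start

    def __post_init__(self) -> None:
        if self.a_length < 0 or self.b_length < 0:
            raise ValueError("negative connector interval")
        if self.a_length == 0 and self.b_length == 0:
            raise ValueError("connector must be non-empty on at least one side")


@dataclass
class DiffRecord:
    category: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    detail: str = ""

    def __post_init__(self) -> None:
        if self.category not in DIFF_CATEGORIES:
            raise ValueError(f"unknown difference category {self.category!r}")

    def to_row(self) -> dict:
        return {
            "category": self.category,
            "a_start": self.a_start,
            "a_end": self.a_end,
            "b_start": self.b_start,
            "b_end": self.b_end,
            "detail": self.detail,
        }


def _seq(g: GenomeRecord | str) -> str:
    return g.sequence if isinstance(g, GenomeRecord) else g


# ---------------------------------------------------------------------------
# decomposition


def _unique_kmer_codes(s: str, k: int):
    """(codes, positions) of k-mers occurring exactly once in s.

    k-mers are encoded exactly as base-5 integers (A,C,G,T,N -> 0..4), so
    for k <= 27 the encoding is collision-free in uint64; k-mers containing
    N are excluded.
    """
    import numpy as np

    code = np.frombuffer(s.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint64)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    lut[ord("N")] = 4
    digits = lut[code]
    n = len(s) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    v = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        v = v * np.uint64(5) + digits[i : i + n]
    has_n = np.convolve((digits == 4).astype(np.int32), np.ones(k, dtype=np.int32),
                        mode="valid") > 0
    uniq, first, counts = np.unique(v, return_index=True, return_counts=True)
    keep = (counts == 1) & ~has_n[first]
    return uniq[keep], first[keep].astype(np.int64)


def _anchor_chain(sa: str, sb: str, k: int) -> list[list[int]]:
    """Colinear chain of unique exact matches as [a0, a1, b0, b1] blocks.

    Unique k-mer matches are collapsed along shared diagonals into maximal
    blocks and chained by weighted dynamic programming (maximum matched
    bases, leftmost-in-a on ties); strictly increasing in both genomes.
    """
    if k > 27:
        raise ValueError("min_run anchors support k <= 27")
    import numpy as np

    ca, pa = _unique_kmer_codes(sa, k)
    cb, pb = _unique_kmer_codes(sb, k)
    common, ia_idx, ib_idx = np.intersect1d(ca, cb, return_indices=True)
    if common.size == 0:
        return []
    ia = pa[ia_idx]
    jb = pb[ib_idx]
    order = np.argsort(ia, kind="stable")
    ia, jb = ia[order], jb[order]
    # collapse anchors adjacent on the same diagonal into blocks
    brk = np.nonzero((np.diff(ia) != 1) | (np.diff(jb) != 1))[0] + 1
    starts = np.concatenate([[0], brk])
    ends = np.concatenate([brk, [ia.size]])
    blocks = [
        [int(ia[s]), int(ia[e - 1]) + k, int(jb[s]), int(jb[e - 1]) + k]
        for s, e in zip(starts, ends)
    ]
    if len(blocks) == 1:
        return blocks
    # weighted colinear chaining: maximise matched bases
    if len(blocks) <= 3000:
        m = len(blocks)
        weight = [b[1] - b[0] for b in blocks]
        best = list(weight)
        prev = [-1] * m
        # adjacent blocks may overlap by up to ~k bases around an indel;
        # allow that in the chain (the overlap is trimmed afterwards)
        slack = k
        for i in range(m):
            a0, _, b0, _ = blocks[i]
            for j in range(i):
                if blocks[j][0] >= a0 or blocks[j][2] >= b0:
                    continue
                ov = max(blocks[j][1] - a0, blocks[j][3] - b0, 0)
                if ov > slack:
                    continue
                cand = best[j] + weight[i] - ov
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
        cur = max(range(m), key=lambda i: (best[i], -blocks[i][0]))
        chain = []
        while cur != -1:
            chain.append(blocks[cur])
            cur = prev[cur]
        chain.reverse()
        return chain
    # many blocks: unweighted LIS on block b-starts
    tails: list[int] = []
    tail_idx: list[int] = []
    prev2 = [-1] * len(blocks)
    for idx, blk in enumerate(blocks):
        pos = bisect_left(tails, blk[2])
        if pos == len(tails):
            tails.append(blk[2])
            tail_idx.append(idx)
        else:
            tails[pos] = blk[2]
            tail_idx[pos] = idx
        prev2[idx] = tail_idx[pos - 1] if pos > 0 else -1
    chain = []
    cur = tail_idx[-1]
    while cur != -1:
        chain.append(blocks[cur])
        cur = prev2[cur]
    chain.reverse()
    return chain


def decompose(
    a: GenomeRecord | str, b: GenomeRecord | str, min_run: int = 20
) -> list[Run | Connector]:
    """Split two near-identical sequences into alternating runs and connectors."""
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("both sequences must be non-empty")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if sa == sb:
        return [Run(0, len(sa), 0, len(sb))]

    k = min_run
    chain = _anchor_chain(sa, sb, k) if min(len(sa), len(sb)) >= k else []
    runs: list[list[int]] = [list(blk) for blk in chain]  # [a0, a1, b0, b1]

    # maximal extension of each run
    for r in runs:
        while r[0] > 0 and r[2] > 0 and sa[r[0] - 1] == sb[r[2] - 1]:
            r[0] -= 1
            r[2] -= 1
        while r[1] < len(sa) and r[3] < len(sb) and sa[r[1]] == sb[r[3]]:
            r[1] += 1
            r[3] += 1

    # resolve overlaps between consecutive runs (left-shift preference: the
    # earlier run keeps its full extension, the later run is trimmed)
    resolved: list[list[int]] = []
    for r in runs:
        if resolved:
            p = resolved[-1]
            ov = max(p[1] - r[0], p[3] - r[2], 0)
            if ov:
                r = [r[0] + ov, r[1], r[2] + ov, r[3]]
            if r[1] - r[0] <= 0:
                continue
            p = resolved[-1]
            if r[0] == p[1] and r[2] == p[3]:
                # adjacent on the same diagonal: merge
                p[1], p[3] = r[1], r[3]
                continue
        resolved.append(list(r))

    resolved = [r for r in resolved if r[1] - r[0] >= min_run]

    # assemble the alternating list, peeling shared prefixes/suffixes of
    # connectors into runs where they reach min_run (recovers identical
    # stretches whose k-mers were not genome-unique)
    pieces: list[Run | Connector] = []

    def add_connector(a0: int, a1: int, b0: int, b1: int) -> None:
        la, lb = a1 - a0, b1 - b0
        if la == 0 and lb == 0:
            return
        pre = 0
        lim = min(la, lb)
        while pre < lim and sa[a0 + pre] == sb[b0 + pre]:
            pre += 1
        suf = 0
        lim2 = min(la, lb) - pre
        while suf < lim2 and sa[a1 - 1 - suf] == sb[b1 - 1 - suf]:
            suf += 1
        if pre >= min_run:
            pieces.append(Run(a0, a0 + pre, b0, b0 + pre))
            a0 += pre
            b0 += pre
        if suf >= min_run:
            if a1 - suf > a0 or b1 - suf > b0:
                pieces.append(Connector(a0, a1 - suf, b0, b1 - suf))
            pieces.append(Run(a1 - suf, a1, b1 - suf, b1))
        else:
            pieces.append(Connector(a0, a1, b0, b1))

    pa = pb = 0
    for a0, a1, b0, b1 in resolved:
        if a0 > pa or b0 > pb:
            add_connector(pa, a0, pb, b0)
        pieces.append(Run(a0, a1, b0, b1))
        pa, pb = a1, b1
    if pa < len(sa) or pb < len(sb):
        add_connector(pa, len(sa), pb, len(sb))

    _check_reconstruction(pieces, sa, sb)
    return pieces


def _check_reconstruction(pieces: list[Run | Connector], sa: str, sb: str) -> None:
    ra = "".join(sa[p.a_start : p.a_end] for p in pieces)
    rb = "".join(sb[p.b_start : p.b_end] for p in pieces)
    if ra != sa or rb != sb:
        raise AssertionError("decomposition does not reconstruct the inputs")
    for p in pieces:
        if isinstance(p, Run) and sa[p.a_start : p.a_end] != sb[p.b_start : p.b_end]:
            raise AssertionError("run sides are not identical")
    for prev, cur in zip(pieces, pieces[1:]):
        if isinstance(prev, Run) == isinstance(cur, Run):
            raise AssertionError("pieces do not alternate between runs and connectors")


# ---------------------------------------------------------------------------
# difference typing


def _identity(x: str, y: str) -> float:
    """Aligned identity of two strings (edit-distance based)."""
    if not x or not y:
        return 0.0
    import edlib

    d = edlib.align(x, y, task="distance")["editDistance"]
    return 1.0 - d / max(len(x), len(y))


def _minimal_period(s: str) -> int:
    """Smallest p such that s is a prefix of (s[:p] * inf) — KMP failure fn."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1] if n else 0


def _count_adjacent_copies(seq: str, left: int, right: int, unit: str) -> int:
    """Copies of *unit* tiling [left, right) plus exact copies flanking it."""
    L = len(unit)
    n = (right - left) // L if (right - left) % L == 0 else 0
    inside_ok = all(
        seq[left + i * L : left + (i + 1) * L] == unit for i in range(n)
    )
    if not inside_ok:
        n = 0
    count = n
    p = left
    while p - L >= 0 and seq[p - L : p] == unit:
        count += 1
        p -= L
    p = right
    while p + L <= len(seq) and seq[p : p + L] == unit:
        count += 1
        p += L
    return count


def _try_tandem_cnv(
    conn: Connector, sa: str, sb: str
) -> tuple[str, int, int] | None:
    """Detect a tandem-repeat copy-number difference at this connector.

    Returns (unit, a_copies, b_copies) when the connector's extra material is
    a whole number of 7-16 bp unit copies and the unit tiles the locus on
    both genomes with differing copy counts.
    """
    ca, cb = conn.a_length, conn.b_length
    d = abs(ca - cb)
    if d < TANDEM_UNIT_MIN:
        return None
    longer = sa[conn.a_start : conn.a_end] if ca > cb else sb[conn.b_start : conn.b_end]
    for L in range(TANDEM_UNIT_MIN, TANDEM_UNIT_MAX + 1):
        if d % L != 0 or len(longer) < L:
            continue
        unit = longer[:L]
        if _minimal_period(unit) < TANDEM_UNIT_MIN:
            continue
        tiled = (unit * (len(longer) // L + 1))[: len(longer)]
        mism = sum(1 for x, y in zip(longer, tiled) if x != y)
        if mism > 0.10 * len(longer):
            continue
        a_copies = _count_adjacent_copies(sa, conn.a_start, conn.a_end, unit)
        b_copies = _count_adjacent_copies(sb, conn.b_start, conn.b_end, unit)
        if a_copies == b_copies or max(a_copies, b_copies) < 2:
            continue
        if abs(a_copies - b_copies) * L != d:
            continue
        return unit, a_copies, b_copies
    return None


def _classify_connector(conn: Connector, sa: str, sb: str) -> DiffRecord:
    ca, cb = conn.a_length, conn.b_length
    pa = sa[conn.a_start : conn.a_end]
    pb = sb[conn.b_start : conn.b_end]
    coords = (conn.a_start, conn.a_end, conn.b_start, conn.b_end)
    if ca == 1 and cb == 1:
        return DiffRecord("point_mutation", *coords, detail=f"{pa}>{pb}")
    if {ca, cb} == {0, 1}:
        base = pa or pb
        side = "a" if ca == 1 else "b"
        return DiffRecord("one_base_indel", *coords, detail=f"{side}:+{base}")
    cnv = _try_tandem_cnv(conn, sa, sb)
    if cnv is not None:
        unit, na, nb = cnv
        return DiffRecord(
            "copy_number_variation", *coords,
            detail=f"unit={unit};a_copies={na};b_copies={nb}",
        )
    if (
        min(ca, cb) >= TANDEM_UNIT_MIN
        and _identity(pa, revcomp(pb)) >= INVERSION_MIN_IDENTITY
    ):
        return DiffRecord("inversion", *coords, detail=f"len={max(ca, cb)}")
    if min(ca, cb) == 0 and max(ca, cb) > LONG_INDEL_MIN:
        side = "a" if ca else "b"
        return DiffRecord("long_indel", *coords, detail=f"{side}:+{max(ca, cb)}bp")
    return DiffRecord("few_base_difference", *coords, detail=f"{ca}<->{cb}")


def type_differences(
    decomposition: list[Run | Connector],
    a: GenomeRecord | str,
    b: GenomeRecord | str,
) -> list[DiffRecord]:
    """One typed DiffRecord per connector, merging connectors that form a
    single complex event (an inversion interrupted by a short chance run)."""
    sa, sb = _seq(a), _seq(b)
    for p in decomposition:
        if isinstance(p, Run) and sa[p.a_start : p.a_end] != sb[p.b_start : p.b_end]:
            raise ValueError("decomposition does not match the given sequences")

    connectors = [p for p in decomposition if isinstance(p, Connector)]
    records: list[DiffRecord] = []
    i = 0
    while i < len(connectors):
        conn = connectors[i]
        # try absorbing following connectors separated by short runs when the
        # merged region is one inversion
        j = i
        merged = conn
        while j + 1 < len(connectors):
            nxt = connectors[j + 1]
            gap_a = nxt.a_start - merged.a_end
            if gap_a <= 0 or gap_a > MERGE_RUN_MAX:
                break
            cand = Connector(merged.a_start, nxt.a_end, merged.b_start, nxt.b_end)
            xa = sa[cand.a_start : cand.a_end]
            xb = sb[cand.b_start : cand.b_end]
            if (
                min(len(xa), len(xb)) >= 2 * TANDEM_UNIT_MIN
                and _identity(xa, revcomp(xb)) >= INVERSION_MIN_IDENTITY
            ):
                merged = cand
                j += 1
            else:
                break
        records.append(_classify_connector(merged, sa, sb))
        i = j + 1
    return records
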