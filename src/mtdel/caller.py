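"""Breakpoint calling: split reads -> deletion candidates with heteroplasmy.

A split read's two blocks imply a junction: the reference gap between the
read-ordered blocks is the deleted interval, reported 1-based inclusive.
Supporting counts accumulate per unique (del_start, del_end, crosses_origin)
key; wild-type support is the mean coverage of the two junction flanks by
non-split reads, and heteroplasmy is f = s / (s + w).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .align import NON_SPLIT, SPLIT, ReadAlignment

DEFAULT_MIN_DEL_LEN = 20
#: wild-type reads must cover the junction with this many bases on each side;
#: matches the split-read min_anchor so f = s/(s+w) estimates heteroplasmy
#: without window-size bias.
DEFAULT_WT_ANCHOR = 20


@dataclass
class DeletionCandidate:
    """One candidate deletion junction in one cell-type pool.

    ``del_start``/``del_end`` delimit the deleted interval, 1-based
    inclusive; ``crosses_origin`` marks intervals wrapping the circular
    origin (then ``del_start > del_end``). ``s`` counts distinct
    breakpoint-supporting (split) reads, ``w`` wild-type reads spanning the
    junction flanks, ``f = s/(s+w)`` the heteroplasmy estimate. ``p``/``q``
    are filled by the error model; ``reason`` records why a candidate
    failed, if it did.
    """

    cell_type: str
    del_start: int
    del_end: int
    crosses_origin: bool
    s: int
    w: int = 0
    f: float = 1.0
    p: Optional[float] = None
    q: Optional[float] = None
    passed: bool = False
    reason: str = ""
    support_read_names: set = field(default_factory=set, repr=False, compare=False)

    @property
    def key(self) -> tuple[int, int, bool]:
        return (self.del_start, self.del_end, self.crosses_origin)

    def deletion_length(self, L: int) -> int:
        if self.crosses_origin:
            return (L - self.del_start + 1) + self.del_end
        return self.del_end - self.del_start + 1


def infer_junction(
    split: ReadAlignment, L: int, min_del_len: int = DEFAULT_MIN_DEL_LEN
) -> tuple[int, int, bool] | None:
    """Infer (del_start, del_end, crosses_origin) from a 2-block alignment.

    With read-ordered blocks [a1,b1) then [a2,b2) on the forward reference,
    the deleted interval is 1-based [b1+1, a2]; a gap below ``min_del_len``
    returns None (the read counts as non-split), and reference-overlapping
    block pairs (putative duplications) return None as well. On the circle
    the interval may wrap, in which case del_start > del_end and
    crosses_origin is set.
    """
    if len(split.blocks) != 2:
        raise ValueError(f"expected 2 blocks, got {len(split.blocks)}")
    b1, b2 = split.aligned_order_blocks()
    s1, e1 = b1.ref_interval_mod(L)
    s2, e2 = b2.ref_interval_mod(L)
    span1, span2 = e1 - s1, e2 - s2
    off = (s2 - s1) % L
    if off < span1 or off + span2 > L:
        return None  # overlapping on the reference: putative duplication
    gap = (s2 - (e1 % L)) % L
    if gap < min_del_len:
        return None
    j5 = e1 % L           # 0-based first deleted position
    del_start = j5 + 1    # 1-based
    del_end = s2          # 0-based s2 is first retained => 1-based s2 is last deleted
    if del_end == 0:
        del_end = L
    crosses = del_start > del_end
    return del_start, del_end, crosses


def accumulate_candidates(
    split_alignments: Iterable[ReadAlignment],
    L: int,
    min_del_len: int = DEFAULT_MIN_DEL_LEN,
    cell_type: str = "pool",
) -> tuple[list[DeletionCandidate], list[ReadAlignment]]:
    """Group split reads by junction; count distinct supporting reads.

    Returns (candidates sorted by coordinates, reclassified_non_split) where
    the second list holds split alignments whose gap fell below
    ``min_del_len`` (they count as wild-type evidence downstream).
    Duplication-like pairs are dropped (tallied via candidates' absence).
    """
    buckets: dict[tuple[int, int, bool], set[str]] = {}
    reclassified: list[ReadAlignment] = []
    for aln in split_alignments:
        if aln.classification != SPLIT:
            continue
        junc = infer_junction(aln, L, min_del_len)
        if junc is None:
            # small-gap pairs behave as wild-type molecules
            b1, b2 = aln.aligned_order_blocks()
            s1, e1 = b1.ref_interval_mod(L)
            s2, e2 = b2.ref_interval_mod(L)
            if 0 <= (s2 - (e1 % L)) % L < min_del_len:
                reclassified.append(
                    ReadAlignment(aln.read_name, list(aln.blocks), NON_SPLIT)
                )
            continue
        buckets.setdefault(junc, set()).add(aln.read_name)
    out = [
        DeletionCandidate(
            cell_type=cell_type,
            del_start=k[0],
            del_end=k[1],
            crosses_origin=k[2],
            s=len(names),
            support_read_names=set(names),
        )
        for k, names in buckets.items()
    ]
    out.sort(key=lambda c: c.key)
    return out, reclassified


class WildtypeCounter:
    """Vectorized junction-flank coverage counting over non-split blocks."""

    def __init__(self, non_split_alignments: Iterable[ReadAlignment], L: int):
        starts, ends = [], []
        for aln in non_split_alignments:
            for b in aln.blocks:
                s, e = b.ref_interval_mod(L)
                starts.append(s)
                ends.append(e)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.L = L

    def site_coverage(self, u: int, anchor: int) -> int:
        """Blocks covering the junction between 0-based positions u and u+1
        with >= anchor bases on each side."""
        L = self.L
        u %= L
        lo, hi = u - anchor + 1, u + anchor + 1
        cov = (self.starts <= lo) & (self.ends >= hi)
        cov |= (self.starts <= lo + L) & (self.ends >= hi + L)
        return int(np.count_nonzero(cov))

    def count(self, candidate: DeletionCandidate, anchor: int = DEFAULT_WT_ANCHOR) -> int:
        # 5' junction: boundary between del_start-1 and del_start (1-based)
        c5 = self.site_coverage(candidate.del_start - 2, anchor)
        # 3' junction: boundary between del_end and del_end+1 (1-based)
        c3 = self.site_coverage(candidate.del_end - 1, anchor)
        return int(np.floor((c5 + c3) / 2 + 0.5))  # round half up


def count_wildtype(
    candidate: DeletionCandidate,
    non_split_alignments: Iterable[ReadAlignment],
    anchor: int = DEFAULT_WT_ANCHOR,
    L: int | None = None,
) -> int:
    """Wild-type support of one candidate: mean flank coverage, rounded
    half up. Convenience wrapper over :class:`WildtypeCounter`."""
    if anchor < 1:
        raise ValueError("anchor must be >= 1")
    if L is None:
        raise ValueError("reference length L is required")
    return WildtypeCounter(non_split_alignments, L).count(candidate, anchor)


def estimate_heteroplasmy(s: int, w: int) -> float:
    """Heteroplasmy f = s / (s + w) of a junction."""
    if s < 1:
        raise ValueError("need at least one supporting read")
    if w < 0:
        raise ValueError("wild-type count must be non-negative")
    return s / (s + w)


def call_candidates(
    alignments: Iterable[ReadAlignment],
    L: int,
    min_del_len: int = DEFAULT_MIN_DEL_LEN,
    anchor: int = DEFAULT_WT_ANCHOR,
    cell_type: str = "pool",
) -> list[DeletionCandidate]:
    """Full caller stage: junctions, supporting counts, wild-type counts, f."""
    alignments = list(alignments)
    splits = [a for a in alignments if a.classification == SPLIT]
    non_splits = [a for a in alignments if a.classification == NON_SPLIT]
    candidates, reclassified = accumulate_candidates(
        splits, L, min_del_len, cell_type=cell_type
    )
    counter = WildtypeCounter(non_splits + reclassified, L)
    for c in candidates:
        c.w = counter.count(c, anchor)
        c.f = estimate_heteroplasmy(c.s, c.w)
    return candidates
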