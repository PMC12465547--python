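"""Split-read local alignment against a circular mitochondrial reference.

Two alignment routes feed the breakpoint caller:

* a built-in seed-and-extend aligner over the doubled reference (so blocks
  may span the origin), producing at most two ungapped, same-strand,
  read-collinear blocks per read — the self-contained analogue of a local
  aligner followed by split-read resolution;
* parsers for externally produced LAST TAB / MAF alignments.

Reads are classified as ``non_split`` (one block), ``split`` (two blocks
whose reference gap is at least ``min_del_len``), ``unaligned`` or
``ambiguous`` (>=3 external blocks, or conflicting duplicates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ReferenceGenome, FormatError

NON_SPLIT = "non_split"
SPLIT = "split"
UNALIGNED = "unaligned"
AMBIGUOUS = "ambiguous"

_RC = str.maketrans("ACGTN", "TGCAN")

DEFAULT_K = 20
DEFAULT_MIN_ANCHOR = 20
DEFAULT_MISMATCH_RATE = 0.05
DEFAULT_MIN_DEL_LEN = 20


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class AlignmentBlock:
    """One ungapped aligned block.

    ``ref_start``/``ref_end`` are 0-based half-open on the linearized
    reference with ``ref_start < L``; ``ref_end`` may exceed ``L`` for a
    block spanning the circular origin. ``read_start``/``read_end`` are
    0-based half-open in forward-read orientation (minus-strand coordinates
    are converted before blocks are ordered); junction inference walks the
    blocks in aligned orientation, i.e. reversed for ``-`` strand.
    """

    read_name: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str = "+"
    score: int = 0

    def ref_interval_mod(self, L: int) -> tuple[int, int]:
        """(start mod L, start mod L + length): normalized circular coords."""
        s = self.ref_start % L
        return s, s + (self.ref_end - self.ref_start)


@dataclass
class ReadAlignment:
    read_name: str
    blocks: list[AlignmentBlock] = field(default_factory=list)
    classification: str = UNALIGNED

    @property
    def strand(self) -> str:
        return self.blocks[0].strand if self.blocks else "+"

    def aligned_order_blocks(self) -> list[AlignmentBlock]:
        """Blocks in the order they appear along the forward reference
        strand (reversed read order for minus-strand alignments)."""
        if self.strand == "-":
            return list(reversed(self.blocks))
        return list(self.blocks)


@dataclass
class SeedIndex:
    """Exact k-mer index over the doubled reference sequence."""

    k: int
    L: int
    table: dict[str, list[int]]
    doubled: str      # ref+ref plus slack padding for slicing
    arr: np.ndarray   # uint8 view of ``doubled``

    @property
    def reference_length(self) -> int:
        return self.L


def build_seed_index(ref: ReferenceGenome, k: int = DEFAULT_K) -> SeedIndex:
    """Index all k-mers of the doubled reference (circularity); k in [8, 31].

    k-mers containing ``N`` are skipped. Both strands are handled at query
    time by reverse-complementing the read.
    """
    if not 8 <= k <= 31:
        raise ValueError(f"seed length k={k} out of range [8, 31]")
    L = ref.length
    if L < k:
        raise ValueError(f"reference length {L} < seed length {k}")
    doubled = ref.sequence * 2
    table: dict[str, list[int]] = {}
    for p in range(2 * L - k + 1):
        kmer = doubled[p : p + k]
        if "N" in kmer:
            continue
        table.setdefault(kmer, []).append(p)
    # slack so that slicing d:d+read_len never runs off the end
    padded = doubled + ref.sequence[: min(L, 512)]
    arr = np.frombuffer(padded.encode("ascii"), dtype=np.uint8)
    return SeedIndex(k=k, L=L, table=table, doubled=padded, arr=arr)


def _full_block(name: str, d: int, rl: int, strand: str, score: int, L: int) -> AlignmentBlock:
    return AlignmentBlock(
        read_name=name,
        ref_start=d % L,
        ref_end=d % L + rl,
        read_start=0,
        read_end=rl,
        strand=strand,
        score=score,
    )


def align_read(
    index: SeedIndex,
    seq: str,
    name: str = "read",
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    mismatch_rate: float = DEFAULT_MISMATCH_RATE,
    min_del_len: int = DEFAULT_MIN_DEL_LEN,
) -> ReadAlignment:
    """Align one read; return its (0-, 1- or 2-block) ReadAlignment.

    Fast path: a full-length exact occurrence (either strand) in the doubled
    reference is accepted outright as a single block. Otherwise seeds vote
    for diagonals; the best single diagonal is taken when it explains the
    read within the mismatch tolerance, and a two-diagonal split is sought
    when at least ``min_anchor`` read bases remain unexplained. Ties are
    broken by smallest ref_start, then ``+`` strand.
    """
    rl = len(seq)
    L = index.L
    if rl < index.k:
        return ReadAlignment(read_name=name, classification=UNALIGNED)
    max_mm = int(mismatch_rate * rl)

    # --- fast path: exact full-length match via first-k-mer lookup ----------
    doubled = index.doubled
    k = index.k
    hits = index.table.get(seq[:k])
    if hits:
        for p in hits:
            if doubled[p : p + rl] == seq:
                blk = _full_block(name, p, rl, "+", rl, L)
                return ReadAlignment(name, [blk], NON_SPLIT)
    rc = revcomp(seq)
    hits = index.table.get(rc[:k])
    if hits:
        for p in hits:
            if doubled[p : p + rl] == rc:
                blk = _full_block(name, p, rl, "-", rl, L)
                return ReadAlignment(name, [blk], NON_SPLIT)

    # --- probe stage: near-exact single diagonal ----------------------------
    probe = _probe_single_diagonal(index, seq, rc, name, max_mm)
    if probe is not None:
        return ReadAlignment(name, [probe], NON_SPLIT)

    # --- seeded path --------------------------------------------------------
    best = None  # (score, ref_start_key, strand_key, blocks)
    for strand, s in (("+", seq), ("-", rc)):
        cand = _seeded_align(index, s, name, strand, min_anchor, max_mm, rl)
        if cand is not None and (best is None or _better(cand, best)):
            best = cand
    if best is None:
        return ReadAlignment(read_name=name, classification=UNALIGNED)
    blocks = best[3]
    if len(blocks) == 2:
        gap = _ref_gap(blocks, L)
        if gap is None:
            # reference-overlapping pair: putative duplication, keep best block
            blocks = [max(blocks, key=lambda b: b.score)]
        elif gap < min_del_len:
            blocks = [max(blocks, key=lambda b: b.score)]
    cls = SPLIT if len(blocks) == 2 else NON_SPLIT
    if blocks and blocks[0].strand == "-":
        blocks = _to_forward_read_coords(blocks, rl)
    return ReadAlignment(read_name=name, blocks=blocks, classification=cls)


def _to_forward_read_coords(blocks: list[AlignmentBlock], rl: int) -> list[AlignmentBlock]:
    """Convert minus-strand blocks from RC-read to forward-read coordinates
    and order them by forward read_start."""
    out = [
        AlignmentBlock(
            read_name=b.read_name,
            ref_start=b.ref_start,
            ref_end=b.ref_end,
            read_start=rl - b.read_end,
            read_end=rl - b.read_start,
            strand=b.strand,
            score=b.score,
        )
        for b in blocks
    ]
    out.sort(key=lambda b: b.read_start)
    return out


def _probe_single_diagonal(index, seq, rc, name, max_mm):
    """Cheap detection of a full-length single-diagonal alignment with few
    mismatches: probe a handful of disjoint k-mers (a single substitution
    can spoil at most one) and verify candidate diagonals wholesale."""
    rl = len(seq)
    k = index.k
    L = index.L
    offsets = (0, (rl - k) // 3, 2 * (rl - k) // 3, rl - k)
    best = None  # (n_match, d, strand)
    for strand, s in (("+", seq), ("-", rc)):
        q = None
        tried = set()
        for o in offsets:
            hits = index.table.get(s[o : o + k])
            if not hits:
                continue
            for p in hits:
                d = (p - o) % L
                if d in tried:
                    continue
                tried.add(d)
                if q is None:
                    q = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
                n_match = int((index.arr[d : d + rl] == q).sum())
                if rl - n_match <= max_mm:
                    cand = (n_match, d, strand)
                    if (
                        best is None
                        or cand[0] > best[0]
                        or (cand[0] == best[0] and cand[1] < best[1])
                    ):
                        best = cand
        if best is not None and best[0] == rl:
            break
    if best is None:
        return None
    n_match, d, strand = best
    blk = _full_block(name, d, rl, strand, n_match, L)
    if strand == "-":
        blk = _to_forward_read_coords([blk], rl)[0]
    return blk


def _better(a, b) -> bool:
    """Higher score wins; then smaller ref_start; then '+' strand."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] < b[1]
    return a[2] < b[2]


def _ref_gap(blocks: list[AlignmentBlock], L: int) -> int | None:
    """Circular reference gap between two read-ordered blocks, or None if
    the pair overlaps on the reference (putative duplication, not a simple
    deletion). A "backwards" but disjoint pair is an origin-crossing
    deletion on the circle and yields its (large) arc length."""
    b1, b2 = blocks
    s1, e1 = b1.ref_interval_mod(L)
    s2, e2 = b2.ref_interval_mod(L)
    span1, span2 = e1 - s1, e2 - s2
    off = (s2 - s1) % L
    if off < span1 or off + span2 > L:
        return None
    return (s2 - (e1 % L)) % L


def _seeded_align(index, s, name, strand, min_anchor, max_mm, rl):
    k = index.k
    L = index.L
    table = index.table
    votes: dict[int, int] = {}
    for o in range(0, rl - k + 1):
        hits = table.get(s[o : o + k])
        if hits:
            for p in hits:
                d = (p - o) % L
                votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    # top diagonals by votes (then smallest d for determinism)
    diags = sorted(votes, key=lambda d: (-votes[d], d))[:4]
    arr = index.arr
    q = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    match = {d: (arr[d : d + rl] == q) for d in diags}
    n_match = {d: int(match[d].sum()) for d in diags}
    d1 = min(diags, key=lambda d: (-n_match[d], d))
    # single full-length block within mismatch tolerance?
    if rl - n_match[d1] <= max_mm:
        blk = _full_block(name, d1, rl, strand, n_match[d1], L)
        return (n_match[d1], blk.ref_start, strand == "-", [blk])
    # try a two-diagonal split whenever one diagonal cannot explain the
    # read within the mismatch tolerance (scattered accidental matches on
    # the wrong arm must not mask a junction); the per-arm match-fraction
    # requirement in _best_split rejects spurious pairings
    best_pair = None
    if len(diags) > 1:
        best_pair = _best_split(diags, match, rl, min_anchor, name, strand, L)
    if best_pair is not None and best_pair[0] > n_match[d1]:
        return best_pair
    # fall back: trimmed single block on the best diagonal
    blk = _trimmed_block(d1, match[d1], name, strand, L, min_anchor)
    if blk is None:
        return None
    return (blk.score, blk.ref_start, strand == "-", [blk])


def _best_split(diags, match, rl, min_anchor, name, strand, L):
    """Best (left-diagonal, right-diagonal, cut) split of the read."""
    pref = {d: np.concatenate(([0], np.cumsum(match[d]))) for d in diags}
    best = None
    for da in diags:
        pa = pref[da]
        for db in diags:
            if db == da:
                continue
            pb = pref[db]
            # total matches if read[0:c] on da and read[c:] on db
            totals = pa[min_anchor : rl - min_anchor + 1] + (
                pb[rl] - pb[min_anchor : rl - min_anchor + 1]
            )
            c_rel = int(np.argmax(totals))
            c = c_rel + min_anchor
            score = int(totals[c_rel])
            left_matches = int(pa[c])
            right_matches = int(pb[rl] - pb[c])
            # each arm must be mostly matching
            if left_matches < c - max(1, int(0.05 * c)):
                continue
            if right_matches < (rl - c) - max(1, int(0.05 * (rl - c))):
                continue
            b1 = AlignmentBlock(
                read_name=name, ref_start=da % L, ref_end=da % L + c,
                read_start=0, read_end=c, strand=strand, score=left_matches,
            )
            b2 = AlignmentBlock(
                read_name=name, ref_start=(db + c) % L,
                ref_end=(db + c) % L + (rl - c),
                read_start=c, read_end=rl, strand=strand, score=right_matches,
            )
            key = (score, b1.ref_start, strand == "-", [b1, b2])
            if best is None or _better(key, best):
                best = key
    return best


def _trimmed_block(d, m, name, strand, L, min_anchor):
    """Largest well-matched contiguous stretch on one diagonal."""
    idx = np.flatnonzero(m)
    if idx.size < min_anchor:
        return None
    i0, i1 = int(idx[0]), int(idx[-1]) + 1
    if i1 - i0 < min_anchor:
        return None
    score = int(m[i0:i1].sum())
    return AlignmentBlock(
        read_name=name,
        ref_start=(d + i0) % L,
        ref_end=(d + i0) % L + (i1 - i0),
        read_start=i0,
        read_end=i1,
        strand=strand,
        score=score,
    )


def align_reads(
    index: SeedIndex,
    reads,
    **kwargs,
) -> list[ReadAlignment]:
    """Align an iterable of (name, sequence) reads."""
    return [align_read(index, seq, name, **kwargs) for name, seq in reads]


def classify_reads(alignments) -> dict[str, int]:
    """Tally classifications; duplicate read names with conflicting blocks
    are demoted to ``ambiguous``. Tallies sum to the number of distinct reads."""
    by_name: dict[str, ReadAlignment] = {}
    ambiguous: set[str] = set()
    for a in alignments:
        prev = by_name.get(a.read_name)
        if prev is None:
            by_name[a.read_name] = a
        else:
            same = prev.classification == a.classification and [
                (b.ref_start, b.ref_end) for b in prev.blocks
            ] == [(b.ref_start, b.ref_end) for b in a.blocks]
            if not same:
                ambiguous.add(a.read_name)
    tallies = {NON_SPLIT: 0, SPLIT: 0, UNALIGNED: 0, AMBIGUOUS: 0}
    for name, a in by_name.items():
        cls = AMBIGUOUS if name in ambiguous else a.classification
        tallies[cls] += 1
    return tallies


# --- external alignment parsers ------------------------------------------------

_TAB_FIELDS = 12


def parse_last_tab(path: str | Path, ref_name: str | None = None) -> list[ReadAlignment]:
    """Parse LAST TAB lines (as produced by ``maf-convert tab``).

    Lines are grouped by read name: one line -> non_split, two -> split,
    three or more -> ambiguous (kept, counted, excluded from calling).
    Minus-strand read coordinates are converted to forward-read orientation
    before ordering blocks.
    """
    path = Path(path)
    groups: dict[str, list[AlignmentBlock]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _TAB_FIELDS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_TAB_FIELDS} fields, got {len(fields)}"
                )
            try:
                score = int(fields[0])
                r_name = fields[1]
                r_start = int(fields[2])
                r_size = int(fields[3])
                q_name = fields[6]
                q_start = int(fields[7])
                q_size = int(fields[8])
                q_strand = fields[9]
                q_len = int(fields[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if ref_name is not None and r_name != ref_name:
                raise FormatError(
                    f"{path}:{lineno}: reference {r_name!r} does not match {ref_name!r}"
                )
            if q_strand == "-":
                q_start = q_len - (q_start + q_size)
            blk = AlignmentBlock(
                read_name=q_name,
                ref_start=r_start,
                ref_end=r_start + r_size,
                read_start=q_start,
                read_end=q_start + q_size,
                strand=q_strand,
                score=score,
            )
            if q_name not in groups:
                groups[q_name] = []
                order.append(q_name)
            groups[q_name].append(blk)
    return _group_blocks(groups, order)


def parse_maf(path: str | Path) -> list[ReadAlignment]:
    """Parse MAF alignments (reference sequence first, read second)."""
    from Bio import AlignIO

    groups: dict[str, list[AlignmentBlock]] = {}
    order: list[str] = []
    for msa in AlignIO.parse(str(path), "maf"):
        if len(msa) < 2:
            continue
        ref_rec, read_rec = msa[0], msa[1]
        score = int(msa.annotations.get("score", 0))
        r_start = ref_rec.annotations["start"]
        r_size = ref_rec.annotations["size"]
        q_start = read_rec.annotations["start"]
        q_size = read_rec.annotations["size"]
        q_len = read_rec.annotations["srcSize"]
        strand = "+" if read_rec.annotations["strand"] == 1 else "-"
        if strand == "-":
            q_start = q_len - (q_start + q_size)
        blk = AlignmentBlock(
            read_name=read_rec.id,
            ref_start=r_start,
            ref_end=r_start + r_size,
            read_start=q_start,
            read_end=q_start + q_size,
            strand=strand,
            score=score,
        )
        if read_rec.id not in groups:
            groups[read_rec.id] = []
            order.append(read_rec.id)
        groups[read_rec.id].append(blk)
    return _group_blocks(groups, order)


def _group_blocks(groups: dict[str, list[AlignmentBlock]], order: list[str]) -> list[ReadAlignment]:
    out = []
    for name in order:
        blocks = sorted(groups[name], key=lambda b: b.read_start)
        if len(blocks) == 1:
            out.append(ReadAlignment(name, blocks, NON_SPLIT))
        elif len(blocks) == 2 and blocks[0].strand == blocks[1].strand:
            out.append(ReadAlignment(name, blocks, SPLIT))
        else:
            out.append(ReadAlignment(name, blocks, AMBIGUOUS))
    return out
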