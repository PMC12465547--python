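"""Synthetic scRNA-seq read generation on a circular mitochondrial genome.

Emulates the benchmark design the pipeline is evaluated on: deletion
genomes over a grid of deletion lengths, position-weighted single-end
reads with substitution errors, heteroplasmy mixing of deletion-derived
and wild-type reads, a structured junction-noise pool built from many
low-support deletions, and coverage downsampling. Transcript-level library
preparation (poly-A selection, fragmentation, priming biases) is not
modeled: the downstream caller consumes only positional coverage, which
optional per-interval weights can shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import ReferenceGenome

#: deletion-length grid of the benchmark (bp)
DEFAULT_DELETION_LENGTHS = (50, 120, 250, 500, 1000, 2000, 4000, 6000, 8000, 10000)
#: coverage tiers (total reads per evaluation dataset after downsampling)
DEFAULT_COVERAGE_TIERS = (5_000, 10_000, 50_000, 100_000, 500_000)

DEFAULT_READ_LENGTH = 100
DEFAULT_ERROR_RATE = 0.001
DEFAULT_REFERENCE_LENGTH = 16_300

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_x] = _y


@dataclass(frozen=True)
class TruthRecord:
    """A simulated deletion with its nominal heteroplasmy and role."""

    del_start: int          # 1-based inclusive
    del_end: int            # 1-based inclusive; < del_start when wrapping
    crosses_origin: bool
    target_heteroplasmy: float
    role: str               # "true_deletion" | "noise"


@dataclass
class SimConfig:
    """Benchmark simulation conditions (defaults are the study conditions)."""

    ref: ReferenceGenome
    deletion_lengths: Sequence[int] = DEFAULT_DELETION_LENGTHS
    per_length: int = 10
    read_length: int = DEFAULT_READ_LENGTH
    n_del_reads: int = 50_000
    n_wt_reads: int = 200_000
    n_noise_reads: int = 250_000
    n_true: int = 20
    coverage_tiers: Sequence[int] = DEFAULT_COVERAGE_TIERS
    error_rate: float = DEFAULT_ERROR_RATE
    #: "auto" draws a per-seed random transcript profile (the benchmark's
    #: study condition); None means uniform positional coverage; a dict of
    #: 0-based half-open intervals -> relative expression is used verbatim.
    gene_weights: object = "auto"
    #: fraction of mature-transcript-level coverage available to span a
    #: junction that fuses two distinct gene intervals. mtDNA transcription
    #: is polycistronic, so gene-fusing junctions are spanned only by
    #: readthrough/unprocessed molecules, far rarer than mature transcripts;
    #: intra-gene junctions are spanned at full transcript abundance.
    readthrough_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        L = self.ref.length
        if any(dl >= L for dl in self.deletion_lengths):
            raise ValueError("deletion length must be shorter than the genome")
        if self.read_length < 2:
            raise ValueError("read_length too small")
        if min(
            self.per_length, self.n_del_reads, self.n_wt_reads,
            self.n_noise_reads, self.n_true,
        ) < 0:
            raise ValueError("counts must be non-negative")


def synthetic_reference(
    length: int = DEFAULT_REFERENCE_LENGTH,
    seed: int = 16_300,
    name: str = "chrM_synthetic",
) -> ReferenceGenome:
    """Deterministic synthetic circular mtDNA-like reference.

    Base composition loosely follows mammalian mtDNA (G-poor heavy
    strand). The fixed default seed makes the bundled-equivalent reference
    reproducible everywhere without shipping a FASTA.
    """
    rng = np.random.default_rng(seed)
    probs = np.array([0.31, 0.25, 0.13, 0.31])
    seq = bytes(_BASES[rng.choice(4, size=length, p=probs)]).decode()
    return ReferenceGenome(name=name, sequence=seq)


def make_deletion_genome(ref: ReferenceGenome, del_start: int, del_end: int) -> str:
    """Excise the 1-based inclusive interval [del_start, del_end] (may wrap).

    For a wrapping interval (del_start > del_end) the retained sequence is
    the contiguous arc ref[del_end .. del_start-1]; the result's length is
    L minus the deletion length in both cases.
    """
    L = ref.length
    if not (1 <= del_start <= L and 1 <= del_end <= L):
        raise ValueError(f"interval [{del_start},{del_end}] outside 1..{L}")
    seq = ref.sequence
    if del_start <= del_end:
        dlen = del_end - del_start + 1
        if dlen >= L:
            raise ValueError("cannot delete the entire genome")
        return seq[: del_start - 1] + seq[del_end:]
    dlen = (L - del_start + 1) + del_end
    if dlen >= L:
        raise ValueError("cannot delete the entire genome")
    return seq[del_end : del_start - 1]


def junction_position(del_start: int, del_end: int, L: int) -> int:
    """0-based index, in deletion-genome coordinates, of the first base
    after the junction (the junction sits between index j-1 and j,
    circularly)."""
    if del_start > del_end:  # wrapping: retained arc starts right after it
        return 0
    return del_start - 1


def sample_deletions(
    ref: ReferenceGenome,
    lengths: Sequence[int] = DEFAULT_DELETION_LENGTHS,
    per_length: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[tuple[int, int]]:
    """Uniform unique (del_start, del_end) pairs, ``per_length`` per length."""
    if per_length < 1:
        raise ValueError("per_length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = ref.length
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for dlen in lengths:
        if not 0 < dlen < L:
            raise ValueError(f"cannot place deletion of length {dlen} on L={L}")
        placed = 0
        while placed < per_length:
            start = int(rng.integers(1, L + 1))
            end = start + dlen - 1
            if end > L:
                end -= L
            key = (start, end)
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
            placed += 1
    return out


class _GenomeSampler:
    """Vectorized circular read materialization for one genome."""

    def __init__(self, genome: str, read_length: int):
        self.G = len(genome)
        if read_length > self.G:
            raise ValueError("read_length exceeds genome length")
        self.rl = read_length
        ext = genome + genome[: read_length]
        self.arr = np.frombuffer(ext.encode("ascii"), dtype=np.uint8)
        self._offsets = np.arange(read_length)

    def materialize(
        self,
        starts: np.ndarray,
        reverse: np.ndarray,
        error_rate: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """(n, read_length) uint8 matrix of read sequences."""
        mat = self.arr[np.asarray(starts, dtype=np.int64)[:, None] + self._offsets]
        n = mat.shape[0]
        if n and error_rate > 0:
            n_err = rng.binomial(n * self.rl, error_rate)
            if n_err:
                flat = rng.choice(n * self.rl, size=n_err, replace=False)
                view = mat.reshape(-1)
                cur = _BASE_INDEX[view[flat]]
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                view[flat] = _BASES[(cur + shift) % 4]
        if n and reverse is not None:
            rev_idx = np.flatnonzero(reverse)
            if rev_idx.size:
                mat[rev_idx] = _COMPLEMENT[mat[rev_idx][:, ::-1]]
        return mat


@dataclass(frozen=True)
class TranscriptProfile:
    """Positional coverage profile with gene structure.

    ``weights`` maps 0-based half-open intervals to per-position read-start
    densities; ``genes`` lists the gene intervals (several weight tiles per
    gene), which determine whether a deletion junction is intra-gene or
    gene-fusing.
    """

    weights: dict[tuple[int, int], float]
    genes: list[tuple[int, int]]


def random_gene_weights(
    L: int,
    seed: int | np.random.Generator = 0,
    sigma: float = 1.0,
    background: float = 0.02,
) -> TranscriptProfile:
    """Random mtDNA-like transcript-expression profile over the circle.

    Mimics the mammalian mitochondrial transcript architecture: two long,
    heavily expressed rRNA-like units (~1 and ~1.6 kb) and thirteen
    CDS-like transcript units (the polycistronic precursor is processed
    into ~15 mature transcripts that tile essentially the whole molecule)
    with log-normal relative expression (``sigma`` on the log scale),
    shuffled around the circle each seed (the benchmark reassigns gene
    positions semirandomly so deletions hit varied contexts). A small
    uniform ``background`` share of reads emulates pervasive low-level
    transcription and keeps every position reachable. Values are
    per-position read-start densities.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # coverage-unevenness tiles are longer than a read so a junction and its
    # flanking wild-type sites share one tile's density (noise rates stay
    # proportional to local coverage)
    tile = 400
    lengths = np.concatenate(
        [
            [950.0, 1550.0],                       # rRNA-like
            rng.uniform(600.0, 1800.0, size=13),   # CDS-like
        ]
    )
    # expression share per transcript (before spreading over its length);
    # steady-state mito transcript levels are strongly bimodal: rRNAs
    # dominate, heavy-strand mRNAs form a middle tier, and light-strand /
    # rapidly-degraded transcripts sit far below
    expr = np.concatenate(
        [
            rng.lognormal(2.0, 0.5, size=2),            # rRNA: dominant
            rng.lognormal(0.0, sigma, size=9),          # heavy-strand CDS
            0.04 * rng.lognormal(0.0, 0.5, size=4),     # light-strand-like
        ]
    )
    order = rng.permutation(len(lengths))
    lengths, expr = lengths[order], expr[order]
    lengths = np.maximum(1, np.round(lengths * L / lengths.sum()).astype(int))
    expr = expr / expr.sum()
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    weights: dict[tuple[int, int], float] = {}
    genes: list[tuple[int, int]] = []
    for i in range(len(lengths)):
        a, b = int(bounds[i]), min(int(bounds[i + 1]), L)
        if b <= a:
            continue
        genes.append((a, b))
        # per-position density: the gene's expression share spread over its
        # length, modulated tile-by-tile (library-prep positional bias makes
        # within-gene coverage uneven over ~fragment-length scales), plus
        # genome-wide background
        base = (1 - background) * expr[i] / (b - a)
        for t0 in range(a, b, tile):
            t1 = min(t0 + tile, b)
            bump = rng.gamma(3.0, 1.0 / 3.0)
            weights[(t0, t1)] = base * bump + background / L
    return TranscriptProfile(weights=weights, genes=genes)


def _position_weights(G: int, gene_weights) -> Optional[np.ndarray]:
    if gene_weights is None:
        return None
    if isinstance(gene_weights, TranscriptProfile):
        gene_weights = gene_weights.weights
    w = np.zeros(G, dtype=float)
    for (a, b), weight in gene_weights.items():
        if weight < 0:
            raise ValueError("weights must be non-negative")
        a %= G
        b = b if b > a else b + G
        for pos in range(a, min(b, a + G)):
            w[pos % G] += weight
    total = w.sum()
    if total <= 0:
        raise ValueError("gene weights sum to zero")
    return w / total


def sample_starts(
    G: int,
    n: int,
    rng: np.random.Generator,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    if weights is None:
        return rng.integers(0, G, size=n)
    return rng.choice(G, size=n, p=weights)


def mat_to_reads(mat: np.ndarray, prefix: str, start_id: int = 0) -> list[tuple[str, str]]:
    return [
        (f"{prefix}:{start_id + i}", bytes(row).decode("ascii"))
        for i, row in enumerate(mat)
    ]


def simulate_reads(
    genome: str,
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    gene_weights: Optional[dict] = None,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | np.random.Generator = 0,
    prefix: str = "sim",
) -> list[tuple[str, str]]:
    """Single-end reads from a circular genome.

    Start positions are uniform (or weighted by ``gene_weights``, a map of
    0-based half-open intervals to relative expression), strands 50/50,
    substitution errors Bernoulli per base at ``error_rate``. Deterministic
    under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = _GenomeSampler(genome, read_length)
    weights = _position_weights(sampler.G, gene_weights)
    starts = sample_starts(sampler.G, n_reads, rng, weights)
    reverse = rng.random(n_reads) < 0.5
    mat = sampler.materialize(starts, reverse, error_rate, rng)
    return mat_to_reads(mat, prefix)


def gene_id_array(L: int, gene_intervals) -> np.ndarray:
    """Map each reference position to the index of its gene interval."""
    gid = np.zeros(L, dtype=np.int32)
    for idx, (a, b) in enumerate(gene_intervals):
        a %= L
        b = b if b > a else b + L
        span = np.arange(a, min(b, a + L)) % L
        gid[span] = idx
    return gid


def genome_weights_for_deletion(
    ref_w: Optional[np.ndarray],
    gene_id: Optional[np.ndarray],
    del_start: int,
    del_end: int,
    L: int,
    read_length: int,
    readthrough_fraction: float = 0.1,
    floor: float = 0.0,
) -> Optional[np.ndarray]:
    """Positional read-start weights on a deletion genome.

    The transcript (above-``floor``) component of the profile is excised
    and renormalized — a simulated library yields its fixed read number
    from whatever transcripts remain. The uniform background component
    keeps its global per-position rate (pervasive background transcription
    does not concentrate when genes are lost). When the junction fuses two
    distinct gene intervals, transcript-derived read starts whose read
    would span the junction are scaled by ``readthrough_fraction``:
    mature transcripts do not cross gene boundaries, so fusing junctions
    are spanned only by readthrough/unprocessed molecules. Intra-gene
    junctions keep full transcript density. Returns normalized weights, or
    None for uniform sampling.
    """
    if ref_w is None:
        return None
    if del_start <= del_end:
        w = np.concatenate([ref_w[: del_start - 1], ref_w[del_end :]])
    else:
        w = ref_w[del_end : del_start - 1].copy()
    G = len(w)
    if G == 0:
        return None
    gene_part = np.maximum(w - floor, 0.0)
    if gene_id is not None and read_length > 1:
        left = (del_start - 2) % L
        right = del_end % L
        if gene_id[left] != gene_id[right]:
            j = junction_position(del_start, del_end, L)
            win = np.arange(j - read_length + 1, j) % G
            gene_part[win] = readthrough_fraction * gene_part[win]
    # background keeps its per-position rate: its share of this genome's
    # reads scales with the genome's length, so losing transcripts never
    # concentrates background coverage
    bg_share = min(1.0, floor * G)
    total = gene_part.sum()
    if total > 0:
        out = (1.0 - bg_share) * gene_part / total + bg_share / G
    else:
        out = np.full(G, 1.0 / G)
    return out


def junction_covering_starts(
    starts: np.ndarray, j: int, G: int, read_length: int, anchor: int
) -> np.ndarray:
    """Mask of read starts whose read spans the junction at ``j`` with at
    least ``anchor`` bases on each side (circular)."""
    starts = np.asarray(starts)
    lo = (j + anchor - read_length) % G
    width = read_length - 2 * anchor + 1
    if width <= 0:
        return np.zeros(starts.shape, dtype=bool)
    rel = (starts - lo) % G
    return rel < width


def mix_heteroplasmy(
    del_reads: Sequence[tuple[str, str]],
    wt_reads: Sequence[tuple[str, str]],
    noise_reads: Sequence[tuple[str, str]] = (),
    seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[str, str]], float]:
    """Concatenate and shuffle read pools; returns (reads, heteroplasmy)
    where heteroplasmy is the deletion-read fraction of non-noise reads."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    combined = list(del_reads) + list(wt_reads) + list(noise_reads)
    order = rng.permutation(len(combined))
    n_signal = len(del_reads) + len(wt_reads)
    h = len(del_reads) / n_signal if n_signal else 0.0
    return [combined[i] for i in order], h


def downsample_reads(
    reads: Sequence[tuple[str, str]],
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """Uniform sample of ``n`` reads without replacement."""
    if n > len(reads):
        raise ValueError(f"cannot downsample {len(reads)} reads to {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]
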