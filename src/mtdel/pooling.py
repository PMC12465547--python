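"""Cell-type pooling: split a barcoded BAM into per-cell-type read pools.

Droplet scRNA-seq BAMs carry a cell-barcode tag (``CB`` by CellRanger
convention). Primary alignments whose barcode is annotated are routed to
their cell type's pool; per-type pools can be capped at a maximum number
of cells (uniform subsampling) and exported as FASTQ in original read
orientation. UMI deduplication is deliberately not performed; counts are
read-level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pysam

from .align import revcomp
from .io import CellAnnotation

logger = logging.getLogger(__name__)

DEFAULT_BARCODE_TAG = "CB"
DEFAULT_MAX_CELLS = 50

#: which records to export from the BAM
POLICY_MITO_AND_UNMAPPED = "mito_and_unmapped"
POLICY_ALL_READS = "all_reads"

MITO_CONTIG_ALIASES = ("chrM", "MT", "chrMT", "M")


@dataclass
class PooledRead:
    name: str
    sequence: str
    quality: str
    barcode: str


@dataclass
class CellPool:
    cell_type: str
    barcodes: set[str] = field(default_factory=set)
    reads: list[PooledRead] = field(default_factory=list)
    source_sample: str = ""

    @property
    def read_count(self) -> int:
        return len(self.reads)


def subsample_barcodes(
    annotation: CellAnnotation,
    max_per_type: int = DEFAULT_MAX_CELLS,
    seed: int = 0,
) -> CellAnnotation:
    """Retain at most ``max_per_type`` barcodes per label, drawn uniformly
    without replacement; deterministic under the seed."""
    if max_per_type < 1:
        raise ValueError("max_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    kept: dict[str, str] = {}
    for label in annotation.labels:
        bcs = annotation.barcodes_for(label)
        if len(bcs) > max_per_type:
            idx = rng.choice(len(bcs), size=max_per_type, replace=False)
            chosen = {bcs[i] for i in idx}
        else:
            chosen = set(bcs)
        for bc in annotation.entries:  # preserve input order
            if annotation.entries[bc] == label and bc in chosen:
                kept[bc] = label
    return CellAnnotation(entries=kept)


def split_bam_by_cell_type(
    bam_path: str | Path,
    annotation: CellAnnotation,
    barcode_tag: str = DEFAULT_BARCODE_TAG,
    read_policy: str = POLICY_MITO_AND_UNMAPPED,
    mito_contig: Optional[str] = None,
) -> tuple[dict[str, CellPool], dict[str, int]]:
    """Assign each primary alignment to its cell type's pool by barcode.

    Secondary/supplementary records are skipped; reads lacking the tag or
    with unannotated barcodes are counted and dropped. Under the default
    policy only records mapped to the mitochondrial contig (any common
    alias, or ``mito_contig``) or unmapped are exported. Returns
    (pools by label, tallies).
    """
    if not len(annotation):
        raise ValueError("empty cell annotation")
    aliases = {mito_contig} if mito_contig else set(MITO_CONTIG_ALIASES)
    pools = {label: CellPool(cell_type=label) for label in annotation.labels}
    tallies = {
        "primary_records": 0,
        "pooled": 0,
        "no_tag": 0,
        "unannotated_barcode": 0,
        "filtered_by_policy": 0,
    }
    tagged_seen = False
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for rec in bam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if read_policy == POLICY_MITO_AND_UNMAPPED:
                if not rec.is_unmapped and rec.reference_name not in aliases:
                    tallies["filtered_by_policy"] += 1
                    continue
            tallies["primary_records"] += 1
            try:
                bc = rec.get_tag(barcode_tag)
            except KeyError:
                tallies["no_tag"] += 1
                continue
            tagged_seen = True
            label = annotation.entries.get(bc)
            if label is None:
                tallies["unannotated_barcode"] += 1
                continue
            seq = rec.query_sequence or ""
            if rec.query_qualities is not None:
                qual = "".join(chr(q + 33) for q in rec.query_qualities)
            else:
                qual = "I" * len(seq)
            if rec.is_reverse:  # restore original read orientation
                seq = revcomp(seq)
                qual = qual[::-1]
            pools[label].reads.append(
                PooledRead(name=rec.query_name, sequence=seq, quality=qual, barcode=bc)
            )
            pools[label].barcodes.add(bc)
            tallies["pooled"] += 1
    if not tagged_seen and tallies["primary_records"] > 0:
        raise ValueError(
            f"barcode tag {barcode_tag!r} absent on every record; wrong tag name?"
        )
    for key in ("no_tag", "unannotated_barcode"):
        if tallies[key]:
            logger.info("dropped %d reads (%s)", tallies[key], key)
    return pools, tallies


def pool_to_fastq(pool: CellPool, out_path: str | Path) -> int:
    """Write one FASTQ record per pooled read; duplicate names are suffixed
    to stay unique. An empty pool yields an empty file with a warning."""
    if pool.read_count == 0:
        logger.warning("pool %s is empty; writing empty FASTQ", pool.cell_type)
    seen: dict[str, int] = {}
    n = 0
    with open(out_path, "w", newline="\n") as fh:
        for read in pool.reads:
            name = read.name
            if name in seen:
                seen[name] += 1
                name = f"{name}.{seen[read.name]}"
            else:
                seen[name] = 0
            fh.write(f"@{name}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n
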