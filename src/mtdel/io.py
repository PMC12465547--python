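"""Readers and writers for the formats the pipeline touches.

FASTA references, TSV cell annotations and the deletion call table. All
emitted coordinates are 1-based inclusive for the deleted interval; internal
block coordinates elsewhere in the package are 0-based half-open.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

#: reserved words that mark the second column of an annotation header row
_HEADER_WORDS = {"cell_type", "celltype", "label"}

#: fixed column order of the call table
CALL_TABLE_COLUMNS = [
    "cell_type",
    "del_start",
    "del_end",
    "crosses_origin",
    "support_reads",
    "wildtype_reads",
    "heteroplasmy",
    "p_value",
    "q_value",
    "pass",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ReferenceGenome:
    """A (circular) reference contig, e.g. the mitochondrial genome."""

    name: str
    sequence: str
    is_circular: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"reference {self.name!r} has empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"reference {self.name!r} contains non-nucleotide "
                f"characters: {sorted(bad)}"
            )


@dataclass
class CellAnnotation:
    """Ordered barcode -> cell-type label map from a TSV annotation."""

    entries: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        """Distinct labels in first-seen order."""
        seen: dict[str, None] = {}
        for lab in self.entries.values():
            seen.setdefault(lab)
        return list(seen)

    def barcodes_for(self, label: str) -> list[str]:
        return [bc for bc, lab in self.entries.items() if lab == label]

    def counts_per_label(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.entries.values():
            out[lab] = out.get(lab, 0) + 1
        return out


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read the first record of a FASTA file as the reference genome.

    The sequence is uppercased; ``N`` is allowed. Non-nucleotide characters
    raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - VALID_BASES
    if bad:
        lineno = _find_bad_line(path, bad)
        raise FormatError(
            f"{path}:{lineno}: non-nucleotide characters {sorted(bad)} "
            f"in record {rec.id!r}"
        )
    if not seq:
        raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
    return ReferenceGenome(name=rec.id, sequence=seq)


def _find_bad_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if bad & set(line.rstrip("\n").upper()):
                return i
    return 0


def read_cell_annotation(path: str | Path) -> CellAnnotation:
    """Read a two-column barcode/cell-type TSV.

    A header row is auto-detected: if the first row's second field is one of
    ``cell_type``/``celltype``/``label`` it is treated as a header. Duplicate
    barcodes, empty labels and rows with fewer than two columns are errors.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty annotation file")
    first_fields = lines[0].split("\t")
    start = 0
    if len(first_fields) >= 2 and first_fields[1].strip().lower() in _HEADER_WORDS:
        start = 1
    if start == 1 and len(lines) == 1:
        raise FormatError(f"{path}: annotation contains only a header row")
    for lineno, line in enumerate(lines[start:], start + 1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated columns")
        bc, label = fields[0].strip(), fields[1].strip()
        if not bc:
            raise FormatError(f"{path}:{lineno}: empty barcode")
        if not label:
            raise FormatError(f"{path}:{lineno}: empty cell-type label")
        if bc in entries:
            raise FormatError(f"{path}:{lineno}: duplicate barcode {bc!r}")
        entries[bc] = label
    return CellAnnotation(entries=entries)


def write_cell_annotation(annotation: CellAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for bc, label in annotation.entries.items():
            fh.write(f"{bc}\t{label}\n")


def calls_to_frame(calls: Iterable) -> pd.DataFrame:
    """Render DeletionCandidate-like records as the call-table DataFrame."""
    rows = []
    for c in calls:
        rows.append(
            {
                "cell_type": c.cell_type,
                "del_start": c.del_start,
                "del_end": c.del_end,
                "crosses_origin": c.crosses_origin,
                "support_reads": c.s,
                "wildtype_reads": c.w,
                "heteroplasmy": c.f,
                "p_value": c.p,
                "q_value": c.q,
                "pass": c.passed,
            }
        )
    df = pd.DataFrame(rows, columns=CALL_TABLE_COLUMNS)
    return df.sort_values(
        ["cell_type", "del_start", "del_end"], kind="stable"
    ).reset_index(drop=True)


def write_call_table(calls: Iterable, path: str | Path) -> None:
    """Write calls as TSV with a fixed header and deterministic row order.

    Heteroplasmy is formatted with six decimal places; p/q values with six
    significant digits (p-values span many orders of magnitude). Missing
    p/q (pre-filtering tables) are emitted as ``NA``.
    """
    df = calls_to_frame(calls)
    buf = _io.StringIO()
    buf.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
    for ct, ds, de, co, s, w, f, p, q, ok in df.itertuples(index=False, name=None):
        p_str = "NA" if p is None or pd.isna(p) else f"{p:.6g}"
        q_str = "NA" if q is None or pd.isna(q) else f"{q:.6g}"
        buf.write(
            f"{ct}\t{ds}\t{de}\t{str(bool(co)).lower()}\t{s}\t{w}\t"
            f"{f:.6f}\t{p_str}\t{q_str}\t{str(bool(ok)).lower()}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_call_table(path: str | Path) -> pd.DataFrame:
    """Read a call table written by :func:`write_call_table`."""
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        dtype={"cell_type": str},
    )
    missing = set(CALL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: call table missing columns {sorted(missing)}")
    for col in ("crosses_origin", "pass"):
        if df[col].dtype == object:
            df[col] = df[col].map({"true": True, "false": False})
        df[col] = df[col].astype(bool)
    return df


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> int:
    """Write (name, sequence) reads as 4-line FASTQ records with constant quality."""
    n = 0
    with open(path, "w", newline="\n") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into (name, sequence) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper()))
    return out
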