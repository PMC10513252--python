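"""Sequence and annotation I/O: FASTA reading, window slicing, one-hot
encoding, and the tab/GFF text formats used for predictions and ground truth.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``.  All text
formats emitted or ingested (the prediction table, GFF3) are 1-based
inclusive, following the GFF convention.  Conversion happens only at the
I/O boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .labels import DomainAnnotation


class FastaError(ValueError):
    """Base class for FASTA parsing problems."""


class EmptyFastaError(FastaError):
    """The file contains no sequence records."""


class MalformedFastaError(FastaError):
    """The first non-blank line does not start with '>'."""


class GffFormatError(ValueError):
    """A GFF row is structurally invalid."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence (upper-cased on read)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class Window:
    """A slice of a source sequence, 0-based offset into the source."""

    source_id: str
    offset: int
    sequence: str

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("window offset must be >= 0")

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Sequences are upper-cased; soft-masked lower-case bases are treated as
    ordinary bases.  Record order is preserved.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    MalformedFastaError
        If the first non-blank line is not a '>' header.
    EmptyFastaError
        If the file contains no records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    text = path.read_text()
    for line in text.splitlines():
        if line.strip():
            if not line.startswith(">"):
                raise MalformedFastaError(
                    f"first non-blank line of {path} is not a FASTA header"
                )
            break
    else:
        raise EmptyFastaError(f"no FASTA records in {path}")
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def slice_windows(
    record: SequenceRecord, window_len: int, stride: int | None = None
) -> list[Window]:
    """Cut a sequence into windows of ``window_len`` bp.

    Default stride equals ``window_len`` (non-overlapping partition); a
    smaller stride yields overlapping windows, useful to avoid domains being
    split at window boundaries (duplicates are later removed by NMS in
    absolute coordinates).  The final partial window is retained.
    """
    if stride is None:
        stride = window_len
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    if stride <= 0 or stride > window_len:
        raise ValueError("stride must satisfy 0 < stride <= window_len")
    windows = []
    pos = 0
    n = record.length
    while pos < n:
        windows.append(
            Window(source_id=record.id, offset=pos, sequence=record.sequence[pos : pos + window_len])
        )
        pos += stride
    return windows


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


# byte-value lookup: A,C,G,T -> row 0..3, everything else -> 4 (dropped)
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i


def one_hot_encode(window: Window | str, pad_to: int | None = None) -> np.ndarray:
    """One-hot encode DNA as a ``4 x pad_to`` {0,1} matrix, rows A, C, G, T.

    Any symbol outside ACGT (N, other IUPAC codes) and any padding column
    beyond the window length maps to an all-zero column.
    """
    seq = window if isinstance(window, str) else window.sequence
    n = len(seq)
    if pad_to is None:
        pad_to = n
    if pad_to < n:
        raise ValueError(f"pad_to={pad_to} is smaller than window length {n}")
    idx = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    mat = np.zeros((4, pad_to), dtype=np.float32)
    cols = np.nonzero(idx < 4)[0]
    mat[idx[cols], cols] = 1.0
    return mat


_TABLE_COLUMNS = ("seq_id", "start", "end", "domain_type", "lineage", "presence_prob")


def write_predictions_table(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    """Write domain calls as a tab-delimited table.

    Columns: sequence id, start (1-based inclusive), end (inclusive), domain
    type, lineage, presence probability.  Rows sorted by (sequence id, start).
    Domains must carry absolute coordinates.
    """
    rows = sorted(domains, key=lambda d: (d.source_id, d.start))
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for d in rows:
            fh.write(
                f"{d.source_id}\t{d.start + 1}\t{d.start + d.length}\t"
                f"{d.domain_type}\t{d.lineage}\t{d.presence_prob:.6g}\n"
            )


def read_predictions_table(path: str | Path) -> list[DomainAnnotation]:
    """Read the tab-delimited prediction table back (inverse of write)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TABLE_COLUMNS:
            raise ValueError(f"unexpected prediction-table header in {path}")
        for line in fh:
            if not line.strip():
                continue
            sid, start, end, dtype, lineage, prob = line.rstrip("\n").split("\t")
            start_i = int(start) - 1
            out.append(
                DomainAnnotation(
                    source_id=sid,
                    start=start_i,
                    length=int(end) - start_i,
                    domain_type=dtype,
                    lineage=lineage,
                    presence_prob=float(prob),
                )
            )
    return out


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_annotation_gff(path: str | Path) -> list[DomainAnnotation]:
    """Read domain annotations from a GFF3-like 9-column file.

    1-based inclusive GFF coordinates are converted to internal 0-based
    half-open.  The feature type column is used as the domain type; lineage
    and presence probability are taken from ``lineage=`` / ``score`` when
    present (lineage defaults to the first known lineage, probability to 1).
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise GffFormatError(f"{path}:{ln}: expected 9 columns, got {len(cols)}")
            try:
                start1 = int(cols[3])
                end1 = int(cols[4])
            except ValueError as exc:
                raise GffFormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if end1 < start1:
                raise GffFormatError(f"{path}:{ln}: end < start")
            attrs = _parse_gff_attributes(cols[8])
            try:
                prob = float(cols[5])
            except ValueError:
                prob = 1.0
            out.append(
                DomainAnnotation(
                    source_id=cols[0],
                    start=start1 - 1,
                    length=end1 - start1 + 1,
                    domain_type=attrs.get("domain_type", cols[2]),
                    lineage=attrs.get("lineage", "ALE-RETROFIT"),
                    presence_prob=prob,
                )
            )
    return out


def write_annotation_gff(
    domains: Sequence[DomainAnnotation], path: str | Path, source: str = "retrodetect"
) -> None:
    """Write domain annotations as GFF3 (1-based inclusive)."""
    rows = sorted(domains, key=lambda d: (d.source_id, d.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for d in rows:
            fh.write(
                f"{d.source_id}\t{source}\t{d.domain_type}\t{d.start + 1}\t"
                f"{d.start + d.length}\t{d.presence_prob:.6g}\t+\t.\t"
                f"domain_type={d.domain_type};lineage={d.lineage}\n"
            )
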