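"""Readers and writers for FASTA, BED and binned contact-matrix files.

Every coordinate in this package is 0-based half-open (BED convention):
an interval ``[start, end)`` covers ``end - start`` bases.  Sequences are
case-folded to upper case on read and restricted to the {A,C,G,T,N}
alphabet; anything else becomes N so that coordinates are preserved.

Contact matrices come in two plain-text dialects, both carrying a header
line ``#bin_size=<int>\\t#n_bins=<int>``:

* ``triplet`` — one ``bin_i<TAB>bin_j<TAB>value`` line per nonzero entry;
* ``dense``   — a full square TSV matrix.

Bins whose entire row is zero are marked invalid in the matrix mask
(processed Hi-C maps carry no explicit mask; unmappable bins end up as
empty rows).  Masking of annotated regions such as centromeres is done
downstream by interval, not here.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("redfas")

_VALID = set("ACGTN")


@dataclass
class SequenceRecord:
    """A chromosome (or contig) sequence over the {A,C,G,T,N} alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"sequence {self.name!r} contains invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(order=True)
class GenomicInterval:
    """0-based half-open interval with optional BED name/score columns."""

    chrom: str
    start: int
    end: int
    label: str = ""
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ContactMatrix:
    """Symmetric binned contact map with a per-bin validity mask."""

    bin_size: int
    values: np.ndarray
    mask: np.ndarray  # bool, True = valid bin

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("contact matrix must be nonnegative")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.values.shape[0],):
            raise ValueError("mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file, fold to upper case and sanitize to {A,C,G,T,N}."""
    records: list[SequenceRecord] = []
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        cleaned = []
        for ch in seq:
            if ch in _VALID:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_replaced += 1
        records.append(SequenceRecord(name=rec.id, sequence="".join(cleaned)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_replaced:
        logger.warning("replaced %d non-ACGTN characters by N in %s", n_replaced, path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqio_records = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records
    ]
    SeqIO.write(seqio_records, str(path), "fasta")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED5; returns intervals sorted by (chrom, start)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            label = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, label=label, score=score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label or iv.score is not None:
                cols.append(iv.label or ".")
            if iv.score is not None:
                cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def _parse_matrix_header(line: str, path: str | Path) -> tuple[int, int]:
    if not line.startswith("#bin_size="):
        raise ValueError(f"{path}: missing '#bin_size=...\\t#n_bins=...' header")
    parts = line.strip().split("\t")
    bin_size = int(parts[0].split("=", 1)[1])
    n_bins = int(parts[1].split("=", 1)[1])
    return bin_size, n_bins


def read_contacts(path: str | Path, format: str = "triplet") -> ContactMatrix:
    """Read a contact matrix in the ``triplet`` or ``dense`` dialect.

    Triplet files are symmetrized by mirroring; if both (i, j) and (j, i)
    appear their values must agree within 1e-9.
    """
    if format not in ("triplet", "dense"):
        raise ValueError(f"unknown contact-matrix format {format!r}")
    with open(path) as fh:
        header = fh.readline()
        bin_size, n_bins = _parse_matrix_header(header, path)
        values = np.zeros((n_bins, n_bins))
        if format == "triplet":
            seen = np.zeros((n_bins, n_bins), dtype=bool)
            for lineno, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                i_s, j_s, v_s = line.split("\t")
                i, j, v = int(i_s), int(j_s), float(v_s)
                if v < 0:
                    raise ValueError(f"{path}:{lineno}: negative contact value")
                if seen[i, j] and abs(values[i, j] - v) > 1e-9:
                    raise ValueError(
                        f"{path}:{lineno}: asymmetric duplicate entry ({i},{j})"
                    )
                values[i, j] = values[j, i] = v
                seen[i, j] = seen[j, i] = True
        else:
            rows = [line.strip().split("\t") for line in fh if line.strip()]
            if len(rows) != n_bins:
                raise ValueError(f"{path}: expected {n_bins} rows, got {len(rows)}")
            values = np.array(rows, dtype=float)
    mask = ~np.all(values == 0, axis=1)
    return ContactMatrix(bin_size=bin_size, values=values, mask=mask)


def write_contacts(
    matrix: ContactMatrix, path: str | Path, format: str = "triplet"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"#bin_size={matrix.bin_size}\t#n_bins={matrix.n_bins}\n")
        if format == "triplet":
            iu = np.triu_indices(matrix.n_bins)
            for i, j in zip(*iu):
                v = matrix.values[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:.10g}\n")
        elif format == "dense":
            for row in matrix.values:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
        else:
            raise ValueError(f"unknown contact-matrix format {format!r}")


def read_config(path: str | Path) -> dict:
    """Flat key-value configuration file (YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
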