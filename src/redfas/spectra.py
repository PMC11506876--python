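"""Sliding-window k-mer counting and chromosome segmentation.

A k-mer spectrum is the vector of frequencies of all 4^k DNA words in a
sequence, obtained by sliding a window of length k one base at a time
along the forward strand.  Words are indexed in lexicographic order with
A < C < G < T.  Windows containing N are skipped and excluded from the
total, so assembly gaps do not distort frequencies.

Chromosomes are segmented into consecutive non-overlapping windows of a
fixed size (the trailing remainder is dropped) and each segment gets its
own spectrum, as if it were an independent sequence.  The chromosomal
reference spectrum is the unweighted mean of the valid segment spectra.

Counting is deliberately strand-asymmetric: no reverse-complement
canonicalization is applied, because A-rich and T-rich word families
must remain distinguishable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .genome_io import SequenceRecord

logger = logging.getLogger("redfas")

BASES = "ACGT"

# byte -> 2-bit code; N and anything else -> 4 (sentinel)
_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def word_to_index(word: str) -> int:
    """Lexicographic index of a DNA word (A<C<G<T), base-4 encoding."""
    idx = 0
    for ch in word:
        code = _CODE[ord(ch)]
        if code > 3:
            raise ValueError(f"word {word!r} contains a non-ACGT character")
        idx = idx * 4 + code
    return int(idx)


def index_to_word(idx: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(chars))


def word_size_for_length(n: int) -> int:
    """Word size from sequence length: k = round(0.7 * log4(n)), min 1.

    At the 40 kbp segment size used for human chromosomes this gives k=5.
    """
    if n < 4:
        raise ValueError("sequence length must be >= 4")
    k = math.floor(0.7 * math.log(n, 4) + 0.5)  # round-half-up, no banker's ties
    return max(k, 1)


@dataclass
class Spectrum:
    """k-mer count/frequency vector of one sequence or segment."""

    k: int
    counts: np.ndarray  # int64, length 4^k
    total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError("counts must have length 4^k")

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized to sum 1; NaN vector if no window was counted."""
        if self.total == 0:
            return np.full(4**self.k, np.nan)
        return self.counts / self.total


@dataclass
class Segment:
    """One fixed-size genomic window (0-based half-open coordinates)."""

    chrom: str
    index: int
    start: int
    end: int
    valid_windows: int
    gc: float = float("nan")  # (#G + #C) / (#A + #C + #G + #T) in the segment
    valid: bool = True


@dataclass
class SpectrumMatrix:
    """Per-segment spectra of one chromosome, rows aligned with segments."""

    segments: list[Segment]
    rows: np.ndarray  # (n_segments, 4^k) frequencies; NaN rows for invalid
    k: int
    segment_size: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def valid(self) -> np.ndarray:
        return np.array([s.valid for s in self.segments], dtype=bool)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a sequence string to integer codes (A,C,G,T -> 0..3, N -> 4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _count_encoded(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    n = codes.size
    if n < k:
        raise ValueError(f"sequence shorter than k={k}")
    n_win = n - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    invalid = np.zeros(n_win, dtype=bool)
    for offset in range(k):
        col = codes[offset : offset + n_win]
        invalid |= col > 3
        idx = idx * 4 + np.where(col > 3, 0, col)
    counts = np.bincount(idx[~invalid], minlength=4**k)
    return counts.astype(np.int64), int(n_win - invalid.sum())


def count_kmers(sequence: str | np.ndarray, k: int) -> Spectrum:
    """Count every length-k window advancing by one base (forward strand).

    Windows containing N are skipped; if every window contains N the
    spectrum is returned empty (flagged), not raised.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence)
    counts, total = _count_encoded(codes, k)
    return Spectrum(k=k, counts=counts, total=total)


def segment_chromosome(
    record: SequenceRecord,
    segment_size: int,
    k: int,
    min_valid_fraction: float = 0.5,
) -> SpectrumMatrix:
    """Split a chromosome into fixed windows and compute per-segment spectra.

    Segments with fewer than ``min_valid_fraction * (segment_size - k + 1)``
    N-free windows are flagged invalid.  The trailing remainder shorter
    than one segment is dropped.
    """
    if segment_size < 4**k:
        raise ValueError(
            f"segment_size={segment_size} below 4^k={4 ** k}: too few counts "
            "per word for a stable spectrum"
        )
    codes = encode_sequence(record.sequence)
    n_segments = record.length // segment_size
    if n_segments == 0:
        logger.warning(
            "%s shorter than one segment (%d < %d): empty matrix",
            record.name, record.length, segment_size,
        )
    segments: list[Segment] = []
    rows = np.full((n_segments, 4**k), np.nan)
    min_windows = min_valid_fraction * (segment_size - k + 1)
    for i in range(n_segments):
        start, end = i * segment_size, (i + 1) * segment_size
        seg_codes = codes[start:end]
        spec = count_kmers(seg_codes, k)
        base_counts = np.bincount(seg_codes, minlength=5)
        acgt = int(base_counts[:4].sum())
        gc = (base_counts[1] + base_counts[2]) / acgt if acgt else float("nan")
        valid = spec.total >= min_windows and not spec.is_empty
        segments.append(
            Segment(
                chrom=record.name,
                index=i,
                start=start,
                end=end,
                valid_windows=spec.total,
                gc=gc,
                valid=valid,
            )
        )
        if valid:
            rows[i] = spec.frequencies
    return SpectrumMatrix(segments=segments, rows=rows, k=k, segment_size=segment_size)


def reference_spectrum(matrix: SpectrumMatrix) -> np.ndarray:
    """Chromosomal reference: unweighted mean of valid segment spectra."""
    valid = matrix.valid
    if not valid.any():
        raise ValueError("no valid segments to build a reference spectrum from")
    return matrix.rows[valid].mean(axis=0)
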