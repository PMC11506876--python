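"""TSV round-trip formats for spectrum matrices and deviation tracks.

These are the on-disk interchange formats between CLI stages:

* spectra TSV — chrom, start, end, valid_windows, gc, then one column
  per k-mer word (frequency);
* track TSV — chrom, start, end, valid, gc, d, optional d_gc_corrected
  and one ``d_<set>`` column per word set.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .deviation import DeviationTrack
from .spectra import Segment, SpectrumMatrix, index_to_word


def write_spectra_tsv(matrix: SpectrumMatrix, path: str | Path) -> None:
    words = [index_to_word(i, matrix.k) for i in range(4**matrix.k)]
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in matrix.segments],
            "start": [s.start for s in matrix.segments],
            "end": [s.end for s in matrix.segments],
            "valid_windows": [s.valid_windows for s in matrix.segments],
            "gc": [s.gc for s in matrix.segments],
        }
    )
    freq = pd.DataFrame(matrix.rows, columns=words)
    pd.concat([df, freq], axis=1).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_spectra_tsv(path: str | Path) -> SpectrumMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["chrom", "start", "end", "valid_windows", "gc"]
    words = [c for c in df.columns if c not in meta_cols]
    k = len(words[0])
    if len(words) != 4**k:
        raise ValueError(f"{path}: expected {4 ** k} word columns, found {len(words)}")
    rows = df[sorted(words)].to_numpy(dtype=float)
    segment_size = int(df["end"].iloc[0] - df["start"].iloc[0]) if len(df) else 0
    segments = [
        Segment(
            chrom=str(r.chrom),
            index=i,
            start=int(r.start),
            end=int(r.end),
            valid_windows=int(r.valid_windows),
            gc=float(r.gc),
            valid=bool(np.isfinite(rows[i]).all()),
        )
        for i, r in enumerate(df.itertuples())
    ]
    return SpectrumMatrix(segments=segments, rows=rows, k=k, segment_size=segment_size)


def write_track_tsv(track: DeviationTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in track.segments],
            "start": [s.start for s in track.segments],
            "end": [s.end for s in track.segments],
            "valid": track.valid.astype(int),
            "gc": track.gc,
            "d": track.d,
        }
    )
    if track.d_gc_corrected is not None:
        df["d_gc_corrected"] = track.d_gc_corrected
    for name, vals in track.d_by_set.items():
        df[f"d_{name}"] = vals
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_track_tsv(path: str | Path) -> DeviationTrack:
    df = pd.read_csv(path, sep="\t")
    segments = [
        Segment(
            chrom=str(r.chrom),
            index=i,
            start=int(r.start),
            end=int(r.end),
            valid_windows=0,
            gc=float(r.gc),
            valid=bool(r.valid),
        )
        for i, r in enumerate(df.itertuples())
    ]
    d_by_set = {
        c[2:]: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c.startswith("d_") and c != "d_gc_corrected"
    }
    corrected = (
        df["d_gc_corrected"].to_numpy(dtype=float) if "d_gc_corrected" in df else None
    )
    return DeviationTrack(
        segments=segments,
        d=df["d"].to_numpy(dtype=float),
        gc=df["gc"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        d_by_set=d_by_set,
        d_gc_corrected=corrected,
    )
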