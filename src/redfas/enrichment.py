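"""Interval coverage, breakpoint content, and enrichment in sigma units.

Given a set of breakpoint regions and a genomic feature track (called
deviant regions, coding sequence, transposon annotations, ...), the
questions answered here are: what fraction of the chromosome does the
feature cover, what fraction of breakpoint bases fall inside it, and is
that fold enrichment larger than expected by chance?

The null model places each breakpoint interval uniformly at random on
the chromosome, preserving its length (overlaps among placed intervals
are permitted), and recomputes the base-weighted content fraction; the
observed fraction is expressed in standard deviations of that null
(``sigma_diff``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .deviation import DeviationTrack
from .genome_io import GenomicInterval
from .hic import BootstrapResult, bootstrap_correlation

logger = logging.getLogger("redfas")


@dataclass
class EnrichmentResult:
    feature_name: str
    coverage: float  # fraction of chromosome covered by the feature
    bp_fraction: float  # fraction of breakpoint bases inside the feature
    fold: float  # bp_fraction / coverage
    sigma_diff: float  # (observed - null mean) / null sd; NaN if sd == 0
    n_permutations: int


def merge_intervals(
    intervals: list[GenomicInterval] | tuple[GenomicInterval, ...]
) -> np.ndarray:
    """Union of intervals as a (m, 2) array of merged [start, end) pairs."""
    if not intervals:
        return np.empty((0, 2), dtype=np.int64)
    pairs = sorted((iv.start, iv.end) for iv in intervals)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


class _UnionOverlap:
    """Vectorized overlap of query intervals with a fixed interval union.

    Precomputes the cumulative covered bases up to every union boundary;
    overlap of [s, e) is then C(e) - C(s), evaluated by binary search.
    """

    def __init__(self, merged: np.ndarray) -> None:
        self.starts = merged[:, 0]
        self.ends = merged[:, 1]
        lengths = self.ends - self.starts
        self.cum = np.concatenate([[0], np.cumsum(lengths)])

    def _covered_before(self, pos: np.ndarray) -> np.ndarray:
        # bases of the union strictly left of each position
        i = np.searchsorted(self.starts, pos, side="right")
        base = self.cum[np.maximum(i - 1, 0)]
        inside = np.where(
            i > 0, np.clip(pos - self.starts[np.maximum(i - 1, 0)], 0, None), 0
        )
        seg_len = np.where(
            i > 0,
            self.ends[np.maximum(i - 1, 0)] - self.starts[np.maximum(i - 1, 0)],
            0,
        )
        return base + np.minimum(inside, seg_len)

    def overlap(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        if self.starts.size == 0:
            return np.zeros(np.shape(starts), dtype=np.int64)
        return self._covered_before(np.asarray(ends)) - self._covered_before(
            np.asarray(starts)
        )


def coverage_fraction(
    features: list[GenomicInterval], chrom_length: int
) -> float:
    """Fraction of the chromosome covered by the union of the features."""
    merged = merge_intervals(features)
    if merged.size and merged[:, 1].max() > chrom_length:
        raise ValueError("feature interval exceeds chromosome length")
    covered = int((merged[:, 1] - merged[:, 0]).sum()) if merged.size else 0
    return covered / chrom_length


def content_fraction(
    bp: list[GenomicInterval], features: list[GenomicInterval]
) -> float:
    """Fraction of breakpoint bases lying inside the feature union."""
    if not bp:
        logger.warning("empty breakpoint set; content fraction undefined")
        return float("nan")
    union = _UnionOverlap(merge_intervals(features))
    starts = np.array([iv.start for iv in bp])
    ends = np.array([iv.end for iv in bp])
    total = int((ends - starts).sum())
    return float(union.overlap(starts, ends).sum() / total)


def enrichment_sigma(
    bp: list[GenomicInterval],
    features: list[GenomicInterval],
    chrom_length: int,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    feature_name: str = "",
) -> EnrichmentResult:
    """Permutation z-score of breakpoint content in a feature track.

    Each permutation redraws every breakpoint interval's start uniformly
    so the interval fits on the chromosome (length preserved), then
    recomputes the content fraction.  ``sigma_diff`` is NaN when the
    null has zero spread (e.g. the feature covers everything).
    """
    if not bp:
        raise ValueError("need at least one breakpoint interval")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for the permutation null")
        rng = np.random.default_rng(seed)
    cov = coverage_fraction(features, chrom_length)
    obs = content_fraction(bp, features)
    union = _UnionOverlap(merge_intervals(features))
    lengths = np.array([iv.length for iv in bp])
    if np.any(lengths > chrom_length):
        raise ValueError("breakpoint interval longer than the chromosome")
    total = lengths.sum()
    # (n_perm, n_bp) random starts, each interval kept fully on-chromosome
    starts = (rng.random((n_perm, lengths.size)) * (chrom_length - lengths + 1)).astype(
        np.int64
    )
    null = union.overlap(starts, starts + lengths).sum(axis=1) / total
    sd = float(null.std())
    if sd == 0:
        logger.warning("degenerate null (sd=0); sigma_diff undefined")
        sigma = float("nan")
    else:
        sigma = float((obs - null.mean()) / sd)
    return EnrichmentResult(
        feature_name=feature_name,
        coverage=cov,
        bp_fraction=obs,
        fold=obs / cov if cov > 0 else float("nan"),
        sigma_diff=sigma,
        n_permutations=n_perm,
    )


def segment_feature_density(
    track: DeviationTrack, features: list[GenomicInterval]
) -> np.ndarray:
    """Covered fraction of each segment by the feature union."""
    union = _UnionOverlap(merge_intervals(features))
    starts = np.array([s.start for s in track.segments])
    ends = np.array([s.end for s in track.segments])
    return union.overlap(starts, ends) / (ends - starts)


def annotation_density_correlation(
    track: DeviationTrack,
    features: list[GenomicInterval],
    n_reps: int = 100,
    n_sample: int = 100,
    seed: int | None = None,
    use_corrected: bool = False,
) -> BootstrapResult:
    """Bootstrap correlation of the deviation track with feature density."""
    density = segment_feature_density(track, features)
    d = track.values(use_corrected).astype(float).copy()
    d[~track.valid] = np.nan
    return bootstrap_correlation(d, density, n_reps=n_reps, n_sample=n_sample, seed=seed)
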