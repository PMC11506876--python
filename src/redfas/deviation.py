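"""Deviation from the average k-mer spectrum and ReDFAS calling.

The core statistic compares each segment's local spectrum with a single
chromosomal reference spectrum (the mean of all valid segment spectra)
instead of performing all pairwise segment comparisons.  For a word set
S the deviation of a segment is

    d_S = 100 * sum_{i in S} |f_local,i - f_ref,i| / sum_{i in S} f_ref,i

For the full word space the denominator is 1 (frequencies sum to 1), so
d is the L1 distance between probability vectors times 100 and lies in
[0, 200].  Restricted word sets are normalized by the reference mass of
the set, so their deviations can exceed several hundred percent.

A ReDFAS (Region Deviating From Average Spectrum) is a run of
consecutive segments whose deviation exceeds the empirical 95th
percentile of the per-segment deviations (strict inequality,
nearest-rank quantile), optionally computed after removing the linear
dependence of d on the local G+C content.  Regions are classified as
centromeric, subtelomeric or intermediate by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .genome_io import GenomicInterval
from .spectra import Segment, SpectrumMatrix, reference_spectrum, word_to_index
from .wordsets import WordSet

logger = logging.getLogger("redfas")


@dataclass
class DeviationTrack:
    """Per-segment deviation percentages plus auxiliary tracks."""

    segments: list[Segment]
    d: np.ndarray  # percent, NaN where invalid
    gc: np.ndarray
    valid: np.ndarray
    d_by_set: dict[str, np.ndarray] = field(default_factory=dict)
    d_gc_corrected: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segment_size(self) -> int:
        return self.segments[0].end - self.segments[0].start if self.segments else 0

    def values(self, use_corrected: bool = False) -> np.ndarray:
        if use_corrected:
            if self.d_gc_corrected is None:
                raise ValueError("track has no G+C-corrected deviations; run gc_correct")
            return self.d_gc_corrected
        return self.d


@dataclass
class ReDFASRegion:
    """A called region: one or more consecutive high-deviation segments."""

    chrom: str
    start: int
    end: int
    mean_d: float
    n_segments: int
    class_label: str = ""

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end,
            label=self.class_label or "ReDFAS", score=self.mean_d,
        )


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, 4^k), orthonormal rows
    scores: np.ndarray  # (n_segments, n_components), NaN rows for invalid
    explained_variance: np.ndarray  # fraction per component, non-increasing


def _set_indices(word_set: WordSet) -> np.ndarray:
    return np.array([word_to_index(w) for w in word_set.words], dtype=int)


def spectrum_deviation(local, ref, word_set: WordSet | None = None) -> float:
    """Deviation (percent) of a local spectrum from a reference spectrum.

    Accepts ``Spectrum`` objects or raw frequency vectors.  ``word_set``
    restricts the sum to that set's words and normalizes by the set's
    reference mass; ``None`` means all 4^k words (denominator 1).
    Returns NaN if the local spectrum is empty or the reference mass of
    the word set is zero.
    """
    f_local = np.asarray(getattr(local, "frequencies", local), dtype=float)
    f_ref = np.asarray(getattr(ref, "frequencies", ref), dtype=float)
    if f_local.shape != f_ref.shape:
        raise ValueError("local and reference spectra must share k")
    if np.isnan(f_local).any() or np.isnan(f_ref).any():
        return float("nan")
    if word_set is None:
        return float(100.0 * np.abs(f_local - f_ref).sum())
    idx = _set_indices(word_set)
    denom = f_ref[idx].sum()
    if denom == 0:
        return float("nan")
    return float(100.0 * np.abs(f_local[idx] - f_ref[idx]).sum() / denom)


def deviation_track(
    matrix: SpectrumMatrix, word_sets: list[WordSet] | tuple[WordSet, ...] = ()
) -> DeviationTrack:
    """Per-segment deviation from the chromosomal average spectrum."""
    ref = reference_spectrum(matrix)
    valid = matrix.valid
    d = np.full(matrix.n_segments, np.nan)
    diffs = np.abs(matrix.rows - ref)
    d[valid] = 100.0 * diffs[valid].sum(axis=1)
    d_by_set: dict[str, np.ndarray] = {}
    for ws in word_sets:
        idx = _set_indices(ws)
        denom = ref[idx].sum()
        track = np.full(matrix.n_segments, np.nan)
        if denom > 0:
            track[valid] = 100.0 * diffs[np.ix_(valid, idx)].sum(axis=1) / denom
        else:
            logger.warning("word set %s has zero reference mass; track undefined", ws.name)
        d_by_set[ws.name] = track
    gc = np.array([s.gc for s in matrix.segments])
    return DeviationTrack(
        segments=matrix.segments, d=d, gc=gc, valid=valid.copy(), d_by_set=d_by_set
    )


def pairwise_peculiarity(matrix: SpectrumMatrix) -> np.ndarray:
    """Mean Pearson correlation of each segment's spectrum with all others.

    This is the expensive all-pairs similarity measure that the single
    reference-spectrum deviation replaces; on heterogeneous chromosomes
    the two tracks are strongly anti-correlated.  Zero-variance spectra
    yield undefined correlations and are excluded pairwise.
    """
    valid = matrix.valid
    if valid.sum() < 3:
        raise ValueError("need >= 3 valid segments for pairwise comparison")
    rows = matrix.rows[valid]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(rows)
    np.fill_diagonal(corr, np.nan)
    mean_corr = np.nanmean(corr, axis=1)
    out = np.full(matrix.n_segments, np.nan)
    out[valid] = mean_corr
    return out


def gc_correct(track: DeviationTrack) -> DeviationTrack:
    """Remove the linear dependence of d on local G+C content.

    Fits d ~ a + b*gc by ordinary least squares over valid segments and
    subtracts b*(gc - mean(gc)), so the corrected track keeps the
    original mean (threshold comparability).  With constant G+C the
    track is returned unchanged with a warning.
    """
    valid = track.valid & np.isfinite(track.d) & np.isfinite(track.gc)
    if valid.sum() < 10:
        raise ValueError("need >= 10 valid segments for G+C correction")
    gc_v, d_v = track.gc[valid], track.d[valid]
    if np.ptp(gc_v) == 0:
        logger.warning("constant G+C content; correction is a no-op")
        return replace(track, d_gc_corrected=track.d.copy())
    fit = stats.linregress(gc_v, d_v)
    corrected = track.d - fit.slope * (track.gc - gc_v.mean())
    return replace(track, d_gc_corrected=corrected)


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Empirical quantile, nearest-rank definition: x_(ceil(q*n))."""
    srt = np.sort(values)
    rank = int(np.ceil(q * srt.size))
    return float(srt[max(rank, 1) - 1])


def call_redfas(
    track: DeviationTrack,
    quantile: float = 0.95,
    use_corrected: bool = False,
    merge_gap: int = 0,
) -> list[ReDFASRegion]:
    """Call regions whose deviation exceeds the per-chromosome quantile.

    The threshold is the nearest-rank empirical quantile of d over valid
    segments; segments strictly above it are flagged (so ties never push
    the flagged fraction above 1-quantile).  Runs of flagged segments,
    allowing up to ``merge_gap`` unflagged segments in between, are
    merged into regions.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    vals = track.values(use_corrected)
    valid = track.valid & np.isfinite(vals)
    if valid.sum() < 20:
        raise ValueError("need >= 20 valid segments to calibrate a threshold")
    threshold = nearest_rank_quantile(vals[valid], quantile)
    flagged = valid & (vals > threshold)
    regions: list[ReDFASRegion] = []
    idx = np.flatnonzero(flagged)
    if idx.size == 0:
        return regions
    run_start = prev = idx[0]
    members = [idx[0]]

    def _close(run_start: int, prev: int, members: list[int]) -> None:
        segs = track.segments
        regions.append(
            ReDFASRegion(
                chrom=segs[run_start].chrom,
                start=segs[run_start].start,
                end=segs[prev].end,
                mean_d=float(np.mean(vals[members])),
                n_segments=prev - run_start + 1,
            )
        )

    for i in idx[1:]:
        if i - prev - 1 <= merge_gap:
            prev = i
            members.append(i)
        else:
            _close(run_start, prev, members)
            run_start = prev = i
            members = [i]
    _close(run_start, prev, members)
    return regions


def classify_redfas(
    regions: list[ReDFASRegion],
    centromere: GenomicInterval | None,
    chrom_length: int,
    subtelomere_margin: int = 2_000_000,
) -> list[ReDFASRegion]:
    """Label regions centromeric / subtelomeric / intermediate by position.

    Overlap with the centromere wins over telomere proximity; a region
    within ``subtelomere_margin`` of either chromosome end is
    subtelomeric; everything else is intermediate.
    """
    if centromere is None:
        logger.warning("no centromere annotation; non-telomeric regions -> intermediate")
    labeled = []
    for r in regions:
        if centromere is not None and r.start < centromere.end and centromere.start < r.end:
            label = "centromeric"
        elif r.start < subtelomere_margin or r.end > chrom_length - subtelomere_margin:
            label = "subtelomeric"
        else:
            label = "intermediate"
        labeled.append(replace(r, class_label=label))
    return labeled


def pca_spectra(matrix: SpectrumMatrix, n_components: int = 3) -> PCAResult:
    """PCA of the per-segment spectra (centered frequencies, unscaled).

    Component signs are fixed by making each component's largest-
    magnitude loading positive, so results are reproducible.
    """
    valid = matrix.valid
    if valid.sum() < n_components + 1:
        raise ValueError("need more valid segments than components")
    rows = matrix.rows[valid]
    pca = PCA(n_components=n_components, svd_solver="full")
    scores_valid = pca.fit_transform(rows)
    components = pca.components_.copy()
    for c in range(n_components):
        j = np.argmax(np.abs(components[c]))
        if components[c, j] < 0:
            components[c] *= -1
            scores_valid[:, c] *= -1
    scores = np.full((matrix.n_segments, n_components), np.nan)
    scores[valid] = scores_valid
    return PCAResult(
        components=components,
        scores=scores,
        explained_variance=pca.explained_variance_ratio_,
    )
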