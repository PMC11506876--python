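"""Per-segment Hi-C contact summaries and bootstrap correlation tests.

Each segment's contact level is summarized as the mean of its matrix row
over valid, unmasked bins, excluding the diagonal (self-contacts
dominate Hi-C rows and carry no between-locus proximity information).

Significance of a track-vs-track correlation follows a subsampling
scheme: in each of ``n_reps`` repetitions, ``n_sample`` jointly valid
segments are drawn without replacement and Pearson-correlated; the mean
and standard deviation over repetitions summarize the empirical
distribution.  A reference distribution is obtained the same way after
independently permuting one track across segments in every repetition
(destroying the pairing while preserving both marginals).  The
correlation is called significant when the empirical and reference
means differ by more than one combined standard deviation,
sigma^2 = sigma_empirical^2 + sigma_reference^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import ContactMatrix, GenomicInterval

logger = logging.getLogger("redfas")


@dataclass
class ContactTrack:
    """Mean off-diagonal contact frequency per segment/bin."""

    mean_contact: np.ndarray  # NaN where invalid
    valid: np.ndarray
    bin_size: int

    @property
    def n_bins(self) -> int:
        return self.mean_contact.size


@dataclass
class BootstrapResult:
    """Subsampled correlation distribution and its shuffled reference."""

    mean_r: float
    sd_r: float
    ref_mean_r: float
    ref_sd_r: float
    n_reps: int
    n_sample: int

    @property
    def significant(self) -> bool:
        """1-sigma rule on the combined empirical + reference spread."""
        return abs(self.mean_r - self.ref_mean_r) > np.sqrt(
            self.sd_r**2 + self.ref_sd_r**2
        )

    def to_dict(self) -> dict:
        return {
            "mean_r": self.mean_r,
            "sd_r": self.sd_r,
            "ref_mean_r": self.ref_mean_r,
            "ref_sd_r": self.ref_sd_r,
            "n_reps": self.n_reps,
            "n_sample": self.n_sample,
            "significant": bool(self.significant),
        }


def contact_track(
    matrix: ContactMatrix,
    mask_intervals: list[GenomicInterval] | tuple[GenomicInterval, ...] = (),
) -> ContactTrack:
    """Mean contact per bin over valid, unmasked partner bins (j != i).

    Bins overlapping any mask interval (e.g. the centromere) are
    invalidated entirely: they get no value and are excluded from every
    other bin's mean.
    """
    n = matrix.n_bins
    valid = matrix.mask.copy()
    for iv in mask_intervals:
        lo = iv.start // matrix.bin_size
        hi = -(-iv.end // matrix.bin_size)  # ceil division
        valid[max(lo, 0) : min(hi, n)] = False
    mean_contact = np.full(n, np.nan)
    for i in np.flatnonzero(valid):
        cols = valid.copy()
        cols[i] = False
        if cols.any():
            mean_contact[i] = matrix.values[i, cols].mean()
    track_valid = valid & np.isfinite(mean_contact)
    return ContactTrack(mean_contact=mean_contact, valid=track_valid, bin_size=matrix.bin_size)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float((a @ b) / denom)


def bootstrap_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_reps: int = 100,
    n_sample: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Subsampled Pearson correlation of two per-segment tracks.

    ``x`` and ``y`` are aligned per-segment value arrays (NaN = invalid).
    Each repetition draws ``n_sample`` jointly valid segments without
    replacement; if fewer are available, sampling falls back to with-
    replacement with a warning.  A seed (or generator) is mandatory.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    joint = np.isfinite(x) & np.isfinite(y)
    xv, yv = x[joint], y[joint]
    n_avail = xv.size
    replace = n_avail < n_sample
    if replace:
        logger.warning(
            "only %d jointly valid segments for n_sample=%d; sampling with replacement",
            n_avail, n_sample,
        )
    r_emp = np.empty(n_reps)
    r_ref = np.empty(n_reps)
    for rep in range(n_reps):
        idx = rng.choice(n_avail, size=n_sample, replace=replace)
        r_emp[rep] = _pearson(xv[idx], yv[idx])
    for rep in range(n_reps):
        y_shuf = rng.permutation(yv)
        idx = rng.choice(n_avail, size=n_sample, replace=replace)
        r_ref[rep] = _pearson(xv[idx], y_shuf[idx])
    return BootstrapResult(
        mean_r=float(np.nanmean(r_emp)),
        sd_r=float(np.nanstd(r_emp)),
        ref_mean_r=float(np.nanmean(r_ref)),
        ref_sd_r=float(np.nanstd(r_ref)),
        n_reps=n_reps,
        n_sample=n_sample,
    )


def compare_cell_lines(
    a: BootstrapResult, b: BootstrapResult, n_samples: int | None = None
) -> bool:
    """Significant-difference flag between two correlation results.

    Uses the combined standard error of the means,
    sqrt(sd_a^2/n + sd_b^2/n), with n the number of correlated samples
    per repetition (each result's own ``n_sample`` unless overridden).
    Strict inequality: a borderline difference is not significant.
    """
    n_a = n_samples if n_samples is not None else a.n_sample
    n_b = n_samples if n_samples is not None else b.n_sample
    se = np.sqrt(a.sd_r**2 / n_a + b.sd_r**2 / n_b)
    return bool(abs(a.mean_r - b.mean_r) > se)
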