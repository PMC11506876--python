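"""Synthetic chromosomes with planted spectrum-deviant regions.

The generator emulates the structures the scan is designed to find:

* a background chromosome drawn i.i.d. with a controllable G+C content;
* planted regions where a chosen fraction of positions is overwritten
  by tandem copies of words from a tandem-repeat word set (AT-rich
  blocks mimic centromere-like satellite, GC-rich blocks mimic
  interstitial deviant clusters);
* a distance-decay contact matrix whose local intensity is coupled to
  the deviation track through a log-linear factor;
* breakpoint intervals enriched inside the planted regions at a target
  base-fold over coverage.

Every generator takes an explicit seed and is bit-reproducible; the
ground truth (planted intervals, parameters, seed) travels alongside
each dataset so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .deviation import DeviationTrack
from .genome_io import ContactMatrix, GenomicInterval, SequenceRecord
from .wordsets import WordSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedRegion:
    start: int
    end: int
    word_set: str
    excess_fraction: float
    label: str = ""

    def as_interval(self, chrom: str) -> GenomicInterval:
        return GenomicInterval(chrom, self.start, self.end, label=self.label or self.word_set)


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    chrom: str
    length: int
    segment_size: int
    background_gc: float
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    coupling: float = 0.0
    bp_enrichment_fold: float = 1.0
    seed: int = 0

    def planted_intervals(self) -> list[GenomicInterval]:
        return [p.as_interval(self.chrom) for p in self.planted_regions]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["planted_regions"] = [PlantedRegion(**p) for p in data["planted_regions"]]
        return cls(**data)


def generate_chromosome(
    length: int,
    segment_size: int,
    background_gc: float,
    planted: list[tuple[int, int, WordSet, float]],
    seed: int,
    chrom: str = "synth1",
    tandem_copies: int = 6,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Background i.i.d. chromosome with planted tandem-repeat regions.

    ``planted`` lists (position, region_length, word_set, excess_fraction)
    tuples; inside each region approximately ``excess_fraction`` of the
    positions is overwritten by blocks of ``tandem_copies`` tandem
    repeats of words drawn from the word set.  Regions must be
    non-overlapping and within bounds.
    """
    rng = np.random.default_rng(seed)
    p_gc = background_gc / 2.0
    probs = [(1 - background_gc) / 2, p_gc, p_gc, (1 - background_gc) / 2]
    seq = rng.choice(_BASES, size=length, p=probs)

    regions = sorted(planted, key=lambda t: t[0])
    prev_end = 0
    truth_regions: list[PlantedRegion] = []
    for pos, reg_len, word_set, excess in regions:
        if not 0 < excess <= 1:
            raise ValueError("excess_fraction must be in (0, 1]")
        if pos < prev_end or pos + reg_len > length:
            raise ValueError("planted regions must be non-overlapping and in bounds")
        prev_end = pos + reg_len
        k = word_set.k
        block_len = k * tandem_copies
        n_blocks = int(np.ceil(excess * reg_len / block_len))
        words = np.array([list(w.encode("ascii")) for w in word_set.words], dtype=np.uint8)
        for _ in range(n_blocks):
            w = words[rng.integers(len(words))]
            block = np.tile(w, tandem_copies)
            offset = pos + int(rng.integers(0, max(reg_len - block_len, 0) + 1))
            end = min(offset + block_len, pos + reg_len)
            seq[offset:end] = block[: end - offset]
        truth_regions.append(
            PlantedRegion(start=pos, end=pos + reg_len, word_set=word_set.name,
                          excess_fraction=excess)
        )
    record = SequenceRecord(name=chrom, sequence=seq.tobytes().decode("ascii"))
    truth = SyntheticTruth(
        chrom=chrom,
        length=length,
        segment_size=segment_size,
        background_gc=background_gc,
        planted_regions=truth_regions,
        seed=seed,
    )
    return record, truth


def generate_contacts(
    track: DeviationTrack,
    coupling: float,
    decay_exponent: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> ContactMatrix:
    """Distance-decay contact matrix coupled to a deviation track.

    values[i,j] = (1+dist(i,j))^(-decay_exponent) * exp(coupling*(z_i+z_j)/2)
    times multiplicative lognormal noise, where z is the standardized
    deviation track.  Two modelling choices keep the coupling parameter
    the only driver of track-level correlation:

    * dist is the circular bin distance min(|i-j|, n-|i-j|), so every
      bin sees the same decay profile and the marginal contact level is
      homogeneous along the chromosome (a linear distance would impose
      a deterministic edge gradient on the per-bin means, correlating
      with any spatially structured track even at coupling 0);
    * the lognormal noise has a per-bin visibility component
      exp((eta_i+eta_j)/2) in addition to the per-entry component, so
      noise survives row-averaging (pure per-entry noise cancels over
      hundreds of bins and the per-bin mean would degenerate to a
      noiseless function of z).

    Invalid segments get all-zero rows (masked).
    """
    rng = np.random.default_rng(seed)
    n = track.n_segments
    d = track.d.astype(float)
    valid = track.valid & np.isfinite(d)
    z = np.zeros(n)
    if valid.sum() > 1 and d[valid].std() > 0:
        z[valid] = (d[valid] - d[valid].mean()) / d[valid].std()
    lin = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    dist = np.minimum(lin, n - lin)
    decay = (1.0 + dist) ** (-decay_exponent)
    boost = np.exp(coupling * (z[:, None] + z[None, :]) / 2.0)
    eta = rng.normal(0.0, noise_sd, size=n)  # per-bin visibility factor
    eps = rng.normal(0.0, noise_sd, size=(n, n))
    eps = (eps + eps.T) / np.sqrt(2)  # symmetric per-entry noise
    values = decay * boost * np.exp((eta[:, None] + eta[None, :]) / 2.0 + eps)
    values[~valid, :] = 0.0
    values[:, ~valid] = 0.0
    return ContactMatrix(bin_size=track.segment_size, values=values, mask=valid.copy())


def demo_chromosome(seed: int) -> tuple[SequenceRecord, SyntheticTruth]:
    """Standard recovery scenario: 2 Mb, 10 kb segments, two planted regions.

    One AT-rich and one GC-rich region of 50 kb (5 segments each) at
    excess 0.5, i.e. 10 of 200 segments are deviant -- exactly the 5%
    budget the 95th-percentile calling rule can flag.
    """
    from .wordsets import builtin_word_sets

    sets = {w.name: w for w in builtin_word_sets()}
    planted = [
        (500_000, 50_000, sets["AT-rich"], 0.5),
        (1_400_000, 50_000, sets["GC-rich"], 0.5),
    ]
    return generate_chromosome(2_000_000, 10_000, 0.41, planted, seed)


def heterogeneous_chromosome(seed: int) -> tuple[SequenceRecord, SyntheticTruth]:
    """Repeat-landscape scenario: six planted regions, one per word family.

    2 Mb, 10 kb segments; 40 kb regions of A-, C-, G-, T-, AT- and
    GC-rich tandem repeats at excess 0.5, emulating a chromosome whose
    deviant regions differ in repeat composition (centromeric satellite
    vs subtelomeric vs interstitial clusters).
    """
    from .wordsets import builtin_word_sets

    sets = builtin_word_sets()
    planted = [
        (100_000 + i * 300_000, 40_000, ws, 0.5) for i, ws in enumerate(sets)
    ]
    return generate_chromosome(2_000_000, 10_000, 0.41, planted, seed)


def generate_breakpoints(
    truth: SyntheticTruth,
    n_bp: int,
    bp_length: int,
    fold: float,
    seed: int,
) -> list[GenomicInterval]:
    """Breakpoint intervals enriched in the planted regions.

    Each interval is placed fully inside a planted region with a
    probability chosen so the expected base-fold over the planted
    coverage equals ``fold`` (fold < 1 depletes instead by forcing a
    share of placements outside).  fold = 1 reduces to uniform placement.
    """
    if fold < 0:
        raise ValueError("fold must be >= 0")
    rng = np.random.default_rng(seed)
    length = truth.length
    planted = [(p.start, p.end) for p in truth.planted_regions]
    cov_bases = sum(e - s for s, e in planted)
    cov = cov_bases / length
    if cov == 0 and fold > 1:
        raise ValueError("cannot enrich: no planted regions")
    intervals: list[GenomicInterval] = []
    if fold >= 1 and cov > 0:
        p_inside = min(cov * (fold - 1) / (1 - cov), 1.0) if cov < 1 else 0.0
    else:
        p_inside = 0.0
    p_outside = max(1.0 - fold, 0.0) if fold < 1 else 0.0
    weights = np.array([max(e - s - bp_length + 1, 0) for s, e in planted], dtype=float)
    for i in range(n_bp):
        u = rng.random()
        if u < p_inside and weights.sum() > 0:
            r = rng.choice(len(planted), p=weights / weights.sum())
            s0, e0 = planted[r]
            start = int(rng.integers(s0, e0 - bp_length + 1))
        elif fold < 1 and u < p_outside:
            start = _uniform_outside(rng, length, bp_length, planted)
        else:
            start = int(rng.integers(0, length - bp_length + 1))
        intervals.append(
            GenomicInterval(truth.chrom, start, start + bp_length, label=f"bp{i}")
        )
    intervals.sort(key=lambda iv: iv.start)
    return intervals


def _uniform_outside(
    rng: np.random.Generator,
    length: int,
    bp_length: int,
    planted: list[tuple[int, int]],
) -> int:
    for _ in range(1000):
        start = int(rng.integers(0, length - bp_length + 1))
        if not any(start < e and s < start + bp_length for s, e in planted):
            return start
    raise RuntimeError("could not place interval outside planted regions")
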