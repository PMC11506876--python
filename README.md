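# redfas

Alignment-free detection of **Re**gions **D**eviating **F**rom **A**verage
**S**pectra (ReDFAS) in genomic sequences, with the downstream statistics
that relate those regions to 3D chromatin contacts and breakpoint
catalogues.

## The problem and the method

Standard k-mer analysis reduces a sequence to the frequencies of all 4^k
DNA words (its *k-mer spectrum*) and loses positional information. To get
position back, a chromosome is split into fixed-size segments (e.g.
40 kbp, with word size chosen as k = 0.7·log₄(n), giving k = 5 at that
resolution), and each segment's local spectrum **f**_local is compared to
a single chromosomal reference spectrum **f**_ref — the mean of all valid
segment spectra. The deviation of a segment over a word set S is

    d_S = 100 · Σ_{i∈S} |f_local,i − f_ref,i| / Σ_{i∈S} f_ref,i   [%]

For S = all words the denominator is 1 and d is the L1 distance between
probability vectors × 100, bounded by [0, 200]. This single-reference
statistic replaces the quadratic all-pairs comparison of segment spectra:
a segment's mean Pearson correlation with every other segment is strongly
anti-correlated with d, so the two rank segments equivalently.

A **ReDFAS** is a run of consecutive segments whose deviation exceeds the
empirical 95th percentile of all segments (nearest-rank quantile, strict
inequality). Regions are classified *centromeric*, *subtelomeric* or
*intermediate* by position; restricted word sets built from tandem-repeat
families (A-/C-/G-/T-rich with one free position, AT-rich = WWWWW,
GC-rich = SSSSS) characterize what drives each region. Because deviation
correlates weakly with base composition, d can also be corrected for
local G+C content by removing its ordinary-least-squares linear component.

Two downstream statistics connect ReDFAS to biology:

* **Hi-C correlation** — per-segment mean contact frequency (off-diagonal
  row mean of a binned contact matrix, invalid/masked bins excluded) is
  correlated with d by a subsampling scheme: 100 repetitions × 100
  randomly sampled segments, Pearson correlation each time; significance
  when the empirical mean differs from a shuffled-segment reference mean
  by more than 1σ with σ² = σ²_empirical + σ²_reference.
* **Breakpoint enrichment** — the fraction of breakpoint-region bases
  falling inside a feature track, compared to the feature's chromosomal
  coverage (fold) and to a length-preserving uniform-placement
  permutation null (z-score in σ units).

A synthetic-data module generates chromosomes with planted tandem-repeat
regions, coupled distance-decay contact matrices and enriched breakpoint
sets, so the whole pipeline is testable without reference-genome
downloads.

## Worked example

```python
import numpy as np
import redfas as rf
from redfas.synthetic import demo_chromosome, generate_contacts, generate_breakpoints

# 2 Mb chromosome, 10 kb segments; one AT-rich and one GC-rich planted region
record, truth = demo_chromosome(seed=0)
matrix = rf.segment_chromosome(record, 10_000, k=5)
track  = rf.gc_correct(rf.deviation_track(matrix, rf.builtin_word_sets()))
print("segments:", matrix.n_segments, " mean d: %.1f%%" % np.nanmean(track.d))

for r in rf.classify_redfas(rf.call_redfas(track, quantile=0.95),
                            centromere=None, chrom_length=truth.length,
                            subtelomere_margin=100_000):
    print(f"  {r.chrom}:{r.start}-{r.end}  mean_d={r.mean_d:.1f}%  {r.class_label}")

contacts = generate_contacts(track, coupling=1.0, seed=1)
ct = rf.contact_track(contacts)
d = track.d.copy(); d[~track.valid] = np.nan
res = rf.bootstrap_correlation(d, ct.mean_contact, seed=2)
print("Hi-C: mean_r=%.2f±%.2f  ref %.2f±%.2f  significant=%s"
      % (res.mean_r, res.sd_r, res.ref_mean_r, res.ref_sd_r, res.significant))

bps = generate_breakpoints(truth, n_bp=300, bp_length=1000, fold=2.5, seed=3)
enr = rf.enrichment_sigma(bps, truth.planted_intervals(), truth.length, seed=4)
print("enrichment: fold=%.2f sigma=%.1f" % (enr.fold, enr.sigma_diff))
```

prints

```
segments: 200  mean d: 28.0%
  synth1:500000-550000  mean_d=70.3%  intermediate
  synth1:1400000-1450000  mean_d=75.8%  intermediate
Hi-C: mean_r=0.96±0.02  ref 0.00±0.10  significant=True
enrichment: fold=2.47 sigma=5.8
```

Both planted regions are recovered exactly at segment resolution, with
deviations ~2.5× the chromosomal mean; the coupled contact matrix yields
a strongly significant positive correlation while the shuffled reference
sits at 0.00 ± 0.10; and breakpoints planted at base-fold 2.5 come back
at fold 2.47, nearly 6σ above the uniform-placement null.

The same workflow is available from the shell:

```sh
redfas synth   --config synth.yaml --out-dir fixtures/
redfas spectra --fasta chrom.fa --segment-size 40000 --out spectra.tsv
redfas deviate --spectra spectra.tsv --word-sets builtin --gc-correct --out track.tsv
redfas call    --track track.tsv --quantile 0.95 --centromeres cen.bed --out redfas.bed
redfas hic-corr --track track.tsv --contacts chr.triplet --seed 17 --out corr.json
redfas enrich  --redfas redfas.bed --bp breakpoints.bed --chrom-length 2000000 \
               --seed 7 --out enrich.tsv
redfas run     --config pipeline.yaml    # all stages in order
```

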