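# s1seqmap

Strand-specific resection-endpoint mapping and analysis for S1-seq and its
nuclease variants (Exo7/T-seq, ExoT-seq).

## The problem

Meiotic recombination starts with programmed DNA double-strand breaks
(DSBs) made by SPO11 at hotspots. The 5′-terminated strands at each break
are nucleolytically resected, exposing 3′ ssDNA tails. S1-seq and related
methods map the endpoints of these resection tracts genome-wide: a
ssDNA-specific nuclease (S1, or *E. coli* exonuclease VII + T, or
exonuclease T alone) blunts the resected ends, a biotinylated adaptor is
ligated, and sequencing reads are counted at the nucleotide next to the
adaptor — the ssDNA/dsDNA junction. The signal is strand-polarized: reads
on the top strand accumulate to the *right* of a hotspot center (resection
moving rightward) and bottom-strand reads to the *left*.

`s1seqmap` implements the downstream computational method: endpoint signal
extraction from aligned reads, hotspot-anchored profiling, the
resection-length statistics, H-DNA artifact quantification, and a
generative simulator with per-read ground truth so every pipeline stage is
testable without sequencing data.

## The method in brief

Given aligned paired-end reads, the endpoint of a properly paired,
non-duplicate first mate with MAPQ ≥ 20 is its first aligned genomic base
(leftmost for forward alignments → top strand; rightmost for reverse →
bottom strand). Counts are normalized to reads per million (RPM).

Around a set of hotspot anchors with centers *c₁…cₙ* the package computes:

- **Co-oriented average profile** — the bottom strand is folded through
  each center (*x → −x*) and combined with the top strand, then averaged
  across hotspots; display smoothing uses a 151-bp (or 51-bp) Hann window.
- **Internal normalization** — subtract the background *b* = signal at
  +2500 bp, clamp negatives to 0, and scale so the resection peak (the
  maximum over offsets [100, 2500]) equals 1, making spatial shapes
  comparable across libraries of different strength.
- **Mean resection length** — after background subtraction and masking
  outside [100, 2500], signal fractions *fᵢ* are computed in 24 bins of
  100 bp and the estimate is Σ *fᵢ·mᵢ* over bin midpoints
  *mᵢ* = 150, …, 2450 nt.
- **Central:resection ratio** — signal summed over [−1500, +100) divided
  by [+100, +2500]; S1 cleaves recombination intermediates (central peak
  with opposite polarity), Exo7/T maps SPO11-capped ends (centered peak),
  ExoT has essentially none.
- **Heatmaps** — per-hotspot strand matrices in 50-bp (or 40-bp) bins,
  optionally locally normalized so each hotspot's signal in a 4001-bp
  window sums to 1.
- **H-DNA scan** — all maximal C(TC)ⁿ (n ≥ 20) polypyrimidine•polypurine
  mirror repeats on either strand, the pH-dependent ex vivo source of
  background S1 cleavage, with strand-resolved (pyrimidine/purine) signal
  profiles at the hits.

## Worked example

```sh
python examples/simulate_and_profile.py
```

```
hotspots: 100, reads: 500000
estimated mean resection length: 1101 nt
simulation truth (Monte-Carlo oracle): 1099 nt
resection peak position: +1052 bp
normalized profile value at +2500 bp: 0.0
```

The simulator drew 5×10⁵ reads with resection distances from a truncated
gamma (mean 1100 nt); the profile-based estimator recovers the true mean
to within ~2 nt, the resection peak sits ~1 kb right of hotspot centers as
in real maps, and the internally normalized profile is 0 at +2500 bp by
the background definition. The other scripts in `examples/` demonstrate
the method comparison (S1 vs Exo7/T vs ExoT central signal), the H-DNA pH
series, and replicate reproducibility.

The same operations are exposed as a CLI for file-based runs:

```sh
s1seqmap simulate --seed 1 --out-dir run/
s1seqmap endpoints --bam sample.bam --out endpoints.bed
s1seqmap profile --endpoints run/endpoints.bed --hotspots run/hotspots.bed \
    --chrom-sizes run/chrom.sizes --out profile.tsv
s1seqmap stats --endpoints run/endpoints.bed --hotspots run/hotspots.bed \
    --chrom-sizes run/chrom.sizes --out summary.tsv
s1seqmap hdna-scan --fasta run/genome.fa --out motifs.bed
```

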