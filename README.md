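# rotasig

Detection and promoter stratification of the 10-bp purine/pyrimidine
dinucleotide periodicity phased to transcription start sites.

## The problem

Nucleosomes prefer DNA sequences in which certain dinucleotides recur every
~10 bp — one helical turn — because they ease the bending of DNA around the
histone core and fix its *rotational setting* (shifting a nucleosome by 1 bp
rotates the helix ~36°; by a full turn, 360°). Around human transcription
start sites, the first (+1) nucleosome downstream of the TSS sits on a region
where purine–purine (RR = AA, AG, GA, GG) dinucleotide frequencies oscillate
with a 10-bp period *in phase with the TSS*, counter-phased by
pyrimidine–pyrimidine (YY) dinucleotides. The signal is invisible in single
promoters; it emerges only in the average composition profile of thousands of
TSS-aligned sequences, and it concentrates in CpG-island promoters of
lowly-expressed, tissue-specific genes.

`rotasig` implements this analysis as a reusable library for people working
on promoter architecture and nucleosome positioning: the aggregate-profile
spectral statistic, its randomization and bootstrap statistics, and the
promoter stratifications (CpG islands, expression level and breadth, motif
presence, ChIP tag enrichment) that correlate with the signal. A synthetic
cohort generator with recorded generative truth makes every stage testable
without genome downloads.

## The statistic

For a set of N TSS-aligned promoter sequences, let f(i) be the fraction of
sequences whose dinucleotide starting at TSS-relative position i belongs to
the RR class. Over the window covering the +1 nucleosome (positions +40 to
+190; 150 dinucleotide start offsets), the pipeline computes

1. a 3-bp centered moving average of f,
2. mean subtraction and multiplication by a Hamming window
   w(n) = 0.54 − 0.46·cos(2πn/(N−1)),
3. the DFT periodogram P(k) = |X_k|² / N for k = 1 … ⌊N/2⌋,
4. area normalization so Σ_k P(k) = 1,
5. the readout **m₁₀ = P(k) at the bin with period 10 bp** — with 150 points
   this is bin k = 15 exactly.

m₁₀ is the fraction of the profile's spectral power at one helical turn.
Significance comes from a *shift null*: each sequence is offset by a random
1–9 bp at its 5′ end, which preserves composition but destroys the phase
coherence with the TSS. Group comparisons bootstrap promoters with
replacement (the magnitude is not defined per sequence) and compare the
resulting distributions with Wilcoxon rank-sum tests.

## Worked example

```sh
python examples/01_periodicity_detection.py
```

```
cohort: 1000 promoters, planted amplitude 0.15
magnitude at 10 bp (bin period 10 bp): 0.731
shift-null mean 0.405, max 0.606
empirical p = 0.0020
```

A cohort of 1,000 synthetic promoters carries a planted purine-track
modulation of amplitude 0.15 between +40 and +190. The observed m₁₀ = 0.73
means ~73% of the profile's spectral power sits at the 10-bp period (the
Hamming window caps the attainable maximum near 0.73). Every one of the 500
shifted-alignment replicates scores lower, so the empirical p-value is at its
floor 1/501 ≈ 0.002: the periodicity is phased to the TSS. The other
examples stratify a mixed cohort by CpG islands (only the island class shows
the signal), partition genes by expression and tau tissue-specificity, scan
for a planted 7-bp motif against its column-shuffle control, and run the full
pipeline on a written fixture bundle.

The same stages are exposed as a thin CLI (`rotasig extract | profile | psd |
null | cpg | motif | tags | expr | synth | run`).

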