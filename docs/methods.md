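# Methods

This note documents the models, conventions and numerical choices behind
`rotasig`, and what the synthetic cohorts do and do not establish about real
data.

## Coordinates and extraction

Genomic input is 1-based inclusive; `pos` is the coordinate of the first
transcribed base. Internally every TSS-relative position is a 0-based offset
with offset 0 = the first transcribed base and increasing offsets downstream
of transcription; the field's skip-zero display convention (…, −1, +1, …) is
applied only in reports, plots and region parameters expressed in display
coordinates (e.g. the statistic region "+40..+190" is internal offsets
39..188 for dinucleotide starts). Minus-strand records are
reverse-complemented at extraction; windows overrunning a contig edge are
padded with `N`, and `N` is excluded from every frequency denominator (a
dinucleotide contributes only when both bases are non-N), so the sequence
count is constant across positions in reporting.

TSS quality filtering drops records supported by fewer than 2 cDNAs, then
collapses same-chromosome records linked transitively by pairwise distance
≤ 200 bp (single linkage) to the record with maximal support, ties broken to
the smaller coordinate. Single linkage and the tie rule are our
determinism choices; both the clustering distance and the support threshold
are parameters. The operation is idempotent by construction.

## The periodicity statistic

Profile → 3-bp centered moving average (shrinking at edges) → mean
subtraction → Hamming window w(n) = 0.54 − 0.46·cos(2πn/(N−1)) → DFT →
P(k) = |X_k|²/N for k = 1..⌊N/2⌋ → divide by ΣP → read the bin whose period
N/k is closest to 10 bp. Choices worth making explicit:

* **Series length 150** makes 10 bp the exact bin k = 15; the inclusive
  "+40..+190" span is realized as dinucleotide start offsets +40..+189.
  Other periods use nearest-bin readout (no interpolation); the grid
  resolution is available from the periodogram object.
* **Mean subtraction and DC exclusion.** Without them the DC term dominates
  the area normalization and every magnitude shrinks by a data-dependent
  factor. A flag (`include_dc`) restores the DC bin for sensitivity
  analysis.
* **Smooth, then window.** The profile is smoothed before the region is cut
  (with a 1-bp margin so interior smoothing equals full-profile smoothing).
* **Degenerate input.** A zero-variance series cannot be area-normalized;
  a flagged zero-power spectrum is returned and its magnitude is 0.
* **Ceiling.** The Hamming window spreads a pure cosine's power over the
  target bin ± 1 (≈ 0.73 / 0.13 / 0.13), so the normalized magnitude of even
  a noiseless periodic profile is ≈ 0.73, and ≥ 0.99 within ± one bin.

The noise floor of the magnitude for an uninformative profile is not 1/75
(the flat-spectrum value): 3-bp smoothing colors the noise toward low
frequencies, raising the expected value at bin 15 to ≈ 0.03 for cohorts of
~500–1,000 promoters. All significance statements therefore come from
resampling, never from comparing the magnitude to a fixed constant.

## Randomization and bootstrap

**Shift null.** Each sequence independently receives a uniform random 1–9 bp
shift at its 5′ end (implemented by moving its analysis window upstream),
the average RR profile is rebuilt and the magnitude recomputed; 500
iterations by default, per-sequence shifts (a global-shift mode exists for
sensitivity and, as expected, preserves the signal, since the statistic is
phase-invariant under a common translation). A subtlety: the nine phase
vectors e^{2πis/10}, s = 1..9, sum to −1, so a 1–9 bp shift leaves a coherent
residual of 1/9 of the profile amplitude. At realistic aggregate amplitudes
(~0.01) this residual is far below sampling noise and the null collapses to
the noise floor; with strong planted signals (amplitude ≥ 0.2 at n = 1,000)
the residual dominates and the null median remains a substantial fraction of
the observed magnitude — the observed statistic still exceeds every null
draw. A `shift_max = 10` range covers a full period, cancels the residual
exactly, and abolishes the signal completely; the default stays 1–9, the
construction used for the original analyses.

**Bootstrap.** Groups are compared through with-replacement samples of
500–1,000 promoters (2,000–5,000 samplings), recomputing the magnitude on
each sample's average RR profile — RR serves as proxy for the joint RR/YY
signal, which the complementary-strand construction ties together. A
Kolmogorov–Smirnov check against a normal with the sample's moments serves
as the stopping diagnostic for the number of samplings. Distributions are
compared with Wilcoxon rank-sum tests (`scipy.stats.mannwhitneyu`).

**Label permutation.** Association between two binary promoter properties is
tested by shuffling one label vector and counting co-occurrences, with the
(b+1)/(n+1) correction. The count statistic is discrete, so p-values are
uniform only up to the lattice of attainable counts; at n ≈ 2,000 labels the
lattice is fine enough for calibration checks.

Every stochastic operation takes a seed and is reproducible bit for bit;
the pipeline derives per-stage seeds from the run seed via
`numpy.random.SeedSequence(seed).spawn` in stage order.

## CpG islands and expression groups

Promoters are scored by CpG observed/expected over −500..+500
(o/e = #CG·L/(#C·#G), L = non-N length; 0 when #C·#G = 0) and split by a
two-component univariate Gaussian mixture (EM via scikit-learn with
deterministic quantile initialization — means at the 25th/75th percentiles,
equal weights, pooled variance). Components are ordered by mean; the
high-mean component is the island class; ties in posterior break to the
high-mean component, so the assigned posterior is always ≥ 0.5. Fits whose
component separation is under one pooled standard deviation are flagged
degenerate rather than rejected. The same machinery partitions the per-gene
median of log2-scale expression across tissues into low/high classes.

Tissue specificity uses the tau index,
τ(g) = Σᵢ (1 − xᵢ/maxᵢxᵢ)/(n_tissues − 1): 0 for uniform, 1 for
single-tissue expression; all-zero genes are undefined (NaN, warned).
Specificity groups are tertiles by default; explicit score cut-points are
first-class because real cohorts are reported with unequal group sizes.

A note on recoverability: a two-component mixture whose means are 3 sd
apart has a Bayes accuracy of only Φ(1.5) ≈ 93%. Recovery claims of ≥ 95–98%
require the means to sit ~3 sd from the *midpoint*; the expression generator
uses components 4.0 and 8.0 with sd 2/3 accordingly.

## Motif scan

A PWM of width 7 (TRANSFAC-style counts, pseudocount 0.01 per cell before
column normalization) is slid over −500..+500; the score at each start offset
is the product of per-column base probabilities (a local probability, not a
log-odds ratio — a log-probability view is trivial to derive from it). An
offset matches when its score strictly exceeds the arithmetic mean of all
defined scores along the region; a promoter is *selected* when the 0..+40
window holds exactly one match. The mean threshold makes the match rule
scale-free but liberal: for any graded PWM the top-scoring tier always
exceeds the regional mean, so ~0.5 background matches are expected in the
41-offset window and "exactly one" occurs in a nontrivial fraction of random
promoters. Hard-zero matrices (pseudocount 0) implement a strict-consensus
regime where background matches are rare.

The specificity control permutes PWM columns and re-counts the total
occurrences in the window; the observed count is compared to the shuffle
distribution with an empirical p. Permutations that preserve the consensus
string (possible whenever the consensus repeats letters) would leave planted
sites matching and are redrawn; fully degenerate matrices (single-letter
consensus, uniform) keep identity-equivalent shuffles so their invariance
case (p ≈ 1) holds. The regional-mean rule also couples a strong match to
its own threshold — a planted site raises its promoter's regional mean and
suppresses background matches there — which is why the control counts total
occurrences rather than uniquely-matched promoters.

## ChIP tags and enrichment groups

Tags are 5′ ends of mapped reads (BED6: start+1 on '+', end on '−');
forward/reverse densities mark the two boundaries of nucleosome-protected
DNA. Profiles are transcription-oriented (for minus-strand TSSs the genomic
strands swap roles and offsets mirror), averaged per TSS, and smoothed with a
sliding 70-bp window spanning [i−34, i+35] (even widths take the extra
position downstream; the window shrinks at profile edges). Per-TSS tag
counts in +40..+200 (closed, both strands) feed rank-based quantile groups:
group sizes differ by at most one, larger groups take lower ranks, ties
break by stable input order. Per-group bootstrap magnitude distributions are
tested for a monotone trend (Pearson correlation between the group-level
score and the bootstrap magnitudes) and pairwise one-sided rank-sum
comparisons between consecutive and extreme groups.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants the periodicity on the purine/pyrimidine track:
P(purine at i) = p_R + a·cos(2π(i − φ)/T) inside the planted region
(default +40..+190, φ at the region start, T = 10), bases then drawn within
class from background frequencies. Amplitude `a` ∈ [0, 0.5] keeps the track
probability in [0, 1]; the induced RR-profile modulation is ≈ 0.95a, and the
YY profile is automatically counter-phased — one knob controls the joint
signal, as observed. RR-pair peaks sit at the pair midpoint, half a base
upstream of φ, so discrete profile peaks land on φ or φ−1 (mod 10).

Island promoters use GC-rich composition (C+G = 0.64) inside an island
window and carry the planted amplitude; non-island background suppresses G
after C (CpG o/e well below 1, as in bulk genome) and defaults to amplitude
0\. Tags fall at Normal(center ∓ 73, jitter) around the +1-nucleosome dyad
(display +115). Expression is log2-scale with bimodal baselines
(4.0/8.0, sd 2/3, high fraction 0.578) and an on-tissue lift in 3 tissues
graded by specificity group (fractions 0.274/0.494/0.232, lifts
0.3/2.0/8.0); the fixture enrichment table adds a signal-correlated
log2-ratio-style score. Fixture bundles place promoters on random strands in
a spacer-separated FASTA genome and round-trip exactly through the
extraction path; generative truth is recorded in the bundle and recovery
tests read it from there.

What passing tests show: the statistic, nulls, classifiers and pipeline
recover planted structure of the stated form at the stated sizes, with
calibrated type-I behavior under the no-signal configuration. What they do
not show: performance on real promoters — the generator's positions are
independent given the track (no dinucleotide autocorrelation beyond CpG
depletion, no TATA/Inr elements, no GC plateau shape), its amplitudes are
homogeneous within a class, and tag clouds are Gaussian rather than
nucleosome-map-derived. Conclusions about real cohorts require real inputs
through the same interfaces.

## Problem sizes

Default test and demonstration sizes — cohorts of 300–2,000 promoters,
nulls of 300–500 iterations, bootstraps of 150–2,000 samplings of 60–500
sequences — were chosen so the full suite and the acceptance run each finish
in minutes on one CPU while keeping every comparison's power high; all are
parameters, and the paper-scale values (13,622 promoters, 5,000 samplings)
run unchanged.

## Known limitations

* The magnitude is an aggregate-cohort statistic; no per-sequence
  periodicity calling is attempted (individual promoters do not carry a
  detectable signal).
* The regional-mean match rule admits background matches for graded PWMs
  (see above); a density-estimated threshold would be a natural alternative
  and is noted as such, not implemented.
* The CpG feature is univariate o/e over a fixed window; genome-wide island
  segmentation is out of scope.
* Expression matrices are consumed already normalized; probe-level
  processing is out of scope.
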