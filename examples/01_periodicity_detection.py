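"""Detect a 10-bp RR/YY periodicity planted in a synthetic promoter cohort.

Generates 1,000 TSS-aligned promoters whose downstream region (+40..+190)
carries a purine-track modulation of amplitude 0.15, computes the smoothed RR
dinucleotide profile, its normalized periodogram, and the magnitude at the
10-bp bin, and compares the observed magnitude to the 1-9 bp shift null.
"""

import numpy as np

import rotasig as rs

cfg = rs.SynthConfig(n_promoters=1000, upstream=100, downstream=300,
                     planted_amplitude=0.15, seed=42)
seqs, truth = rs.generate_promoters(cfg)

stat = rs.periodicity_stat(seqs)
null = rs.shift_null(seqs, n_iter=500, seed=1)
p = rs.empirical_p(stat.magnitude10, null.values)

print(f"cohort: {len(seqs)} promoters, planted amplitude {truth['planted_amplitude']}")
print(f"magnitude at 10 bp (bin period {stat.period_bin:g} bp): {stat.magnitude10:.3f}")
print(f"shift-null mean {null.values.mean():.3f}, max {null.values.max():.3f}")
print(f"empirical p = {p:.4f}")
print()
print("The observed magnitude is the fraction of the profile's spectral power")
print("at the 10-bp period; beating every shifted-alignment replicate shows")
print("the periodicity is phased to the TSS, not a property of composition.")
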