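"""Split a mixed promoter cohort by CpG-island state and compare periodicity.

A 70/30 island/non-island cohort is generated in which only island promoters
carry the planted 10-bp signal (the configuration observed in real promoter
populations).  A two-component Gaussian mixture on the CpG observed/expected
ratio recovers the split, and bootstrap magnitude distributions separate the
two classes.
"""

import numpy as np

import rotasig as rs
from rotasig.cpg_islands import classify_cpg, cpg_features, fit_cpg_gmm

cfg = rs.SynthConfig(n_promoters=1500, upstream=550, downstream=550,
                     planted_amplitude=0.12, cpg_fraction=0.708, seed=7)
seqs, truth = rs.generate_promoters(cfg)

feats = cpg_features(seqs, window=(-500, 500))
fit = fit_cpg_gmm(feats, seed=0)
table = classify_cpg(fit, feats)
island = table["cpg_island"].to_numpy()

print(f"mixture means (CpG o/e): {fit.means[0]:.2f} / {fit.means[1]:.2f}")
print(f"called islands: {island.sum()} of {len(seqs)} "
      f"({100 * island.mean():.1f}%); generative fraction {cfg.cpg_fraction:.1%}")

is_set = seqs.subset(np.flatnonzero(island))
no_set = seqs.subset(np.flatnonzero(~island))
m_is = rs.periodicity_stat(is_set).magnitude10
m_no = rs.periodicity_stat(no_set).magnitude10
b_is = rs.bootstrap_magnitudes(is_set, sample_size=500, n_boot=2000, seed=1)
b_no = rs.bootstrap_magnitudes(no_set, sample_size=400, n_boot=2000, seed=2)
p = rs.compare_groups(b_no, b_is, alternative="less")

print(f"magnitude at 10 bp: islands {m_is:.3f}, non-islands {m_no:.3f}")
print(f"rank-sum p (non-island < island): {p:.3g}")
print()
print("Only the island class shows the rotational positioning signal; the")
print("non-island magnitude sits at the noise floor of the estimator.")
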