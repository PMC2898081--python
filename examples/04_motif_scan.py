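"""Scan promoters for a 7-bp motif with the sliding local-probability rule.

Plants a synthetic consensus in 30% of promoters at offsets +10..+30, scans
-500..+500 with the product-probability score, calls unique matches in the
0..+40 window, and runs the column-shuffle specificity control.
"""

import rotasig as rs
from rotasig.motif_scan import call_matches, column_shuffle_control, scan_set

cfg = rs.SynthConfig(n_promoters=600, upstream=550, downstream=550,
                     planted_amplitude=0.0,
                     motif=rs.MotifSpec(fraction=0.3), seed=3)
seqs, truth = rs.generate_promoters(cfg)
pwm = cfg.motif.pwm()

scans = scan_set(seqs, pwm, region=(-500, 500))
matched = [m for s in scans for m in call_matches(s, (0, 40))]
planted = set(truth["motif_rows"])
hit_rows = {seqs.source_ids.index(m.tss_id) for m in matched}

print(f"planted instances: {len(planted)} of {len(seqs)} promoters")
print(f"promoters with a unique match in 0..+40: {len(matched)}")
print(f"  of which carry a planted instance: {len(hit_rows & planted)}")

observed, null, p = column_shuffle_control(pwm, seqs, n_shuffles=100, seed=0)
print(f"total occurrences: {observed}; column-shuffle null "
      f"mean {null.values.mean():.0f}, max {null.values.max():.0f}; p = {p:.3g}")
print()
print("Shuffling the matrix columns preserves its composition but destroys")
print("its positional structure: the observed occurrence count exceeding all")
print("shuffles shows the matches are specific, not compositional.")
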