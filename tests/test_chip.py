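"""Tag densities around TSSs, region counts, quantile groups, trend tests."""

import numpy as np
import pandas as pd
import pytest

import rotasig as rs
from rotasig.chip_profiles import (TagSet, periodicity_by_group,
                                   quantile_partition, read_tags_bed,
                                   region_tag_counts, tag_density_profile)
from rotasig.tss_io import TssRecord, TssSet, concat_aligned


def tagset(entries, source="t"):
    chrom, pos, strand = zip(*entries) if entries else ((), (), ())
    return TagSet(np.array(chrom, dtype=object), np.array(pos),
                  np.array(strand, dtype=object), source=source)


ONE_TSS = TssSet([TssRecord("a", "chr1", 5000, "+", 2)])


class TestTagDensity:
    def test_unit_impulse_smoothed_over_70bp(self):
        # forward tag at internal offset +60 -> 1/70 over offsets 25..94
        tags = tagset([("chr1", 5060, "+")])
        prof = tag_density_profile(tags, ONE_TSS, window=(-200, 200), smooth_bp=70)
        nz = prof.offsets[prof.values > 0]
        assert nz[0] == 25 and nz[-1] == 94
        assert np.allclose(prof.values[prof.values > 0], 1 / 70)

    def test_strand_separation(self):
        tags = tagset([("chr1", 5060, "+"), ("chr1", 5200, "-")])
        fwd = tag_density_profile(tags, ONE_TSS, window=(-300, 300), smooth_bp=1)
        rev = tag_density_profile(tags, ONE_TSS, window=(-300, 300),
                                  strand="reverse", smooth_bp=1)
        assert fwd.values.sum() == 1.0 and rev.values.sum() == 1.0
        assert fwd.values[fwd.offsets.tolist().index(60)] == 1.0
        assert rev.values[rev.offsets.tolist().index(200)] == 1.0

    def test_duplicated_tss_gives_identical_profile(self):
        tags = tagset([("chr1", 5060, "+")])
        two = TssSet([TssRecord("a", "chr1", 5000, "+", 2),
                      TssRecord("b", "chr1", 5000, "+", 2)])
        p1 = tag_density_profile(tags, ONE_TSS, window=(-100, 100), smooth_bp=1)
        p2 = tag_density_profile(tags, two, window=(-100, 100), smooth_bp=1)
        # per-TSS averaging: each duplicate sees the same tag, so the
        # averaged profile is unchanged
        assert np.allclose(p1.values, p2.values)

    def test_minus_strand_tss_orientation(self):
        # minus-strand TSS at 5000: genomic 4940 is downstream offset +60;
        # a genomic '-' tag is transcription-forward there
        tags = tagset([("chr1", 4940, "-")])
        tss = TssSet([TssRecord("m", "chr1", 5000, "-", 2)])
        fwd = tag_density_profile(tags, tss, window=(-100, 100), smooth_bp=1)
        assert fwd.values[fwd.offsets.tolist().index(60)] == 1.0

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(4500, 5500, 40)
        strands = rng.choice(["+", "-"], 40)
        plus_tags = tagset([("chr1", int(p), s) for p, s in zip(pos, strands)])
        plus_tss = TssSet([TssRecord("a", "chr1", 5000, "+", 2)])
        flip = {"+": "-", "-": "+"}
        minus_tags = tagset([("chr1", int(2 * 5000 - p), flip[s])
                             for p, s in zip(pos, strands)])
        minus_tss = TssSet([TssRecord("a", "chr1", 5000, "-", 2)])
        for strand in ("forward", "reverse"):
            a = tag_density_profile(plus_tags, plus_tss, (-300, 300), strand, 1)
            b = tag_density_profile(minus_tags, minus_tss, (-300, 300), strand, 1)
            assert np.array_equal(a.values, b.values)

    def test_conservation_of_total_counts(self):
        rng = np.random.default_rng(1)
        tags = tagset([("chr1", int(p), "+") for p in rng.integers(4900, 5200, 55)])
        prof = tag_density_profile(tags, ONE_TSS, window=(-150, 250), smooth_bp=1,
                                   per_tss_average=False)
        assert prof.values.sum() == 55

    def test_smoothing_preserves_area_in_interior(self):
        tags = tagset([("chr1", 5000 + o, "+") for o in range(20, 40)])
        raw = tag_density_profile(tags, ONE_TSS, (-500, 500), smooth_bp=1)
        sm = tag_density_profile(tags, ONE_TSS, (-500, 500), smooth_bp=70)
        assert sm.values.sum() == pytest.approx(raw.values.sum(), rel=1e-9)

    def test_bed_round_trip(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t99\t120\tt1\t0\t+\nchr2\t200\t260\tt2\t0\t-\n")
        ts = read_tags_bed(p)
        assert ts.pos.tolist() == [100, 260]  # 5' ends
        assert ts.strand.tolist() == ["+", "-"]


class TestRegionCounts:
    def test_hand_placed_containment(self):
        # display region +40..+200 = internal offsets 39..199
        tags = tagset([("chr1", 5039, "+"), ("chr1", 5100, "-"),
                       ("chr1", 5199, "+"), ("chr1", 5210, "+")])
        counts = region_tag_counts(tags, ONE_TSS, region=(40, 200))
        assert counts["a"] == 3

    def test_minus_strand_mirror(self):
        # for a '-' TSS at 5000, internal offset +50 is genomic 4950
        tags = tagset([("chr1", 4950, "+"), ("chr1", 5050, "+")])
        tss = TssSet([TssRecord("m", "chr1", 5000, "-", 2)])
        counts = region_tag_counts(tags, tss, region=(40, 200))
        assert counts["m"] == 1

    def test_zero_tags(self):
        counts = region_tag_counts(tagset([]), ONE_TSS)
        assert counts["a"] == 0


class TestQuantilePartition:
    def test_equal_sizes(self):
        s = pd.Series(np.arange(8), index=[f"i{k}" for k in range(8)])
        labels = quantile_partition(s, 4)
        assert labels.value_counts().sort_index().tolist() == [2, 2, 2, 2]

    def test_remainder_goes_to_lower_ranks(self):
        s = pd.Series(np.arange(10))
        sizes = quantile_partition(s, 3).value_counts().sort_index().tolist()
        assert sizes == [4, 3, 3]

    def test_groups_ordered_by_score(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.random(30))
        labels = quantile_partition(s, 3)
        means = [s[labels == g].mean() for g in range(3)]
        assert means[0] < means[1] < means[2]

    def test_all_tied_is_stable(self):
        s = pd.Series(np.zeros(6), index=list("abcdef"))
        labels = quantile_partition(s, 3)
        assert labels.tolist() == [0, 0, 1, 1, 2, 2]
        assert quantile_partition(s, 3).tolist() == labels.tolist()

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            quantile_partition(pd.Series([1.0]), 2)


class TestPeriodicityByGroup:
    def _graded_cohort(self):
        sets, labels = [], {}
        for g, amp in enumerate((0.0, 0.1, 0.25)):
            cfg = rs.SynthConfig(n_promoters=150, upstream=12, downstream=200,
                                 planted_amplitude=amp, seed=50 + g)
            seqs, _ = rs.generate_promoters(cfg)
            seqs.source_ids = [f"g{g}_{s}" for s in seqs.source_ids]
            sets.append(seqs)
            labels.update({sid: g for sid in seqs.source_ids})
        return concat_aligned(sets), pd.Series(labels)

    def test_graded_amplitude_recovers_ordering(self):
        seqs, groups = self._graded_cohort()
        res = periodicity_by_group(seqs, groups, sample_size=100, n_boot=300,
                                   seed=0, min_group_size=100)
        medians = [np.median(res.distributions[g].values) for g in range(3)]
        assert medians[0] < medians[1] < medians[2]
        assert res.trend_r > 0 and res.trend_p < 1e-6
        assert all(p < 1e-6 for p in res.pairwise.values())

    def test_constant_amplitude_trend_centered_on_zero(self):
        # a single replicate can show a large trend of random sign (the two
        # finite cohorts realize slightly different aggregate signals); over
        # replicates the correlation is centered on zero
        rs_values = []
        for rep in range(6):
            sets, labels = [], {}
            for g in range(2):
                cfg = rs.SynthConfig(n_promoters=150, upstream=12, downstream=200,
                                     planted_amplitude=0.1, seed=60 + 2 * rep + g)
                seqs, _ = rs.generate_promoters(cfg)
                seqs.source_ids = [f"g{g}_{s}" for s in seqs.source_ids]
                sets.append(seqs)
                labels.update({sid: g for sid in seqs.source_ids})
            res = periodicity_by_group(concat_aligned(sets), pd.Series(labels),
                                       sample_size=100, n_boot=100, seed=rep,
                                       min_group_size=100)
            rs_values.append(res.trend_r)
        assert min(rs_values) < 0 < max(rs_values)
        assert abs(np.mean(rs_values)) < 0.6

    def test_single_group_rejected(self, make_cohort):
        seqs, _ = make_cohort(n=150, amplitude=0.1, seed=4)
        groups = pd.Series(0, index=seqs.source_ids)
        with pytest.raises(ValueError):
            periodicity_by_group(seqs, groups, min_group_size=100)

    def test_small_group_named_in_error(self, make_cohort):
        seqs, _ = make_cohort(n=150, amplitude=0.1, seed=4)
        groups = pd.Series([0] * 140 + [1] * 10, index=seqs.source_ids)
        with pytest.raises(ValueError, match="1"):
            periodicity_by_group(seqs, groups, min_group_size=100)
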