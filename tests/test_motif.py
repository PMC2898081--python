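"""PWM parsing, product-probability scanning, match calling, shuffle control."""

import numpy as np
import pytest

import rotasig as rs
from rotasig.motif_scan import (Pwm, call_matches, column_shuffle_control,
                                read_pwm, scan_local_probability, scan_set,
                                write_pwm)
from rotasig.tss_io import AlignedSeqSet

from conftest import brute_force_pwm_scores


def point_mass_pwm(consensus, pseudocount=0.0):
    counts = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 10.0
    if pseudocount == 0.0:
        with pytest.warns(UserWarning):
            return Pwm.from_counts(counts, pseudocount=0.0)
    return Pwm.from_counts(counts, pseudocount=pseudocount)


class TestPwmIO:
    def test_round_trip(self, tmp_path):
        counts = np.random.default_rng(0).integers(0, 20, (4, 7)).astype(float)
        p = tmp_path / "m.txt"
        write_pwm(counts, p, id="toy")
        pwm = read_pwm(p, pseudocount=0.01)
        expected = (counts + 0.01) / (counts + 0.01).sum(axis=0)
        assert np.allclose(pwm.probs, expected)
        assert pwm.id == "toy"

    def test_columns_sum_to_one(self, tmp_path):
        p = tmp_path / "m.txt"
        write_pwm(np.random.default_rng(1).random((4, 5)) * 9, p)
        assert np.allclose(read_pwm(p).probs.sum(axis=0), 1.0)

    def test_ragged_matrix_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("P0 A C G T\n01 1 2 3 4\n02 1 2 3\n")
        with pytest.raises(ValueError):
            read_pwm(p)

    def test_zero_counts_with_zero_pseudocount_warn(self):
        pwm = point_mass_pwm("ACGT")
        assert (pwm.probs == 0).any()

    def test_width_minimum(self):
        with pytest.raises(ValueError):
            Pwm(np.full((4, 3), 0.25))


class TestScan:
    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(2)
        pwm = Pwm.from_counts(rng.integers(1, 30, (4, 6)).astype(float))
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGTN"), 80, p=[0.24] * 4 + [0.04]))
            scan = scan_local_probability(seq, pwm, start_offset=0)
            oracle = brute_force_pwm_scores(seq, pwm.probs)
            assert np.allclose(scan.scores, oracle, equal_nan=True, rtol=0, atol=0)

    def test_point_mass_consensus(self):
        pwm = point_mass_pwm("AAAA")
        seq = "CCAAAACCAAAAACC"
        scan = scan_local_probability(seq, pwm, start_offset=0)
        hits = np.flatnonzero(scan.scores == 1.0)
        assert hits.tolist() == [2, 8, 9]
        assert np.all(scan.scores[scan.scores != 1.0] == 0.0)

    def test_uniform_pwm_yields_no_matches(self):
        pwm = Pwm(np.full((4, 5), 0.25))
        seq = "ACGTACGTACGTACGTACGT"
        scan = scan_local_probability(seq, pwm, start_offset=0)
        assert np.allclose(scan.scores, 0.25**5)
        assert call_matches(scan, (0, 15), require_unique=False) == []

    def test_hand_computed_product(self):
        # columns: (A=.9, C=.1), (G=.8, T=.2), (A=.7, G=.3), (T=1.0)
        probs = np.array([
            [0.9, 0.0, 0.7, 0.0],
            [0.1, 0.0, 0.0, 0.0],
            [0.0, 0.8, 0.3, 0.0],
            [0.0, 0.2, 0.0, 1.0],
        ])
        scan = scan_local_probability("AGATC", Pwm(probs), start_offset=0)
        assert scan.scores[0] == pytest.approx(0.9 * 0.8 * 0.7 * 1.0)
        assert scan.scores[1] == 0.0  # G at a (A=.9, C=.1) column

    def test_region_shorter_than_width(self):
        with pytest.raises(ValueError):
            scan_local_probability("ACG", Pwm(np.full((4, 5), 0.25)), 0)

    def test_offsets_are_tss_relative(self):
        pwm = Pwm(np.full((4, 4), 0.25))
        seqs = AlignedSeqSet(["ACGTACGTACGT"], 6, ["s0"])
        scans = scan_set(seqs, pwm, region=(-3, 3))
        # region covers internal offsets -3..2 (display -3..+3), 6 bases
        assert scans[0].offsets.tolist() == [-3, -2, -1]


class TestCallMatches:
    def _scan_with_plant(self, plant_offsets, n_background=60, seed=0):
        rng = np.random.default_rng(seed)
        seq = list("".join(rng.choice(list("ACGT"), n_background)))
        for off in plant_offsets:
            seq[off : off + 4] = "GGCA"
        return scan_local_probability("".join(seq),
                                      point_mass_pwm("GGCA", pseudocount=0.05),
                                      start_offset=0)

    def test_single_plant_reported(self):
        scan = self._scan_with_plant([20])
        matches = call_matches(scan, (0, 40))
        assert len(matches) == 1 and matches[0].offset == 20
        assert matches[0].unique_in_window
        assert matches[0].local_prob > matches[0].regional_mean

    def test_two_plants_excluded_under_uniqueness(self):
        scan = self._scan_with_plant([10, 30])
        assert call_matches(scan, (0, 40), require_unique=True) == []
        assert len(call_matches(scan, (0, 40), require_unique=False)) >= 2

    def test_background_match_rate_low(self):
        # strict-consensus regime (hard-zero columns): only exact consensus
        # windows score above the regional mean, so background promoters
        # almost never report a unique downstream match
        rng = np.random.default_rng(3)
        pwm = point_mass_pwm("GGCAGTG")  # pseudocount 0
        n_matched = 0
        for i in range(300):
            seq = "".join(rng.choice(list("ACGT"), 300))
            if call_matches(scan_local_probability(seq, pwm, -100), (0, 40)):
                n_matched += 1
        assert n_matched / 300 < 0.10


class TestShuffleControl:
    def test_preserves_column_multiset(self):
        rng = np.random.default_rng(4)
        pwm = Pwm.from_counts(rng.integers(0, 9, (4, 7)).astype(float))
        shuffled = pwm.shuffled_columns(np.random.default_rng(0))
        orig = sorted(map(tuple, pwm.probs.T.round(12).tolist()))
        shuf = sorted(map(tuple, shuffled.probs.T.round(12).tolist()))
        assert orig == shuf

    def test_planted_cohort_beats_all_shuffles(self, make_cohort):
        # full-width scan region: the regional-mean threshold needs the long
        # background stretch for the occurrence counts to be comparable
        # between original and column-shuffled matrices
        cfg = rs.SynthConfig(n_promoters=300, upstream=550, downstream=550,
                             planted_amplitude=0.0,
                             motif=rs.MotifSpec(fraction=0.5), seed=12)
        seqs, truth = rs.generate_promoters(cfg)
        pwm = cfg.motif.pwm()
        observed, null, p = column_shuffle_control(pwm, seqs, n_shuffles=50, seed=0)
        assert observed > null.values.max()
        assert p == 1 / 51

    def test_uniform_pwm_invariant_under_shuffle(self, make_cohort):
        seqs, _ = make_cohort(n=100, amplitude=0.0, seed=13, upstream=60,
                              downstream=80)
        pwm = Pwm(np.full((4, 5), 0.25))
        observed, null, p = column_shuffle_control(
            pwm, seqs, n_shuffles=20, seed=0, region=(-60, 80),
            region_of_interest=(0, 40))
        assert np.all(null.values == observed)
        assert p == 1.0

    def test_seed_determinism(self, make_cohort):
        seqs, _ = make_cohort(n=80, amplitude=0.0, seed=14, upstream=60,
                              downstream=80)
        pwm = Pwm.from_counts(np.random.default_rng(5).integers(0, 9, (4, 6)).astype(float))
        kw = dict(n_shuffles=10, seed=3, region=(-60, 80))
        r1 = column_shuffle_control(pwm, seqs, **kw)
        r2 = column_shuffle_control(pwm, seqs, **kw)
        assert np.array_equal(r1[1].values, r2[1].values) and r1[2] == r2[2]
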