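"""sRNA shuffling, Allen scoring, target scanning, and the empirical-null test."""

import numpy as np
import pandas as pd
import pytest

from endkit.core_io import revcomp
from endkit.endcut import (
    _PENALTY,
    _encode,
    _position_weights,
    _revcomp_codes,
    _scan_batch,
    allen_score,
    combine_and_adjust,
    empirical_pvalues,
    fisher_combine,
    predict_targets,
    rptm,
    shuffle_srna,
    site_fold_change,
)
from endkit.endmask import TranscriptTrack


class TestShuffle:
    def test_single_permutation_class(self):
        assert set(shuffle_srna("A" * 16, 10, seed=0)) == {"A" * 16}

    def test_composition_preserved(self):
        seq = "ACGTACGTACGGTTACGATCG"
        for s in shuffle_srna(seq, 50, seed=1):
            assert sorted(s) == sorted(seq)

    def test_deterministic_under_seed(self):
        seq = "ACGTACGTACGGTTACGATCG"
        assert shuffle_srna(seq, 20, seed=7) == shuffle_srna(seq, 20, seed=7)
        assert shuffle_srna(seq, 20, seed=7) != shuffle_srna(seq, 20, seed=8)

    def test_short_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            shuffle_srna("AAAA", 5, seed=0)


class TestAllenScore:
    def test_perfect_duplex(self):
        assert allen_score(["match"] * 21) == 0.0

    def test_gu_in_core_is_doubled(self):
        states = ["match"] * 21
        states[4] = "gu"  # sRNA position 5, inside 2-13
        assert allen_score(states) == 1.0

    def test_mismatch_outside_core_not_doubled(self):
        states = ["match"] * 21
        states[19] = "mismatch"  # position 20
        assert allen_score(states) == 1.0

    def test_bulge_and_target_bulge(self):
        states = ["match"] * 21
        states[0] = "bulge"  # position 1, outside core
        assert allen_score(states) == 1.0
        assert allen_score(["match"] * 21, target_bulges=[5]) == 2.0

    def test_unknown_state_is_an_error(self):
        with pytest.raises(ValueError):
            allen_score(["match", "banana"])


def scan_oracle(srna, target):
    """Exhaustive per-offset enumeration of ungapped and single-bulge
    duplexes, independent of the compiled kernel."""
    m = len(srna)
    rc = _revcomp_codes(_encode(srna))
    t = _encode(target)
    w = _position_weights(m)
    qstar = m - 10
    L = len(target)

    def pen(q, ti):
        if ti < 0 or ti >= L:
            return 1e3 * float(w[q])
        return float(_PENALTY[rc[q], t[ti]] * w[q])

    best = {}
    for o in range(L - m + 1):
        cands = [(sum(pen(q, o + q) for q in range(m)), o + qstar)]
        for j in range(1, m):
            s = (sum(pen(q, o + q) for q in range(j)) + w[j]
                 + sum(pen(q, o + q + 1) for q in range(j, m)))
            cands.append((s, o + qstar + 1 if qstar >= j else o + qstar))
        for j in range(m):
            s = (sum(pen(q, o + q) for q in range(j)) + w[j]
                 + sum(pen(q, o + q - 1) for q in range(j + 1, m)))
            cands.append((s, o + qstar - 1 if qstar > j else o + qstar))
        smin = min(c[0] for c in cands)
        best[o] = (smin, {cl for s, cl in cands if abs(s - smin) < 1e-4})
    return best


class TestPredictTargets:
    def test_perfect_complement_site(self):
        srna = "ACGATGAAGTGGTTAGCTTCA"  # 21 nt
        target = "T" * 30 + revcomp(srna) + "A" * 30
        sites = predict_targets("mir", srna, {"tx": target}, max_score=0.0)
        (s,) = [x for x in sites if x.allen_score == 0.0]
        assert s.start == 30
        # scissile bond between duplex positions 10/11: 3' fragment starts
        # opposite sRNA position 10
        assert s.cleavage_offset == 30 + 21 - 10
        assert s.states == ["match"] * 21

    def test_no_qualifying_window_is_empty(self):
        srna = "ACGATGAAGTGGTTAGCTTCA"
        assert predict_targets("mir", srna, {"tx": "A" * 80}, max_score=3.0) == []

    def test_single_core_mismatch_scores_two(self):
        srna = "ACGATGAAGTGGTTAGCTTCA"
        m = len(srna)
        site = list(revcomp(srna))
        # mutate the target base opposite sRNA position 5 (core, weight 2)
        p = 5
        srna_base = srna[p - 1]
        banned = {"ACGT"[("TGCA").index(srna_base)]}
        wc = {"A": "T", "C": "G", "G": "C", "T": "A"}[srna_base]
        wobble = {"G": "T", "T": "G"}.get(srna_base, "")
        repl = next(b for b in "ACGT" if b not in {wc, wobble})
        site[m - p] = repl
        target = "T" * 25 + "".join(site) + "A" * 25
        sites = predict_targets("mir", srna, {"tx": target}, max_score=2.0)
        hit = [x for x in sites if x.start == 25]
        assert hit and hit[0].allen_score == pytest.approx(2.0)

    @pytest.mark.parametrize("trial", range(6))
    def test_scanner_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(trial)
        srna = "".join(rng.choice(list("ACGT"), int(rng.integers(19, 25))))
        target = "".join(rng.choice(list("ACGT"), 70))
        if trial % 2 == 0:
            pos = int(rng.integers(0, 70 - len(srna)))
            target = target[:pos] + revcomp(srna) + target[pos + len(srna):]
        vv, oo, sc, cl, kind = _scan_batch(
            _revcomp_codes(_encode(srna))[None, :], _encode(target), max_score=1e6
        )
        expected = scan_oracle(srna, target)
        assert len(oo) == len(expected)
        for o, s, c in zip(oo, sc, cl):
            es, ecls = expected[int(o)]
            assert float(s) == pytest.approx(es, abs=1e-6)
            assert int(c) in ecls


class TestFoldChange:
    def _track(self, length, entries):
        tt = TranscriptTrack(transcript_id="t", length=length)
        for off, w in entries:
            tt.add(off, w)
        return tt

    def test_site_over_flank(self):
        tt = self._track(300, [(150, 9.0), (120, 4.0)])
        assert site_fold_change(tt, 150, window=50) == pytest.approx(2.0)

    def test_empty_track_is_one(self):
        tt = self._track(300, [])
        assert site_fold_change(tt, 150, window=50) == pytest.approx(1.0)

    def test_exclusion_zone_spares_adjacent_spike(self):
        tt = self._track(300, [(150, 5.0), (151, 50.0)])
        assert site_fold_change(tt, 150, window=50) == pytest.approx(6.0)

    def test_window_clipped_at_bounds(self):
        tt = self._track(40, [(2, 3.0), (30, 7.0)])
        # site at 2: left flank is clipped; right flank reaches 30 only for w=50
        assert site_fold_change(tt, 2, window=50) == pytest.approx(4.0 / 8.0)
        assert site_fold_change(tt, 2, window=20) == pytest.approx(4.0 / 1.0)


class TestEmpiricalPvalues:
    def test_extreme_rank(self):
        nulls = np.arange(999, dtype=float)
        p_fc, p_as = empirical_pvalues([1e9], [-1.0], nulls, nulls)
        assert p_fc[0] == pytest.approx(1 / 1000)
        assert p_as[0] == pytest.approx(1 / 1000)

    def test_median_observation(self):
        nulls = np.linspace(0, 1, 1001)
        p_fc, _ = empirical_pvalues([0.5], [0.0], nulls, nulls)
        assert p_fc[0] == pytest.approx(0.5, abs=0.01)

    def test_small_counting_case(self):
        p_fc, _ = empirical_pvalues([2.0], [0.0], np.array([1.0, 1.0, 2.0, 3.0]),
                                    np.array([1.0]))
        assert p_fc[0] == pytest.approx(0.6)

    def test_empty_null_is_an_error(self):
        with pytest.raises(ValueError):
            empirical_pvalues([1.0], [1.0], np.empty(0), np.empty(0))


class TestCombineAndAdjust:
    def test_fisher_identity_at_one(self):
        assert fisher_combine(np.array([1.0]), np.array([1.0]))[0] == pytest.approx(1.0)

    def test_fisher_hand_checked_value(self):
        # X = -2(ln 0.05 + ln 0.05) = 11.9829; chi-square(4) tail = 0.01748
        p = fisher_combine(np.array([0.05]), np.array([0.05]))[0]
        assert p == pytest.approx(0.0174787, abs=1e-6)

    def test_bh_on_uniform_ranks_is_identity(self):
        calls = pd.DataFrame(
            {
                "p_fc": [0.1] * 6, "p_as": [0.1] * 6,
                "fc50": [2.0] * 6, "rptm": [5.0] * 6,
            }
        )
        out = combine_and_adjust(calls)
        np.testing.assert_allclose(out["p_adjusted"], out["p_combined"])

    def test_significance_gates(self):
        base = {"p_fc": 1e-5, "p_as": 1e-5}
        calls = pd.DataFrame(
            [
                {**base, "fc50": 5.0, "rptm": 5.0},   # all gates pass
                {**base, "fc50": 1.0, "rptm": 5.0},   # FC not > 1
                {**base, "fc50": 5.0, "rptm": 0.5},   # under 1 RPTM
                {"p_fc": 0.9, "p_as": 0.9, "fc50": 5.0, "rptm": 5.0},  # not significant
            ]
        )
        out = combine_and_adjust(calls)
        assert list(out["significant"]) == [True, False, False, False]


class TestRptm:
    @pytest.mark.parametrize("reads,total,expected", [(1, 1e7, 1.0), (5, 5e7, 1.0)])
    def test_scaling(self, reads, total, expected):
        assert rptm(reads, total) == pytest.approx(expected)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            rptm(1, 0)


class TestOrderInvariance:
    def test_transcript_order_does_not_change_calls(self):
        from endkit.endcut import run_endcut

        rng = np.random.default_rng(4)
        srna = "".join(rng.choice(list("ACGT"), 21))
        seqs = {}
        tracks = {}
        for i in range(4):
            s = "".join(rng.choice(list("ACGT"), 300))
            if i == 1:
                s = s[:100] + revcomp(srna) + s[100 + 21:]
            tid = f"t{i}"
            seqs[tid] = s
            tt = TranscriptTrack(transcript_id=tid, length=300)
            for p in rng.integers(0, 300, size=12):
                tt.add(int(p), 1.0)
            tracks[tid] = tt
        kw = dict(total_transcriptome_reads=1e4, n_shuffles=50, seed=3)
        a = run_endcut({"m": srna}, seqs, tracks, **kw)
        rev_seqs = dict(reversed(list(seqs.items())))
        rev_tracks = dict(reversed(list(tracks.items())))
        b = run_endcut({"m": srna}, rev_seqs, rev_tracks, **kw)
        key = ["srna", "transcript", "cleavage_offset"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )
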