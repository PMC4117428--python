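import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nucpos.alphabet import encode
from nucpos.config import SignalConfig
from nucpos.patterns import dinucleotide_profile
from nucpos.predict import (
    PatternSet,
    dinucleotide_shuffle,
    evaluate_precision,
    pattern_correlation_track,
    predict_dyads,
    random_baseline,
)
from nucpos.simulate import _emit_footprints


@pytest.fixture(scope="module")
def trained_sets(mnase_profile):
    return [
        PatternSet.train(mnase_profile, ["AA", "TT", "AT"], "{AA,TT,AT}"),
        PatternSet.train(mnase_profile, ["GG", "CC", "GC"], "{GG,CC,GC}"),
    ]


@pytest.fixture(scope="module")
def eval_windows(default_genome):
    """2000 evaluation windows, 313 bp, true dyad at the center."""
    genome, truth = default_genome["genome"], default_genome["truth"]
    pick = truth.sample(2200, random_state=7)
    wins = []
    for rec in pick.itertuples(index=False):
        seq = genome.sequences[rec.chrom]
        lo = rec.dyad_pos - 156
        if lo >= 0 and lo + 313 <= len(seq):
            wins.append(encode(seq[lo:lo + 313]))
    return np.vstack(wins[:2000])


def _null_windows(n, width, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    return rng.choice(4, size=(n, width),
                      p=[at, gc / 2, gc / 2, at]).astype(np.int8)


def _consensus_footprint():
    """Deterministic footprint matching the planted signal's phasing:
    member dinucleotides of {AA,TT,AT} exactly at WW-phased steps, of
    {GG,CC,GC} at SS-phased steps, non-member AC/CA alternation elsewhere."""
    from nucpos.simulate import phased_steps
    ww, ss = phased_steps(SignalConfig())
    seq = ["A"]
    for s in range(146):
        prev = seq[-1]
        if ww[s]:
            seq.append(prev if prev in "AT" else "A")
        elif ss[s]:
            seq.append(prev if prev in "GC" else "G")
        else:
            seq.append("C" if prev != "C" else "A")
    return encode("".join(seq))


def _alternating(n, start="A"):
    out = []
    cur = start
    for _ in range(n):
        out.append(cur)
        cur = "C" if cur != "C" else "A"
    return encode("".join(out))


class TestPatternSet:
    def test_iupac_expansion(self, mnase_profile):
        ps = PatternSet.train(mnase_profile, ["WW"], "{WW}")
        assert ps.members == frozenset({"AA", "AT", "TA", "TT"})
        assert ps.template.shape == (146,)

    def test_template_is_sum_of_member_rows(self, mnase_profile):
        ps = PatternSet.train(mnase_profile, ["AA", "TT"])
        np.testing.assert_allclose(
            ps.template, mnase_profile.track({"AA", "TT"}))


class TestCorrelationTrack:
    def test_values_bounded(self, trained_sets, eval_windows):
        track = pattern_correlation_track(eval_windows[0], trained_sets[0])
        finite = track[np.isfinite(track)]
        assert track.size == 313 - 147 + 1
        assert (np.abs(finite) <= 1.0).all()

    @pytest.mark.parametrize("offset", [10, 37, 60, 99])
    def test_planted_consensus_peaks_at_planted_offset(self, trained_sets,
                                                       offset):
        """A footprint built to match the template's consensus phasing is
        found by the correlation argmax at the planted offset."""
        fp = _consensus_footprint()
        seq = np.concatenate([_alternating(offset), fp, _alternating(60)])
        track = pattern_correlation_track(seq, trained_sets[0])
        # the template is trained from jittered reads whose dyad sits ~1.5
        # bp right of the window center, hence the +/-3 bp slack
        assert abs(int(np.nanargmax(track)) - offset) <= 3

    def test_flat_template_errors(self):
        flat = PatternSet("flat", frozenset({"AA"}), np.ones(146), 1)
        with pytest.raises(ValueError, match="flat"):
            pattern_correlation_track("ACGT" * 50, flat)

    def test_zero_variance_indicator_is_missing(self, trained_sets):
        # poly-A: the member indicator has zero variance for both sets
        # (identically 1 for {AA,TT,AT}, 0 for {GG,CC,GC}) -> missing
        for ps in trained_sets:
            track = pattern_correlation_track("A" * 200, ps)
            assert np.isnan(track).all()

    def test_short_sequence_errors(self, trained_sets):
        with pytest.raises(ValueError, match="shorter"):
            pattern_correlation_track("ACGT" * 10, trained_sets[0])


class TestPredictDyads:
    def test_placement_range_is_one_footprint(self, trained_sets):
        wins = _null_windows(5, 313, 1)
        res = predict_dyads(wins, trained_sets[:1])
        assert res.placement_range == 147
        dyads = res.table[f"dyad_{trained_sets[0].name}"]
        center = 156
        assert (np.abs(dyads - center) <= 73).all()

    def test_planted_consensus_center_predicted(self, trained_sets):
        fp = _consensus_footprint()
        win = np.concatenate([_alternating(83), fp, _alternating(83)])
        res = predict_dyads(win[None, :], trained_sets)
        err = abs(int(res.table["dyad_combined"].iloc[0]) -
                  int(res.table["true_dyad"].iloc[0]))
        assert err <= 3

    def test_all_placements_missing_window_skipped(self, trained_sets):
        win = np.zeros((1, 313), dtype=np.int8)  # poly-A window
        res = predict_dyads(win, trained_sets)
        assert res.n_skipped == 1
        assert len(res.table) == 0

    def test_null_windows_uniform_over_placements(self, trained_sets):
        """On i.i.d. windows predicted dyads are uniform over the placement
        range (chi-square GOF, p > 0.01)."""
        wins = _null_windows(6000, 313, 3)
        res = predict_dyads(wins, trained_sets[:1])
        dyads = res.table[f"dyad_{trained_sets[0].name}"].to_numpy()
        counts = np.bincount(dyads - 83, minlength=147)
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01

    def test_union_hit_beats_baseline(self, trained_sets, eval_windows):
        """The {AA,TT,AT}+{GG,CC,GC} combination detects nucleosomes at
        +/-15 bp well above the 31/147 random expectation."""
        res = predict_dyads(eval_windows, trained_sets)
        ev = evaluate_precision(res)
        row = ev[ev["tolerance"] == 15].iloc[0]
        assert row["hit_union"] >= 1.5 * row["random_baseline"]
        for name in res.pset_names:
            assert row[f"hit_{name}"] > row["random_baseline"]

    def test_null_signal_hits_at_random_baseline(self, trained_sets):
        """With no planted signal the +/-15 bp hit fraction sits within 3
        binomial SD of 31/147."""
        wins = _null_windows(800, 313, 5)
        res = predict_dyads(wins, trained_sets)
        ev = evaluate_precision(res)
        row = ev[ev["tolerance"] == 15].iloc[0]
        p = 31 / 147
        sd = np.sqrt(p * (1 - p) / len(res.table))
        assert abs(row["hit_combined"] - p) <= 3 * sd


class TestEvaluatePrecision:
    def test_analytic_baselines(self):
        assert random_baseline(15) == pytest.approx(31 / 147)
        assert random_baseline(15) == pytest.approx(0.2109, abs=5e-4)
        assert random_baseline(36) == pytest.approx(73 / 147)

    def test_perfect_predictor_hits_everything(self, trained_sets,
                                               eval_windows):
        res = predict_dyads(eval_windows[:100], trained_sets)
        res.table["dyad_combined"] = res.table["true_dyad"]
        ev = evaluate_precision(res, tolerances=(0, 15, 36))
        assert (ev["hit_combined"] == 1.0).all()

    def test_hit_fraction_monotone_in_tolerance(self, trained_sets,
                                                eval_windows):
        res = predict_dyads(eval_windows, trained_sets)
        ev = evaluate_precision(res, tolerances=(5, 15, 36, 73))
        for col in ["hit_combined", "hit_union", "hit_both"]:
            assert ev[col].is_monotonic_increasing

    def test_saturation_at_tol_73(self, trained_sets, eval_windows):
        """Any predictor confined to a one-footprint placement range hits
        everything at +/-73 bp."""
        res = predict_dyads(eval_windows[:200], trained_sets)
        ev = evaluate_precision(res, tolerances=(73,))
        assert ev.iloc[0]["hit_combined"] == 1.0
        assert ev.iloc[0]["hit_union"] == 1.0

    def test_union_between_max_and_sum(self, trained_sets, eval_windows):
        res = predict_dyads(eval_windows, trained_sets)
        ev = evaluate_precision(res)
        for _, row in ev.iterrows():
            hits = [row[f"hit_{n}"] for n in res.pset_names]
            assert row["hit_union"] >= max(hits) - 1e-12
            assert row["hit_union"] <= sum(hits) + 1e-12
            assert row["hit_both"] == pytest.approx(
                sum(hits) - row["hit_union"], abs=1e-12)


class TestShuffle:
    def test_homopolymer_flagged_noop(self):
        out = dinucleotide_shuffle("AAAA", seed=0)
        assert out.sequence == "AAAA"
        assert not out.changed

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=120),
           st.integers(0, 1000))
    def test_composition_conserved_exactly(self, seq, seed):
        from nucpos.alphabet import dinucleotide_codes
        out = dinucleotide_shuffle(seq, seed=seed)
        a = np.bincount(dinucleotide_codes(encode(seq)), minlength=16)
        b = np.bincount(dinucleotide_codes(encode(out.sequence)),
                        minlength=16)
        np.testing.assert_array_equal(a, b)
        assert out.sequence[0] == seq[0] and out.sequence[-1] == seq[-1]

    def test_shuffles_differ_from_original(self, default_genome):
        seq = default_genome["genome"].sequences["chr_AT_rich"][5000:5313]
        n = 300
        distinct = sum(dinucleotide_shuffle(seq, seed=s).changed
                       for s in range(n))
        assert distinct / n >= 0.99

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("ACG")
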