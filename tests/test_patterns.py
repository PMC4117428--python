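import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucpos.alphabet import DINUCLEOTIDES, RC_PERMUTATION, encode
from nucpos.config import APOPTOTIC_PROTOCOL, SignalConfig
from nucpos.io import GenomeSequence, revcomp
from nucpos.patterns import (
    DinucleotideProfile,
    dinucleotide_profile,
    estimate_dyad_offset,
    extract_aligned_windows,
    fragment_length_stats,
    kmer_positional_profile,
    recenter_reads,
)
from nucpos.periodicity import profile_lag
from nucpos.simulate import _emit_footprints, simulate_protocol_reads

dna = st.text(alphabet="ACGT", min_size=12, max_size=40)


def _reads(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "fragment_len",
                       "strand"])


class TestExtractWindows:
    def test_plus_strand_window_is_genome_slice(self):
        g = GenomeSequence({"c": "ACGTACGTACGTACGTACGT"})
        reads = _reads([("c", 10, 14, "r", 8, "+")])
        w = extract_aligned_windows(reads, g, L=8)
        assert "".join("ACGTN"[c] for c in w[0]) == g.sequences["c"][10:18]

    def test_minus_strand_window_is_revcomp_ending_at_five_prime(self):
        g = GenomeSequence({"c": "ACGTACGTACGTACGTACGT"})
        reads = _reads([("c", 12, 16, "r", 8, "-")])
        w = extract_aligned_windows(reads, g, L=8)
        assert "".join("ACGTN"[c] for c in w[0]) == \
            revcomp(g.sequences["c"][16 - 8:16])

    def test_out_of_range_windows_dropped_and_counted(self):
        g = GenomeSequence({"c": "ACGTACGT"})
        reads = _reads([("c", 0, 4, "a", 8, "+"), ("c", 6, 8, "b", 8, "+")])
        w = extract_aligned_windows(reads, g, L=6)
        assert w.shape[0] == 1
        assert extract_aligned_windows.last_n_dropped == 1

    def test_empty_read_set_errors(self):
        g = GenomeSequence({"c": "ACGT" * 50})
        with pytest.raises(ValueError, match="empty"):
            extract_aligned_windows(_reads([]), g)

    def test_window_start_tracks_planted_dyad(self, default_genome,
                                              mnase_reads):
        """Mean distance from window start to the true dyad equals the
        fragment-geometry expectation (length/2 up to rounding) +/- 1 bp."""
        genome = default_genome["genome"]
        truth = default_genome["truth"]
        dyads = {c: g["dyad_pos"].to_numpy()
                 for c, g in truth.groupby("chrom")}
        sub = mnase_reads.head(5000)
        starts = np.where(sub["strand"] == "-", 0, 1)
        dists = []
        for rec in sub.itertuples(index=False):
            anchor = rec.start if rec.strand == "+" else rec.end - 1
            pos = dyads[rec.chrom]
            d = pos[np.argmin(np.abs(pos - anchor))]
            dists.append(abs(d - anchor))
        assert abs(np.mean(dists) - 150 / 2) <= 1.0


class TestDinucleotideProfile:
    def test_single_sequence_counts(self):
        w = np.vstack([encode("AATT"), encode("AATT")])
        prof = dinucleotide_profile(w)
        assert prof.freq[DINUCLEOTIDES.index("AA"), 0] == 1.0
        assert prof.freq[DINUCLEOTIDES.index("AT"), 1] == 1.0
        assert prof.freq[DINUCLEOTIDES.index("TT"), 2] == 1.0
        assert prof.freq.sum() == pytest.approx(3.0)

    def test_columns_sum_to_one(self, mnase_profile):
        sums = mnase_profile.freq.sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_n_steps_excluded_from_normalization(self):
        w = np.vstack([encode("ANTT"), encode("AATT")])
        prof = dinucleotide_profile(w)
        # steps 0 and 1 have a single valid observation each
        assert prof.n_valid.tolist() == [1, 1, 2]
        np.testing.assert_allclose(prof.freq.sum(axis=0), 1.0)

    def test_reverse_complement_symmetry_exact(self, rng):
        codes = rng.integers(0, 4, size=(300, 30)).astype(np.int8)
        rc = (3 - codes)[:, ::-1]
        prof = dinucleotide_profile(codes)
        prof_rc = dinucleotide_profile(rc)
        np.testing.assert_array_equal(
            prof_rc.freq, prof.freq[RC_PERMUTATION][:, ::-1])

    def test_invariant_to_order_and_duplication(self, rng):
        codes = rng.integers(0, 4, size=(100, 20)).astype(np.int8)
        p1 = dinucleotide_profile(codes)
        p2 = dinucleotide_profile(codes[::-1])
        p3 = dinucleotide_profile(np.vstack([codes, codes]))
        np.testing.assert_allclose(p1.freq, p2.freq)
        np.testing.assert_allclose(p1.freq, p3.freq)

    def test_tsv_round_trip(self, tmp_path, mnase_profile):
        p = tmp_path / "prof.tsv"
        mnase_profile.to_tsv(p)
        back = DinucleotideProfile.from_tsv(p)
        assert back.n_sequences == mnase_profile.n_sequences
        assert back.dyad_step == mnase_profile.dyad_step
        np.testing.assert_allclose(back.freq, mnase_profile.freq, atol=1e-12)

    def test_counter_phased_tracks_recover_planted_offset(self,
                                                          mnase_profile):
        """AA+TT and GG+CC rows are counter-phased by the planted 5 bp."""
        lag, _ = profile_lag(mnase_profile.track({"AA", "TT"}),
                             mnase_profile.track({"GG", "CC"}), max_lag=20)
        assert abs(lag) == 5


class TestKmerProfile:
    def test_homopolymer_all_ones(self):
        w = np.vstack([encode("AAAA")] * 3)
        prof = kmer_positional_profile(w, ["AA"])
        np.testing.assert_allclose(prof.tracks["AA"], 1.0)

    def test_invalid_kmer_rejected(self):
        w = np.vstack([encode("ACGTACGT")])
        with pytest.raises(ValueError):
            kmer_positional_profile(w, ["QQ"])
        with pytest.raises(ValueError):
            kmer_positional_profile(w, ["ACGTA"])

    def test_tetramer_bounded_by_trimers(self, rng):
        codes = rng.integers(0, 4, size=(400, 25)).astype(np.int8)
        prof = kmer_positional_profile(codes, ["GGC", "GCC", "GGCC"])
        g4 = prof.tracks["GGCC"]
        n4 = g4.size
        assert (g4 <= prof.tracks["GGC"][:n4] + 1e-12).all()
        assert (g4 <= prof.tracks["GCC"][1:n4 + 1] + 1e-12).all()

    def test_trinucleotide_peaks_coincide_with_dinucleotide_peaks(self):
        """AAT/ATT maxima sit on AA/TT maxima of planted footprints."""
        rng = np.random.default_rng(11)
        fp = _emit_footprints(30000, SignalConfig(),
                              np.array([0.3, 0.2, 0.2, 0.3]), rng)
        prof = kmer_positional_profile(fp, ["AA", "TT", "AAT", "ATT"])
        central = slice(40, 100)  # away from envelope extremes

        def local_peak(track):
            return 40 + int(np.nanargmax(track[central]))

        aa_peak = local_peak(prof.tracks["AA"])
        assert abs(local_peak(prof.tracks["AAT"]) - aa_peak) <= 1 or \
            abs(local_peak(prof.tracks["ATT"]) -
                local_peak(prof.tracks["TT"])) <= 1


class TestDyadOffset:
    def test_symmetric_placement_recovers_half_fragment(self):
        """Jitter-free fragments of length 2d+1 put the dyad exactly d
        from either 5' end."""
        rng = np.random.default_rng(21)
        sig = SignalConfig()
        fp = _emit_footprints(4000, sig, np.array([0.25] * 4), rng)
        d = 75
        rows = []
        seqs = {}
        for i, f in enumerate(fp):
            pad_l = rng.integers(0, 4, 40).astype(np.int8)
            pad_r = rng.integers(0, 4, 40).astype(np.int8)
            codes = np.concatenate([pad_l, f, pad_r])
            seqs[f"c{i}"] = "".join("ACGTN"[c] for c in codes)
            dyad = 40 + 73
            start, end = dyad - d, dyad + d + 1  # length 2d+1
            strand = "+" if i % 2 == 0 else "-"
            rows.append((f"c{i}", start, end, f"r{i}", end - start, strand))
        genome = GenomeSequence(seqs)
        off, _ = estimate_dyad_offset(_reads(rows), genome,
                                      range(60, 91), L=147)
        assert abs(off - d) <= 1

    def test_mnase_geometry_recovers_75(self, default_genome, mnase_reads):
        off, _ = estimate_dyad_offset(mnase_reads, default_genome["genome"])
        assert abs(off - 75) <= 2

    def test_apoptotic_geometry_recovers_85(self, default_genome,
                                            apoptotic_reads):
        off, _ = estimate_dyad_offset(apoptotic_reads,
                                      default_genome["genome"])
        assert abs(off - 85) <= 2

    def test_single_strand_errors(self, mnase_reads, default_genome):
        plus_only = mnase_reads[mnase_reads["strand"] == "+"]
        with pytest.raises(ValueError, match="strand"):
            estimate_dyad_offset(plus_only, default_genome["genome"])


class TestFragmentLengths:
    def test_constant_lengths(self):
        reads = _reads([("c", 0, 120, f"f{i}/1", 170, "+")
                        for i in range(5)])
        stats = fragment_length_stats(reads)
        assert stats["mean"] == 170.0
        assert stats["sd"] == 0.0

    def test_apoptotic_mean_170(self, apoptotic_reads):
        stats = fragment_length_stats(apoptotic_reads)
        assert abs(stats["mean"] - 170.0) < 1.0

    def test_length_strata_shift_peaks_by_half(self, default_genome):
        """Two strata 10 bp apart in fragment length shift the 5'-anchored
        pattern peaks by 5 bp."""
        proto = dataclasses.replace(APOPTOTIC_PROTOCOL, fragment_sd_bp=8.0,
                                    reads_per_nucleosome_mean=6.0)
        reads = simulate_protocol_reads(
            default_genome["genome"], default_genome["truth"], proto, seed=4)
        stats = fragment_length_stats(
            reads, default_genome["genome"],
            {"short": (164, 167), "long": (174, 177)})
        short = stats["profiles"]["short"].track("WW")
        long_ = stats["profiles"]["long"].track("WW")
        right = slice(90, 146)
        lag, _ = profile_lag(short[right], long_[right], max_lag=8)
        assert abs(abs(lag) - 5) <= 1


class TestRecenter:
    def test_centered_profile_puts_dyad_midwindow(self, default_genome,
                                                  mnase_reads):
        genome = default_genome["genome"]
        centered = recenter_reads(mnase_reads, 75)
        off, _ = estimate_dyad_offset(centered, genome, range(60, 91))
        assert abs(off - 73) <= 2


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.lists(dna.filter(lambda s: len(s) >= 12), min_size=2, max_size=8))
def test_profile_rc_symmetry_property(seqs):
    """Profile of an RC'd window set is the row-permuted, column-reversed
    profile, for arbitrary same-length window sets."""
    L = min(len(s) for s in seqs)
    codes = np.vstack([encode(s[:L]) for s in seqs])
    rc = np.vstack([encode(revcomp(s[:L])) for s in seqs])
    p = dinucleotide_profile(codes)
    p_rc = dinucleotide_profile(rc)
    np.testing.assert_array_equal(p_rc.freq, p.freq[RC_PERMUTATION][:, ::-1])
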