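"""K-mer spectrum: counting vs a naive oracle, peak, size, heterozygosity."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import genomesurvey as gs
from genomesurvey.kmerspec import (
    KmerHistogram,
    estimate_from_histogram,
    estimate_het_fraction,
    genome_size_from_counts,
)
from conftest import random_dna
from oracles import naive_kmer_histogram


class TestCounting:
    def test_single_window_and_too_short_reads(self):
        assert gs.count_kmers(["ACGTACGTACGTACGTA"], 17).counts == {1: 1}
        assert gs.count_kmers(["ACGTACGTAC"], 17).counts == {}

    def test_total_individuals_is_window_count(self):
        rng = np.random.default_rng(0)
        hist = gs.count_kmers([random_dna(rng, 100)], 17)
        assert hist.total_individuals == 84

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_histogram_equals_naive_oracle_with_ns(self, seed):
        rng = np.random.default_rng(seed)
        seqs = [random_dna(rng, int(n), with_n=0.02) for n in rng.integers(10, 2000, 8)]
        assert gs.count_kmers(seqs, 17).counts == naive_kmer_histogram(seqs, 17)

    def test_histogram_equals_naive_oracle_on_10kb(self):
        rng = np.random.default_rng(99)
        # repeat-rich input so depths above 1 actually occur
        core = random_dna(rng, 2000)
        seq = core + random_dna(rng, 6000) + core
        assert gs.count_kmers([seq], 17).counts == naive_kmer_histogram([seq], 17)

    def test_strand_collapse_reverse_complement_counts_once(self):
        seq = "ACGTACGTACGTACGTA"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert gs.count_kmers([seq, rc], 17).counts == {2: 1}

    @pytest.mark.parametrize("k", [0, 32])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(gs.ValidationError):
            gs.count_kmers(["ACGT"], k)

    @given(st.lists(st.text(alphabet="ACGTN", min_size=0, max_size=60), max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_conservation_individuals_equal_valid_windows(self, seqs):
        k = 5
        hist = gs.count_kmers(seqs, k)
        expected = 0
        for s in seqs:
            for i in range(len(s) - k + 1):
                if "N" not in s[i : i + k]:
                    expected += 1
        assert hist.total_individuals == expected


class TestPeak:
    def test_unique_maximum(self):
        hist = KmerHistogram(17, {6: 50, 74: 500, 75: 499})
        assert gs.detect_peak(hist) == 74

    def test_low_frequency_mass_is_ignored(self):
        hist = KmerHistogram(17, {3: 10**6, 74: 500})
        assert gs.detect_peak(hist) == 74

    def test_ties_break_to_smaller_depth(self):
        hist = KmerHistogram(17, {40: 100, 41: 100})
        assert gs.detect_peak(hist) == 40

    def test_poisson_shaped_histogram_peaks_near_its_mean(self):
        rng = np.random.default_rng(5)
        depths = rng.poisson(68, size=100_000)
        counts = np.bincount(depths)
        hist = KmerHistogram(17, {d: int(c) for d, c in enumerate(counts) if d >= 1 and c})
        assert abs(gs.detect_peak(hist) - 68) <= 1

    def test_no_mass_above_cutoff_raises(self):
        with pytest.raises(gs.EstimationError):
            gs.detect_peak(KmerHistogram(17, {2: 100}))


class TestGenomeSize:
    @pytest.mark.parametrize(
        "kmer_number,peak,mbp",
        [(45_374_105_016, 74, 613.16), (41_637_691_628, 68, 612.32)],
    )
    def test_published_survey_rows(self, kmer_number, peak, mbp):
        assert round(genome_size_from_counts(kmer_number, peak) / 1e6, 2) == mbp

    def test_single_depth_histogram(self):
        res = gs.estimate_genome_size(KmerHistogram(17, {74: 1000}), 74)
        assert res.genome_size == pytest.approx(1000)
        assert res.error_rate_kmer == 0
        assert res.revised_genome_size == pytest.approx(1000)

    def test_low_frequency_individuals_define_the_error_rate(self):
        hist = KmerHistogram(17, {1: 100, 74: 100})  # 100 of 7500 individuals are low-freq
        res = gs.estimate_genome_size(hist, 74)
        assert res.kmer_number == 7400
        assert res.error_rate_kmer == pytest.approx(100 / 7500)
        assert res.revised_genome_size == pytest.approx(res.genome_size * (1 - 100 / 7500))

    def test_size_times_peak_recovers_kmer_number(self):
        hist = KmerHistogram(17, {30: 123, 60: 456, 90: 7})
        res = gs.estimate_genome_size(hist, 60)
        assert res.genome_size * 60 == pytest.approx(res.kmer_number, rel=1e-12)

    def test_empty_histogram_raises(self):
        with pytest.raises(gs.EstimationError):
            gs.estimate_genome_size(KmerHistogram(17, {}), 74)


class TestHeterozygosity:
    def test_rate_formula_examples(self):
        assert gs.heterozygosity_rate(0.0, 17) == 0.0
        assert gs.heterozygosity_rate(0.1, 17) == pytest.approx(0.003096, abs=1e-6)
        assert gs.heterozygosity_rate(0.11836, 17) == pytest.approx(0.0037, abs=1e-5)

    @given(st.floats(min_value=1e-6, max_value=0.999))
    @settings(max_examples=80, deadline=None)
    def test_rate_is_monotone_and_linear_near_zero(self, a):
        k = 17
        r = gs.heterozygosity_rate(a, k)
        assert r > gs.heterozygosity_rate(a * 0.999, k)
        assert abs(gs.heterozygosity_rate(a / 100, k) - (a / 100) / (2 * k)) <= (a / 100) ** 2

    def test_out_of_range_a_half_rejected(self):
        with pytest.raises(gs.ValidationError):
            gs.heterozygosity_rate(1.2, 17)

    def test_mixture_fit_recovers_known_weights(self):
        # expected species counts of a 10:1 hom:het Poisson mixture
        depths = np.arange(1, 160)
        counts = 10_000 * sps.poisson.pmf(depths, 74) + 1_000 * sps.poisson.pmf(depths, 37)
        hist = KmerHistogram(17, {int(d): int(round(c)) for d, c in zip(depths, counts) if c >= 0.5})
        a_half = estimate_het_fraction(hist, 74)
        assert a_half == pytest.approx(1_000 / 11_000, abs=0.01)

    def test_homozygous_spectrum_has_negligible_half_depth_weight(self):
        depths = np.arange(1, 160)
        counts = 10_000 * sps.poisson.pmf(depths, 74)
        hist = KmerHistogram(17, {int(d): int(round(c)) for d, c in zip(depths, counts) if c >= 0.5})
        assert estimate_het_fraction(hist, 74) < 0.01

    def test_degenerate_histogram_raises_with_diagnostics(self):
        with pytest.raises(gs.EstimationError, match="depth range"):
            estimate_het_fraction(KmerHistogram(17, {200: 10}), 74)


class TestRepeatRatio:
    def test_no_repeat_tail_gives_zero(self):
        assert gs.repeat_ratio(KmerHistogram(17, {74: 500}), 74) == 0.0

    def test_tail_arithmetic(self):
        hist = KmerHistogram(17, {74: 100, 140: 10})
        assert gs.repeat_ratio(hist, 74) == pytest.approx(1400 / 8800)

    def test_empty_denominator_raises(self):
        with pytest.raises(gs.EstimationError):
            gs.repeat_ratio(KmerHistogram(17, {2: 5}), 74)


class TestSurveyPipeline:
    def test_histogram_tsv_roundtrip_preserves_estimates(self, tmp_path, small_sim):
        _, _, pairs = small_sim
        hist = gs.count_kmers([s for p in pairs for s in (p.seq1, p.seq2)], 17)
        path = tmp_path / "histo.tsv"
        hist.to_tsv(path)
        back = KmerHistogram.from_tsv(path, k=17)
        assert back.counts == hist.counts
        assert estimate_from_histogram(back) == estimate_from_histogram(hist)

    def test_empty_input_raises(self):
        with pytest.raises((gs.EstimationError, gs.ValidationError)):
            gs.run_survey(sequences=[])

    def test_survey_from_fastq_matches_in_memory(self, tmp_path, small_sim):
        from genomesurvey.readqc import write_fastq_pairs

        _, _, pairs = small_sim
        f1, f2 = tmp_path / "s_1.fastq", tmp_path / "s_2.fastq"
        write_fastq_pairs(pairs, f1, f2)
        via_fastq = gs.run_survey(fastq=[f1, f2])
        in_memory = gs.run_survey(sequences=[s for p in pairs for s in (p.seq1, p.seq2)])
        assert via_fastq == in_memory
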