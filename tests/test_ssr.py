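"""Microsatellite detection vs a regex oracle, compound/flank rules, classes."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import genomesurvey as gs
from genomesurvey.ssr import (
    DEFAULT_THRESHOLDS,
    SsrSummary,
    canonical_motif,
    filter_flanks,
    find_ssrs,
    merge_compound,
    summarize_ssrs,
)
from conftest import random_dna
from oracles import regex_ssrs, revcomp


def planted_sequence(rng: np.random.Generator, length: int, n_ssrs: int = 12) -> str:
    """Random DNA with tandem repeats planted at random positions."""
    seq = list(random_dna(rng, length))
    for _ in range(n_ssrs):
        u = int(rng.integers(1, 7))
        motif = random_dna(rng, u)
        reps = int(rng.integers(4, 16))
        pos = int(rng.integers(0, length - u * reps))
        seq[pos : pos + u * reps] = motif * reps
    return "".join(seq)


class TestFind:
    def test_dinucleotide_threshold_boundary(self):
        assert len(find_ssrs("ACACACACACAC")) == 1  # 6 units: reported
        locus = find_ssrs("ACACACACACAC")[0]
        assert (locus.motif, locus.repeat_number, locus.start, locus.end) == ("AC", 6, 1, 12)
        assert find_ssrs("ACACACACAC") == []  # 5 units: below threshold

    def test_mononucleotide_run_of_ten(self):
        [locus] = find_ssrs("AAAAAAAAAA")
        assert (locus.motif, locus.repeat_number, locus.ssr_type) == ("A", 10, "p1")

    def test_partial_trailing_unit_is_not_counted(self):
        [locus] = find_ssrs("T" + "ACA" * 6 + "C" + "T")  # (ACA)6 then AC...
        assert locus.motif == "ACA"
        assert locus.repeat_number == 6
        assert locus.end - locus.start + 1 == 18

    def test_n_breaks_runs(self):
        assert find_ssrs("ACACACNACACACACACAC") == [] or all(
            l.repeat_number < 10 for l in find_ssrs("ACACACNACACACACACAC")
        )
        # the right-hand run alone has 6 units and is found
        loci = find_ssrs("ACACACNACACACACACACT")
        assert any(l.motif in ("AC", "CA") and l.repeat_number == 6 for l in loci)

    def test_non_dna_characters_rejected(self):
        with pytest.raises(gs.FormatError):
            find_ssrs("ACGTXACGT")

    @pytest.mark.parametrize("seed", range(100))
    def test_equivalence_with_regex_oracle_on_planted_10kb(self, seed):
        rng = np.random.default_rng(seed)
        seq = planted_sequence(rng, 10_000)
        ours = {(l.start, l.end, l.motif) for l in find_ssrs(seq)}
        assert ours == regex_ssrs(seq, DEFAULT_THRESHOLDS)

    @pytest.mark.parametrize("seed", range(5))
    def test_emitted_motifs_are_primitive(self, seed):
        rng = np.random.default_rng(1000 + seed)
        for locus in find_ssrs(planted_sequence(rng, 5000, n_ssrs=25)):
            u = len(locus.motif)
            for d in range(1, u):
                if u % d == 0:
                    assert locus.motif != locus.motif[:d] * (u // d)

    def test_reverse_complement_preserves_classes_and_repeat_numbers(self):
        rng = np.random.default_rng(7)
        seq = planted_sequence(rng, 8000)
        fwd = sorted((l.canonical_class, l.repeat_number) for l in find_ssrs(seq))
        rev = sorted((l.canonical_class, l.repeat_number) for l in find_ssrs(revcomp(seq)))
        assert fwd == rev


class TestCompound:
    def _two_loci(self, gap: int):
        # random filler between the runs (itself SSR-free at these thresholds)
        filler = random_dna(np.random.default_rng(555), gap)
        seq = "AC" * 6 + filler + "AG" * 6
        loci = find_ssrs(seq)
        assert [l.motif for l in loci] == ["AC", "AG"]
        return loci

    def test_distant_loci_stay_separate(self):
        merged = merge_compound(self._two_loci(200))
        assert [l.ssr_type for l in merged] == ["p2", "p2"]

    def test_close_loci_merge_into_one_compound(self):
        merged = merge_compound(self._two_loci(10))
        assert len(merged) == 1
        assert merged[0].ssr_type == "c"
        assert merged[0].start == 1 and merged[0].end == 34
        assert [m.motif for m in merged[0].members] == ["AC", "AG"]
        assert merged[0].annotation() == "(AC)6...(AG)6"

    def test_single_locus_unchanged(self):
        loci = find_ssrs("AAAAAAAAAA")
        assert merge_compound(loci) == loci

    def test_remove_mode_drops_close_loci(self):
        assert merge_compound(self._two_loci(10), mode="remove") == []

    def test_unsorted_input_rejected(self):
        loci = self._two_loci(200)[::-1]
        with pytest.raises(gs.ValidationError):
            merge_compound(loci)


class TestFlanks:
    def test_locus_near_contig_start_is_removed(self):
        loci = find_ssrs("AAAA" + "AC" * 6 + "G" * 10_000)
        # shift a locus to start 5: construct directly
        kept = filter_flanks(loci, {"seq": 10_016})
        assert all(l.start - 1 >= 100 for l in kept)

    def test_interior_locus_is_kept(self):
        rng = np.random.default_rng(556)
        seq = random_dna(rng, 4999) + "ACACAC" * 2 + random_dna(rng, 4989)
        [locus] = find_ssrs(seq)
        assert filter_flanks([locus], {"seq": len(seq)}) == [locus]

    def test_short_contig_loses_all_loci(self):
        seq = "G" * 50 + "AC" * 6 + "G" * 50  # 150 bp total: both flanks < 100
        loci = find_ssrs(seq)
        assert loci and filter_flanks(loci, {"seq": len(seq)}) == []

    def test_out_of_bounds_locus_rejected(self):
        [locus] = find_ssrs("AC" * 6)
        with pytest.raises(gs.ValidationError):
            filter_flanks([locus], {"seq": 5})


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "motif,expected",
        [("GT", "AC/GT"), ("CCT", "AGG/CCT"), ("A", "A/T"), ("AC", "AC/GT"), ("AAT", "AAT/ATT")],
    )
    def test_known_classes(self, motif, expected):
        assert canonical_motif(motif) == expected

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    @settings(max_examples=120, deadline=None)
    def test_invariance_under_rotation_and_reverse_complement(self, motif):
        cls = canonical_motif(motif)
        for i in range(len(motif)):
            assert canonical_motif(motif[i:] + motif[:i]) == cls
        assert canonical_motif(revcomp(motif)) == cls

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(gs.FormatError):
            canonical_motif("AXC")


class TestSummary:
    def test_published_unit_shares(self):
        summary = SsrSummary(total_ssrs=299_574, per_unit_counts={2: 205_789, 3: 31_228})
        shares = summary.unit_percents()
        assert shares[2] == 68.69
        assert shares[3] == 10.42

    def test_empty_loci_list_gives_zero_counts(self):
        summary = summarize_ssrs([], sequences_examined=10)
        assert summary.total_ssrs == 0
        assert summary.sequences_with_ssr == 0

    def test_three_contig_fixture_matches_regex_oracle(self):
        rng = np.random.default_rng(42)
        contigs = {f"ctg{i}": planted_sequence(rng, 4000, n_ssrs=8) for i in range(3)}
        loci = [l for sid, s in contigs.items() for l in find_ssrs(s, sequence_id=sid)]
        summary = summarize_ssrs(loci, sequences_examined=3)
        oracle_total = sum(len(regex_ssrs(s, DEFAULT_THRESHOLDS)) for s in contigs.values())
        assert summary.total_ssrs == oracle_total
        assert summary.sequences_with_ssr == sum(
            1 for s in contigs.values() if regex_ssrs(s, DEFAULT_THRESHOLDS)
        )
        assert sum(summary.per_unit_counts.values()) == summary.total_ssrs
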