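"""Bisulfite conversion, in-silico PCR, clone alignment and methylation calling."""

import numpy as np
import pytest
from scipy.stats import binom

from methclone.bisulfite import (
    Amplicon,
    BisulfitePrimerPair,
    CloneRead,
    CloneRejectedError,
    ContextCounts,
    MethylationProfile,
    NonSpecificPrimerError,
    NoProductError,
    align_clone,
    call_methylation,
    callable_positions,
    classify_context,
    convert_bisulfite,
    count_potential_sites,
    find_primer_sites,
    fully_converted_top,
    in_silico_pcr,
    stable_sites,
    summarize_clones,
)
from methclone.seq_core import Interval, ReferenceLocus, revcomp

from conftest import oracle_context


def make_locus_with_primed_amplicon(seed=0, length=500, start=100, end=400,
                                    primer_len=20):
    """A random locus plus the amplicon its converted-template primers define."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    locus = ReferenceLocus(f"locus{seed}", seq)
    conv = fully_converted_top(locus)
    pair = BisulfitePrimerPair(
        gene="g",
        forward=conv[start : start + primer_len],
        reverse=revcomp(conv[end - primer_len : end]),
        expected_product_bp=end - start,
    )
    return locus, pair


class TestConvertBisulfite:
    def test_unmethylated_c_converts(self):
        locus = ReferenceLocus("x", "ACGT")
        profile = MethylationProfile("x", {})
        assert convert_bisulfite(locus, profile, 1.0) == "ATGT"

    def test_methylated_c_protected(self):
        locus = ReferenceLocus("x", "ACGT")
        profile = MethylationProfile("x", {1: True})
        assert convert_bisulfite(locus, profile, 1.0) == "ACGT"

    def test_partial_efficiency_binomial(self):
        # 1000 unmethylated Cs at efficiency 0.95: retained C count within
        # the central 99% of Binomial(1000, 0.05)
        locus = ReferenceLocus("x", "CA" * 1000)
        profile = MethylationProfile("x", {})
        out = convert_bisulfite(locus, profile, efficiency=0.95, seed=123)
        retained = out.count("C")
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.05)
        assert lo <= retained <= hi

    def test_efficiency_one_deterministic(self):
        locus = ReferenceLocus("x", "CCCGGG" * 50)
        profile = MethylationProfile("x", {0: True})
        a = convert_bisulfite(locus, profile, 1.0, seed=1)
        b = convert_bisulfite(locus, profile, 1.0, seed=999)
        assert a == b

    def test_rejects_bad_efficiency(self):
        locus = ReferenceLocus("x", "ACGT")
        with pytest.raises(ValueError):
            convert_bisulfite(locus, MethylationProfile("x", {}), 1.5)


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,expected",
        [
            ("ACGA", 1, "CpG"),
            ("ACTGA", 1, "CpHpG"),
            ("ACTTA", 1, "CpHpH"),
            ("ACCGA", 1, "CpHpG"),   # H = C
            ("AC", 1, None),          # runs past the end
            ("ACT", 1, None),         # CHH/CHG needs pos+2
            ("ACNG", 1, None),        # N breaks the context
        ],
    )
    def test_examples(self, seq, pos, expected):
        locus = ReferenceLocus("x", seq)
        assert classify_context(locus, pos) == expected

    def test_non_c_position_rejected(self):
        with pytest.raises(ValueError):
            classify_context(ReferenceLocus("x", "ACGT"), 0)

    def test_matches_oracle_on_random(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGTN"), size=600, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        locus = ReferenceLocus("x", seq)
        for pos, base in enumerate(seq):
            if base == "C":
                assert classify_context(locus, pos) == oracle_context(seq, pos)


class TestPrimerSitesAndPcr:
    def test_unique_substring_single_site(self):
        locus, pair = make_locus_with_primed_amplicon(seed=1)
        sites = find_primer_sites(pair, fully_converted_top(locus), 0)
        assert sites == [(100, 400)]

    def test_degenerate_y_covers_t(self):
        # forward primer with Y where the converted template reads T
        locus, pair = make_locus_with_primed_amplicon(seed=2)
        fwd = list(pair.forward)
        t_pos = fwd.index("T")
        fwd[t_pos] = "Y"
        pair2 = BisulfitePrimerPair("g", "".join(fwd), pair.reverse,
                                    pair.expected_product_bp)
        sites = find_primer_sites(pair2, fully_converted_top(locus), 0)
        assert (100, 400) in sites

    def test_absent_primer_no_sites(self):
        locus, pair = make_locus_with_primed_amplicon(seed=3)
        absent = BisulfitePrimerPair("g", "G" * 20, pair.reverse, 300)
        assert find_primer_sites(absent, fully_converted_top(locus), 0) == []

    def test_pcr_product_length(self):
        locus, pair = make_locus_with_primed_amplicon(seed=4)
        amp = in_silico_pcr(pair, locus)
        assert amp.length == 300 == pair.expected_product_bp
        assert amp.interval == Interval(100, 400)

    def test_inverted_pair_no_product(self):
        locus, pair = make_locus_with_primed_amplicon(seed=5)
        inverted = BisulfitePrimerPair("g", pair.reverse, pair.forward,
                                       pair.expected_product_bp)
        with pytest.raises(NoProductError):
            in_silico_pcr(inverted, locus)

    def test_duplicated_site_non_specific(self):
        seq = "ATGCATTGCAAGGCCTTAGACAT" * 2 + "A" * 200 + "ATGCATTGCAAGGCCTTAGACAT"
        locus = ReferenceLocus("dup", seq + "C" * 0)
        conv = fully_converted_top(locus)
        pair = BisulfitePrimerPair(
            "g", conv[0:20], revcomp(conv[-20:]), len(conv) - 1
        )
        with pytest.raises(NonSpecificPrimerError):
            in_silico_pcr(pair, locus)


class TestAlignAndCall:
    def setup_method(self):
        self.locus, self.pair = make_locus_with_primed_amplicon(seed=7)
        self.amp = in_silico_pcr(self.pair, self.locus)

    def _converted_read(self, profile=None, sample="root"):
        profile = profile or MethylationProfile(self.locus.id, {})
        region = ReferenceLocus(
            "region", self.locus.sequence[self.amp.interval.start : self.amp.interval.end]
        )
        shifted = MethylationProfile(
            "region",
            {
                p - self.amp.interval.start: True
                for p in profile.methylated_positions
            },
        )
        return CloneRead("c1", sample, convert_bisulfite(region, shifted, 1.0))

    def test_fully_converted_perfect_alignment(self):
        read = self._converted_read()
        aln = align_clone(read, self.locus, self.amp)
        assert aln.mismatches == 0 and aln.gaps == 0
        calls = call_methylation(aln, self.locus)
        assert calls and all(c.status == "unmethylated" for c in calls)

    def test_retained_cpg_called_methylated(self):
        cpg_positions = [
            pos for pos, ctx in callable_positions(self.locus, self.amp)
            if ctx == "CpG"
        ][:3]
        profile = MethylationProfile(self.locus.id, {p: True for p in cpg_positions})
        read = self._converted_read(profile)
        aln = align_clone(read, self.locus, self.amp)
        assert aln.mismatches == 0
        calls = call_methylation(aln, self.locus)
        meth = {c.ref_pos for c in calls if c.status == "methylated"}
        assert meth == set(cpg_positions)
        assert all(
            c.context == "CpG" for c in calls if c.ref_pos in meth
        )

    def test_single_substitution_counts_one_mismatch(self):
        read = self._converted_read()
        seq = list(read.sequence)
        # flip an A to G somewhere mid-read (A->G is never bisulfite-legal)
        i = seq.index("A", 50)
        seq[i] = "G"
        aln = align_clone(CloneRead("c2", "root", "".join(seq)), self.locus, self.amp)
        assert aln.mismatches == 1

    def test_primer_footprint_not_called(self):
        read = self._converted_read()
        aln = align_clone(read, self.locus, self.amp)
        calls = call_methylation(aln, self.locus)
        fwd, rev = self.amp.forward_footprint, self.amp.reverse_footprint
        assert all(
            not fwd.contains(c.ref_pos) and not rev.contains(c.ref_pos)
            for c in calls
        )

    def test_low_identity_rejected(self):
        junk = "A" * self.amp.length
        with pytest.raises(CloneRejectedError):
            align_clone(CloneRead("bad", "root", junk), self.locus, self.amp)

    def test_length_gate_rejects(self):
        with pytest.raises(CloneRejectedError, match="length"):
            align_clone(
                CloneRead("short", "root", "ACGT" * 10), self.locus, self.amp
            )

    def test_alignment_agrees_with_direct_comparison_without_indels(self):
        # oracle: on indel-free reads every ref position maps 1:1
        profile = MethylationProfile(
            self.locus.id,
            {pos: True for pos, _ in callable_positions(self.locus, self.amp)[::2]},
        )
        read = self._converted_read(profile)
        aln = align_clone(read, self.locus, self.amp)
        start = self.amp.interval.start
        for off, base in enumerate(read.sequence):
            assert aln.ref_to_read[start + off] == base

    def test_conservation_invariant(self):
        read = self._converted_read()
        aln = align_clone(read, self.locus, self.amp)
        calls = call_methylation(aln, self.locus)
        assert len(calls) == len(callable_positions(self.locus, self.amp))


class TestPotentialSites:
    def test_hand_enumerated_toy(self, toy_locus):
        # AACGACTGACTTA: C@2 CpG, C@5 CpHpG (CTG), C@9 CpHpH (CTT)
        amp = Amplicon(
            toy_locus.id,
            Interval(0, 13),
            BisulfitePrimerPair("g", "A" * 15, "A" * 15, 31),
        )
        # footprints are primer-length based; use include_primer_footprint to
        # observe the whole toy interval
        counts = count_potential_sites(toy_locus, [amp], include_primer_footprint=True)
        assert (counts.cpg, counts.chg, counts.chh) == (1, 1, 1)

    def test_no_c_region(self):
        locus = ReferenceLocus("x", "ATGGATTAGGTTAAGGATTAG")
        amp = Amplicon(
            locus.id, Interval(0, 21), BisulfitePrimerPair("g", "A" * 15, "A" * 15, 31)
        )
        counts = count_potential_sites(locus, [amp], include_primer_footprint=True)
        assert counts.total() == 0

    def test_partition_invariant_and_dedup(self):
        locus, pair = make_locus_with_primed_amplicon(seed=9)
        amp = in_silico_pcr(pair, locus)
        counts = count_potential_sites(locus, [amp])
        assert counts.total() == len(callable_positions(locus, amp))
        # overlapping duplicate amplicon must not change the union counts
        counts2 = count_potential_sites(locus, [amp, amp])
        assert counts2 == counts

    def test_denominators_independent_of_profile(self):
        locus, pair = make_locus_with_primed_amplicon(seed=10)
        amp = in_silico_pcr(pair, locus)
        assert count_potential_sites(locus, [amp]) == count_potential_sites(
            locus, [amp]
        )


class TestSummaries:
    def _calls(self, ks, context="CpG", denom=50):
        """Synthesize calls where clone i has ks[i] methylated CpG sites."""
        from methclone.bisulfite import MethylationCall

        calls = []
        for i, k in enumerate(ks):
            cid = f"clone{i}"
            for j in range(denom):
                calls.append(
                    MethylationCall(
                        ref_pos=j * 3,
                        context=context,
                        status="methylated" if j < k else "unmethylated",
                        clone_id=cid,
                        sample="root",
                    )
                )
        return calls

    def test_all_unmethylated_formats_table_cell(self):
        counts = ContextCounts(cpg=44, chg=0, chh=0)
        summary = summarize_clones(self._calls([0] * 10, denom=44), counts, 10,
                                   gene="g", sample="coleoptile")
        assert summary.format_cell("CpG") == "0/44 in 10"

    def test_uniform_seven_of_fifty(self):
        counts = ContextCounts(cpg=50, chg=0, chh=0)
        summary = summarize_clones(self._calls([7] * 10), counts, 10)
        assert summary.format_cell("CpG") == "7/50 in 10"

    def test_grouping_by_k(self):
        counts = ContextCounts(cpg=50, chg=0, chh=0)
        summary = summarize_clones(self._calls([0, 0, 2]), counts, 3)
        assert summary.groups["CpG"] == ((0, 2), (2, 1))

    def test_group_sizes_sum_to_n(self):
        counts = ContextCounts(cpg=50, chg=0, chh=0)
        summary = summarize_clones(self._calls([0, 1, 1, 5, 7, 7, 7]), counts, 7)
        assert sum(m for _, m in summary.groups["CpG"]) == 7

    def test_clone_count_mismatch_rejected(self):
        counts = ContextCounts(cpg=50, chg=0, chh=0)
        with pytest.raises(ValueError):
            summarize_clones(self._calls([0] * 5), counts, 3)


class TestPrimerTable:
    def test_shipped_wheat_table_loads_and_validates(self):
        from importlib import resources

        from methclone.bisulfite import read_primer_table

        ref = resources.files("methclone.data") / "primers_wheat_flavonoid.tsv"
        with resources.as_file(ref) as path:
            pairs = read_primer_table(path)
        assert len(pairs) == 14
        genes = {p.gene for p in pairs}
        assert len(genes) == 5
        for p in pairs:
            # converted-template primers: degeneracy only where the readout
            # depends on methylation (R on reverse, Y on forward)
            assert set(p.forward) <= set("ACGTY")
            assert set(p.reverse) <= set("ACGTR")
            assert p.expected_product_bp > len(p.forward) + len(p.reverse)

    def test_missing_column_rejected(self, tmp_path):
        from methclone.bisulfite import read_primer_table

        p = tmp_path / "bad.tsv"
        p.write_text("gene\tforward\n" + "g\tACGT\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_primer_table(p)


class TestStableSites:
    def _calls_at(self, pos, methylated_in, n=10):
        from methclone.bisulfite import MethylationCall

        return [
            MethylationCall(
                ref_pos=pos,
                context="CpG",
                status="methylated" if i < methylated_in else "unmethylated",
                clone_id=f"c{i}",
                sample="root",
            )
            for i in range(n)
        ]

    def test_all_clones_included(self):
        assert stable_sites(self._calls_at(5, 10), 10, 1.0) == [5]

    def test_individual_marks_excluded(self):
        # a mark in only 2 of 10 clones is "individual", not stable
        assert stable_sites(self._calls_at(5, 2), 10, 1.0) == []

    def test_zero_threshold_every_ever_methylated(self):
        calls = self._calls_at(5, 2) + self._calls_at(9, 0)
        assert stable_sites(calls, 10, 0.0) == [5]
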