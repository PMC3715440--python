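"""Attachment-site data model: decomposition, mismatch scoring,
integration/excision bookkeeping, catalog tallying, genome scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iceatt.attsite import (
    AlphabetError,
    AttSiteCore,
    InsertionRecord,
    JunctionPair,
    SiteContext,
    SiteStructureError,
    decompose_core,
    excise,
    integrate,
    mismatch_count,
    predict_heteroduplex,
    reverse_complement,
    scan_genome,
    tally_sites,
)
from iceatt.synth import DEFAULT_REFERENCE_CORE

core_seq = st.text(alphabet="ACGT", min_size=17, max_size=17)


class TestDecompose:
    def test_fixed_partition(self):
        core = decompose_core("AAAAA" + "TTTTTTT" + "GGGGG")
        assert core.left_arm == "AAAAA"
        assert core.spacer == "TTTTTTT"
        assert core.right_arm == "GGGGG"
        assert not core.perfect_stem

    def test_perfect_stem_is_revcomp_of_left_arm(self):
        core = decompose_core("AAAAA" + "CCCCCCC" + "TTTTT")
        assert core.perfect_stem

    @given(core_seq)
    @settings(max_examples=100, derandomize=True)
    def test_partition_matches_slicing_oracle(self, seq):
        core = decompose_core(seq)
        assert core.left_arm == seq[:5]
        assert core.spacer == seq[5:12]
        assert core.right_arm == seq[12:]
        assert core.left_arm + core.spacer + core.right_arm == seq
        assert core.perfect_stem == (seq[12:] == reverse_complement(seq[:5]))

    @pytest.mark.parametrize("bad", ["ACGT", "A" * 18, ""])
    def test_wrong_length_rejected(self, bad):
        with pytest.raises(SiteStructureError):
            decompose_core(bad)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(AlphabetError):
            decompose_core("ACGTNACGTACGTACGT")


class TestMismatchCount:
    def test_identity_is_zero(self, reference):
        assert mismatch_count(reference, reference) == 0

    def test_constructed_three_changes(self, reference):
        seq = list(reference.sequence)
        for i in (0, 6, 16):
            seq[i] = {"A": "C"}.get(seq[i], "A")
        assert mismatch_count(AttSiteCore("".join(seq)), reference) == 3

    @given(core_seq, core_seq)
    @settings(max_examples=200, derandomize=True)
    def test_matches_positionwise_oracle_and_symmetry(self, a, b):
        ca, cb = AttSiteCore(a), AttSiteCore(b)
        oracle = sum(1 for x, y in zip(a, b) if x != y)
        assert mismatch_count(ca, cb) == oracle
        assert mismatch_count(cb, ca) == oracle
        assert (oracle == 0) == (a == b)

    @given(core_seq, core_seq, core_seq)
    @settings(max_examples=100, derandomize=True)
    def test_triangle_inequality(self, a, b, c):
        ca, cb, cc = map(AttSiteCore, (a, b, c))
        assert mismatch_count(ca, cc) <= mismatch_count(ca, cb) + mismatch_count(cb, cc)


class TestHeteroduplexPrediction:
    def test_arm_differences_alone_do_not_trigger(self, reference):
        seq = list(reference.sequence)
        for i in (0, 1, 13, 14):  # arms only
            seq[i] = "G" if seq[i] != "G" else "A"
        assert not predict_heteroduplex(AttSiteCore("".join(seq)), reference)

    def test_single_spacer_mismatch_triggers(self, reference):
        seq = list(reference.sequence)
        seq[8] = "G" if seq[8] != "G" else "A"
        assert predict_heteroduplex(AttSiteCore("".join(seq)), reference)

    @given(core_seq)
    @settings(max_examples=100, derandomize=True)
    def test_equals_spacer_inequality(self, seq):
        t = AttSiteCore(seq)
        assert predict_heteroduplex(t, DEFAULT_REFERENCE_CORE) == (
            t.spacer != DEFAULT_REFERENCE_CORE.spacer
        )


class TestIntegrateExcise:
    def test_homoduplex_round_trip_is_identity(self, reference):
        j = integrate(reference, reference)
        assert j.attL == j.attR == reference
        prod = excise(j)
        assert not prod.heteroduplex
        assert prod.circle_att == reference
        assert prod.empty_site == reference

    def test_divergent_spacers_give_unequal_junctions(self, reference):
        seq = list(reference.sequence)
        seq[7] = "G" if seq[7] != "G" else "A"
        target = AttSiteCore("".join(seq))
        j = integrate(target, reference)
        assert j.attL.spacer != j.attR.spacer
        assert j.attL.spacer == target.spacer  # default: chromosomal spacer left

    def test_element_left_assignment_swaps_spacers(self, reference):
        seq = list(reference.sequence)
        seq[7] = "G" if seq[7] != "G" else "A"
        target = AttSiteCore("".join(seq))
        j = integrate(target, reference, spacer_assignment="element-left")
        assert j.attL.spacer == reference.spacer
        assert j.attR.spacer == target.spacer

    @given(core_seq)
    @settings(max_examples=200, derandomize=True)
    def test_excise_flag_matches_prediction_and_recovers_sequences(self, seq):
        target = AttSiteCore(seq)
        element = DEFAULT_REFERENCE_CORE
        prod = excise(integrate(target, element))
        assert prod.heteroduplex == predict_heteroduplex(target, element)
        # under the default spacer assignment excision restores both parties
        assert prod.empty_site == target
        assert prod.circle_att == element

    @given(core_seq, core_seq)
    @settings(max_examples=100, derandomize=True)
    def test_excise_flag_equals_direct_spacer_comparison(self, a, b):
        j = JunctionPair(attL=AttSiteCore(a), attR=AttSiteCore(b))
        assert excise(j).heteroduplex == (a[5:12] != b[5:12])


class TestTallySites:
    @staticmethod
    def paper_table():
        records = [
            InsertionRecord("yrkM", "co-directional", 11),
            InsertionRecord("mmsA", "co-directional", 3),
            InsertionRecord("yqhG", "co-directional", 1),
            InsertionRecord("yqhG", "head-on", 1),
        ]
        records += [
            InsertionRecord(f"single_{i}", "co-directional", 1) for i in range(11)
        ]
        return records

    def test_published_occurrence_table(self):
        summary = tally_sites(self.paper_table())
        assert summary.n_sites == 15
        assert summary.n_insertions == 27
        assert summary.modal_site.locus == "yrkM"
        assert summary.modal_site.percent == 41
        assert summary.sites[1].locus == "mmsA"
        assert summary.sites[1].percent == 11

    def test_opposite_orientations_are_distinct_sites(self):
        recs = [
            InsertionRecord("yqhG", "co-directional", 2),
            InsertionRecord("yqhG", "head-on", 1),
        ]
        assert tally_sites(recs).n_sites == 2

    def test_single_record(self):
        summary = tally_sites([InsertionRecord("x", "head-on", 5)])
        assert summary.n_sites == 1
        assert summary.modal_site.percent == 100
        assert summary.n_insertions == 5

    def test_occurrence_conservation_and_percent_sum(self, rng):
        records = [
            InsertionRecord(f"L{i}", "co-directional", int(n))
            for i, n in enumerate(rng.integers(1, 20, size=12))
        ]
        summary = tally_sites(records)
        assert summary.n_insertions == sum(r.occurrences for r in records)
        assert abs(sum(s.percent for s in summary.sites) - 100) <= 0.5 * summary.n_sites

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            tally_sites([])


from oracles import brute_force_scan  # noqa: E402


class TestScanGenome:
    def test_planted_exact_site_is_sole_hit(self, reference, rng):
        from iceatt.synth import make_genome

        truth = make_genome(5_000, [(0, False, "+")], reference, seed=11)
        hits = scan_genome(truth.contigs, reference, 0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (truth.sites[0].start, truth.sites[0].end)
        assert hits[0].mismatches == 0

    def test_recovers_planted_sites_at_mixed_mismatch_counts(self, reference):
        from iceatt.synth import make_genome

        counts = [2, 3, 7, 12]
        # >10 mismatches cannot fit in the arms alone: such sites are
        # necessarily spacer-divergent
        truth = make_genome(8_000, [(m, m > 10, "+") for m in counts], reference, seed=5)
        hits = scan_genome(truth.contigs, reference, 12)
        by_key = {(h.start, h.strand): h for h in hits}
        for site in truth.sites:
            assert (site.start, site.strand) in by_key
            assert by_key[(site.start, site.strand)].mismatches == site.mismatches

    @pytest.mark.parametrize("threshold", [0, 3, 9, 17])
    def test_matches_brute_force_oracle(self, reference, rng, threshold):
        seq = "".join(rng.choice(list("ACGTN"), size=2_000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        genome = {"c1": seq}
        hits = scan_genome(genome, reference, threshold)
        got = [(h.contig, h.start, h.strand, h.core.sequence, h.mismatches) for h in hits]
        assert got == brute_force_scan(genome, reference, threshold)

    def test_minus_strand_core_is_revcomp_of_slice(self, reference):
        from iceatt.synth import make_genome

        truth = make_genome(3_000, [(1, False, "-")], reference, seed=3)
        (site,) = truth.sites
        hits = [h for h in scan_genome(truth.contigs, reference, 1) if h.strand == "-"]
        assert any(
            h.start == site.start
            and h.core.sequence
            == reverse_complement(truth.contigs["chr"][h.start : h.end])
            for h in hits
        )

    def test_empty_genome_rejected(self, reference):
        with pytest.raises(ValueError):
            scan_genome({}, reference, 2)
        with pytest.raises(ValueError):
            scan_genome({"c": ""}, reference, 2)


class TestSiteContext:
    def test_core_extraction_respects_offset(self, reference):
        window = "ACGTA" + reference.sequence + "CGTA"
        ctx = SiteContext(window, core_offset=5)
        assert ctx.core == reference

    def test_length_and_offset_validated(self):
        with pytest.raises(SiteStructureError):
            SiteContext("ACGT")
        with pytest.raises(SiteStructureError):
            SiteContext("A" * 26, core_offset=10)
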