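"""Primer model: IUPAC semantics, shifted anchoring, susceptibility scan."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primerslip import (
    BindingSite,
    DegeneratePrimer,
    anchor_matches_at,
    expand_degenerate,
    feasible_slips,
    homopolymer_run,
    iupac_match,
    susceptibility_report,
    three_prime_distinct,
)
from primerslip.primers import IUPAC_CODES, degeneracy

from _oracles import brute_feasible
from conftest import random_primer_template

IUPAC_ALPHABET = "".join(IUPAC_CODES)


class TestIupacBasics:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACY", {"ACC", "ACT"}),
            ("ACGT", {"ACGT"}),
        ],
    )
    def test_expansion_examples(self, seq, expected):
        assert expand_degenerate(seq) == expected

    def test_expansion_cardinality_nn(self):
        assert len(expand_degenerate("NN")) == 16

    def test_non_iupac_character_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            DegeneratePrimer("bad", "ACXGT")
        with pytest.raises(ValueError):
            expand_degenerate("ACXGT")

    @given(st.text(alphabet=IUPAC_ALPHABET, min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_expansion_cardinality_is_analytic_product(self, seq):
        assert len(expand_degenerate(seq)) == degeneracy(seq)

    @pytest.mark.parametrize(
        "code,base,expected",
        [("Y", "C", True), ("Y", "T", True), ("Y", "A", False), ("N", "G", True)],
    )
    def test_iupac_match(self, code, base, expected):
        assert iupac_match(code, base) is expected

    def test_iupac_match_rejects_ambiguous_base(self):
        with pytest.raises(ValueError, match="swap"):
            iupac_match("C", "Y")

    @pytest.mark.parametrize(
        "seq,pos,direction,expected",
        [
            ("AACCCCCCCG", 2, 1, 7),  # seven-cytosine run
            ("ACGT", 0, 1, 1),
            ("TTTT", 3, -1, 4),
        ],
    )
    def test_homopolymer_run(self, seq, pos, direction, expected):
        assert homopolymer_run(seq, pos, direction) == expected

    def test_homopolymer_run_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            homopolymer_run("ACGT", 7)


class TestThreePrimeDistinct:
    @pytest.mark.parametrize(
        "end,expected",
        [("AAATGC", True), ("AAATCC", False), ("AAATYC", False), ("AAAKM", True),
         ("AAAWK", False)],
    )
    def test_examples(self, end, expected):
        assert three_prime_distinct(DegeneratePrimer("p", end)) is expected

    @given(st.text(alphabet=IUPAC_ALPHABET, min_size=2, max_size=6))
    @settings(max_examples=80, deadline=None)
    def test_matches_exhaustive_expansion(self, seq):
        primer = DegeneratePrimer("p", seq)
        by_expansion = all(v[-1] != v[-2] for v in expand_degenerate(primer))
        assert three_prime_distinct(primer) is by_expansion


class TestAnchorMatching:
    def _site(self, template, primer, start=4):
        return BindingSite("tpl", start, "+", len(primer))

    def test_slip_into_continuing_homopolymer(self):
        # primer ends CCCC, flank continues with C: 3' anchor matches 1 nt on
        primer = DegeneratePrimer("p", "GATTCCCC")
        template = "AAAAGATTCCCCCGTTACGTA"
        site = self._site(template, primer)
        assert anchor_matches_at(primer, template, site, 0, anchor_len=4)
        assert anchor_matches_at(primer, template, site, 1, anchor_len=4)

    def test_interrupting_flank_base_blocks_slip(self):
        primer = DegeneratePrimer("p", "GATTCCCC")
        template = "AAAAGATTCCCCAGTTACGTA"  # poly-C followed by A
        site = self._site(template, primer)
        assert not anchor_matches_at(primer, template, site, 1, anchor_len=4)

    def test_slip_zero_full_length_always_matches_defining_site(self):
        primer = DegeneratePrimer("p", "GRTTYCCC")
        template = "AAAAGATTCCCCAGTTACGTA"
        site = self._site(template, primer)
        assert anchor_matches_at(primer, template, site, 0, anchor_len=len(primer))

    def test_out_of_bounds_shift_is_nonmatch_with_warning(self):
        primer = DegeneratePrimer("p", "ACGT")
        template = "ACGT"
        site = BindingSite("tpl", 0, "+", 4)
        with pytest.warns(UserWarning):
            assert not anchor_matches_at(primer, template, site, 2, anchor_len=4)


class TestFeasibleSlips:
    def test_homopolymer_extension_gives_forward_slips(self):
        # in-site CCCC run, flank extension CCC -> slips 0..3
        primer = DegeneratePrimer("p", "GATTACAGTCCCC")
        template = "AAAA" + "GATTACAGTCCCC" + "CCC" + "ATTGACGGT"
        site = BindingSite("tpl", 4, "+", len(primer))
        a = feasible_slips(primer, template, site, window=(-1, 4), anchor_len=4)
        assert a.feasible == (0, 1, 2, 3)
        assert a.run_in_site == 4 and a.run_extension == 3
        assert a.class_label == "deletion_prone"

    def test_tandem_repeat_enables_four_base_slip(self, tandem_primer):
        site_seq = "ACAGGCTGAACAGTTCACCC"
        template = "TTTT" + site_seq + "ACCC" + "GGATTAGGACCAT"
        site = BindingSite("tpl", 4, "+", len(tandem_primer))
        a = feasible_slips(tandem_primer, template, site)
        assert 4 in a.feasible

    def test_clamped_primer_with_in_site_run_does_not_slip(self):
        # 4 nt in-site C run but a GC clamp and non-continuing flank
        primer = DegeneratePrimer("p", "GATTACCCCAGC")
        template = "AAAA" + "GATTACCCCAGC" + "TTGCAGGAT"
        site = BindingSite("tpl", 4, "+", len(primer))
        a = feasible_slips(primer, template, site)
        assert a.feasible == (0,)
        assert a.distinct_3prime is True
        assert a.class_label == "none"

    def test_window_must_contain_zero(self):
        primer = DegeneratePrimer("p", "GATTCCCC")
        template = "AAAAGATTCCCCCGTT"
        site = BindingSite("tpl", 4, "+", len(primer))
        with pytest.raises(ValueError, match="window"):
            feasible_slips(primer, template, site, window=(1, 4))

    def test_invalid_site_rejected(self):
        primer = DegeneratePrimer("p", "GGGGGGGG")
        template = "AAAAGATTCCCCCGTT"
        site = BindingSite("tpl", 4, "+", len(primer))
        with pytest.raises(ValueError, match="slip 0"):
            feasible_slips(primer, template, site)

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence_randomized(self, seed):
        """Feasible set equals brute force over all variants x all offsets."""
        rng = np.random.default_rng(1000 + seed)
        primer, template, site = random_primer_template(rng)
        anchor = int(rng.integers(3, min(6, len(primer)) + 1))
        a = feasible_slips(primer, template, site, window=(-1, 4), anchor_len=anchor)
        expected = brute_feasible(
            primer.sequence, template, site.start, (-1, 4), anchor
        )
        assert list(a.feasible) == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_interrupted_homopolymer_rule(self, seed):
        """No extension and no tandem match => no positive slip feasible."""
        rng = np.random.default_rng(2000 + seed)
        primer, template, site = random_primer_template(rng)
        a = feasible_slips(primer, template, site)
        if a.run_extension == 0 and all(s <= 0 for s in brute_feasible(
                primer.sequence, template, site.start, (-1, 4), a.anchor_len)):
            assert all(s <= 0 for s in a.feasible)

    @pytest.mark.parametrize("seed", range(15))
    def test_flank_extension_monotonicity(self, seed):
        """Extending the 3' run into the flank never removes a run-driven slip.

        Forward slips within the homopolymer extension (s <= run_extension)
        survive when one more run base is inserted at the site/flank
        junction, and run_extension itself grows by one.  (Slips feasible
        only through coincidental downstream matches are outside the
        homopolymer mechanism and carry no such guarantee.)
        """
        rng = np.random.default_rng(3000 + seed)
        primer, template, site = random_primer_template(rng)
        a = feasible_slips(primer, template, site)
        run_base = template[site.end - 1]
        extended = template[: site.end] + run_base + template[site.end:]
        b = feasible_slips(primer, extended, site)
        run_driven = {s for s in a.feasible if 0 < s <= a.run_extension}
        assert run_driven <= set(b.feasible)
        assert b.run_extension == a.run_extension + 1


class TestSusceptibilityReport:
    def test_clamped_primer_all_rows_none(self, rev_primer):
        from primerslip.synth import make_template, protected_spec

        templates = [
            make_template(protected_spec(f"t{i}"), seed=i) for i in range(5)
        ]
        report = susceptibility_report(
            [rev_primer], [(t.taxon_id, t.sequence) for t in templates]
        )
        assert (report["class_label"] == "none").all()

    def test_classes_match_engineered_ground_truth(self, fwd_primer):
        from primerslip.synth import make_template, protected_spec, slip_prone_spec

        prone = [make_template(slip_prone_spec(f"p{i}"), seed=i) for i in range(3)]
        prot = [make_template(protected_spec(f"n{i}"), seed=50 + i) for i in range(3)]
        report = susceptibility_report(
            [fwd_primer],
            [(t.taxon_id, t.sequence) for t in prone + prot],
        )
        by_id = report.set_index("template_id")["class_label"]
        for t in prone:
            assert by_id[t.taxon_id] == "deletion_prone"
            assert report.set_index("template_id").loc[t.taxon_id, "run_extension"] >= 1
        for t in prot:
            assert by_id[t.taxon_id] == "none"

    def test_unalignable_template_flagged_not_dropped(self, fwd_primer):
        report = susceptibility_report([fwd_primer], [("junk", "ACGT" * 20)])
        assert len(report) == 1
        assert report.loc[0, "class_label"] == "unalignable"

    def test_empty_template_set_gives_empty_report(self, fwd_primer):
        with pytest.warns(UserWarning):
            report = susceptibility_report([fwd_primer], [])
        assert len(report) == 0
        assert list(report.columns)[:2] == ["primer", "template_id"]
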