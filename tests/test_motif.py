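"""IUPAC/PWM compilation, strand-aware scanning, and annotation filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cismotif.genome import RegionKind, reverse_complement
from cismotif.motif import (
    IUPAC_SETS,
    PWM,
    FilterSpec,
    MotifError,
    apply_filters,
    compile_iupac,
    dedupe_palindromic,
    load_pwm,
    pwm_match_prob,
    pwm_to_pattern,
    reverse_complement_pattern,
    scan_unit,
    scan_unit_naive,
)

from conftest import make_multi_unit, make_unit, plus_gene


class TestCompileIupac:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("R", {"A", "G"}), ("Y", {"C", "T"}), ("S", {"G", "C"}),
            ("W", {"A", "T"}), ("K", {"G", "T"}), ("M", {"A", "C"}),
            ("B", {"C", "G", "T"}), ("D", {"A", "G", "T"}),
            ("H", {"A", "C", "T"}), ("V", {"A", "C", "G"}),
            ("N", {"A", "C", "G", "T"}),
        ],
    )
    def test_degeneracy_table(self, code, expected):
        assert set(compile_iupac(code).allowed_sets[0]) == expected

    def test_concrete_bases_are_singletons(self):
        pat = compile_iupac("ACGT")
        assert [set(s) for s in pat.allowed_sets] == [{"A"}, {"C"}, {"G"}, {"T"}]

    def test_case_insensitive(self):
        assert compile_iupac("ryn").text == "RYN"

    def test_invalid_character_names_position(self):
        with pytest.raises(MotifError, match="position 3"):
            compile_iupac("ACZT")

    def test_empty_rejected(self):
        with pytest.raises(MotifError):
            compile_iupac("")


class TestReverseComplementPattern:
    def test_concrete(self):
        assert reverse_complement_pattern(compile_iupac("ATCCG")).text == "CGGAT"

    def test_degenerate_complements(self):
        for a, b in [("R", "Y"), ("K", "M"), ("S", "S"), ("W", "W"),
                     ("B", "V"), ("D", "H"), ("N", "N")]:
            assert reverse_complement_pattern(compile_iupac(a)).text == b

    @given(st.text(alphabet=sorted(IUPAC_SETS), min_size=1, max_size=12))
    @settings(derandomize=True)
    def test_involution(self, text):
        pat = compile_iupac(text)
        assert reverse_complement_pattern(reverse_complement_pattern(pat)) == pat


class TestScanUnit:
    def test_single_forward_hit(self):
        unit = make_unit("AAATCCGAA")
        hits = scan_unit(unit, compile_iupac("ATCCG"))
        assert [(h.unit_offset, h.strand) for h in hits] == [(2, "forward")]
        assert hits[0].matched_sequence == "ATCCG"
        assert hits[0].genomic_interval == ("chr1", 3, 7)

    def test_overlapping_matches_all_reported(self):
        hits = scan_unit(make_unit("AAAA"), compile_iupac("AA"))
        assert [h.unit_offset for h in hits] == [0, 1, 2]

    def test_palindrome_both_mode_double_reports(self):
        unit = make_unit("TTGAATTCTT")
        hits = scan_unit(unit, compile_iupac("GAATTC", strand_mode="both"))
        assert [(h.unit_offset, h.strand) for h in hits] == [
            (2, "forward"), (2, "reverse"),
        ]
        assert len(dedupe_palindromic(hits)) == 1

    def test_reverse_mode_reports_gene_strand_sequence(self):
        # CGGAT on the gene strand is ATCCG on the opposite strand
        unit = make_unit("TTCGGATTT")
        hits = scan_unit(unit, compile_iupac("ATCCG", strand_mode="reverse"))
        assert [(h.unit_offset, h.strand) for h in hits] == [(2, "reverse")]
        assert hits[0].matched_sequence == "CGGAT"
        assert hits[0].motif_word == "ATCCG"

    def test_genome_n_never_matches(self):
        hits = scan_unit(make_unit("AANAA"), compile_iupac("NNN"))
        assert hits == []

    def test_motif_longer_than_unit_is_empty(self):
        assert scan_unit(make_unit("ACG"), compile_iupac("ACGT")) == []

    def test_boundary_spanning_hit_carries_two_region_labels(self):
        unit = make_multi_unit(
            [(RegionKind.UTR5, "AAAGA"), (RegionKind.CDS, "ATCTT")]
        )
        (hit,) = scan_unit(unit, compile_iupac("GAAT"))
        assert hit.region_labels == ("utr5", "exon_cds")

    def test_atg_positions_attached(self):
        unit = make_multi_unit([(RegionKind.UTR5, "TTTT"), (RegionKind.CDS, "ATGCC")])
        unit = unit.__class__(**{**unit.__dict__, "atg_genomic": 5})
        hits = scan_unit(unit, compile_iupac("ATG"))
        assert [(h.unit_offset, h.atg_position) for h in hits] == [(4, 1)]


@st.composite
def random_case(draw):
    seq = draw(
        st.text(alphabet="ACGTN", min_size=0, max_size=200).map(str)
    )
    pattern = draw(st.text(alphabet=sorted(IUPAC_SETS), min_size=1, max_size=8))
    mode = draw(st.sampled_from(["forward", "reverse", "both"]))
    return seq, pattern, mode


class TestOracleEquivalence:
    @given(random_case())
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_fast_scan_equals_naive_scan(self, case):
        seq, pattern_text, mode = case
        unit = make_unit(seq)
        pattern = compile_iupac(pattern_text, strand_mode=mode)
        fast = scan_unit(unit, pattern)
        naive = scan_unit_naive(unit, pattern)
        assert [(h.unit_offset, h.strand, h.matched_sequence) for h in fast] == [
            (h.unit_offset, h.strand, h.matched_sequence) for h in naive
        ]

    def test_strand_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            text = "".join(rng.choice(list("ACGTRYSWKMN"), size=5))
            unit = make_unit(seq)
            rev = scan_unit(unit, compile_iupac(text, strand_mode="reverse"))
            fwd_rc = scan_unit(
                unit,
                reverse_complement_pattern(compile_iupac(text)),
            )
            assert [(h.unit_offset, h.matched_sequence) for h in rev] == [
                (h.unit_offset, h.matched_sequence) for h in fwd_rc
            ]


class TestPWM:
    def test_point_mass_consensus_prob_one(self):
        m = np.zeros((4, 3))
        m[0, 0] = m[1, 1] = m[2, 2] = 1.0  # A C G
        pwm = PWM(m)
        assert pwm.consensus == "ACG"
        assert pwm_match_prob(pwm, "ACG") == 1.0

    def test_zero_column_probability_annihilates(self):
        m = np.zeros((4, 2))
        m[0, 0] = 1.0
        m[1, 1] = 1.0
        assert pwm_match_prob(PWM(m), "AG") == 0.0

    def test_half_half_product(self):
        m = np.array(
            [[0.5, 0.0], [0.5, 0.0], [0.0, 0.5], [0.0, 0.5]]
        )
        assert pwm_match_prob(PWM(m), "AG") == pytest.approx(0.25)

    def test_window_length_mismatch_rejected(self):
        m = np.full((4, 2), 0.25)
        with pytest.raises(MotifError):
            pwm_match_prob(PWM(m), "ACG")

    def test_monotone_in_used_column_entry(self):
        base = np.full((4, 3), 0.25)
        low = pwm_match_prob(PWM(base), "AAA")
        bumped = base.copy()
        bumped[0, :] = 0.7
        bumped[1:, :] = 0.1
        assert pwm_match_prob(PWM(bumped), "AAA") > low

    def test_pwm_to_pattern_threshold(self):
        m = np.array([[0.5], [0.5], [0.0], [0.0]])
        assert pwm_to_pattern(PWM(m), 0.05).text == "M"

    def test_pwm_to_pattern_point_mass_is_consensus(self):
        m = np.zeros((4, 2))
        m[2, 0] = 1.0
        m[3, 1] = 1.0
        assert pwm_to_pattern(PWM(m)).text == "GT"

    def test_pwm_to_pattern_uniform_is_all_n(self):
        m = np.full((4, 3), 0.25)
        assert pwm_to_pattern(PWM(m), 0.05).text == "NNN"

    def test_pwm_to_pattern_empty_column_advises(self):
        m = np.array([[0.4], [0.3], [0.2], [0.1]])
        with pytest.raises(MotifError, match="lower the threshold"):
            pwm_to_pattern(PWM(m), 0.5)

    def test_load_pwm_counts_normalised(self, tmp_path):
        p = tmp_path / "pwm.txt"
        p.write_text("A 8 0\nC 0 8\nG 2 1\nT 0 1\n")
        pwm = load_pwm(p)
        assert pwm.matrix[:, 0] == pytest.approx([0.8, 0.0, 0.2, 0.0])
        assert pwm.consensus == "AC"

    def test_pwm_scan_attaches_v_pwm(self):
        m = np.array([[0.6, 0.1], [0.2, 0.1], [0.1, 0.7], [0.1, 0.1]])
        pwm = PWM(m)
        unit = make_unit("TTAGTT")
        pattern = pwm_to_pattern(pwm, 0.05)
        (hit,) = [h for h in scan_unit(unit, pattern, pwm=pwm) if h.unit_offset == 2]
        assert hit.v_pwm == pytest.approx(0.6 * 0.7)


class TestFilters:
    def test_contain_retains(self):
        gene = plus_gene()
        gene.description = "protein kinase"
        unit = make_unit("AAATCCGAA")
        hits = scan_unit(unit, compile_iupac("ATCCG"))
        spec = FilterSpec(contain="kinase")
        assert apply_filters(hits, spec, {"G1": gene}) == hits

    def test_devoid_removes(self):
        gene = plus_gene()
        gene.description = "protein kinase"
        hits = scan_unit(make_unit("AAATCCGAA"), compile_iupac("ATCCG"))
        assert apply_filters(hits, FilterSpec(devoid="kinase"), {"G1": gene}) == []

    @pytest.mark.parametrize(
        "mode,description,kept",
        [
            ("and", "receptor kinase", False),  # contains 'receptor' → devoid fails
            ("or", "receptor kinase", True),   # contain passes
            ("and", "protein kinase", True),
            ("or", "unknown protein", True),   # devoid passes
            ("or", "receptor protein", False),  # both criteria fail
        ],
    )
    def test_contain_devoid_truth_table(self, mode, description, kept):
        gene = plus_gene()
        gene.description = description
        hits = scan_unit(make_unit("AAATCCGAA"), compile_iupac("ATCCG"))
        spec = FilterSpec(contain="kinase", devoid="receptor", mode=mode)
        out = apply_filters(hits, spec, {"G1": gene})
        assert bool(out) is kept

    def test_empty_spec_rejected(self):
        with pytest.raises(MotifError):
            FilterSpec()
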