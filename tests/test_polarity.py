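"""Polarity alphabet, incidence matrix, signature and template tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import oracle_counts
from polindex import (DEFAULT_ALPHABET, IncidenceMatrix, PeptideRecord,
                      SequenceError, Signature, TemplateModel,
                      build_incidence_matrix, build_template,
                      classify_peptide, classify_residue, compare_signatures,
                      extract_signature, pair_position, position_label,
                      template_candidates)

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
CECROPIN_A = "KWKLFKKIEKVGQNIRDGIIKAGPAVAVVGQATQIAK"
CA18M118 = "KWKLFKKIGIGAVLKVLTTGLPALIS"

peptides = st.text(alphabet=CANONICAL, min_size=2, max_size=60)


def matrix_of(*sequences, **kwargs):
    records = [PeptideRecord(id=f"p{i}", sequence=s)
               for i, s in enumerate(sequences)]
    return build_incidence_matrix(records, **kwargs)


class TestAlphabet:
    @pytest.mark.parametrize("residue, code, index", [
        ("K", "P+", 1), ("H", "P+", 1), ("R", "P+", 1),
        ("D", "P-", 2), ("E", "P-", 2), ("Y", "P-", 2),
        ("C", "N", 3), ("S", "N", 3),
        ("A", "NP", 4), ("W", "NP", 4),
    ])
    def test_residue_groups(self, residue, code, index):
        group = classify_residue(residue)
        assert (group.code, group.index) == (code, index)

    def test_alphabet_is_total_and_disjoint(self):
        groups = {r: classify_residue(r).code for r in CANONICAL}
        assert len(groups) == 20
        by_group = {}
        for residue, code in groups.items():
            by_group.setdefault(code, set()).add(residue)
        assert by_group == {"P+": set("HKR"), "P-": set("DEY"),
                            "N": set("CGNQST"), "NP": set("AFILMPVW")}

    def test_lowercase_accepted(self):
        assert classify_residue("k").code == "P+"

    def test_non_canonical_rejected(self):
        with pytest.raises(SequenceError, match="X"):
            classify_residue("X")

    @pytest.mark.parametrize("first, second, position", [
        ("K", "K", 1),   # (P+,P+) row 1 col 1
        ("K", "W", 4),   # (P+,NP) row 1 col 4
        ("L", "F", 16),  # (NP,NP) row 4 col 4
        ("N", "E", 10),  # (N,P-)  row 3 col 2
        ("D", "C", 7),   # (P-,N)  row 2 col 3
    ])
    def test_pair_position(self, first, second, position):
        assert pair_position(first, second) == position

    def test_position_labels(self):
        assert position_label(1) == "(P+,P+)"
        assert position_label(10) == "(N,P-)"
        assert position_label(16) == "(NP,NP)"


class TestIncidenceMatrix:
    def test_single_pair(self):
        matrix = matrix_of("KK")
        assert matrix.as_dict() == {1: 1}
        assert matrix.total_pairs == 1

    def test_cecropin_a_counts(self):
        # frozen from the independent dipeptide-tabulation oracle
        matrix = matrix_of(CECROPIN_A)
        assert matrix.total_pairs == 36
        assert matrix.as_dict() == {1: 1, 2: 1, 4: 5, 5: 1, 7: 1, 11: 4,
                                    12: 5, 13: 5, 14: 1, 15: 4, 16: 8}

    def test_pooled_template_counts(self):
        matrix = matrix_of(CECROPIN_A, CA18M118)
        assert matrix.total_pairs == 61
        assert matrix.as_dict() == {1: 2, 2: 1, 4: 9, 5: 1, 7: 1, 11: 6,
                                    12: 8, 13: 8, 14: 1, 15: 8, 16: 16}

    def test_no_pairs_across_sequence_boundaries(self):
        # pooled ["KK","DD"] must not create the KD pair that "KKDD" has
        assert matrix_of("KK", "DD").as_dict() == {1: 1, 6: 1}
        assert matrix_of("KKDD").as_dict() == {1: 1, 2: 1, 6: 1}

    def test_short_or_empty_inputs_rejected(self):
        with pytest.raises(SequenceError):
            matrix_of("K")
        with pytest.raises(ValueError):
            build_incidence_matrix([])

    def test_non_canonical_strict_vs_lenient(self):
        with pytest.raises(SequenceError, match="position 2"):
            matrix_of("KXK")
        lenient = matrix_of("KXK", lenient=True)
        assert lenient.total_pairs == 0  # both pairs touch the X
        assert matrix_of("KXKK", lenient=True).as_dict() == {1: 1}

    def test_weighted_normalisation(self):
        matrix = matrix_of(CECROPIN_A, weight_factor=0.30)
        assert matrix.weighted.sum() == pytest.approx(0.30, abs=1e-12)
        np.testing.assert_allclose(
            matrix.weighted, 0.30 * matrix.counts / matrix.total_pairs)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(peptides, min_size=1, max_size=5))
    def test_matches_brute_force_oracle(self, sequences):
        matrix = matrix_of(*sequences)
        assert matrix.as_dict() == {
            p: c for p, c in oracle_counts(sequences).items() if c}
        assert matrix.total_pairs == sum(len(s) - 1 for s in sequences)

    @settings(derandomize=True, max_examples=200)
    @given(peptides)
    def test_reversal_transposes_counts(self, sequence):
        forward = matrix_of(sequence).counts.reshape(4, 4)
        backward = matrix_of(sequence[::-1]).counts.reshape(4, 4)
        np.testing.assert_array_equal(forward, backward.T)


class TestSignature:
    def test_template_signature(self, template):
        sig = template.signature
        assert sig.top4 == {16, 4, 13, 15}
        assert sig.m16 == 10
        assert sig.tie_note  # three-way tie at count 8, five zero cells

    def test_untied_descending_counts(self):
        counts = np.zeros(16, dtype=int)
        counts[:4] = [5, 4, 3, 2]
        sig = extract_signature(IncidenceMatrix(counts=counts))
        assert sig.top4_ordered == (1, 2, 3, 4)
        assert sig.m16 == 16  # highest-index zero cell

    def test_all_cells_equal(self):
        sig = extract_signature(IncidenceMatrix(counts=np.ones(16, int)))
        assert sig.top4_ordered == (16, 15, 14, 13)
        assert sig.m16 == 12  # highest index not consumed by the top four
        assert sig.tie_note

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_signature(IncidenceMatrix(counts=np.zeros(16, int)))

    @settings(derandomize=True, max_examples=200)
    @given(peptides, st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, sequence, factor):
        # the 0.30 weighting (or any positive scaling) never moves ranks
        matrix = matrix_of(sequence, weight_factor=0.30)
        rescaled = IncidenceMatrix(
            counts=matrix.counts, weight_factor=0.30 * factor)
        assert extract_signature(matrix) == extract_signature(rescaled)
        order = np.argsort(matrix.weighted)
        np.testing.assert_array_equal(order, np.argsort(rescaled.weighted))

    @settings(derandomize=True, max_examples=100)
    @given(peptides)
    def test_deterministic(self, sequence):
        assert extract_signature(matrix_of(sequence)) == \
            extract_signature(matrix_of(sequence))


class TestTemplate:
    def test_retains_only_high_ti_candidates(self, template):
        assert set(template.source_ids) == {"Cecropin-A", "CA(1-8)M(1-18)NH2"}
        assert template.q_matrix.total_pairs == 61

    def test_threshold_is_inclusive(self):
        # TI exactly 1000 (Cecropin-A) is retained
        assert "Cecropin-A" in build_template(
            template_candidates(), ti_threshold=1000.0).source_ids

    def test_unreachable_threshold_lists_rejected(self):
        with pytest.raises(ValueError, match="Melittin=500"):
            build_template(template_candidates(), ti_threshold=3000.0)

    def test_json_round_trip(self, template, tmp_path):
        path = tmp_path / "template.json"
        template.save(path)
        loaded = TemplateModel.load(path)
        assert loaded.signature == template.signature
        np.testing.assert_array_equal(loaded.q_matrix.counts,
                                      template.q_matrix.counts)
        assert loaded.source_ids == template.source_ids


class TestComparison:
    def sig(self, top4, m16):
        return Signature(top4_ordered=tuple(top4), m16=m16)

    def test_identity_matches(self, template):
        assert compare_signatures(template.signature, template.signature)

    def test_m16_only_in_strict_mode(self, template):
        subject = self.sig((16, 4, 15, 13), m16=14)
        assert not compare_signatures(subject, template.signature, "strict")
        assert compare_signatures(subject, template.signature, "top4")

    def test_disjoint_top4_never_matches(self, template):
        subject = self.sig((9, 11, 12, 15), m16=10)
        assert not compare_signatures(subject, template.signature, "strict")
        assert not compare_signatures(subject, template.signature, "top4")

    def test_top4_compared_as_set(self, template):
        scrambled = self.sig((13, 15, 4, 16), m16=10)
        assert compare_signatures(scrambled, template.signature, "strict")

    def test_unknown_mode_rejected(self, template):
        with pytest.raises(ValueError):
            compare_signatures(template.signature, template.signature, "bad")


class TestClassification:
    def test_cecropin_a_alone_is_not_scaap(self, template):
        # oracle-verified: its own top4 is {16,13,12,4}, not the
        # template's {16,4,13,15} (three-way tie at count 5 pulls in 12)
        record = PeptideRecord(id="Cecropin-A", sequence=CECROPIN_A)
        result = classify_peptide(record, template, mode="strict")
        assert result.signature.top4 == {16, 13, 12, 4}
        assert result.signature.m16 == 10
        assert not result.is_scaap
        assert not classify_peptide(record, template, mode="top4").is_scaap

    def test_bactenecin7_matches_top4_but_not_m16(self, template):
        # oracle-verified: top4 {16,4,13,15} but m16 = 14
        record = PeptideRecord(
            id="BACTENECIN 7",
            sequence="RRIRPRPPRLPRPRPRPLPFPRPGPRPIPRPLPFPRPGPRPIPRPLPFPRPG"
                     "PRPIPRPL")
        strict = classify_peptide(record, template, mode="strict")
        assert strict.signature.top4 == {16, 4, 13, 15}
        assert strict.signature.m16 == 14
        assert not strict.is_scaap
        assert classify_peptide(record, template, mode="top4").is_scaap

    def test_defensin_disjoint_signature(self, template):
        # oracle-verified: top4 {9,11,12,15} shares little with the template
        record = PeptideRecord(
            id="Bovine beta-defensin 6",
            sequence="QGVRNHVTCRIYGGFCVPIRCPGRTRQIGTCFGRPVKCCRRW")
        result = classify_peptide(record, template, mode="top4")
        assert result.signature.top4 == {9, 11, 12, 15}
        assert not result.is_scaap

    def test_single_cell_peptide_never_matches(self, template):
        record = PeptideRecord(id="kk", sequence="KK")
        for mode in ("strict", "top4"):
            assert not classify_peptide(record, template, mode=mode).is_scaap

    def test_template_reproduction_from_scratch(self, template):
        matrix = build_incidence_matrix(
            [PeptideRecord(id="a", sequence=CECROPIN_A),
             PeptideRecord(id="b", sequence=CA18M118)])
        assert extract_signature(matrix) == template.signature
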