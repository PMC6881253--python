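"""Motif coordinate assignment, classification, census, and logo."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pipflank.errors import (
    EmptyInputError,
    IncompleteMapError,
    InvalidSpanError,
    UndefinedColumnError,
)
from pipflank.motifs import (
    AMINO_ACIDS,
    MotifEntry,
    assign_positions,
    build_logo,
    classify_motif,
    coord_label,
    motif_set_statistics,
    round_half_up,
)


def make_entry(context, start, end, cls="pip_box", **kw):
    return MotifEntry(protein_id="x", species="t", context_seq=context,
                      motif_start=start, motif_end=end, declared_class=cls, **kw)


class TestAssignPositions:
    def test_p21_coordinates(self, p21_entry):
        pmap = assign_positions(p21_entry)
        assert pmap.residue_at(1) == "Q"
        assert pmap.residue_at(4) == "M"
        assert pmap.residue_at(7) == "F"
        assert pmap.residue_at(8) == "Y"
        assert pmap.index_to_coord[1] == -1       # upstream R
        assert pmap.residue_at(-1) == "R"
        assert pmap.index_to_coord[12] == 11      # K three past the motif
        assert coord_label(11) == "+3"

    def test_apim_core_aligns_to_6_plus2(self, apim_entry):
        pmap = assign_positions(apim_entry)
        # core RWLVK occupies 6, 7, 8, +1, +2
        assert [pmap.residue_at(c) for c in (6, 7, 8, 9, 10)] == list("RWLVK")
        # contiguous back-extension: D -> 5, M -> 4; trailing W -> +3
        assert pmap.residue_at(5) == "D"
        assert pmap.residue_at(4) == "M"
        assert pmap.residue_at(11) == "W"

    def test_motif_at_chain_start_has_no_negative_coords(self):
        pmap = assign_positions(make_entry("QTSMTDFYHS", 1, 8))
        assert min(pmap.coords()) == 1

    def test_zero_never_used_and_span_crosses_it(self):
        pmap = assign_positions(make_entry("ASCDQTSMTDFY", 5, 12))
        coords = pmap.coords()
        assert 0 not in coords
        assert coords == [-4, -3, -2, -1, 1, 2, 3, 4, 5, 6, 7, 8]

    @pytest.mark.parametrize("cls,start,end", [
        ("pip_box", 1, 7), ("pip_degron", 1, 9), ("apim", 1, 8),
    ])
    def test_invalid_span_rejected(self, cls, start, end):
        entry = make_entry("QTSMTDFYHSKRR", start, end, cls=cls)
        with pytest.raises(InvalidSpanError):
            assign_positions(entry)

    @given(start=st.integers(1, 10))
    def test_bijection_round_trip(self, start):
        seq = "GSGSGSGSG" + "QTSMTDFY" + "GSGSGSGSG"
        entry = make_entry(seq[: start + 16], start, start + 7)
        pmap = assign_positions(entry)
        inv = pmap.coord_to_index
        assert len(inv) == len(pmap.index_to_coord)
        for i, c in pmap.index_to_coord.items():
            assert inv[c] == i


class TestClassify:
    def test_p21_is_degron_with_all_flags(self, p21_entry):
        flags = classify_motif(p21_entry)
        assert flags.motif_class == "pip_degron"
        assert flags.has_Q1 and flags.has_hydrophobic4
        assert flags.has_aromatic7 and flags.has_aromatic8
        assert flags.degron_TD56 and flags.degron_basic_plus4

    def test_degron_rule_is_monotone_in_plus4(self, p21_entry):
        # mutate the +4 basic (R at context index 13) to S: degron -> box
        seq = p21_entry.context_seq[:12] + "S" + p21_entry.context_seq[13:]
        mutant = make_entry(seq, 2, 9, cls="pip_degron")
        assert classify_motif(mutant).motif_class == "pip_box"

    def test_fen1_is_canonical_pip_box(self):
        flags = classify_motif(make_entry("TQGRLDDFFKVTGSL", 2, 9))
        assert flags.motif_class == "pip_box"
        assert flags.has_Q1 and flags.has_hydrophobic4
        assert flags.has_aromatic7 and flags.has_aromatic8
        assert not flags.degron_basic_plus4

    def test_srs2_single_canonical_residue_is_unknown(self):
        flags = classify_motif(make_entry("ASSQMDIF", 1, 8, cls="unknown"))
        assert flags.motif_class == "unknown"
        assert flags.has_aromatic8
        assert not (flags.has_Q1 or flags.has_hydrophobic4 or flags.has_aromatic7)

    def test_apim_consensus_matched(self, apim_entry):
        flags = classify_motif(apim_entry)
        assert flags.apim_consensus
        assert flags.motif_class == "apim"

    def test_strict_mode_requires_coordinates_1_to_8(self, apim_entry):
        # the APIM peptide starts mid-ladder: coordinates 1-3 do not exist
        with pytest.raises(IncompleteMapError):
            classify_motif(apim_entry, strict=True)


class TestCensus:
    def test_two_entry_toy_set(self, p21_entry):
        noq = make_entry("ASSQMDIF", 1, 8, cls="unknown")
        stats = motif_set_statistics([p21_entry, noq])
        assert stats.percents["no_Q1"] == 50
        assert stats.total == 2

    def test_fractions_match_flag_counts_on_built_fixture(self):
        # 10 entries with known flags: 3 lack Q1, 2 lack exactly one aromatic
        entries = (
            [make_entry("QTSMTDFYHS", 1, 8)] * 4
            + [make_entry("ATSMTDFYHS", 1, 8, cls="unknown")] * 3  # no Q1
            + [make_entry("QTSMTDFGHS", 1, 8, cls="unknown")] * 2  # 8 not arom
            + [make_entry("QTSATDGGHS", 1, 8, cls="unknown")]      # none
        )
        stats = motif_set_statistics(entries)
        assert stats.counts == {
            "no_Q1": 3, "no_hydrophobic4": 1,
            "missing_one_aromatic": 2, "missing_both_aromatics": 1,
        }
        assert stats.fractions["no_Q1"] == pytest.approx(0.3)

    def test_order_permutation_invariance(self, reference_entries):
        fwd = motif_set_statistics(reference_entries)
        rev = motif_set_statistics(list(reversed(reference_entries)))
        assert fwd.counts == rev.counts

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            motif_set_statistics([])


class TestLogo:
    def test_single_letter_column_is_maximal(self):
        entries = [make_entry("QTSMTDFY", 1, 8) for _ in range(5)]
        logo = build_logo(entries, range(1, 9))
        assert logo.information == pytest.approx(np.log2(20), abs=1e-12)

    def test_uniform_column_is_zero_bits(self):
        entries = [make_entry(aa + "TSMTDFY", 1, 8, cls="unknown")
                   for aa in AMINO_ACIDS]
        logo = build_logo(entries, [1])
        assert logo.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_entropy_four_sequences(self):
        # column 1 over {Q, Q, A, S}: H = -(1/2 log 1/2 + 2 * 1/4 log 1/4)
        seqs = ["QTSMTDFY", "QTSMTDFY", "ATSMTDFY", "STSMTDFY"]
        entries = [make_entry(s, 1, 8, cls="unknown") for s in seqs]
        logo = build_logo(entries, [1])
        h = -(0.5 * np.log2(0.5) + 2 * 0.25 * np.log2(0.25))
        assert logo.information[0] == pytest.approx(np.log2(20) - h, abs=1e-12)
        assert logo.freq(1, "Q") == pytest.approx(0.5)

    def test_gaps_excluded_from_counts(self):
        entries = [make_entry("QARL--PF", 1, 8),
                   make_entry("QARLKSPF", 1, 8)]
        logo = build_logo(entries, range(1, 9))
        assert logo.counts[4] == 1  # only the ungapped entry observes coord 5
        assert logo.freq(5, "K") == pytest.approx(1.0)

    def test_column_without_observations_is_an_error(self):
        entries = [make_entry("QARL--PF", 1, 8)]
        with pytest.raises(UndefinedColumnError):
            build_logo(entries, [5])

    def test_frequencies_sum_to_one(self, reference_entries):
        logo = build_logo(reference_entries, range(1, 9))
        assert logo.frequencies.sum(axis=1) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("x,dec,expected", [
    (33.73, 0, 34), (9.64, 0, 10), (6.25, 1, 6.3), (3.75, 1, 3.8),
    (0.9375, 0, 1), (-0.5, 0, -1),
])
def test_round_half_up(x, dec, expected):
    assert round_half_up(x, dec) == expected
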