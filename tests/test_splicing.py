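import numpy as np
import pytest

from pepsplice import (
    CIS_NORMAL,
    CIS_REVERSE,
    NON_SPLICED,
    TRANS,
    UNMAPPED,
    Decomposition,
    Substrate,
    classify_peptide,
    enumerate_cis,
    enumerate_nonspliced,
    map_peptide,
)

from conftest import as_tuples, brute_force_decompositions


class TestSubstrate:
    def test_parental_numbering(self):
        sub = Substrate(id="s", sequence="ACDEF", numbering_offset=10)
        assert sub.first_position == 10
        assert sub.last_position == 14
        assert sub.residue_at(12) == "D"
        assert sub.segment(11, 13) == "CDE"

    def test_out_of_range_position_errors(self):
        sub = Substrate(id="s", sequence="ACDEF", numbering_offset=10)
        with pytest.raises(IndexError):
            sub.residue_at(9)


class TestDecomposition:
    def test_category_coordinate_consistency_enforced(self):
        with pytest.raises(ValueError):
            Decomposition(CIS_NORMAL, (5, 9), (7, 12))  # overlap
        with pytest.raises(ValueError):
            Decomposition(TRANS, (1, 3), (5, 8))  # disjoint
        with pytest.raises(ValueError):
            Decomposition(NON_SPLICED, (1, 3), (5, 8))

    def test_derived_positions(self):
        d = Decomposition(CIS_NORMAL, (5, 6), (8, 14))
        assert d.psp_p1 == 6
        assert d.scs_p1 == 14
        assert d.intervening_length == 1
        assert (d.sr1_length, d.sr2_length) == (2, 7)
        ns = Decomposition(NON_SPLICED, (5, 14))
        assert ns.psp_p1 is None
        assert ns.scs_p1 == 14
        assert ns.intervening_length is None
        tr = Decomposition(TRANS, (1, 5), (1, 5))
        assert tr.intervening_length is None


class TestEnumerateNonspliced:
    def test_exact_fit_yields_single_entry(self):
        sub = Substrate(id="s", sequence="ACDEFGHI")  # length 8
        assert len(enumerate_nonspliced(sub, 8, 12)) == 1

    def test_too_short_substrate_yields_nothing(self):
        sub = Substrate(id="s", sequence="ACDEFGH")  # length 7
        assert enumerate_nonspliced(sub, 8, 12) == []

    def test_closed_form_count_for_length_34(self, kras):
        # sum over l in 8..12 of (34 - l + 1)
        expected = sum(34 - l + 1 for l in range(8, 13))
        assert expected == 125
        assert len(enumerate_nonspliced(kras.g12v, 8, 12)) == 125

    def test_empty_range_errors(self, kras):
        with pytest.raises(ValueError):
            enumerate_nonspliced(kras.g12v, 9, 8)

    def test_coordinates_reconstruct_sequences(self, kras):
        for seq, d in enumerate_nonspliced(kras.g12v, 8, 12):
            assert d.sequence(kras.g12v) == seq
            assert len(seq) == d.sr1[1] - d.sr1[0] + 1


def oracle_cis_pairs(sub, min_len, max_len, include_reverse, min_sr_len=1):
    """Quadruple-loop oracle over all disjoint interval pairs."""
    lo, hi = sub.first_position, sub.last_position
    out = set()
    for i1 in range(lo, hi + 1):
        for j1 in range(i1, hi + 1):
            for i2 in range(lo, hi + 1):
                for j2 in range(i2, hi + 1):
                    l1, l2 = j1 - i1 + 1, j2 - i2 + 1
                    if l1 < min_sr_len or l2 < min_sr_len:
                        continue
                    if not min_len <= l1 + l2 <= max_len:
                        continue
                    if j1 < i2:
                        out.add((CIS_NORMAL, (i1, j1), (i2, j2)))
                    elif j2 < i1 and include_reverse:
                        out.add((CIS_REVERSE, (i1, j1), (i2, j2)))
    return out


class TestEnumerateCis:
    def test_equals_quadruple_loop_oracle(self):
        sub = Substrate(id="s", sequence="ACDEFGHIK")
        got = {(d.category, d.sr1, d.sr2) for _s, d in enumerate_cis(sub, 8, 8, include_reverse=False)}
        assert got == oracle_cis_pairs(sub, 8, 8, include_reverse=False)

    def test_reverse_flag_contract(self, kras):
        normal_only = enumerate_cis(kras.g12v, 8, 9, include_reverse=False)
        assert all(d.category == CIS_NORMAL for _s, d in normal_only)
        both = enumerate_cis(kras.g12v, 8, 9, include_reverse=True)
        assert any(d.category == CIS_REVERSE for _s, d in both)

    def test_kras_g12v_contains_printed_spliced_candidate(self, kras):
        seqs = {s for s, d in enumerate_cis(kras.g12v, 8, 12) if d.category == CIS_NORMAL}
        assert "KLVVGAVGV" in seqs

    def test_min_sr_len_respected(self, kras):
        entries = enumerate_cis(kras.g12v, 8, 10, min_sr_len=3)
        assert all(d.sr1_length >= 3 and d.sr2_length >= 3 for _s, d in entries)


class TestMapPeptide:
    def test_three_equivalent_decompositions_of_spliced_candidate(self, kras):
        # removal of any one of the three consecutive V residues explains the
        # same 9mer, so exactly 3 cis-normal decompositions with one
        # intervening residue each
        decomps = map_peptide("KLVVGAVGV", kras.g12v)
        assert len(decomps) == 3
        assert all(d.category == CIS_NORMAL for d in decomps)
        assert all(d.intervening_length == 1 for d in decomps)
        assert {(d.sr1, d.sr2) for d in decomps} == {
            ((5, 6), (8, 14)),
            ((5, 7), (9, 14)),
            ((5, 8), (10, 14)),
        }

    def test_substring_has_nonspliced_decomposition(self, kras):
        decomps = map_peptide("KLVVVGAVGV", kras.g12v)
        assert any(d.category == NON_SPLICED and d.sr1 == (5, 14) for d in decomps)

    def test_doubled_sequence_requires_two_molecules(self):
        sub = Substrate(id="s", sequence="ACDEF")
        decomps = map_peptide("ACDEFACDEF", sub)
        assert decomps
        assert all(d.category == TRANS for d in decomps)

    def test_unmappable_peptide_yields_empty_list(self, kras):
        assert map_peptide("WWWWWWWW", kras.g12v) == []

    def test_matches_brute_force_oracle_on_random_substrates(self):
        rng = np.random.default_rng(123)
        aas = np.array(list("ACDG"))  # small alphabet forces repeats/ambiguity
        for _ in range(30):
            L = rng.integers(4, 13)
            sub = Substrate(id="r", sequence="".join(rng.choice(aas, size=L)),
                            numbering_offset=int(rng.integers(1, 50)))
            k = rng.integers(2, 7)
            start = rng.integers(0, L - 1)
            pep = (sub.sequence * 2)[start : start + k]
            got = as_tuples(map_peptide(pep, sub))
            assert got == brute_force_decompositions(pep, sub)


class TestClassifyPeptide:
    def test_precedence_nonspliced_over_cis(self):
        decomps = [
            Decomposition(CIS_NORMAL, (1, 2), (4, 6)),
            Decomposition(NON_SPLICED, (1, 5)),
        ]
        assert classify_peptide(decomps) == NON_SPLICED

    def test_spliced_candidate_is_cis(self, kras):
        assert classify_peptide(map_peptide("KLVVGAVGV", kras.g12v)) == CIS_NORMAL

    def test_trans_only_when_nothing_else_fits(self):
        sub = Substrate(id="s", sequence="ACDEF")
        assert classify_peptide(map_peptide("ACDEFACDEF", sub)) == TRANS

    def test_empty_list_is_unmapped(self):
        assert classify_peptide([]) == UNMAPPED

    def test_no_substring_ever_labeled_spliced(self, kras):
        sub = kras.g12v
        rng = np.random.default_rng(5)
        for _ in range(25):
            i = rng.integers(0, len(sub) - 2)
            j = rng.integers(i + 2, len(sub) + 1)
            pep = sub.sequence[i:j]
            assert classify_peptide(map_peptide(pep, sub)) == NON_SPLICED


class TestCoordinateReporting:
    def test_parental_offset_applied_everywhere(self):
        rng = np.random.default_rng(9)
        base = Substrate(id="b", sequence="ACDEACDGH", numbering_offset=1)
        for _ in range(10):
            off = int(rng.integers(1, 200))
            shifted = Substrate(id="s", sequence=base.sequence, numbering_offset=off)
            for (s0, d0), (s1, d1) in zip(
                enumerate_cis(base, 6, 8), enumerate_cis(shifted, 6, 8)
            ):
                assert s0 == s1
                assert d1.sr1 == (d0.sr1[0] + off - 1, d0.sr1[1] + off - 1)
                assert d1.sr2 == (d0.sr2[0] + off - 1, d0.sr2[1] + off - 1)
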