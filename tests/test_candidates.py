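import numpy as np
import pandas as pd
import pytest
from pyteomics import mass as pyt_mass

from pepsplice import (
    ProteinRecord,
    Substrate,
    ToyAnchorPredictor,
    build_inclusion_list,
    candidates_from_enumeration,
    check_uniqueness,
    enumerate_cis,
    enumerate_nonspliced,
    export_search_database,
    filter_binding,
    filter_mutation,
    peptide_mz,
)
from pepsplice.candidates import PROTON_MASS
from pepsplice.io import read_fasta

from conftest import brute_force_decompositions


@pytest.fixture()
def kras_candidates(kras):
    entries = enumerate_nonspliced(kras.g12v, 8, 12)
    entries += enumerate_cis(kras.g12v, 8, 12)
    return candidates_from_enumeration(entries)


class TestMutationFilter:
    def test_nonspliced_candidate_covering_mutation_kept(self, kras, kras_candidates):
        kept = {c.sequence for c in filter_mutation(kras_candidates, kras.g12v, 12, "V")}
        assert "KLVVVGAVGV" in kept  # parental interval [5, 14] covers 12

    def test_spliced_candidate_kept_via_sr2(self, kras, kras_candidates):
        kept = {c.sequence: c for c in filter_mutation(kras_candidates, kras.g12v, 12, "V")}
        assert "KLVVGAVGV" in kept
        assert kept["KLVVGAVGV"].carries_mutation

    def test_candidate_away_from_mutation_removed(self, kras, kras_candidates):
        kept = filter_mutation(kras_candidates, kras.g12v, 12, "V")
        distal = kras.g12v.segment(20, 30)
        assert distal not in {c.sequence for c in kept}

    def test_inconsistent_substrate_errors(self, kras, kras_candidates):
        with pytest.raises(ValueError, match="expected mutant"):
            filter_mutation(kras_candidates, kras.wild_type, 12, "V")


class TestBindingFilter:
    def _cands(self, kras_candidates):
        return [c for c in kras_candidates if c.sequence in ("KLVVGAVGV", "KLVVVGAVGV")]

    def test_cutoff_is_boundary_inclusive(self, kras_candidates):
        cands = self._cands(kras_candidates)
        table = {"KLVVGAVGV": 99.0, "KLVVVGAVGV": 101.0}
        kept = filter_binding(cands, table, cutoff_nM=100.0)
        assert {c.sequence for c in kept} == {"KLVVGAVGV"}
        assert kept[0].predicted_ic50 == 99.0

    def test_missing_prediction_drops_with_warning(self, kras_candidates, caplog):
        cands = self._cands(kras_candidates)
        kept = filter_binding(cands, {"KLVVGAVGV": 50.0}, cutoff_nM=100.0)
        assert len(kept) == 1

    def test_empty_candidate_list_passes_through(self):
        assert filter_binding([], {}, cutoff_nM=100.0) == []

    def test_negative_cutoff_errors(self, kras_candidates):
        with pytest.raises(ValueError):
            filter_binding(kras_candidates, {}, cutoff_nM=-1.0)

    def test_callable_predictor_interface(self, kras_candidates):
        cands = self._cands(kras_candidates)
        kept = filter_binding(cands, lambda s: 10.0, cutoff_nM=100.0)
        assert len(kept) == 2

    def test_toy_anchor_predictor_scores_both_levels(self):
        toy = ToyAnchorPredictor()
        assert toy("KLVVGAVGV") == toy.binder_nM  # P2 L, C-term V
        assert toy("KGGGGGGGD") == toy.nonbinder_nM


class TestUniqueness:
    def test_verbatim_substring_flags_protein(self):
        proteome = [
            ProteinRecord(id="a", sequence="XXACDEFYY".replace("X", "G").replace("Y", "G")),
            ProteinRecord(id="b", sequence="CCCCCCCC"),
        ]
        report = check_uniqueness("ACDEF", proteome)
        assert report.table.loc["a", "hydrolysis"]
        assert not report.unique

    def test_absent_peptide_is_unique(self):
        report = check_uniqueness("AAAA", [ProteinRecord(id="c", sequence="CCCC")])
        assert report.unique

    def test_source_protein_excluded_from_verdict(self, kras):
        proteome = [ProteinRecord(id="KRAS", sequence=kras.g12v.sequence)]
        report = check_uniqueness("KLVVGAVGV", proteome, source_ids=["KRAS"])
        assert report.table.loc["KRAS", "cis_splicing"]
        assert report.unique

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        aas = np.array(list("ACDEG"))
        proteome = [
            ProteinRecord(id=f"p{k}", sequence="".join(rng.choice(aas, size=40)))
            for k in range(50)
        ]
        pep = "".join(rng.choice(aas, size=9))
        report = check_uniqueness(pep, proteome)
        for rec in proteome:
            sub = Substrate(id=rec.id, sequence=rec.sequence)
            oracle = brute_force_decompositions(pep, sub)
            oracle_hydrolysis = any(c == "non-spliced" for c, *_ in oracle)
            oracle_cis = any(c in ("cis-normal", "cis-reverse") for c, *_ in oracle)
            assert report.table.loc[rec.id, "hydrolysis"] == oracle_hydrolysis
            assert report.table.loc[rec.id, "cis_splicing"] == oracle_cis


class TestSearchDatabase:
    def test_unique_sequences_and_round_trip(self, tmp_path, kras):
        entries = enumerate_nonspliced(kras.g12v, 8, 12)
        expected = len({s for s, _ in entries})
        path = tmp_path / "db.fasta"
        n = export_search_database(entries, path, kras.g12v.id)
        assert n == expected
        records = read_fasta(path)
        assert {r.sequence for r in records} == {s for s, _ in entries}

    def test_duplicate_across_categories_collapses_by_precedence(self, tmp_path, kras):
        entries = enumerate_nonspliced(kras.g12v, 8, 12) + enumerate_cis(kras.g12v, 8, 12)
        path = tmp_path / "db.fasta"
        export_search_database(entries, path, kras.g12v.id)
        headers = {r.id.split("|")[2].split("=")[0]: r for r in read_fasta(path)}
        for rec in read_fasta(path):
            seq_is_substring = rec.sequence in kras.g12v.sequence
            category = rec.id.split("|")[1]
            if seq_is_substring:
                assert category == "non-spliced"


class TestInclusionList:
    def test_gg_neutral_mass_from_residue_table(self):
        # 2 x Gly (57.02146) + water (18.010565)
        mz1 = peptide_mz("GG", 1)
        assert mz1 * 1 - PROTON_MASS == pytest.approx(132.05349, abs=1e-4)

    def test_mz_definition_per_charge(self):
        m = pyt_mass.calculate_mass(sequence="SAMPLER")
        assert peptide_mz("SAMPLER", 2) == pytest.approx((m + 2 * PROTON_MASS) / 2, abs=1e-9)

    def test_sorted_by_mz_and_recomputable(self, kras):
        peps = [s for s, _ in enumerate_nonspliced(kras.g12v, 8, 9)]
        df = build_inclusion_list(peps, charges=(1, 2, 3))
        assert (df["mz"].diff().dropna() >= 0).all()
        for row in df.itertuples():
            assert abs(row.mz - peptide_mz(row.sequence, row.charge)) < 1e-4

    def test_unknown_residue_errors(self):
        with pytest.raises(ValueError):
            peptide_mz("ACDEFZ1", 1)

    def test_charge_range_enforced(self):
        with pytest.raises(ValueError):
            build_inclusion_list(["ACDEFGHK"], charges=(0,))
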