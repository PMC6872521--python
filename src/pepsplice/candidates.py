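"""Epitope candidate filtering, uniqueness scanning and targeted-MS exports.

From the exhaustive enumeration of theoretical 8-12mer products, candidates
are narrowed down in sequence-level steps: keep those whose decompositions
cover the tumor mutation, then those predicted to bind the HLA-I allele of
interest with IC50 at or below a cutoff (100 nM by default).  Binding
predictions are pluggable -- an imported table (e.g. a NetMHCPan export) or
any callable mapping a peptide sequence to an IC50 in nM.

A surviving candidate can be checked for uniqueness against a proteome: a
spliced neoepitope is unique when no other protein can produce its sequence
either by plain hydrolysis (substring) or by cis peptide splicing.

For targeted acquisition, peptide lists are turned into an m/z inclusion
list from monoisotopic residue masses (pyteomics), and enumerations can be
exported as a FASTA search database for spectrum identification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping

import pandas as pd
from pyteomics import mass as _mass
from pyteomics.auxiliary import PyteomicsError

from .splicing import (
    CATEGORY_PRECEDENCE,
    Decomposition,
    Substrate,
    classify_peptide,
    find_occurrences,
)

logger = logging.getLogger(__name__)

#: Monoisotopic proton mass in Da, used for m/z computation.
PROTON_MASS = 1.007276466879


@dataclass(frozen=True)
class EpitopeCandidate:
    """A sequence-level candidate with all its substrate decompositions."""

    sequence: str
    decompositions: tuple[Decomposition, ...]
    carries_mutation: bool = False
    predicted_ic50: float | None = None

    @property
    def category(self) -> str:
        return classify_peptide(self.decompositions)


def candidates_from_enumeration(
    entries: Iterable[tuple[str, Decomposition]]
) -> list[EpitopeCandidate]:
    """Collapse coordinate-level enumeration entries to sequence-level
    candidates, retaining every decomposition of each unique sequence."""
    by_seq: dict[str, list[Decomposition]] = {}
    for seq, d in entries:
        by_seq.setdefault(seq, []).append(d)
    return [
        EpitopeCandidate(sequence=s, decompositions=tuple(ds))
        for s, ds in sorted(by_seq.items())
    ]


def filter_length(
    candidates: Iterable[EpitopeCandidate], min_len: int = 8, max_len: int = 12
) -> list[EpitopeCandidate]:
    """Keep candidates within the HLA-I-typical length range."""
    if min_len < 1 or max_len < min_len:
        raise ValueError("invalid length range")
    return [c for c in candidates if min_len <= len(c.sequence) <= max_len]


def _covers(d: Decomposition, position: int) -> bool:
    if d.sr1[0] <= position <= d.sr1[1]:
        return True
    return d.sr2 is not None and d.sr2[0] <= position <= d.sr2[1]


def filter_mutation(
    candidates: Iterable[EpitopeCandidate],
    substrate: Substrate,
    position: int,
    mutant_residue: str,
) -> list[EpitopeCandidate]:
    """Keep candidates with at least one decomposition covering the mutated
    parental position; sets ``carries_mutation`` on the kept candidates.

    Raises
    ------
    ValueError
        If the substrate does not actually carry ``mutant_residue`` at
        ``position`` (inconsistent substrate).
    """
    actual = substrate.residue_at(position)
    if actual != mutant_residue:
        raise ValueError(
            f"substrate {substrate.id!r} carries {actual!r} at position "
            f"{position}, expected mutant residue {mutant_residue!r}"
        )
    return [
        replace(c, carries_mutation=True)
        for c in candidates
        if any(_covers(d, position) for d in c.decompositions)
    ]


#: A binding predictor is any callable peptide -> IC50 (nM).
BindingPredictor = Callable[[str], float]


def predictor_from_table(table: pd.DataFrame | Mapping[str, float]) -> BindingPredictor:
    """Wrap a prediction table as a predictor callable.

    ``table`` is either a mapping ``peptide -> ic50_nM`` or a DataFrame with
    ``peptide`` and ``ic50_nM`` columns (an ``allele`` column may be present
    but is not interpreted; filter it beforehand).  Peptides absent from the
    table raise KeyError, which :func:`filter_binding` treats as "no
    prediction".
    """
    if isinstance(table, pd.DataFrame):
        mapping = dict(zip(table["peptide"], table["ic50_nM"].astype(float)))
    else:
        mapping = dict(table)
    return mapping.__getitem__


class ToyAnchorPredictor:
    """Toy anchor-motif IC50 scorer for offline tests ONLY.

    Scores HLA-A*02:01-like anchors: a hydrophobic P2 residue and a
    hydrophobic C-terminal residue give a "binder" IC50 (50 nM), anything
    else a "non-binder" IC50 (5000 nM).  This is NOT a trained binding
    predictor and must never be used for real candidate selection; it
    exists so the pluggable-predictor interface can be exercised without
    external software.
    """

    P2_ANCHORS = frozenset("LMIV")
    CTERM_ANCHORS = frozenset("VLIAM")

    def __init__(self, binder_nM: float = 50.0, nonbinder_nM: float = 5000.0):
        self.binder_nM = binder_nM
        self.nonbinder_nM = nonbinder_nM

    def __call__(self, peptide: str) -> float:
        if len(peptide) >= 2 and peptide[1] in self.P2_ANCHORS and peptide[-1] in self.CTERM_ANCHORS:
            return self.binder_nM
        return self.nonbinder_nM


def filter_binding(
    candidates: Iterable[EpitopeCandidate],
    predictions: BindingPredictor | Mapping[str, float] | pd.DataFrame,
    cutoff_nM: float = 100.0,
) -> list[EpitopeCandidate]:
    """Keep candidates with predicted IC50 <= cutoff (boundary inclusive).

    Candidates without a prediction are dropped with a warning.  The
    prediction source is pluggable: a callable, a mapping, or a table.
    """
    if cutoff_nM < 0:
        raise ValueError("IC50 cutoff must be non-negative")
    if not callable(predictions):
        predictions = predictor_from_table(predictions)
    kept: list[EpitopeCandidate] = []
    n_missing = 0
    for c in candidates:
        try:
            ic50 = float(predictions(c.sequence))
        except KeyError:
            n_missing += 1
            continue
        if ic50 <= 0:
            raise ValueError(f"non-positive IC50 {ic50} for {c.sequence}")
        if ic50 <= cutoff_nM:
            kept.append(replace(c, predicted_ic50=ic50))
    if n_missing:
        logger.warning("dropped %d candidate(s) without a binding prediction", n_missing)
    return kept


@dataclass
class UniquenessReport:
    """Per-protein producibility of a peptide across a proteome."""

    peptide: str
    table: pd.DataFrame  # columns: hydrolysis (bool), cis_splicing (bool); index: protein id
    source_ids: tuple[str, ...] = ()

    @property
    def unique(self) -> bool:
        """True when no protein other than the designated source(s) can
        produce the peptide by hydrolysis or cis splicing."""
        others = self.table.drop(index=list(self.source_ids), errors="ignore")
        return not bool((others["hydrolysis"] | others["cis_splicing"]).any())


def _cis_producible(peptide: str, sequence: str, min_sr_len: int = 1) -> bool:
    """Whether ``peptide`` has at least one cis (normal or reverse order)
    two-segment decomposition against ``sequence``."""
    n = len(peptide)
    for split in range(min_sr_len, n - min_sr_len + 1):
        occ_l = find_occurrences(peptide[:split], sequence)
        if not occ_l:
            continue
        occ_r = find_occurrences(peptide[split:], sequence)
        if not occ_r:
            continue
        len_l, len_r = split, n - split
        # normal order: some left occurrence ends before some right one starts
        if min(occ_l) + len_l - 1 < max(occ_r):
            return True
        # reverse order: some right occurrence ends before some left one starts
        if min(occ_r) + len_r - 1 < max(occ_l):
            return True
    return False


def check_uniqueness(
    peptide: str,
    proteome: Iterable,
    source_ids: Iterable[str] = (),
    min_sr_len: int = 1,
) -> UniquenessReport:
    """Scan a proteome for proteins able to produce ``peptide``.

    For each protein, reports whether the peptide is a substring (plain
    hydrolysis) and whether it has at least one cis-splicing decomposition.
    ``source_ids`` name the designated source protein(s) excluded from the
    aggregate ``unique`` verdict.
    """
    rows = {}
    for rec in proteome:
        seq = rec.sequence
        rows[rec.id] = (
            peptide in seq,
            _cis_producible(peptide, seq, min_sr_len=min_sr_len),
        )
    if not rows:
        raise ValueError("proteome is empty")
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["hydrolysis", "cis_splicing"]
    )
    table.index.name = "id"
    return UniquenessReport(peptide=peptide, table=table, source_ids=tuple(source_ids))


def _interval_key(d: Decomposition) -> tuple:
    return (CATEGORY_PRECEDENCE.index(d.category), d.sr1, d.sr2 or (0, 0))


def export_search_database(
    entries: Iterable[tuple[str, Decomposition]],
    path,
    substrate_id: str,
) -> int:
    """Write enumeration entries as a FASTA search database.

    One record per unique peptide sequence; the header encodes the
    substrate, the category under classification precedence, the
    coordinates of one representative decomposition (the
    highest-precedence, lowest-coordinate one) and the number of
    alternative decompositions.  Returns the number of records written.
    """
    from .io import write_fasta  # local import to avoid cycle
    from .features import ProteinRecord

    by_seq: dict[str, list[Decomposition]] = {}
    for seq, d in entries:
        by_seq.setdefault(seq, []).append(d)
    if not by_seq:
        raise ValueError("no entries to export")
    records = []
    for seq in sorted(by_seq):
        ds = sorted(by_seq[seq], key=_interval_key)
        rep = ds[0]
        coord = f"sr1={rep.sr1[0]}-{rep.sr1[1]}"
        if rep.sr2 is not None:
            coord += f";sr2={rep.sr2[0]}-{rep.sr2[1]}"
        header = (
            f"{substrate_id}|{classify_peptide(ds)}|{coord}|alt={len(ds) - 1}"
        )
        records.append(ProteinRecord(id=header, sequence=seq))
    write_fasta(records, path)
    return len(records)


def peptide_mz(sequence: str, charge: int) -> float:
    """Mass-to-charge ratio of a peptide at a given charge state.

    The neutral monoisotopic mass is the sum of residue monoisotopic masses
    plus water (pyteomics); m/z = (M + z * m_proton) / z.
    """
    if not 1 <= charge <= 7:
        raise ValueError("charge must be in 1..7")
    try:
        neutral = _mass.calculate_mass(sequence=sequence)
    except PyteomicsError as exc:
        raise ValueError(f"cannot compute mass of {sequence!r}: {exc}") from exc
    return (neutral + charge * PROTON_MASS) / charge


def build_inclusion_list(
    peptides: Iterable[str],
    charges: Iterable[int] = (1, 2, 3),
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Targeted-MS inclusion list: one row per (peptide, charge state).

    Modifications are not modelled (unmodified monoisotopic masses only).
    Returns a DataFrame with columns ``sequence, charge, mz`` (plus
    ``category`` when provided), sorted by non-decreasing m/z.
    """
    charges = sorted(set(int(z) for z in charges))
    if any(z < 1 or z > 7 for z in charges):
        raise ValueError("charges must be within 1..7")
    rows = []
    for pep in sorted(set(peptides)):
        for z in charges:
            row = {"sequence": pep, "charge": z, "mz": peptide_mz(pep, z)}
            if categories is not None:
                row["category"] = categories.get(pep, UNMAPPED_CATEGORY)
            rows.append(row)
    if not rows:
        raise ValueError("no peptides for inclusion list")
    df = pd.DataFrame(rows).sort_values(["mz", "sequence", "charge"], kind="stable")
    return df.reset_index(drop=True)


UNMAPPED_CATEGORY = "unmapped"
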