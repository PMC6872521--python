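"""Protein physicochemical features for antigen prioritization.

Antigens that are over-represented in HLA class I immunopeptidomes by
spliced and non-spliced peptides tend to differ from the bulk proteome in a
small number of intrinsic, cell-state-independent characteristics.  This
module computes the four characteristics used by the ranking model --
sequence length, mean residue hydropathy (GRAVY, Kyte-Doolittle scale),
isoelectric point, and the Guruprasad dipeptide instability index -- and
provides the z-standardization and weighted feature sum

    f = sum_i p_i * c_i

where ``c`` is the standardized feature vector of a protein and ``p`` is a
factor vector with components in [-1, 1] (negative components favor
representation).

The per-protein computations are delegated to Biopython's ProtParam
implementation (the standard ExPASy conventions): GRAVY is the mean
Kyte-Doolittle hydropathy, the instability index is
``II = (10/L) * sum_i DIWV(x_i, x_{i+1})``, and the isoelectric point is the
root of the Henderson-Hasselbalch net-charge function found by bisection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

logger = logging.getLogger(__name__)

#: The canonical 20-letter amino-acid alphabet. Feature tables (hydropathy,
#: DIWV) are defined for these residues only.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Column order used throughout the module.
FEATURE_NAMES = ("length", "gravy", "isoelectric_point", "instability")


class NonCanonicalResidueError(ValueError):
    """A sequence contains a residue outside the canonical 20-letter alphabet.

    Attributes
    ----------
    position : int
        1-based position of the first offending residue.
    residue : str
        The offending character.
    """

    def __init__(self, record_id: str, position: int, residue: str):
        self.position = position
        self.residue = residue
        super().__init__(
            f"protein {record_id!r}: non-canonical residue {residue!r} "
            f"at position {position}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def first_noncanonical(self) -> tuple[int, str] | None:
        """Return (1-based position, residue) of the first non-canonical
        residue, or None if the sequence is clean."""
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in CANONICAL_AA:
                return i, aa
        return None


@dataclass(frozen=True)
class ProteinFeatureVector:
    """The four raw (unstandardized) characteristics of one protein."""

    length: int
    gravy: float
    isoelectric_point: float
    instability: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 < self.isoelectric_point < 14.0:
            raise ValueError(
                f"isoelectric point {self.isoelectric_point} outside (0, 14)"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.length, self.gravy, self.isoelectric_point, self.instability],
            dtype=float,
        )


def compute_protein_features(record: ProteinRecord) -> ProteinFeatureVector:
    """Compute length, GRAVY, pI and instability index for one protein.

    Raises
    ------
    NonCanonicalResidueError
        If the sequence contains a residue outside the canonical alphabet;
        the error reports the offending position.
    """
    bad = record.first_noncanonical()
    if bad is not None:
        raise NonCanonicalResidueError(record.id, bad[0], bad[1])
    pa = ProteinAnalysis(record.sequence)
    return ProteinFeatureVector(
        length=len(record.sequence),
        gravy=pa.gravy(),
        isoelectric_point=pa.isoelectric_point(),
        instability=pa.instability_index(),
    )


def feature_table(
    records: Iterable[ProteinRecord],
    on_noncanonical: str = "skip",
) -> pd.DataFrame:
    """Compute the feature table for a protein set.

    Parameters
    ----------
    records:
        Protein records; IDs must be unique.
    on_noncanonical:
        ``"skip"`` drops proteins with non-canonical residues (count is
        logged), ``"raise"`` propagates the error. Sequences are never
        silently altered.

    Returns
    -------
    DataFrame indexed by protein id with columns
    ``length, gravy, isoelectric_point, instability``.
    """
    if on_noncanonical not in ("skip", "raise"):
        raise ValueError("on_noncanonical must be 'skip' or 'raise'")
    rows: dict[str, np.ndarray] = {}
    n_skipped = 0
    for rec in records:
        if rec.id in rows:
            raise ValueError(f"duplicate protein id {rec.id!r}")
        try:
            rows[rec.id] = compute_protein_features(rec).as_array()
        except NonCanonicalResidueError:
            if on_noncanonical == "raise":
                raise
            n_skipped += 1
    if n_skipped:
        logger.info("skipped %d protein(s) with non-canonical residues", n_skipped)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    table.index.name = "id"
    return table


@dataclass(frozen=True)
class FeatureScaler:
    """Z-standardization parameters fitted on a reference (control) set.

    Candidate antigens must be transformed with the scaler fitted on the
    control proteome so that their feature sums live on the same scale.
    """

    mean: pd.Series
    std: pd.Series

    @classmethod
    def fit(cls, reference: pd.DataFrame) -> "FeatureScaler":
        if reference.empty:
            raise ValueError("reference feature table is empty")
        mean = reference.mean(axis=0)
        std = reference.std(axis=0, ddof=0)
        for name, s in std.items():
            if not np.isfinite(s) or s <= 0.0:
                raise ValueError(f"feature {name!r} has zero variance in the reference set")
        return cls(mean=mean, std=std)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table - self.mean) / self.std


def standardize_features(
    table: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, FeatureScaler]:
    """Standardize ``table`` to zero mean / unit sd of the ``reference`` set.

    Returns the transformed table together with the fitted scaler so that
    further protein sets (e.g. candidate antigens) can be transformed
    identically.
    """
    scaler = FeatureScaler.fit(reference)
    return scaler.transform(table), scaler


def feature_sum(
    factors: Sequence[float], features_std: np.ndarray | Sequence[float]
) -> np.ndarray | float:
    """Weighted feature sum ``f = sum_i p_i c_i`` on standardized features.

    ``features_std`` may be a single 4-vector or an (n, 4) matrix; the
    result is a scalar or a length-n array accordingly.
    """
    p = np.asarray(factors, dtype=float)
    c = np.asarray(features_std, dtype=float)
    if p.shape != (len(FEATURE_NAMES),):
        raise ValueError(f"factor vector must have {len(FEATURE_NAMES)} components")
    if c.shape[-1] != len(FEATURE_NAMES):
        raise ValueError("feature dimension mismatch")
    return c @ p
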