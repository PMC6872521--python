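"""File formats shared by the pipeline: FASTA, ID lists and tables.

FASTA reading/writing goes through Biopython's SeqIO; headers are parsed to
an ID at the first whitespace and sequences are uppercased on read.  The
tabular formats (PSM TSV, kinetics CSV, titration CSV, predictions TSV) are
plain pandas round-trips with column validation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import ProteinRecord
from .splicing import Substrate


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    Sequences are uppercased; the ID is the header up to the first
    whitespace.  Empty files and malformed records raise with the offending
    line number.
    """
    path = Path(path)
    text = path.read_text()
    first_content = next(
        ((n, line) for n, line in enumerate(text.splitlines(), 1) if line.strip()),
        None,
    )
    if first_content is None:
        raise ValueError(f"{path}: empty FASTA file")
    if not first_content[1].lstrip().startswith(">"):
        raise ValueError(
            f"{path}: malformed FASTA, line {first_content[0]} is not a header"
        )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write protein records as FASTA (fixed line width for determinism)."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[k : k + width] + "\n")


def read_substrate_fasta(path, numbering_offset: int = 1) -> list[Substrate]:
    """Read substrates from FASTA, applying one numbering offset to all."""
    return [
        Substrate(id=r.id, sequence=r.sequence, numbering_offset=numbering_offset)
        for r in read_fasta(path)
    ]


def read_id_list(path) -> list[str]:
    """One ID per line; blank lines ignored; duplicates collapsed in order."""
    seen: dict[str, None] = {}
    for line in Path(path).read_text().splitlines():
        token = line.strip().split()[0] if line.strip() else ""
        if token:
            seen.setdefault(token, None)
    if not seen:
        raise ValueError(f"{path}: empty ID list")
    return list(seen)


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def read_psm_table(path) -> pd.DataFrame:
    """PSM export TSV: spectrum_id, peptide, ion_score, q_value, rank."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["spectrum_id", "peptide", "ion_score", "q_value", "rank"], "PSM table")
    return df


def read_kinetics_table(path) -> pd.DataFrame:
    """Long-format kinetics CSV: peptide, bio_rep, tech_rep, time_h, area."""
    df = pd.read_csv(path)
    _require_columns(df, ["peptide", "bio_rep", "tech_rep", "time_h", "area"], "kinetics table")
    return df


def read_titration_table(path) -> pd.DataFrame:
    """Titration CSV: peptide, pmol, area."""
    df = pd.read_csv(path)
    _require_columns(df, ["peptide", "pmol", "area"], "titration table")
    return df


def read_predictions_table(path) -> pd.DataFrame:
    """Binding predictions TSV: peptide, allele, ic50_nM."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["peptide", "ic50_nM"], "predictions table")
    return df


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_manifest(path, config: dict, seed: int | None, inputs: dict) -> None:
    """Machine-readable record of a run: resolved config, seed, input
    checksums and package version."""
    from . import __version__

    manifest = {
        "pepsplice_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_of(p)}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
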