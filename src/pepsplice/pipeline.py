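"""The candidate funnel: enumerate -> mutation -> length -> binding.

Chains the in silico stages into the progressive reduction of theoretical
spliced and non-spliced epitope candidates: exhaustive enumeration of the
substrate's products, restriction to candidates carrying the tumor
mutation, the HLA-I-typical 8-12mer length window, and the binding-affinity
cutoff.  Optionally cross-checks which surviving candidates were actually
identified among quantified digestion products.  Each stage only removes
candidates, so the funnel counts are monotone non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .candidates import (
    BindingPredictor,
    EpitopeCandidate,
    candidates_from_enumeration,
    filter_binding,
    filter_length,
    filter_mutation,
)
from .config import PipelineConfig
from .splicing import Substrate, enumerate_cis, enumerate_nonspliced

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Funnel counts per stage plus the final candidate set."""

    funnel: pd.DataFrame  # columns: stage, n_candidates
    candidates: list[EpitopeCandidate]
    identified: list[str] = field(default_factory=list)

    @property
    def final_sequences(self) -> set[str]:
        return {c.sequence for c in self.candidates}


def run_pipeline(
    substrate: Substrate,
    mutation_position: int,
    mutant_residue: str,
    predictions: BindingPredictor | dict | pd.DataFrame,
    config: PipelineConfig | None = None,
    quantified_sequences: set[str] | None = None,
) -> PipelineResult:
    """Run the in silico candidate funnel on one substrate.

    Parameters
    ----------
    substrate:
        The mutated substrate (must carry ``mutant_residue`` at
        ``mutation_position``).
    predictions:
        Pluggable binding predictor (callable, mapping or table).
    quantified_sequences:
        Optional set of peptides identified among quantified digestion
        products; surviving candidates found in it are flagged in
        ``identified``.

    Returns
    -------
    PipelineResult with a per-stage funnel table; counts are sequence-level
    and monotone non-increasing across stages.
    """
    cfg = config or PipelineConfig()
    e = cfg.enumeration
    stages: list[tuple[str, int]] = []

    entries = enumerate_nonspliced(substrate, e.min_len, e.max_len)
    entries += enumerate_cis(substrate, e.min_len, e.max_len, e.include_reverse, e.min_sr_len)
    cands = candidates_from_enumeration(entries)
    stages.append(("enumerated", len(cands)))

    cands = filter_mutation(cands, substrate, mutation_position, mutant_residue)
    stages.append(("mutation", len(cands)))

    cands = filter_length(cands, e.min_len, e.max_len)
    stages.append(("length", len(cands)))

    if len(cands) == 0:
        logger.warning("no candidates reach the binding-prediction stage")
    cands = filter_binding(cands, predictions, cfg.ic50_cutoff_nM)
    stages.append((f"binding <= {cfg.ic50_cutoff_nM:g} nM", len(cands)))
    if len(cands) == 0:
        logger.warning("no candidates survive the binding filter")

    identified: list[str] = []
    if quantified_sequences is not None:
        identified = sorted(c.sequence for c in cands if c.sequence in quantified_sequences)
        stages.append(("identified in digestion", len(identified)))

    funnel = pd.DataFrame(stages, columns=["stage", "n_candidates"])
    return PipelineResult(funnel=funnel, candidates=cands, identified=identified)
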