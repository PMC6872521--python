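"""Resolved pipeline configuration with the published default thresholds.

Defaults follow the values used in the candidate-identification workflow:
8-12mer length window, IC50 cutoff 100 nM (inclusive), PSM ion score >= 20,
q-value <= 0.05, 30% delta score, 5% t0-artifact threshold and 50%
alternation swings.  Every CLI run logs the fully resolved configuration in
its run manifest.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .digestion import KineticFilterConfig, PsmFilterConfig
from .ranking import KdeConfig, McmcConfig


@dataclass(frozen=True)
class EnumerationConfig:
    min_len: int = 8
    max_len: int = 12
    include_reverse: bool = True
    min_sr_len: int = 1


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and switches of the pipeline in one place."""

    enumeration: EnumerationConfig = field(default_factory=EnumerationConfig)
    ic50_cutoff_nM: float = 100.0
    psm: PsmFilterConfig = field(default_factory=PsmFilterConfig)
    kinetics: KineticFilterConfig = field(default_factory=KineticFilterConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    kde: KdeConfig = field(default_factory=KdeConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path=None, seed: int | None = None) -> PipelineConfig:
    """Load a TOML config file; missing sections keep their defaults.

    ``seed`` overrides the MCMC seed when given (CLI ``--seed``).
    """
    data: dict = {}
    if path is not None:
        data = tomllib.loads(Path(path).read_text())
    mcmc_data = dict(data.get("mcmc", {}))
    if seed is not None:
        mcmc_data["seed"] = seed
    return PipelineConfig(
        enumeration=_build(EnumerationConfig, data.get("enumeration", {})),
        ic50_cutoff_nM=float(data.get("ic50_cutoff_nM", 100.0)),
        psm=_build(PsmFilterConfig, data.get("psm", {})),
        kinetics=_build(KineticFilterConfig, data.get("kinetics", {})),
        mcmc=_build(McmcConfig, mcmc_data),
        kde=_build(KdeConfig, data.get("kde", {})),
    )
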