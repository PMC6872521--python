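"""Synthetic data generators for closed-loop testing of every pipeline stage.

Two generators emulate the structure of the real inputs without requiring
any download:

* :func:`simulate_proteome` draws a proteome with a planted representation
  structure: protein labels ("represented in the immunopeptidome") are
  sampled with probability proportional to ``logistic(-f(p*)/T)`` where
  ``f`` is the standardized feature sum under a known factor vector ``p*``.
  The ground truth ``p*`` is returned so factor-recovery tests are
  closed-loop.
* :func:`simulate_digestion` generates an in vitro digestion dataset --
  kinetics table, PSM table and per-peptide titration curves -- from known
  per-position cleavage and splicing propensities, with multiplicative
  log-normal noise per technical replicate.  The true SCS-P1/PSP-P1
  profiles (computed from the noiseless amounts with the same equal-split
  bookkeeping the analysis uses) are returned alongside.

The KRAS fixture provides the wild-type and G12V substrates (parent
residues 2-35) and the two peptides discussed throughout: the spliced
candidate KLVVGAVGV (KRAS 5-6/8-14 G12V) and the non-spliced KLVVVGAVGV
(KRAS 5-14 G12V).

All generators are pure functions of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digestion import PSP_P1, SCS_P1, QuantifiedProduct, SiteProfile, compute_site_profile
from .features import ProteinRecord, feature_table, standardize_features
from .splicing import (
    Substrate,
    classify_peptide,
    enumerate_cis,
    enumerate_nonspliced,
    map_peptide,
)

# ---------------------------------------------------------------------------
# KRAS fixture
# ---------------------------------------------------------------------------

#: Synthetic fixture: N-terminal 35 residues of canonical human KRAS
#: (UniProt P01116), from which the substrate spanning residues 2-35 is cut.
_KRAS_1_35 = "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEYDPT"

SPLICED_CANDIDATE = "KLVVGAVGV"  # KRAS 5-6/8-14 G12V
NONSPLICED_CANDIDATE = "KLVVVGAVGV"  # KRAS 5-14 G12V


@dataclass(frozen=True)
class KrasFixture:
    wild_type: Substrate
    g12v: Substrate
    spliced_candidate: str = SPLICED_CANDIDATE
    spliced_candidate_name: str = "KRAS 5-6/8-14 G12V"
    nonspliced_candidate: str = NONSPLICED_CANDIDATE
    nonspliced_candidate_name: str = "KRAS 5-14 G12V"


def kras_fixture() -> KrasFixture:
    """KRAS 2-35 wild-type and G12V substrates plus the two candidate
    peptides, with parental numbering offset 2."""
    wt_seq = _KRAS_1_35[1:35]  # residues 2..35 inclusive
    mut = list(wt_seq)
    mut[12 - 2] = "V"  # parental position 12
    return KrasFixture(
        wild_type=Substrate(id="KRAS_2-35_WT", sequence=wt_seq, numbering_offset=2),
        g12v=Substrate(id="KRAS_2-35_G12V", sequence="".join(mut), numbering_offset=2),
    )


# ---------------------------------------------------------------------------
# Proteome with planted representation structure
# ---------------------------------------------------------------------------

#: Approximate human proteome amino-acid frequencies (UniProt statistics,
#: rounded); used as the base composition of simulated proteins.
_BASE_AA_FREQ = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}

_KD = {  # Kyte-Doolittle hydropathy, used only to tilt simulated compositions
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.3}


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Settings for the planted-representation proteome.

    Protein lengths are log-normal; per-protein hydropathy and charge tilts
    spread GRAVY and pI so the four features carry independent signal.  The
    default true factor vector points the way the real analysis found:
    length favors representation (negative factor), hydrophobicity and
    instability disfavor it, the isoelectric point has little influence.
    """

    n_proteins: int = 2000
    length_log_mean: float = np.log(300.0)
    length_log_sd: float = 0.45
    min_length: int = 30
    hydropathy_tilt_sd: float = 0.25
    charge_tilt_sd: float = 0.45
    p_star: tuple[float, float, float, float] = (-1.0, 0.5, 0.1, 0.5)
    represented_fraction: float = 0.2
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.represented_fraction < 1.0:
            raise ValueError("represented fraction must be in (0, 1)")
        if self.temperature <= 0:
            raise ValueError("selection temperature must be positive")
        if max(abs(x) for x in self.p_star) > 1.0:
            raise ValueError("p_star components must lie in [-1, 1]")
        if self.n_proteins < 10:
            raise ValueError("n_proteins too small to be useful")


@dataclass
class SimulatedProteome:
    records: list[ProteinRecord]
    represented_ids: list[str]
    p_star: np.ndarray
    features: pd.DataFrame  # raw feature table of all proteins
    config: ProteomeSimConfig


def simulate_proteome(config: ProteomeSimConfig | None = None) -> SimulatedProteome:
    """Draw a synthetic proteome and plant a represented-antigen subset.

    The represented set of size ``round(fraction * n)`` is sampled without
    replacement with weights ``logistic(-f(p*)/T)`` over control-standardized
    features, so low feature sums under ``p*`` are enriched among
    represented proteins (negative factors favor representation).
    """
    cfg = config or ProteomeSimConfig()
    rng = np.random.default_rng(cfg.seed)
    aas = np.array(sorted(_BASE_AA_FREQ))
    base = np.array([_BASE_AA_FREQ[a] for a in aas])
    kd = np.array([_KD[a] for a in aas]) / 4.5
    charge = np.array([_CHARGE.get(a, 0.0) for a in aas])
    records = []
    n_digits = len(str(cfg.n_proteins))
    for k in range(cfg.n_proteins):
        length = max(cfg.min_length, int(round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd))))
        h = rng.normal(scale=cfg.hydropathy_tilt_sd)
        b = rng.normal(scale=cfg.charge_tilt_sd)
        w = base * np.exp(h * kd + b * charge)
        w /= w.sum()
        seq = "".join(rng.choice(aas, size=length, p=w))
        records.append(ProteinRecord(id=f"SIM{k:0{n_digits}d}", sequence=seq))
    feats = feature_table(records, on_noncanonical="raise")
    feats_std, _scaler = standardize_features(feats, feats)
    p_star = np.asarray(cfg.p_star, dtype=float)
    f = feats_std.to_numpy() @ p_star
    weights = 1.0 / (1.0 + np.exp(f / cfg.temperature))  # logistic(-f/T)
    n_rep = int(round(cfg.represented_fraction * cfg.n_proteins))
    if not 0 < n_rep < cfg.n_proteins:
        raise ValueError("represented fraction incompatible with n_proteins")
    idx = rng.choice(cfg.n_proteins, size=n_rep, replace=False, p=weights / weights.sum())
    represented_ids = sorted(feats.index[i] for i in idx)
    return SimulatedProteome(
        records=records,
        represented_ids=represented_ids,
        p_star=p_star,
        features=feats,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Digestion kinetics from known propensities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigestionSimConfig:
    """Settings for the synthetic proteasome digestion.

    Per-position cleavage propensities (the true SCS signal) and splicing
    propensities (the true PSP signal) are drawn from sparse gamma
    distributions and normalized.  Product amounts accumulate linearly over
    the time course; peak areas are amounts times a hidden per-peptide MS
    response factor with multiplicative log-normal noise per technical
    replicate.  ``n_artifact`` / ``n_alternating`` plant filter violations
    for testing the kinetic filters.
    """

    substrate: Substrate | None = None  # defaults to the KRAS G12V fixture
    n_nonspliced: int = 20
    n_cis: int = 10
    min_len: int = 8
    max_len: int = 12
    time_points: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    turnover_pmol_per_h: float = 10.0
    noise_sd: float = 0.05
    n_bio_reps: int = 2
    n_tech_reps: int = 3
    propensity_shape: float = 0.5
    n_artifact: int = 0
    n_alternating: int = 0
    titration_pmol: tuple[float, ...] = (0.0, 1.25, 2.5, 5.0, 10.0)
    titration_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonspliced < 1:
            raise ValueError("need at least one non-spliced product")
        if self.noise_sd < 0 or self.titration_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if len(self.time_points) < 2 or list(self.time_points) != sorted(self.time_points):
            raise ValueError("time points must be increasing with >= 2 entries")


@dataclass
class SimulatedDigestion:
    kinetics: pd.DataFrame  # peptide, bio_rep, tech_rep, time_h, area
    psms: pd.DataFrame  # spectrum_id, peptide, category, ion_score, q_value, rank
    titration: pd.DataFrame  # peptide, pmol, area
    products_true: list[QuantifiedProduct]  # noiseless amounts
    true_scs_p1: SiteProfile
    true_psp_p1: SiteProfile | None
    substrate: Substrate
    config: DigestionSimConfig

    def write_dir(self, out_dir) -> None:
        """Dump the tables in the formats the analysis module consumes."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.kinetics.to_csv(out / "kinetics.csv", index=False)
        self.psms.to_csv(out / "psms.tsv", sep="\t", index=False)
        self.titration.to_csv(out / "titration.csv", index=False)
        self.true_scs_p1.to_frame().to_csv(out / "true_scs_p1.tsv", sep="\t")
        if self.true_psp_p1 is not None:
            self.true_psp_p1.to_frame().to_csv(out / "true_psp_p1.tsv", sep="\t")


def _choose_products(
    substrate: Substrate,
    cfg: DigestionSimConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, float]], np.ndarray, np.ndarray]:
    """Pick products and their true generation rates (pmol/h).

    Non-spliced products are weighted by the cleavage propensity of their
    C-terminal position, cis products by splicing propensity at the
    N-terminal reactant's end times cleavage propensity at the product end.
    Returns (sequence, rate) pairs plus the propensity vectors.
    """
    n_pos = len(substrate)
    scs_prop = rng.gamma(cfg.propensity_shape, size=n_pos)
    psp_prop = rng.gamma(cfg.propensity_shape, size=n_pos)
    scs_prop /= scs_prop.sum()
    psp_prop /= psp_prop.sum()
    off = substrate.numbering_offset

    ns_entries = enumerate_nonspliced(substrate, cfg.min_len, cfg.max_len)
    cis_entries = enumerate_cis(substrate, cfg.min_len, cfg.max_len, include_reverse=False)
    if not ns_entries:
        raise ValueError("substrate too short for the configured length range")

    def pick(entries, n, weight_fn):
        w = np.array([weight_fn(d) for _s, d in entries], dtype=float)
        if w.sum() <= 0:
            raise ValueError("zero total propensity over enumerated products")
        idx = rng.choice(len(entries), size=min(n, len(entries)), replace=False, p=w / w.sum())
        return [entries[i] for i in sorted(idx)]

    chosen = pick(ns_entries, cfg.n_nonspliced, lambda d: scs_prop[d.scs_p1 - off])
    if cfg.n_cis > 0 and cis_entries:
        chosen += pick(
            cis_entries,
            cfg.n_cis,
            lambda d: psp_prop[d.psp_p1 - off] * scs_prop[d.scs_p1 - off],
        )
    # rate proportional to the product's own propensity weight, with a mild
    # random efficiency factor per product
    by_seq: dict[str, float] = {}
    for seq, d in chosen:
        if d.sr2 is None:
            w = scs_prop[d.scs_p1 - off]
        else:
            w = psp_prop[d.psp_p1 - off] * scs_prop[d.scs_p1 - off]
        rate = cfg.turnover_pmol_per_h * w * rng.uniform(0.5, 1.5)
        by_seq[seq] = by_seq.get(seq, 0.0) + rate
    return sorted(by_seq.items()), scs_prop, psp_prop


def simulate_digestion(config: DigestionSimConfig | None = None) -> SimulatedDigestion:
    """Generate a synthetic digestion dataset with known ground truth.

    The returned ``true_scs_p1`` / ``true_psp_p1`` profiles are computed by
    applying :func:`pepsplice.digestion.compute_site_profile` to the
    noiseless product amounts, i.e. they include the same equal-split
    treatment of ambiguous decompositions the estimator applies, so the
    noiseless limit recovers them exactly.
    """
    cfg = config or DigestionSimConfig()
    substrate = cfg.substrate or kras_fixture().g12v
    rng = np.random.default_rng(cfg.seed)
    products_rates, _scs_prop, _psp_prop = _choose_products(substrate, cfg, rng)
    times = np.asarray(cfg.time_points, dtype=float)

    # noiseless QuantifiedProducts (identical across bio reps)
    products_true: list[QuantifiedProduct] = []
    index = pd.MultiIndex.from_product(
        [range(1, cfg.n_bio_reps + 1), times], names=["bio_rep", "time_h"]
    )
    for seq, rate in products_rates:
        decomps = tuple(map_peptide(seq, substrate))
        amounts = pd.Series(
            np.tile(rate * times, cfg.n_bio_reps), index=index, name="pmol"
        )
        products_true.append(
            QuantifiedProduct(
                sequence=seq,
                decompositions=decomps,
                category=classify_peptide(decomps),
                amounts=amounts,
            )
        )
    true_scs = compute_site_profile(products_true, SCS_P1, "mean", substrate)
    try:
        true_psp = compute_site_profile(products_true, PSP_P1, "mean", substrate)
    except Exception:
        true_psp = None

    # hidden per-peptide MS response factors (area units per pmol)
    response = {
        seq: 1e4 * rng.lognormal(0.0, 0.3) for seq, _r in products_rates
    }

    # kinetics with multiplicative log-normal noise per technical replicate
    kin_rows = []
    seqs = [seq for seq, _ in products_rates]
    artifact_peps = set(seqs[: cfg.n_artifact])
    alternating_peps = set(seqs[cfg.n_artifact : cfg.n_artifact + cfg.n_alternating])
    for seq, rate in products_rates:
        for bio in range(1, cfg.n_bio_reps + 1):
            for tech in range(1, cfg.n_tech_reps + 1):
                amounts = rate * times
                areas = amounts * response[seq]
                if cfg.noise_sd > 0:
                    areas = areas * rng.lognormal(0.0, cfg.noise_sd, size=len(times))
                if seq in artifact_peps:
                    # synthesis artifact: material already present at t = 0
                    areas[0] = 0.5 * areas.max()
                if seq in alternating_peps and len(areas) >= 3:
                    # non-physical sawtooth kinetics
                    areas[1::2] *= 0.1
                kin_rows.append(
                    pd.DataFrame(
                        {
                            "peptide": seq,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "time_h": times,
                            "area": areas,
                        }
                    )
                )
    kinetics = pd.concat(kin_rows, ignore_index=True)

    # PSMs: one confidently identified spectrum per peptide; spliced top
    # hits get a clearly separated non-spliced runner-up so the delta-score
    # rule passes by construction
    psm_rows = []
    for k, (seq, _rate) in enumerate(products_rates):
        cat = classify_peptide(map_peptide(seq, substrate))
        score = float(rng.uniform(45.0, 90.0))
        q = float(rng.uniform(0.0, 0.01))
        psm_rows.append(
            {"spectrum_id": f"S{k:04d}", "peptide": seq, "category": cat,
             "ion_score": round(score, 2), "q_value": round(q, 5), "rank": 1}
        )
        if cat != "non-spliced":
            psm_rows.append(
                {"spectrum_id": f"S{k:04d}", "peptide": seq[::-1], "category": "non-spliced",
                 "ion_score": round(score * 0.4, 2), "q_value": round(q, 5), "rank": 2}
            )
    psms = pd.DataFrame(psm_rows)

    # per-peptide titration of the cognate synthetic peptides
    tit_rows = []
    pmols = np.asarray(cfg.titration_pmol, dtype=float)
    for seq, _rate in products_rates:
        areas = pmols * response[seq]
        if cfg.titration_noise_sd > 0:
            noise = rng.lognormal(0.0, cfg.titration_noise_sd, size=len(pmols))
            areas = areas * noise
        tit_rows.append(pd.DataFrame({"peptide": seq, "pmol": pmols, "area": areas}))
    titration = pd.concat(tit_rows, ignore_index=True)

    return SimulatedDigestion(
        kinetics=kinetics,
        psms=psms,
        titration=titration,
        products_true=products_true,
        true_scs_p1=true_scs,
        true_psp_p1=true_psp,
        substrate=substrate,
        config=cfg,
    )
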