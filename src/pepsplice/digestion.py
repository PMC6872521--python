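"""Quantitative analysis of in vitro proteasome digestion products.

Starting from identified peptide-spectrum matches (PSMs) and label-free
MS ion peak areas measured over a digestion time course, this module

1. filters identifications (ion score, q-value, and a delta-score rule for
   spliced-peptide assignments),
2. filters kinetic series for synthesis artifacts, erratic ("alternating")
   kinetics, and replicate irreproducibility,
3. converts peak areas to absolute amounts (pmol) with per-peptide linear
   titration curves of cognate synthetic peptides, and
4. aggregates the quantified products into site-specific profiles and
   category summaries.

The two site profiles are percentages over substrate positions:

* SCS-P1 (site-specific cleavage strength): for each substrate residue, the
  summed amount of ALL products (non-spliced and spliced) whose C-terminus
  is that residue, normalized to 100%.
* PSP-P1 (splicing-site usage): for each substrate residue, the summed
  amount of SPLICED products whose N-terminal splice-reactant ends at that
  residue, normalized to 100%.

A product with k admissible positions (equivalent decompositions, e.g. the
three explanations of KLVVGAVGV) contributes amount/k to each position, so
total amount is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .splicing import (
    NON_SPLICED,
    SPLICED_CATEGORIES,
    UNMAPPED,
    Decomposition,
    Substrate,
    classify_peptide,
    map_peptide,
)

logger = logging.getLogger(__name__)

SCS_P1 = "SCS-P1"
PSP_P1 = "PSP-P1"


class UndefinedProfileError(ValueError):
    """Raised when a site profile is requested but no product contributes a
    non-zero amount (the normalization to 100% is undefined)."""


# ---------------------------------------------------------------------------
# PSM filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsmFilterConfig:
    """Identification filter thresholds.

    ``delta_min`` is the minimum relative ion-score margin
    ``(score_top - score_alt) / score_top`` a top-scoring spliced hit must
    hold over both the best alternative spliced sequence and the best
    non-spliced hit of the same spectrum.
    """

    ion_score_min: float = 20.0
    q_value_max: float = 0.05
    delta_min: float = 0.30


def filter_psms(
    psms: pd.DataFrame,
    config: PsmFilterConfig | None = None,
) -> pd.DataFrame:
    """Filter PSMs and resolve each spectrum to one identification.

    ``psms`` columns: ``spectrum_id, peptide, category, ion_score, q_value,
    rank`` (rank 1 = top hit per spectrum).  PSMs below the ion-score cutoff
    or above the q-value cutoff are dropped.  For spectra whose top hit is a
    spliced peptide, the identification is rejected as ambiguous unless the
    relative delta score against both the best alternative spliced sequence
    and the best non-spliced hit reaches ``delta_min``.

    Returns the accepted rank-1 PSMs (one row per identified spectrum).
    """
    cfg = config or PsmFilterConfig()
    required = {"spectrum_id", "peptide", "category", "ion_score", "q_value", "rank"}
    missing = required - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table missing column(s) {sorted(missing)}")
    accepted_rows = []
    for spectrum, grp in psms.groupby("spectrum_id", sort=True):
        top = grp[grp["rank"] == 1]
        if len(top) != 1:
            raise ValueError(f"spectrum {spectrum!r} has {len(top)} rank-1 hits")
        top = top.iloc[0]
        if top["ion_score"] < cfg.ion_score_min or top["q_value"] > cfg.q_value_max:
            continue
        if top["category"] in SPLICED_CATEGORIES:
            others = grp[(grp["rank"] != 1) & (grp["peptide"] != top["peptide"])]
            rivals = [
                others[others["category"].isin(SPLICED_CATEGORIES)]["ion_score"].max(),
                others[others["category"] == NON_SPLICED]["ion_score"].max(),
            ]
            ambiguous = False
            for alt in rivals:
                if pd.notna(alt):
                    delta = (top["ion_score"] - alt) / top["ion_score"]
                    if delta < cfg.delta_min:
                        ambiguous = True
            if ambiguous:
                continue
        accepted_rows.append(top)
    if not accepted_rows:
        return psms.iloc[0:0].copy()
    return pd.DataFrame(accepted_rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kinetic filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticFilterConfig:
    """Kinetic plausibility thresholds.

    ``artifact_t0_fraction``: a non-zero signal at t = 0 above this fraction
    of the series maximum marks a peptide-synthesis artifact (the product
    should not pre-exist the digestion).
    ``swing_fraction``: an up-then-down or down-then-up excursion between
    consecutive time points, with both relative changes above this fraction,
    marks non-physical "alternating" kinetics.
    ``min_tech_reps`` / ``min_bio_reps``: detection reproducibility
    requirements.
    """

    artifact_t0_fraction: float = 0.05
    swing_fraction: float = 0.50
    min_tech_reps: int = 2
    min_bio_reps: int = 2


def _series_rejection(areas: np.ndarray, times: np.ndarray, cfg: KineticFilterConfig) -> str | None:
    """Reason a single technical-replicate series fails, or None."""
    if len(areas) < 2:
        raise ValueError("kinetic series needs at least 2 time points")
    if not np.all(np.diff(times) > 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(areas < 0):
        raise ValueError("negative peak area")
    peak = areas.max()
    if peak == 0:
        return "not detected"
    if times[0] == 0 and areas[0] > cfg.artifact_t0_fraction * peak:
        return "synthesis artifact"
    # alternating: consecutive opposite-direction swings both > swing_fraction
    diff = np.diff(areas)
    denom = np.maximum(areas[:-1], areas[1:])
    rel = np.divide(diff, denom, out=np.zeros_like(diff), where=denom > 0)
    for k in range(len(rel) - 1):
        if rel[k] * rel[k + 1] < 0 and min(abs(rel[k]), abs(rel[k + 1])) > cfg.swing_fraction:
            return "alternating"
    return None


def filter_kinetics(
    kinetics: pd.DataFrame,
    config: KineticFilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter kinetic series and decide which peptides are quantifiable.

    ``kinetics`` is long format with columns ``peptide, bio_rep, tech_rep,
    time_h, area``.  A technical-replicate series survives if it is free of
    synthesis artifacts and alternating kinetics; a peptide is detected in a
    biological replicate when at least ``min_tech_reps`` of its technical
    series survive; a peptide is kept when detected in at least
    ``min_bio_reps`` biological replicates.

    Returns
    -------
    (kept, reasons):
        ``kept`` is the subset of rows for kept peptides restricted to
        surviving technical series; ``reasons`` has one row per rejected
        peptide with the dominant rejection reason.
    """
    cfg = config or KineticFilterConfig()
    required = {"peptide", "bio_rep", "tech_rep", "time_h", "area"}
    missing = required - set(kinetics.columns)
    if missing:
        raise ValueError(f"kinetics table missing column(s) {sorted(missing)}")
    surviving_keys: list[tuple] = []
    reject_reasons: dict[str, list[str]] = {}
    bio_detect: dict[str, set] = {}
    for (pep, bio, tech), grp in kinetics.groupby(["peptide", "bio_rep", "tech_rep"], sort=True):
        grp = grp.sort_values("time_h")
        reason = _series_rejection(
            grp["area"].to_numpy(dtype=float), grp["time_h"].to_numpy(dtype=float), cfg
        )
        if reason is None:
            surviving_keys.append((pep, bio, tech))
        else:
            reject_reasons.setdefault(pep, []).append(reason)
    tech_counts: dict[tuple, int] = {}
    for pep, bio, _tech in surviving_keys:
        tech_counts[(pep, bio)] = tech_counts.get((pep, bio), 0) + 1
    for (pep, bio), n in tech_counts.items():
        if n >= cfg.min_tech_reps:
            bio_detect.setdefault(pep, set()).add(bio)
        else:
            reject_reasons.setdefault(pep, []).append("technical irreproducibility")
    kept_peptides = sorted(p for p, bios in bio_detect.items() if len(bios) >= cfg.min_bio_reps)
    rejected = sorted(set(kinetics["peptide"]) - set(kept_peptides))
    reason_rows = []
    for pep in rejected:
        reasons = reject_reasons.get(pep, ["insufficient biological replicates"])
        # dominant reason; replicate shortfalls only matter if series were clean
        order = ["synthesis artifact", "alternating", "not detected",
                 "technical irreproducibility", "insufficient biological replicates"]
        reason = min(reasons, key=order.index) if reasons else order[-1]
        if pep in bio_detect and len(bio_detect[pep]) < cfg.min_bio_reps:
            reason = reason if reasons else "insufficient biological replicates"
        reason_rows.append({"peptide": pep, "reason": reason})
    surviving = set(surviving_keys)
    mask = kinetics.apply(
        lambda r: r["peptide"] in set(kept_peptides)
        and (r["peptide"], r["bio_rep"], r["tech_rep"]) in surviving,
        axis=1,
    )
    kept = kinetics[mask].copy()
    reasons_df = pd.DataFrame(reason_rows, columns=["peptide", "reason"])
    return kept, reasons_df


# ---------------------------------------------------------------------------
# Titration-based absolute quantification
# ---------------------------------------------------------------------------

@dataclass
class TitrationCurve:
    """Ordinary-least-squares line ``area = slope * pmol + intercept``."""

    slope: float
    intercept: float
    rmse: float
    n_points: int

    def quantify(self, area: float) -> float:
        """Invert the line; negative results clip to 0 with a warning.

        Small negative inversions are routine for blank (t = 0) areas when
        the fitted intercept is positive."""
        pmol = (area - self.intercept) / self.slope
        if pmol < 0:
            logger.debug("negative quantification (%.3g pmol) clipped to 0", pmol)
            return 0.0
        return pmol


def fit_titration(pmol: Iterable[float], area: Iterable[float]) -> TitrationCurve:
    """Fit a titration line through (injected pmol, peak area) points.

    Requires at least 3 points spanning a non-zero range; a non-positive
    slope makes the curve unusable and raises.
    """
    x = np.asarray(list(pmol), dtype=float)
    y = np.asarray(list(area), dtype=float)
    if x.size < 3:
        raise ValueError("titration needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("titration points span a zero range")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError(f"unusable titration curve: slope {res.slope:.3g} <= 0")
    rmse = float(np.sqrt(np.mean((y - (res.slope * x + res.intercept)) ** 2)))
    return TitrationCurve(
        slope=float(res.slope), intercept=float(res.intercept), rmse=rmse, n_points=x.size
    )


def fit_titrations(titration: pd.DataFrame) -> dict[str, TitrationCurve]:
    """Fit one curve per peptide from a long table (peptide, pmol, area)."""
    return {
        pep: fit_titration(grp["pmol"], grp["area"])
        for pep, grp in titration.groupby("peptide", sort=True)
    }


# ---------------------------------------------------------------------------
# Quantified products and site profiles
# ---------------------------------------------------------------------------

@dataclass
class QuantifiedProduct:
    """An identified peptide with absolute amounts per (bio_rep, time)."""

    sequence: str
    decompositions: tuple[Decomposition, ...]
    category: str
    amounts: pd.Series  # MultiIndex (bio_rep, time_h) -> pmol

    def __post_init__(self) -> None:
        if (np.asarray(self.amounts, dtype=float) < 0).any():
            raise ValueError("amounts must be non-negative")
        if self.category != classify_peptide(self.decompositions):
            raise ValueError(
                f"category {self.category!r} inconsistent with decompositions"
            )

    def amount(self, time_selector="mean") -> float:
        """Amount in pmol: mean over all (replicate, time) entries for
        ``"mean"``, or the cross-replicate mean at a specific time point."""
        if isinstance(time_selector, str):
            if time_selector != "mean":
                raise ValueError("time_selector must be 'mean' or a time value")
            return float(self.amounts.mean())
        sel = self.amounts.xs(time_selector, level="time_h")
        return float(sel.mean())

    def site_positions(self, kind: str) -> tuple[int, ...]:
        """Distinct admissible positions for the given profile kind, taken
        from the decompositions matching the product's own category."""
        own = [d for d in self.decompositions if d.category == self.category]
        if kind == SCS_P1:
            return tuple(sorted({d.scs_p1 for d in own}))
        if kind == PSP_P1:
            if self.category not in SPLICED_CATEGORIES:
                return ()
            return tuple(sorted({d.psp_p1 for d in own}))
        raise ValueError(f"unknown profile kind {kind!r}")


@dataclass
class SiteProfile:
    """Percentage profile over substrate positions (sums to 100)."""

    kind: str
    percent: pd.Series  # index: parental position
    time_selector: object = "mean"
    residues: pd.Series | None = None

    def total(self) -> float:
        return float(self.percent.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"percent": self.percent})
        df.index.name = "position"
        if self.residues is not None:
            df.insert(0, "residue", self.residues)
        return df


def compute_site_profile(
    products: Iterable[QuantifiedProduct],
    kind: str = SCS_P1,
    time_selector="mean",
    substrate: Substrate | None = None,
) -> SiteProfile:
    """Compute the SCS-P1 or PSP-P1 percentage profile.

    Every product contributes its amount (mean over time points by default,
    matching how the profiles are usually reported) split equally over its
    admissible positions; PSP-P1 draws only on spliced products.  The
    profile is normalized so the entries sum to 100%.

    Raises
    ------
    UndefinedProfileError
        If no product contributes a non-zero amount.
    """
    contributions: dict[int, float] = {}
    for prod in products:
        positions = prod.site_positions(kind)
        if not positions:
            continue
        amt = prod.amount(time_selector)
        if amt == 0.0:
            continue
        share = amt / len(positions)
        for pos in positions:
            contributions[pos] = contributions.get(pos, 0.0) + share
    total = sum(contributions.values())
    if total <= 0.0:
        raise UndefinedProfileError(
            f"{kind} profile undefined: no non-zero contributing amounts"
        )
    if substrate is not None:
        index = range(substrate.first_position, substrate.last_position + 1)
    else:
        index = sorted(contributions)
    percent = pd.Series(
        [100.0 * contributions.get(p, 0.0) / total for p in index],
        index=pd.Index(index, name="position"),
        name="percent",
    )
    residues = None
    if substrate is not None:
        residues = pd.Series(
            [substrate.residue_at(p) for p in percent.index],
            index=percent.index,
            name="residue",
        )
    return SiteProfile(kind=kind, percent=percent, time_selector=time_selector, residues=residues)


# ---------------------------------------------------------------------------
# Category summaries
# ---------------------------------------------------------------------------

@dataclass
class CategorySummary:
    """Counts, abundance shares and length statistics per product category."""

    by_category: pd.DataFrame  # index: category; columns: count, percent, abundance, abundance_percent, mean_abundance
    mean_abundance_per_time: pd.DataFrame  # index: category; columns: time points
    length_medians: dict[str, float]


def summarize_products(products: Iterable[QuantifiedProduct]) -> CategorySummary:
    """Summarize quantified products by splice category.

    Percentages (of peptide counts and of total abundance) each sum to 100.
    Length medians cover product length per category, splice-reactant
    lengths and intervening-sequence lengths of cis products (pooled over
    equivalent decompositions).
    """
    products = list(products)
    if not products:
        logger.warning("empty product set: returning empty summary")
        return CategorySummary(
            by_category=pd.DataFrame(
                columns=["count", "percent", "abundance", "abundance_percent", "mean_abundance"]
            ),
            mean_abundance_per_time=pd.DataFrame(),
            length_medians={},
        )
    rows: dict[str, dict[str, float]] = {}
    per_time: dict[str, dict[float, list[float]]] = {}
    for prod in products:
        cat = prod.category
        r = rows.setdefault(cat, {"count": 0, "abundance": 0.0})
        r["count"] += 1
        r["abundance"] += prod.amount("mean")
        times = prod.amounts.index.get_level_values("time_h")
        for t in sorted(set(times)):
            per_time.setdefault(cat, {}).setdefault(t, []).append(prod.amount(t))
    by_cat = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    by_cat["percent"] = 100.0 * by_cat["count"] / by_cat["count"].sum()
    total_ab = by_cat["abundance"].sum()
    by_cat["abundance_percent"] = (
        100.0 * by_cat["abundance"] / total_ab if total_ab > 0 else 0.0
    )
    by_cat["mean_abundance"] = by_cat["abundance"] / by_cat["count"]
    by_cat = by_cat[["count", "percent", "abundance", "abundance_percent", "mean_abundance"]]
    by_cat.index.name = "category"
    mean_per_time = pd.DataFrame(
        {
            cat: {t: float(np.mean(v)) for t, v in times.items()}
            for cat, times in per_time.items()
        }
    ).T.sort_index()
    mean_per_time.index.name = "category"

    length_medians: dict[str, float] = {}
    for cat in by_cat.index:
        lens = [len(p.sequence) for p in products if p.category == cat]
        length_medians[f"product_length_{cat}"] = float(np.median(lens))
    cis_decomps = [
        d
        for p in products
        if p.category in ("cis-normal", "cis-reverse")
        for d in p.decompositions
        if d.category == p.category
    ]
    if cis_decomps:
        length_medians["sr1_length"] = float(np.median([d.sr1_length for d in cis_decomps]))
        length_medians["sr2_length"] = float(np.median([d.sr2_length for d in cis_decomps]))
        length_medians["intervening_length"] = float(
            np.median([d.intervening_length for d in cis_decomps])
        )
    return CategorySummary(
        by_category=by_cat,
        mean_abundance_per_time=mean_per_time,
        length_medians=length_medians,
    )


def compare_length_distributions(a: Iterable[float], b: Iterable[float]):
    """Two-sample KS test between two length distributions."""
    return stats.ks_2samp(list(a), list(b))


# ---------------------------------------------------------------------------
# End-to-end digestion analysis
# ---------------------------------------------------------------------------

@dataclass
class DigestionResult:
    products: list[QuantifiedProduct]
    scs_p1: SiteProfile
    psp_p1: SiteProfile | None
    summary: CategorySummary
    rejected: pd.DataFrame  # peptide, reason (kinetic filter rejections)


def quantify_products(
    substrate: Substrate,
    kinetics_kept: pd.DataFrame,
    curves: Mapping[str, TitrationCurve],
    identified_peptides: Iterable[str] | None = None,
) -> list[QuantifiedProduct]:
    """Turn surviving kinetic series into quantified products.

    Technical replicates are averaged per (bio_rep, time) before the
    titration inversion; peptides without a titration curve or without any
    decomposition against the substrate are skipped with a warning.
    """
    wanted = set(identified_peptides) if identified_peptides is not None else None
    products = []
    for pep, grp in kinetics_kept.groupby("peptide", sort=True):
        if wanted is not None and pep not in wanted:
            continue
        if pep not in curves:
            logger.warning("no titration curve for %s: skipped", pep)
            continue
        decomps = tuple(map_peptide(pep, substrate))
        cat = classify_peptide(decomps)
        if cat == UNMAPPED:
            logger.warning("%s has no decomposition against %s: skipped", pep, substrate.id)
            continue
        curve = curves[pep]
        mean_area = grp.groupby(["bio_rep", "time_h"], sort=True)["area"].mean()
        amounts = mean_area.map(curve.quantify)
        n_clipped = int((mean_area < curve.intercept).sum())
        if n_clipped:
            logger.warning(
                "%s: %d sub-intercept area(s) quantified as 0 pmol", pep, n_clipped
            )
        amounts.index.set_names(["bio_rep", "time_h"], inplace=True)
        products.append(
            QuantifiedProduct(sequence=pep, decompositions=decomps, category=cat, amounts=amounts)
        )
    return products


def analyze_digestion(
    substrate: Substrate,
    psms: pd.DataFrame,
    kinetics: pd.DataFrame,
    titration: pd.DataFrame,
    psm_config: PsmFilterConfig | None = None,
    kinetic_config: KineticFilterConfig | None = None,
    time_selector="mean",
) -> DigestionResult:
    """Full digestion analysis: PSM filter -> kinetic filter -> titration
    quantification -> site profiles and category summary.

    PSP-P1 is None when no spliced product survives (profile undefined).
    """
    accepted = filter_psms(psms, psm_config)
    kept, rejected = filter_kinetics(
        kinetics[kinetics["peptide"].isin(set(accepted["peptide"]))], kinetic_config
    )
    curves = fit_titrations(titration)
    products = quantify_products(substrate, kept, curves, accepted["peptide"])
    scs = compute_site_profile(products, SCS_P1, time_selector, substrate)
    try:
        psp = compute_site_profile(products, PSP_P1, time_selector, substrate)
    except UndefinedProfileError:
        psp = None
    return DigestionResult(
        products=products,
        scs_p1=scs,
        psp_p1=psp,
        summary=summarize_products(products),
        rejected=rejected,
    )
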