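"""Antigen prioritization by feature-sum distribution separation.

The model asks which weighting ``p`` of the four physicochemical features
makes the feature-sum distribution of antigens represented in HLA-I
immunopeptidomes (``F1``) most different from that of the whole proteome
(``F0``).  "Most different" is measured by the two-sample
Kolmogorov-Smirnov distance, and the factors are sampled with a
Metropolis-Hastings chain over the box [-1, 1]^4 with a uniform prior and
the pseudo-likelihood ``exp(beta * KS(F1(p), F0(p)))``.

Candidate antigens are then ranked by the density difference
``F_diff = F1 - F0`` evaluated at the candidate's own feature sum, for every
posterior sample, giving a distribution of F_diff per candidate; positive
values mark feature sums that favor representation.

Sign convention: the KS objective is invariant under ``p -> -p``, so every
retained sample is oriented such that the represented set's median feature
sum does not exceed the control median.  This matches the convention that
negative factors favor representation and makes the posterior identifiable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .features import FEATURE_NAMES, feature_sum

logger = logging.getLogger(__name__)

N_FEATURES = len(FEATURE_NAMES)


def ks_distance(a, b) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup_x |ECDF_a - ECDF_b|.

    Sorted-ECDF implementation, O(n log n); equals
    ``scipy.stats.ks_2samp(a, b).statistic`` (asserted in the test suite).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS distance requires two non-empty samples")
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


@dataclass(frozen=True)
class McmcConfig:
    """Metropolis-Hastings settings for factor inference.

    ``beta`` is the inverse temperature of the pseudo-likelihood
    ``exp(beta * KS)``; proposals are isotropic Gaussians reflected at the
    box boundary. The chain runs ``burn_in + n_samples * thin`` iterations.
    """

    n_samples: int = 1000
    burn_in: int = 1000
    thin: int = 1
    proposal_sd: float = 0.1
    beta: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.burn_in < 0 or self.thin < 1:
            raise ValueError("burn_in must be >= 0 and thin >= 1")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class PosteriorSet:
    """Retained factor samples with their KS objectives."""

    samples: np.ndarray  # (N, 4), each row in [-1, 1]^4
    objective: np.ndarray  # (N,) KS distance per sample
    acceptance_rate: float
    config: McmcConfig

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        """Marginal posterior summary per factor (mean, median, 90% CI)."""
        q = np.quantile(self.samples, [0.05, 0.5, 0.95], axis=0)
        return pd.DataFrame(
            {
                "mean": self.samples.mean(axis=0),
                "q5": q[0],
                "median": q[1],
                "q95": q[2],
            },
            index=list(FEATURE_NAMES),
        )


def _reflect(x: np.ndarray, lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (billiard reflection)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return y + lo


def _orient(p: np.ndarray, x_rep: np.ndarray, x_ctrl: np.ndarray) -> np.ndarray:
    """Flip the sign of p so represented feature sums sit at or below the
    control median (negative factors favor representation)."""
    if np.median(x_rep @ p) > np.median(x_ctrl @ p):
        return -p
    return p


def infer_factors_mcmc(
    represented: pd.DataFrame | np.ndarray,
    control: pd.DataFrame | np.ndarray,
    config: McmcConfig | None = None,
) -> PosteriorSet:
    """Sample factor vectors maximally separating represented vs control.

    Parameters
    ----------
    represented, control:
        Standardized feature tables (rows = proteins, columns = the four
        features).  Standardize with
        :func:`pepsplice.features.standardize_features` against the control
        set first.
    config:
        Chain settings; defaults to :class:`McmcConfig`.

    Returns
    -------
    PosteriorSet with ``config.n_samples`` post-burn-in, thinned, oriented
    samples. Fully deterministic under a fixed ``config.seed``.
    """
    config = config or McmcConfig()
    x_rep = np.asarray(represented, dtype=float)
    x_ctrl = np.asarray(control, dtype=float)
    if x_rep.size == 0 or x_ctrl.size == 0:
        raise ValueError("represented and control sets must be non-empty")
    rng = np.random.default_rng(config.seed)

    def objective(p: np.ndarray) -> float:
        return ks_distance(x_rep @ p, x_ctrl @ p)

    p = rng.uniform(-1.0, 1.0, size=N_FEATURES)
    obj = objective(p)
    samples = np.empty((config.n_samples, N_FEATURES))
    objectives = np.empty(config.n_samples)
    n_iter = config.burn_in + config.n_samples * config.thin
    n_accept = 0
    kept = 0
    for it in range(n_iter):
        prop = _reflect(p + rng.normal(scale=config.proposal_sd, size=N_FEATURES))
        obj_prop = objective(prop)
        # uniform prior on the box: the MH ratio is the likelihood ratio
        if np.log(rng.uniform()) < config.beta * (obj_prop - obj):
            p, obj = prop, obj_prop
            n_accept += 1
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            samples[kept] = _orient(p, x_rep, x_ctrl)
            objectives[kept] = obj
            kept += 1
    rate = n_accept / n_iter
    logger.info("MCMC finished: %d iterations, acceptance rate %.3f", n_iter, rate)
    return PosteriorSet(samples=samples, objective=objectives, acceptance_rate=rate, config=config)


@dataclass(frozen=True)
class KdeConfig:
    """Kernel density settings: Gaussian kernel, Silverman bandwidth,
    ``grid_size`` points spanning the pooled data range padded by
    ``pad_bandwidths`` bandwidths on each side."""

    grid_size: int = 512
    pad_bandwidths: float = 3.0

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if self.pad_bandwidths < 0:
            raise ValueError("pad_bandwidths must be >= 0")


@dataclass
class DensityDifferenceCurve:
    """``F_diff = F1 - F0`` on a common feature-sum grid.

    Each density is renormalized to unit trapezoid integral on the grid, so
    the curve integrates to zero to numerical precision.
    """

    grid: np.ndarray
    diff: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.diff, self.grid))

    def evaluate(self, f) -> np.ndarray:
        """Interpolate F_diff at feature sums ``f``; values outside the grid
        evaluate to 0 (density there is negligible) with a warning."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        if np.any((f < self.grid[0]) | (f > self.grid[-1])):
            warnings.warn(
                "feature sum outside the KDE grid; evaluating F_diff as 0",
                stacklevel=2,
            )
        return np.interp(f, self.grid, self.diff, left=0.0, right=0.0)


def _kde_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    try:
        kde = gaussian_kde(values, bw_method="silverman")
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(f"degenerate sample for KDE: {exc}") from exc
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate sample: zero density mass on grid")
    return dens / area


def density_difference(
    rep, ctrl, kde_config: KdeConfig | None = None
) -> DensityDifferenceCurve:
    """Difference of Gaussian-KDE densities of two feature-sum samples.

    Positive values mark feature sums favoring representation.

    Raises
    ------
    ValueError
        For empty or degenerate (single-point / zero-spread) samples.
    """
    cfg = kde_config or KdeConfig()
    rep = np.asarray(rep, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if rep.size < 2 or ctrl.size < 2:
        raise ValueError("each sample needs at least 2 values for a KDE")
    if np.ptp(rep) == 0.0 or np.ptp(ctrl) == 0.0:
        raise ValueError("degenerate sample: zero spread (bandwidth undefined)")
    # Silverman factor * data sd = kernel bandwidth
    bw = max(
        gaussian_kde(rep, bw_method="silverman").factor * rep.std(ddof=1),
        gaussian_kde(ctrl, bw_method="silverman").factor * ctrl.std(ddof=1),
    )
    lo = min(rep.min(), ctrl.min()) - cfg.pad_bandwidths * bw
    hi = max(rep.max(), ctrl.max()) + cfg.pad_bandwidths * bw
    grid = np.linspace(lo, hi, cfg.grid_size)
    diff = _kde_on_grid(rep, grid) - _kde_on_grid(ctrl, grid)
    return DensityDifferenceCurve(grid=grid, diff=diff)


def rank_candidates(
    candidates_std: pd.DataFrame,
    represented_std: pd.DataFrame | np.ndarray,
    control_std: pd.DataFrame | np.ndarray,
    posterior: PosteriorSet,
    kde_config: KdeConfig | None = None,
    tie_tolerance: float = 1e-12,
) -> pd.DataFrame:
    """Rank candidate antigens by their posterior F_diff distributions.

    For every posterior factor sample, the feature sums of the represented
    and control sets define an F_diff curve which is evaluated at each
    candidate's feature sum.  Candidates are ranked by the median of these
    evaluations (higher median = better = smaller rank); exact ties are
    broken lexicographically by candidate id and flagged.

    Parameters
    ----------
    candidates_std:
        Standardized feature table of the candidates (same scaler as the
        control set), indexed by candidate id.

    Returns
    -------
    DataFrame indexed by candidate id with columns
    ``median_fdiff, q5, q95, rank, tied``, sorted by rank.
    """
    if posterior.samples.shape[0] < 1:
        raise ValueError("posterior is empty")
    if candidates_std.empty:
        raise ValueError("no candidates to rank")
    x_rep = np.asarray(represented_std, dtype=float)
    x_ctrl = np.asarray(control_std, dtype=float)
    x_cand = candidates_std.to_numpy(dtype=float)
    evals = np.empty((posterior.samples.shape[0], x_cand.shape[0]))
    with warnings.catch_warnings():
        # off-grid candidates are expected for extreme posterior draws
        warnings.simplefilter("ignore")
        for k, p in enumerate(posterior.samples):
            curve = density_difference(x_rep @ p, x_ctrl @ p, kde_config)
            evals[k] = curve.evaluate(feature_sum(p, x_cand))
    med = np.median(evals, axis=0)
    q5 = np.quantile(evals, 0.05, axis=0)
    q95 = np.quantile(evals, 0.95, axis=0)
    out = pd.DataFrame(
        {"median_fdiff": med, "q5": q5, "q95": q95}, index=candidates_std.index
    )
    out.index.name = "id"
    # stable sort: id order first, then descending median => ties broken by id
    out = out.sort_index().sort_values("median_fdiff", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    tied = np.zeros(len(out), dtype=bool)
    m = out["median_fdiff"].to_numpy()
    close = np.abs(np.diff(m)) <= tie_tolerance
    tied[:-1] |= close
    tied[1:] |= close
    out["tied"] = tied
    return out


@dataclass
class AntigenRankingResult:
    """Everything the antigen-prioritization stage produces."""

    features: pd.DataFrame  # raw features of the control universe
    posterior: PosteriorSet
    ranking: pd.DataFrame  # rank_candidates output


def rank_antigens(
    proteome,
    represented_ids,
    candidates,
    mcmc_config: McmcConfig | None = None,
    kde_config: KdeConfig | None = None,
    on_noncanonical: str = "skip",
) -> AntigenRankingResult:
    """End-to-end antigen prioritization.

    Computes the feature table of the proteome (the control set),
    standardizes against it, infers the factor posterior separating the
    represented antigens from the control set, and ranks the candidate
    antigens by their posterior F_diff distributions.

    Parameters
    ----------
    proteome:
        Control universe of :class:`~pepsplice.features.ProteinRecord`.
    represented_ids:
        IDs of the antigens represented in the immunopeptidome (must be
        present in the proteome after feature filtering).
    candidates:
        Candidate antigens: protein records, or IDs drawn from the proteome.
    """
    from .features import feature_table, standardize_features

    table = feature_table(proteome, on_noncanonical=on_noncanonical)
    rep_ids = [i for i in represented_ids if i in table.index]
    if not rep_ids:
        raise ValueError("no represented antigen IDs match the proteome")
    table_std, scaler = standardize_features(table, table)
    if candidates and isinstance(candidates[0], str):
        missing = [c for c in candidates if c not in table.index]
        if missing:
            raise ValueError(f"candidate ID(s) not in proteome: {missing}")
        cand_std = table_std.loc[list(candidates)]
    else:
        cand_table = feature_table(candidates, on_noncanonical="raise")
        cand_std = scaler.transform(cand_table)
    posterior = infer_factors_mcmc(table_std.loc[rep_ids], table_std, mcmc_config)
    ranking = rank_candidates(cand_std, table_std.loc[rep_ids], table_std, posterior, kde_config)
    return AntigenRankingResult(features=table, posterior=posterior, ranking=ranking)
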