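"""Abundance-weighted niche statistics and the permutation null model.

For a species ``i`` and an environmental gradient with per-plot values
``L_p``, the niche optimum is the abundance-weighted mean

    AWM_i = sum_p L_p * a_ip / A_i,

the niche breadth is the abundance-weighted (population-form) standard
deviation

    AWSD_i = sqrt( sum_p a_ip * (L_p - AWM_i)^2 / A_i ),

and the standardized breadth is the weighted coefficient of variation
``CV = AWSD / AWM``.  Observed values are compared against a null model that
redistributes the species' observed nonzero abundances over ``N_i`` sites
drawn uniformly without replacement from the plots of the habitat — but only
within the regions where the species was actually recorded, so apparent
specialization cannot arise from a range boundary.  Species whose observed
AWM falls above the nearest-rank 95th percentile of the null AWMs are
"winners" of the gradient (labelled "high" on abiotic gradients), below the
5th percentile "losers" ("low"); among the remainder, a species whose
observed CV is narrower than the null 5th percentile (and nonzero) is a
"mid-specialist", everything else is neutral (an "opportunist").

Per-species random substreams are derived from a master seed and a stable
hash of the species and gradient names, so adding or removing one species
never changes another's classification.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, EnvironmentTable, RedListTable

LANDUSE_STATUSES = ("winner", "loser", "neutral", "mid-specialist")
ABIOTIC_STATUSES = ("high", "low", "neutral", "mid-specialist")

#: Gradients reported with "low"/"high" labels instead of loser/winner.
ABIOTIC_GRADIENTS = frozenset({"pH", "moisture"})

#: The five single niche dimensions entering the hypervolume, per habitat
#: (the three single land-use components plus the two abiotic factors;
#: compound indices are excluded).
HYPERVOLUME_COMPONENTS = {
    "forest": ("Inonat", "Idwcut", "Iharv", "pH", "moisture"),
    "grassland": ("mowing", "grazing", "fertilization", "pH", "moisture"),
}


class NullModelError(ValueError):
    """Raised when the permutation pool is inconsistent with the data."""


# --------------------------------------------------------------------------
# Weighted statistics
# --------------------------------------------------------------------------

def _weighted_stats(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    total = weights.sum()
    awm = float((values * weights).sum() / total)
    awsd = float(np.sqrt((weights * (values - awm) ** 2).sum() / total))
    return awm, awsd


def _species_site_data(
    abund: AbundanceMatrix, env: EnvironmentTable, species: str, gradient: str
) -> tuple[np.ndarray, np.ndarray]:
    if species not in abund.species:
        raise KeyError(f"species '{species}' absent from abundance matrix")
    counts = abund.counts[species]
    occupied = counts[counts > 0]
    grad = env.data[gradient].reindex(occupied.index)
    if grad.isna().any():
        bad = list(grad.index[grad.isna()])
        raise NullModelError(
            f"gradient '{gradient}' undefined on occupied plot(s) {bad}")
    return grad.to_numpy(dtype=float), occupied.to_numpy(dtype=float)


def abundance_weighted_mean(
    abund: AbundanceMatrix, env: EnvironmentTable, species: str, gradient: str
) -> float:
    """Niche optimum: abundance-weighted mean of the gradient (AWM)."""
    values, weights = _species_site_data(abund, env, species, gradient)
    return _weighted_stats(values, weights)[0]


def abundance_weighted_sd(
    abund: AbundanceMatrix, env: EnvironmentTable, species: str, gradient: str
) -> float:
    """Niche breadth: abundance-weighted standard deviation (AWSD).

    Population form (divisor A_i), so a single-site species has breadth 0.
    """
    values, weights = _species_site_data(abund, env, species, gradient)
    return _weighted_stats(values, weights)[1]


@dataclass
class NicheEstimate:
    """Observed niche statistics of one species on one gradient."""

    species: str
    gradient: str
    awm: float
    awsd: float
    cv: float          # NaN when AWM == 0 (undefined)
    n_sites: int
    regions: tuple[str, ...]

    @property
    def cv_defined(self) -> bool:
        return np.isfinite(self.cv)


def niche_estimate(
    abund: AbundanceMatrix, env: EnvironmentTable, species: str, gradient: str
) -> NicheEstimate:
    values, weights = _species_site_data(abund, env, species, gradient)
    awm, awsd = _weighted_stats(values, weights)
    cv = awsd / awm if awm > 0 else float("nan")
    occupied = abund.counts.index[abund.counts[species] > 0]
    regions = tuple(sorted(env.data.loc[occupied, "region"].unique()))
    return NicheEstimate(species=species, gradient=gradient, awm=awm, awsd=awsd,
                         cv=cv, n_sites=len(values), regions=regions)


# --------------------------------------------------------------------------
# Null model
# --------------------------------------------------------------------------

def nearest_rank_quantile(sorted_draws: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile (ceil(q*n)-th order statistic)."""
    n = len(sorted_draws)
    idx = int(np.ceil(q * n)) - 1
    return float(sorted_draws[min(max(idx, 0), n - 1)])


@dataclass
class NullDistribution:
    """Null-model draws of AWM/AWSD/CV for one species × gradient."""

    species: str
    gradient: str
    n_iter: int
    awm_draws: np.ndarray
    awsd_draws: np.ndarray
    cv_draws: np.ndarray
    observed: NicheEstimate
    pool_size: int

    @property
    def p_high(self) -> float:
        """Share of null AWMs at or above the observed AWM (ties extreme)."""
        return float((self.awm_draws >= self.observed.awm).mean())

    @property
    def p_low(self) -> float:
        return float((self.awm_draws <= self.observed.awm).mean())

    @property
    def p_cv_low(self) -> float:
        cv = self.cv_draws[np.isfinite(self.cv_draws)]
        if not self.observed.cv_defined or len(cv) == 0:
            return float("nan")
        return float((cv <= self.observed.cv).mean())

    def awm_quantile(self, q: float) -> float:
        return nearest_rank_quantile(np.sort(self.awm_draws), q)

    def cv_quantile(self, q: float) -> float:
        cv = np.sort(self.cv_draws[np.isfinite(self.cv_draws)])
        if len(cv) == 0:
            return float("nan")
        return nearest_rank_quantile(cv, q)


def species_rng(seed: int, species: str, gradient: str) -> np.random.Generator:
    """Deterministic per-species × gradient random substream.

    The stream depends on the master seed and on stable CRC32 hashes of the
    species and gradient names only — never on the position of the species
    in the matrix or of the plots in the table.
    """
    key = [seed, zlib.crc32(species.encode()), zlib.crc32(gradient.encode())]
    return np.random.default_rng(np.random.SeedSequence(key))


def null_model(
    abund: AbundanceMatrix,
    env: EnvironmentTable,
    species: str,
    gradient: str,
    n_iter: int = 10_000,
    seed: int = 0,
    weighting: str = "abundance",
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Region-restricted permutation null for one species × gradient.

    Each iteration draws ``N_i`` distinct plots uniformly from the pool of
    analyzed plots lying in the regions where the species occurs, assigns
    the observed nonzero-abundance multiset to them in random order
    (``weighting="abundance"``, the default, which preserves the species'
    total abundance) or weights every drawn site equally
    (``weighting="presence"``), and recomputes AWM, AWSD and CV.
    """
    obs = niche_estimate(abund, env, species, gradient)
    pool_mask = env.data["region"].isin(obs.regions) & env.data[gradient].notna()
    pool_plots = env.data.index[pool_mask].sort_values()
    pool = env.data.loc[pool_plots, gradient].to_numpy(dtype=float)
    n_sites = obs.n_sites
    if len(pool) < n_sites:
        raise NullModelError(
            f"pool of {len(pool)} plots smaller than N_i={n_sites} for "
            f"species '{species}' on '{gradient}' (inconsistent region restriction)")
    if weighting == "abundance":
        counts = abund.counts[species]
        # fixed (plot-id) order => draws invariant to matrix row order
        weights = counts[counts > 0].sort_index().to_numpy(dtype=float)
    elif weighting == "presence":
        weights = np.ones(n_sites)
    else:
        raise ValueError(f"unknown null weighting {weighting!r}")
    if rng is None:
        rng = species_rng(seed, species, gradient)

    # Random N_i-subsets in random order: argsort of uniform noise.  The
    # first N_i columns are a uniform ordered sample without replacement,
    # so multiplying by the (fixed-order) weight vector permutes the
    # observed abundances over the drawn sites.
    order = np.argsort(rng.random((n_iter, len(pool))), axis=1)[:, :n_sites]
    L = pool[order]                                    # n_iter × N_i
    total = weights.sum()
    awm = (L * weights).sum(axis=1) / total
    awsd = np.sqrt(((L - awm[:, None]) ** 2 * weights).sum(axis=1) / total)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(awm > 0, awsd / awm, np.nan)
    return NullDistribution(species=species, gradient=gradient, n_iter=n_iter,
                            awm_draws=awm, awsd_draws=awsd, cv_draws=cv,
                            observed=obs, pool_size=len(pool))


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

@dataclass
class ResponseClassification:
    species: str
    gradient: str
    status: str
    p_value: float


def classify_response(
    obs: NicheEstimate,
    null: NullDistribution,
    alpha: float = 0.05,
    gradient_kind: str | None = None,
    cv_rule: str = "quantile",
) -> ResponseClassification:
    """Assign winner/loser/mid-specialist/neutral from observed vs null.

    ``gradient_kind`` is "landuse" (winner/loser labels) or "abiotic"
    (high/low labels); by default it is inferred from the gradient name.
    ``cv_rule`` controls the mid-specialist test: "quantile" (observed CV
    below the null alpha-quantile) or "mean" (below the null mean CV).
    """
    if (obs.species, obs.gradient) != (null.species, null.gradient):
        raise ValueError("observed estimate and null distribution disagree")
    if gradient_kind is None:
        gradient_kind = "abiotic" if obs.gradient in ABIOTIC_GRADIENTS else "landuse"
    hi_label, lo_label = (("winner", "loser") if gradient_kind == "landuse"
                          else ("high", "low"))
    upper = null.awm_quantile(1.0 - alpha)
    lower = null.awm_quantile(alpha)
    if obs.awm > upper:
        return ResponseClassification(obs.species, obs.gradient, hi_label, null.p_high)
    if obs.awm < lower:
        return ResponseClassification(obs.species, obs.gradient, lo_label, null.p_low)
    if obs.cv_defined and obs.cv != 0:
        if cv_rule == "quantile":
            narrow = obs.cv < null.cv_quantile(alpha)
        elif cv_rule == "mean":
            narrow = obs.cv < float(np.nanmean(null.cv_draws))
        else:
            raise ValueError(f"unknown cv_rule {cv_rule!r}")
        if narrow:
            return ResponseClassification(obs.species, obs.gradient,
                                          "mid-specialist", null.p_cv_low)
    return ResponseClassification(obs.species, obs.gradient, "neutral",
                                  min(null.p_low, null.p_high))


# --------------------------------------------------------------------------
# Hypervolume
# --------------------------------------------------------------------------

@dataclass
class Hypervolume:
    """Five-dimensional niche hypervolume: the product of five AWSDs."""

    species: str
    habitat: str
    value: float
    component_awsds: dict[str, float]


def niche_hypervolume(
    estimates: dict[str, NicheEstimate] | dict[str, float],
    habitat: str,
    species: str | None = None,
) -> Hypervolume:
    """Product of the five habitat-appropriate niche breadths.

    ``estimates`` maps gradient name to either a :class:`NicheEstimate` or a
    bare AWSD.  A species found at a single site has every AWSD equal to 0
    and hence a zero hypervolume.
    """
    required = HYPERVOLUME_COMPONENTS[habitat]
    components: dict[str, float] = {}
    for g in required:
        if g not in estimates:
            raise KeyError(f"missing hypervolume component '{g}' for habitat {habitat}")
        est = estimates[g]
        awsd = est.awsd if isinstance(est, NicheEstimate) else float(est)
        components[g] = awsd
        if species is None and isinstance(est, NicheEstimate):
            species = est.species
    value = float(np.prod([components[g] for g in required]))
    return Hypervolume(species=species or "", habitat=habitat,
                       value=value, component_awsds=components)


# --------------------------------------------------------------------------
# Species response table
# --------------------------------------------------------------------------

def species_response_table(
    abund: AbundanceMatrix,
    env: EnvironmentTable,
    gradients: list[str],
    redlist: RedListTable | None = None,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    weighting: str = "abundance",
    cv_rule: str = "quantile",
) -> pd.DataFrame:
    """One row per species: code, region letters, N_i, A_i, status per gradient.

    The machine-readable twin of the study's status tables.  Classifications
    use one deterministic random substream per species × gradient, so they
    are invariant to plot and species ordering.
    """
    rows = []
    occurrence = abund.occurrence
    totals = abund.species_totals
    for sp in abund.species:
        occupied = abund.counts.index[abund.counts[sp] > 0]
        regions = sorted(env.data.loc[occupied, "region"].unique())
        row: dict[str, object] = {
            "species": sp,
            "redlist": (redlist.codes.get(sp, "") if redlist is not None else ""),
            "regions": "".join(r[0] for r in regions),
            "occurrence": int(occurrence[sp]),
            "abundance": int(totals[sp]),
        }
        for g in gradients:
            null = null_model(abund, env, sp, g, n_iter=n_iter, seed=seed,
                              weighting=weighting)
            cls = classify_response(null.observed, null, alpha=alpha, cv_rule=cv_rule)
            row[g] = cls.status
            row[f"{g}_p"] = cls.p_value
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
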