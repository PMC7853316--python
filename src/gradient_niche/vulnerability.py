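"""Habitat association, Red-List encoding and vulnerability models.

A species is a habitat *specialist* when more than 90% of all its recorded
individuals fall in one habitat.  Vulnerability is the species' national
Red-List code encoded as an ordinal rank (least concern = 0, rising with
threat) and modelled two ways:

* a Poisson GLM (log link) of the rank on the species' niche optimum (AWM)
  for a focal gradient plus log occurrence and log total abundance — the
  rarity-vs-response model;
* a Spearman rank correlation between the rank and the five-dimensional
  niche hypervolume, reported through the S statistic
  ``S = sum_i (rank(x_i) - rank(y_i))^2`` with average ranks for ties,
  ``rho = 1 - 6S / (n(n^2-1))`` and a large-sample t approximation for p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import AbundanceMatrix, RedListTable
from .niche import Hypervolume

logger = logging.getLogger("gradient_niche")

#: Default ordinal encoding of the seven Red-List codes, least concern = 0.
#: Near-threatened (V) and very-rare (R) sit below the threat categories;
#: "endangered to unknown extent" (G) is pooled with vulnerable (3).  The
#: source category order leaves the exact coding open, so every entry is
#: overridable.
DEFAULT_REDLIST_RANKS: dict[str, int] = {
    "*": 0, "V": 1, "R": 1, "G": 2, "3": 2, "2": 3, "1": 4,
}

SPECIALIST_THRESHOLD = 0.9


@dataclass
class VulnerabilityRecord:
    species: str
    redlist_code: str | None
    rank: int | None
    occurrence_forest: int
    occurrence_grassland: int
    abundance_forest: int
    abundance_grassland: int
    prop_forest: float
    specialist: str  # "forest" | "grassland" | "none"


def habitat_association(
    abund_forest: AbundanceMatrix,
    abund_grass: AbundanceMatrix,
    redlist: RedListTable | None = None,
    rank_map: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-species habitat association over the union of both species lists.

    ``prop_forest`` is the share of all recorded individuals found in
    forest; the specialist flag applies the >90% rule on either side.
    Species with zero total across both habitats are excluded with a logged
    notice.
    """
    species = abund_forest.species.union(abund_grass.species)
    af = abund_forest.species_totals.reindex(species, fill_value=0)
    ag = abund_grass.species_totals.reindex(species, fill_value=0)
    nf = abund_forest.occurrence.reindex(species, fill_value=0)
    ng = abund_grass.occurrence.reindex(species, fill_value=0)
    total = af + ag
    empty = species[total == 0]
    if len(empty):
        logger.info("excluding %d species with zero total abundance: %s",
                    len(empty), list(empty))
        species = species.difference(empty)
    rows = []
    ranks = encode_redlist(redlist, rank_map) if redlist is not None else None
    for sp in species:
        prop = float(af[sp] / (af[sp] + ag[sp]))
        if prop > SPECIALIST_THRESHOLD:
            flag = "forest"
        elif prop < 1.0 - SPECIALIST_THRESHOLD:
            flag = "grassland"
        else:
            flag = "none"
        code = redlist.codes.get(sp) if redlist is not None else None
        rows.append(VulnerabilityRecord(
            species=sp, redlist_code=code,
            rank=(int(ranks[sp]) if ranks is not None and sp in ranks.index else None),
            occurrence_forest=int(nf[sp]), occurrence_grassland=int(ng[sp]),
            abundance_forest=int(af[sp]), abundance_grassland=int(ag[sp]),
            prop_forest=prop, specialist=flag))
    return pd.DataFrame([vars(r) for r in rows]).set_index("species")


def encode_redlist(
    table: RedListTable,
    mapping: dict[str, int] | None = None,
) -> pd.Series:
    """Ordinal vulnerability rank per species (least concern = 0)."""
    mapping = dict(DEFAULT_REDLIST_RANKS if mapping is None else mapping)
    unknown = sorted(set(table.codes) - set(mapping))
    if unknown:
        raise KeyError(f"Red-List code(s) without rank mapping: {unknown}")
    return table.codes.map(mapping).astype(int).rename("rank")


def percent_least_concern(table: RedListTable) -> float:
    """Percentage of species carrying the least-concern code '*'."""
    if len(table.species) == 0:
        raise ValueError("empty Red-List table")
    return 100.0 * float((table.codes == "*").sum()) / len(table.species)


# --------------------------------------------------------------------------
# Poisson GLM of vulnerability
# --------------------------------------------------------------------------

@dataclass
class GlmResult:
    """Poisson-GLM fit of vulnerability rank on a focal predictor + rarity."""

    gradient: str
    params: pd.Series      # intercept, focal, log_occurrence, log_abundance
    pvalues: pd.Series
    deviance: float
    converged: bool
    n_species: int

    def term(self, name: str) -> tuple[float, float]:
        return float(self.params[name]), float(self.pvalues[name])


class GlmFitError(RuntimeError):
    pass


class GlmDataError(GlmFitError):
    """Too few species for the model (a data-size problem, not a fit failure)."""


def vulnerability_glm(
    ranks: pd.Series,
    focal: pd.Series,
    occurrence: pd.Series,
    abundance: pd.Series,
    gradient: str,
    sqrt_focal: bool | None = None,
) -> GlmResult:
    """Poisson GLM: rank ~ focal AWM + log(occurrence) + log(abundance).

    Occurrence and abundance are natural-log transformed (both are >= 1 by
    construction for recorded species); the focal species-level gradient
    optimum is square-root transformed for grazing and fertilization,
    matching the plot-level convention.
    """
    if sqrt_focal is None:
        sqrt_focal = gradient in {"grazing", "fertilization"}
    df = pd.DataFrame({
        "rank": ranks, "focal": focal,
        "occ": occurrence, "abund": abundance,
    }).dropna()
    n_params = 4
    if len(df) < n_params + 3:
        raise GlmDataError(
            f"{len(df)} species for a {n_params}-parameter model; need at least "
            f"{n_params + 3}")
    if (df["rank"] < 0).any() or not np.allclose(df["rank"], np.round(df["rank"])):
        raise ValueError("vulnerability ranks must be non-negative integers")
    x_focal = np.sqrt(df["focal"]) if sqrt_focal else df["focal"]
    X = pd.DataFrame({
        gradient: x_focal,
        "occurrence": np.log(df["occ"].astype(float)),
        "abundance": np.log(df["abund"].astype(float)),
    })
    X = sm.add_constant(X)
    model = sm.GLM(df["rank"].astype(float), X, family=sm.families.Poisson())
    try:
        fit = model.fit()
    except Exception:
        # degenerate responses (e.g. every rank zero) can break the default
        # starting values; retry from the null model before giving up
        try:
            fit = model.fit(start_params=np.zeros(X.shape[1]))
        except Exception as exc:
            raise GlmFitError(f"Poisson GLM failed for '{gradient}': {exc}") from exc
    if not np.all(np.isfinite(fit.params)):
        raise GlmFitError(f"non-finite estimates for '{gradient}': {fit.params.to_dict()}")
    return GlmResult(gradient=gradient, params=fit.params, pvalues=fit.pvalues,
                     deviance=float(fit.deviance),
                     converged=bool(fit.converged), n_species=len(df))


# --------------------------------------------------------------------------
# Spearman correlation with the hypervolume
# --------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    S: float
    rho: float
    p: float
    n: int


def spearman_rank_correlation(x, y) -> SpearmanResult:
    """Spearman correlation via the S statistic.

    ``S`` is the sum of squared rank differences with average ranks for
    ties; ``rho`` follows the no-tie identity ``1 - 6S/(n(n^2-1))`` (the
    convention used when S is reported alongside rho), and p comes from the
    two-sided large-sample t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one variable: correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    S = float(((rx - ry) ** 2).sum())
    rho = 1.0 - 6.0 * S / (n * (n ** 2 - 1))
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(S=S, rho=rho, p=p, n=n)


def correlate_hypervolume_vulnerability(
    hypervolumes: list[Hypervolume] | pd.Series,
    ranks: pd.Series,
) -> SpearmanResult:
    """Spearman test of vulnerability rank against niche hypervolume."""
    if isinstance(hypervolumes, pd.Series):
        hv = hypervolumes
    else:
        hv = pd.Series({h.species: h.value for h in hypervolumes})
    paired = pd.DataFrame({"hv": hv, "rank": ranks}).dropna()
    return spearman_rank_correlation(paired["hv"], paired["rank"])
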