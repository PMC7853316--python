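"""Community-weighted mean (CWM) traits and their gradient models.

The CWM of a trait in plot ``p`` is the abundance-weighted average of the
species trait values present there,

    CWM_p = sum_i T_i * a_ip / A_p,

where the sum runs over the species with a known trait value and ``A_p`` is
recomputed over those species.  Per-gradient ordinary-least-squares models
``CWM ~ gradient + region + gradient:region`` with a sequential (type-I)
ANOVA decomposition test how land use and abiotic conditions shape community
trait composition; a separate habitat/region comparison reproduces the
forest-vs-grassland contrasts (per-region ANOVA plus Tukey HSD across
regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import AbundanceMatrix, EnvironmentTable, TraitTable

#: Gradients square-root transformed before model fitting (heavily
#: right-skewed management intensities).
SQRT_TRANSFORMED = frozenset({"grazing", "fertilization"})


class ModelDataError(ValueError):
    """Raised when a model has fewer usable plots than parameters."""


def community_weighted_mean(
    abund: AbundanceMatrix,
    traits: TraitTable,
    trait: str,
) -> pd.Series:
    """CWM of ``trait`` for every plot; NaN where no usable abundance.

    Species lacking the trait are excluded and the per-plot total abundance
    is recomputed over the remaining species, so the CWM stays a proper
    weighted mean of known trait values.
    """
    if trait not in traits.data.columns:
        raise KeyError(f"trait '{trait}' not in trait table")
    tvals = traits.data[trait].dropna()
    usable = abund.species.intersection(tvals.index)
    counts = abund.counts[usable]
    totals = counts.sum(axis=1)
    weighted = counts.to_numpy(dtype=float) @ tvals.loc[usable].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        cwm = np.where(totals > 0, weighted / totals.to_numpy(), np.nan)
    return pd.Series(cwm, index=abund.plots, name=trait)


def cwm_table(abund: AbundanceMatrix, traits: TraitTable,
              trait_names: list[str] | None = None) -> pd.DataFrame:
    """CWM of every (or the named) trait, one column per trait."""
    names = trait_names or traits.traits
    return pd.DataFrame({t: community_weighted_mean(abund, traits, t) for t in names})


# --------------------------------------------------------------------------
# Gradient models
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Sequential ANOVA of one CWM ~ gradient (+ region) model.

    ``table`` has one row per term (gradient, region, gradient:region,
    Residual) with df, sum_sq, F and p in fitted order.
    """

    trait: str
    gradient: str
    habitat: str | None
    table: pd.DataFrame
    n_plots: int
    transform: str = "identity"

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _maybe_transform(gradient: str, values: pd.Series,
                     transforms: dict[str, str] | None = None) -> tuple[pd.Series, str]:
    kind = (transforms or {}).get(
        gradient, "sqrt" if gradient in SQRT_TRANSFORMED else "identity")
    if kind == "sqrt":
        return np.sqrt(values), "sqrt"
    if kind == "log":
        return np.log(values), "log"
    return values, "identity"


def fit_cwm_gradient_model(
    cwm: pd.Series,
    env: EnvironmentTable,
    gradient: str,
    habitat: str | None = None,
    transforms: dict[str, str] | None = None,
) -> AnovaResult:
    """OLS fit of CWM ~ gradient + region + gradient:region, type-I ANOVA.

    The gradient enters first, then region, then the interaction, so the
    printed sums of squares decompose sequentially.  With a single region
    the region terms drop out.  ``transforms`` overrides the default
    square-root transform of grazing/fertilization.
    """
    df = env.data if habitat is None else env.data[env.data["habitat"] == habitat]
    if gradient not in df.columns:
        raise KeyError(f"gradient '{gradient}' not in environment table")
    work = pd.DataFrame({
        "cwm": cwm.reindex(df.index),
        "g": df[gradient],
        "region": df["region"],
    }).dropna()
    g_t, tname = _maybe_transform(gradient, work["g"], transforms)
    work = work.assign(g=g_t)
    n_regions = work["region"].nunique()
    n_params = 2 if n_regions == 1 else 3 * n_regions
    if len(work) < n_params + 1:
        raise ModelDataError(
            f"{len(work)} usable plots but {n_params} parameters "
            f"(need at least {n_params + 1 - len(work)} more)")

    # Sequential decomposition with the gradient entered FIRST, then region,
    # then the interaction.  The formula interface would reorder categorical
    # main effects ahead of the gradient, so the nested fits are built
    # explicitly and each term's SS is the drop in residual SS it buys.
    n = len(work)
    y = work["cwm"].to_numpy(dtype=float)
    g = work["g"].to_numpy(dtype=float)
    blocks: list[tuple[str, np.ndarray]] = [(gradient, g.reshape(-1, 1))]
    if n_regions > 1:
        dummies = pd.get_dummies(work["region"], drop_first=True).to_numpy(float)
        blocks.append(("region", dummies))
        blocks.append((f"{gradient}:region", dummies * g[:, None]))

    X = np.ones((n, 1))
    rss_prev = float(sm.OLS(y, X).fit().ssr)
    rows = []
    for name, block in blocks:
        X = np.hstack([X, block])
        fit = sm.OLS(y, X).fit()
        rows.append((name, block.shape[1], rss_prev - float(fit.ssr)))
        rss_prev = float(fit.ssr)
    df_resid = n - X.shape[1]
    ms_resid = rss_prev / df_resid if df_resid > 0 else np.nan
    table_rows = {}
    for name, df_term, ss in rows:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df_term) / ms_resid
        p = np.nan if np.isnan(F) else float(stats.f.sf(F, df_term, df_resid))
        table_rows[name] = {"df": float(df_term), "sum_sq": ss, "F": F, "p": p}
    table_rows["Residual"] = {"df": float(df_resid), "sum_sq": rss_prev,
                              "F": np.nan, "p": np.nan}
    table = pd.DataFrame(table_rows).T[["df", "sum_sq", "F", "p"]]
    return AnovaResult(trait=str(cwm.name), gradient=gradient, habitat=habitat,
                       table=table, n_plots=n, transform=tname)


# --------------------------------------------------------------------------
# Habitat / region comparison
# --------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Habitat contrasts of a CWM within regions, region contrasts within habitats.

    ``habitat_tests`` maps region -> (F, p) of a one-way ANOVA between the
    two habitats; regions with a single habitat are listed in ``skipped``.
    ``region_tests`` maps habitat -> a DataFrame of all region pairs with
    Tukey-HSD family-wise adjusted p-values.
    """

    trait: str
    habitat_tests: dict[str, tuple[float, float]] = field(default_factory=dict)
    region_tests: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)


def compare_cwm_habitat_region(
    cwm: pd.Series,
    env: EnvironmentTable,
) -> ComparisonReport:
    """Per-region habitat ANOVA and per-habitat Tukey region comparison."""
    work = pd.DataFrame({
        "cwm": cwm.reindex(env.plots),
        "habitat": env.data["habitat"],
        "region": env.data["region"],
    }).dropna()
    report = ComparisonReport(trait=str(cwm.name))
    for region, sub in work.groupby("region", observed=True):
        if sub["habitat"].nunique() < 2:
            report.skipped[str(region)] = "only one habitat present"
            continue
        fit = smf.ols("cwm ~ C(habitat)", data=sub).fit()
        an = sm.stats.anova_lm(fit, typ=1)
        report.habitat_tests[str(region)] = (
            float(an.loc["C(habitat)", "F"]), float(an.loc["C(habitat)", "PR(>F)"]))
    for habitat, sub in work.groupby("habitat", observed=True):
        if sub["region"].nunique() < 2:
            report.skipped[str(habitat)] = "only one region present"
            continue
        tk = pairwise_tukeyhsd(sub["cwm"].to_numpy(), sub["region"].to_numpy())
        frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        report.region_tests[str(habitat)] = frame
    return report
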