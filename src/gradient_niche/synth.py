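"""Synthetic communities with known niche ground truth.

The generator emulates the structure of the field study the analysis was
designed for: three regions, two habitats (forest and grassland), ~50 plots
per region × habitat spread along measured land-use and abiotic gradients,
and a species pool whose expected abundance follows Gaussian response curves

    E[a_ip] = lambda_max * h(habitat_p) * prod_g exp(-(L_gp - mu_ig)^2 / (2 sigma_ig^2))

with Poisson (default) or negative-binomial counting noise.  Because the true
niche optimum ``mu``, breadth ``sigma``, habitat affinity and a declared
winner/loser status are recorded per species, every downstream estimator can
be tested for parameter recovery and classification power without field data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AbundanceMatrix,
    EnvironmentTable,
    FOREST_GRADIENTS,
    GRASSLAND_GRADIENTS,
    RedListTable,
    TraitTable,
    TRAIT_LEVELS,
)

#: Observed gradient ranges of the study system (min, max), used as defaults.
DEFAULT_GRADIENT_RANGES: dict[str, tuple[float, float]] = {
    "LUI": (0.53, 4.52),
    "mowing": (0.0, 3.0),
    "grazing": (0.0, 851.0),
    "fertilization": (0.0, 433.0),
    "FORMI": (0.0, 2.82),
    "Inonat": (0.0, 1.0),
    "Idwcut": (0.0, 1.0),
    "Iharv": (0.0, 1.0),
    "pH": (3.0, 6.72),
    "moisture": (8.55, 55.22),
}

DEFAULT_REGIONS = ("ALB", "HAI", "SCH")

#: Primary (classification-driving) gradient per habitat: the compound
#: land-use indices.
PRIMARY_GRADIENT = {"forest": "FORMI", "grassland": "LUI"}

#: Marginal Red-List code frequencies for randomly drawn species, roughly
#: matching a managed central-European landscape where most recorded species
#: are of least concern.
REDLIST_FREQS = {"*": 0.66, "V": 0.11, "R": 0.02, "G": 0.05,
                 "3": 0.08, "2": 0.05, "1": 0.03}


@dataclass
class SpeciesSpec:
    """Ground-truth description of one synthetic species.

    ``habitat_affinity`` is the share of expected abundance falling in
    forest (1 = strict forest species, 0 = strict grassland species).
    ``true_status`` records the status the species was constructed to have
    on its habitat's primary gradient — bookkeeping for power tests, not an
    input to any estimator.  ``regions`` optionally restricts the species'
    range: expectation is zeroed outside the listed regions so the null
    model's region restriction can be exercised.
    """

    name: str
    niche_optimum: dict[str, float]
    niche_sd: dict[str, float]
    peak_abundance: float
    habitat_affinity: float
    traits: dict[str, float]
    true_status: str = "neutral"
    redlist_code: str = "*"
    regions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.peak_abundance <= 0:
            raise ValueError(f"{self.name}: peak_abundance must be > 0")
        if not 0.0 <= self.habitat_affinity <= 1.0:
            raise ValueError(f"{self.name}: habitat_affinity must be in [0, 1]")
        for g, s in self.niche_sd.items():
            if s <= 0:
                raise ValueError(f"{self.name}: niche_sd[{g}] must be > 0")


@dataclass
class ScenarioConfig:
    """Configuration of one synthetic study.

    Defaults mirror the study design: 3 regions × 2 habitats × 50 plots with
    gradients uniform over their observed ranges.  ``short_grassland_region``
    reproduces the reduced sampling in one region (34 instead of 50 grassland
    plots) when set to a region name.
    """

    n_regions: int = 3
    plots_per_region_habitat: int = 50
    short_grassland_region: str | None = None
    short_grassland_plots: int = 34
    gradient_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GRADIENT_RANGES))
    n_species: int = 30
    composition: dict[str, int] | None = None  # true_status -> species count
    abundance_noise: str = "poisson"           # "poisson" | "negbin" | "none"
    negbin_k: float = 2.0                      # overdispersion (smaller = more)
    region_offset: float = 0.0                 # fraction of range shifted/region
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (lo, hi) in self.gradient_ranges.items():
            if lo >= hi:
                raise ValueError(f"invalid range for {g}: min {lo} >= max {hi}")
        if not 1 <= self.n_regions <= len(DEFAULT_REGIONS):
            raise ValueError("n_regions must be between 1 and 3")

    @property
    def regions(self) -> tuple[str, ...]:
        return DEFAULT_REGIONS[: self.n_regions]

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "gradient_ranges" in d:
            d["gradient_ranges"] = {k: tuple(v) for k, v in d["gradient_ranges"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """True niche parameters and declared statuses of the generated pool."""

    species: list[SpeciesSpec]

    def declared(self, status: str) -> list[str]:
        return [s.name for s in self.species if s.true_status == status]

    def by_name(self, name: str) -> SpeciesSpec:
        return next(s for s in self.species if s.name == name)

    def to_json(self) -> str:
        return json.dumps([asdict(s) for s in self.species], indent=2)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# --------------------------------------------------------------------------
# Environment
# --------------------------------------------------------------------------

def generate_environment(config: ScenarioConfig) -> EnvironmentTable:
    """Draw plots uniformly over the configured gradient ranges.

    Each region × habitat gets its own block of plots; ``region_offset``
    optionally shifts each region's draw window by that fraction of the
    range (clipped to the range) to induce region × gradient confounding,
    which real landscapes show.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE17]))
    rows = []
    for r_idx, region in enumerate(config.regions):
        for habitat in ("forest", "grassland"):
            n = config.plots_per_region_habitat
            if (habitat == "grassland"
                    and region == config.short_grassland_region):
                n = config.short_grassland_plots
            grads = FOREST_GRADIENTS if habitat == "forest" else GRASSLAND_GRADIENTS
            block = {}
            for g in grads:
                lo, hi = config.gradient_ranges[g]
                span = hi - lo
                shift = config.region_offset * span * (r_idx - (config.n_regions - 1) / 2)
                vals = rng.uniform(lo, hi, size=n) + shift
                block[g] = np.clip(vals, lo, hi)
            for i in range(n):
                row = {"plot_id": f"{region}-{habitat[0].upper()}{i + 1:03d}",
                       "region": region, "habitat": habitat}
                row.update({g: block[g][i] for g in grads})
                rows.append(row)
    df = pd.DataFrame(rows).set_index("plot_id")
    # keep one column per gradient; habitat-inapplicable gradients stay NaN
    return EnvironmentTable(df)


# --------------------------------------------------------------------------
# Species pool
# --------------------------------------------------------------------------

def _random_traits(rng: np.random.Generator) -> dict[str, float]:
    traits: dict[str, float] = {"shell_size": float(np.round(rng.lognormal(1.2, 0.7), 2))}
    for col, levels in TRAIT_LEVELS.items():
        if levels is not None:
            traits[col] = int(rng.integers(1, len(levels) + 1))
    return traits


def make_species_pool(config: ScenarioConfig) -> list[SpeciesSpec]:
    """Build a pool with the configured status composition.

    ``config.composition`` maps declared status (``winner``, ``loser``,
    ``mid-specialist``, ``neutral``) to species counts; the default is an
    all-but-a-few neutral pool with a couple of winners and losers per
    habitat, enough to exercise every classification branch.  Statuses are
    declared on the habitat's primary gradient (FORMI in forest, LUI in
    grassland); winners sit at the gradient maximum, losers at the minimum,
    mid-specialists at the centre with a narrow breadth, and neutral species
    have a breadth several times the range (an effectively flat response).
    """
    comp = config.composition
    if comp is None:
        n = config.n_species
        comp = {"loser": max(2, n // 6), "winner": max(2, n // 6),
                "mid-specialist": max(1, n // 10)}
        comp["neutral"] = max(0, n - sum(comp.values()))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5BEC]))
    pool: list[SpeciesSpec] = []
    idx = 0
    for status, count in comp.items():
        for _ in range(count):
            idx += 1
            # alternate habitat preference through the pool
            affinity = float(rng.beta(2, 2)) if idx % 3 == 0 else (
                0.9 if idx % 2 == 0 else 0.1)
            habitat = "forest" if affinity >= 0.5 else "grassland"
            primary = PRIMARY_GRADIENT[habitat]
            lo, hi = config.gradient_ranges[primary]
            span = hi - lo
            if status == "loser":
                mu, sd = lo, 0.15 * span
            elif status == "winner":
                mu, sd = hi, 0.15 * span
            elif status == "mid-specialist":
                mu, sd = (lo + hi) / 2, 0.08 * span
            else:
                mu, sd = (lo + hi) / 2, 4.0 * span
            code = str(rng.choice(list(REDLIST_FREQS), p=list(REDLIST_FREQS.values())))
            pool.append(SpeciesSpec(
                name=f"sp{idx:03d}",
                niche_optimum={primary: float(mu)},
                niche_sd={primary: float(sd)},
                peak_abundance=8.0,
                habitat_affinity=affinity,
                traits=_random_traits(rng),
                true_status=status,
                redlist_code=code,
            ))
    return pool


# --------------------------------------------------------------------------
# Abundances
# --------------------------------------------------------------------------

def expected_abundance(spec: SpeciesSpec, env: EnvironmentTable) -> pd.Series:
    """Expected count of ``spec`` at every plot (Gaussian response model)."""
    df = env.data
    lam = np.full(len(df), spec.peak_abundance, dtype=float)
    # habitat split: affinity is the forest share of expected abundance
    hab_factor = np.where(df["habitat"] == "forest",
                          2.0 * spec.habitat_affinity,
                          2.0 * (1.0 - spec.habitat_affinity))
    lam *= hab_factor
    for g, mu in spec.niche_optimum.items():
        if g not in df.columns:
            raise KeyError(f"gradient '{g}' in species {spec.name} absent from environment")
        sd = spec.niche_sd[g]
        L = df[g].to_numpy(dtype=float)
        kern = np.exp(-((L - mu) ** 2) / (2.0 * sd ** 2))
        kern = np.where(np.isnan(L), 0.0, kern)  # habitat lacks this gradient
        lam *= kern
    if spec.regions is not None:
        lam = np.where(df["region"].isin(spec.regions), lam, 0.0)
    return pd.Series(lam, index=df.index, name=spec.name)


def sample_abundances(
    pool: Sequence[SpeciesSpec],
    env: EnvironmentTable,
    config: ScenarioConfig,
) -> AbundanceMatrix:
    """Draw the plot × species count matrix under the configured noise model.

    ``noise="none"`` rounds the expectation to the nearest integer, which is
    useful for deterministic limit checks (a flat-niche species then has
    identical counts everywhere).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xAB0D]))
    cols = {}
    for spec in pool:
        lam = expected_abundance(spec, env).to_numpy()
        if config.abundance_noise == "poisson":
            counts = rng.poisson(lam)
        elif config.abundance_noise == "negbin":
            k = config.negbin_k
            # gamma-Poisson mixture with mean lam, dispersion k
            mix = rng.gamma(shape=k, scale=np.where(lam > 0, lam / k, 0.0))
            counts = rng.poisson(mix)
        elif config.abundance_noise == "none":
            counts = np.round(lam).astype(np.int64)
        else:
            raise ValueError(f"unknown noise model {config.abundance_noise!r}")
        cols[spec.name] = counts.astype(np.int64)
    counts = pd.DataFrame(cols, index=env.plots)
    return AbundanceMatrix(counts)


def generate_dataset(
    config: ScenarioConfig,
    pool: Sequence[SpeciesSpec] | None = None,
) -> tuple[EnvironmentTable, AbundanceMatrix, TraitTable, RedListTable, GroundTruth]:
    """Generate all four analysis inputs plus the ground-truth record."""
    env = generate_environment(config)
    if pool is None:
        pool = make_species_pool(config)
    abund = sample_abundances(pool, env, config).drop_empty_species()
    trait_rows = {s.name: s.traits for s in pool}
    traits = TraitTable(pd.DataFrame.from_dict(trait_rows, orient="index")
                        .rename_axis("species"))
    redlist = RedListTable(pd.DataFrame(
        {"code": {s.name: s.redlist_code for s in pool}}).rename_axis("species"))
    return env, abund, traits, redlist, GroundTruth(list(pool))
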