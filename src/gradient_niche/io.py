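"""Core tables for gradient-niche analyses and their delimited-text I/O.

Four tables drive every analysis stage:

* :class:`EnvironmentTable` — one row per plot with region, habitat and the
  land-use / abiotic gradient values measured there.
* :class:`AbundanceMatrix` — plot × species counts of individuals.
* :class:`TraitTable` — one row per species with continuous and ordinal traits.
* :class:`RedListTable` — one row per species with its national Red-List code.

All four read and write plain CSV/TSV with a header row.  Validation is
collected into a :class:`ValidationReport` rather than raised piecemeal, so a
caller can see every problem in a dataset at once and knows which analysis
stages remain runnable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gradient_niche")

# --------------------------------------------------------------------------
# Gradient roster (names, units and hard ranges used only for validation)
# --------------------------------------------------------------------------

#: Gradients measured on grassland plots.
GRASSLAND_GRADIENTS: tuple[str, ...] = (
    "LUI", "mowing", "grazing", "fertilization", "pH", "moisture",
)
#: Gradients measured on forest plots.
FOREST_GRADIENTS: tuple[str, ...] = (
    "FORMI", "Inonat", "Idwcut", "Iharv", "pH", "moisture",
)
#: Gradient columns constrained to [0, 1] (management-component proportions).
PROPORTION_GRADIENTS: frozenset[str] = frozenset({"Inonat", "Idwcut", "Iharv"})
#: Gradient columns that cannot be negative.
NONNEGATIVE_GRADIENTS: frozenset[str] = frozenset(
    {"mowing", "grazing", "fertilization", "FORMI", "LUI", "moisture"}
)

HABITATS: tuple[str, ...] = ("forest", "grassland")

#: The seven national Red-List codes, from least concern upward.
REDLIST_CODES: tuple[str, ...] = ("*", "V", "R", "G", "3", "2", "1")

#: Trait columns and their admissible ordinal level sets (None = continuous).
TRAIT_LEVELS: dict[str, tuple[int, ...] | None] = {
    "shell_size": None,                      # mm, > 0
    "offspring_class": (1, 2, 3),            # 1-10 / 11-100 / >100 per clutch
    "light_pref": (1, 2, 3, 4),              # deep shade .. indifferent
    "humidity_pref": (1, 2, 3),              # wet / moist / dry
    "drought_resist": (1, 2, 3, 4),          # hours / days / weeks / months
    "inundation_tol": (1, 2, 3),             # low / moderate / high
}


@dataclass(frozen=True)
class Dialect:
    """Delimited-text dialect.  Defaults to comma-separated, decimal point."""

    sep: str = ","
    decimal: str = "."

    def read_kwargs(self) -> dict:
        return {"sep": self.sep, "decimal": self.decimal}


CSV = Dialect()
TSV = Dialect(sep="\t")


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant.

    ``issues`` carries one human-readable message per offending cell/row.
    """

    def __init__(self, issues: Sequence[str]):
        self.issues = list(issues)
        super().__init__("; ".join(self.issues))


# --------------------------------------------------------------------------
# EnvironmentTable
# --------------------------------------------------------------------------

@dataclass
class EnvironmentTable:
    """Per-plot region, habitat and gradient values.

    ``data`` is indexed by ``plot_id`` and holds ``region``, ``habitat`` and
    one numeric column per gradient.  Gradient values may be NaN; plots with a
    missing value are excluded from (and flagged for) analyses of that
    gradient only.
    """

    data: pd.DataFrame

    REQUIRED = ("region", "habitat")

    def __post_init__(self) -> None:
        issues = self._check()
        if issues:
            raise ValidationError(issues)

    def _check(self) -> list[str]:
        issues: list[str] = []
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            issues.append(f"duplicate plot_id(s): {dups}")
        for col in self.REQUIRED:
            if col not in df.columns:
                issues.append(f"missing required column '{col}'")
        if "habitat" in df.columns:
            bad = sorted(set(df["habitat"].dropna()) - set(HABITATS))
            if bad:
                issues.append(f"unknown habitat value(s): {bad}")
        for col in self.gradients:
            vals = df[col]
            if col in PROPORTION_GRADIENTS:
                off = df.index[(vals < 0) | (vals > 1)]
                for plot in off:
                    issues.append(
                        f"plot '{plot}', column '{col}': value "
                        f"{df.loc[plot, col]} outside [0, 1]"
                    )
            if col == "pH":
                off = df.index[(vals <= 0) | (vals >= 14)]
                for plot in off:
                    issues.append(
                        f"plot '{plot}', column 'pH': value "
                        f"{df.loc[plot, col]} outside (0, 14)"
                    )
            if col in NONNEGATIVE_GRADIENTS:
                off = df.index[vals < 0]
                for plot in off:
                    issues.append(
                        f"plot '{plot}', column '{col}': negative value "
                        f"{df.loc[plot, col]}"
                    )
        return issues

    @property
    def plots(self) -> pd.Index:
        return self.data.index

    @property
    def gradients(self) -> list[str]:
        return [
            c for c in self.data.columns
            if c not in self.REQUIRED and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def subset(self, habitat: str | None = None,
               regions: Iterable[str] | None = None) -> "EnvironmentTable":
        df = self.data
        if habitat is not None:
            df = df[df["habitat"] == habitat]
        if regions is not None:
            df = df[df["region"].isin(set(regions))]
        return EnvironmentTable(df.copy())

    def to_csv(self, path: str | Path, dialect: Dialect = CSV) -> None:
        self.data.to_csv(path, sep=dialect.sep, index_label="plot_id")


def load_environment_table(
    path: str | Path,
    dialect: Dialect = CSV,
    rename: Mapping[str, str] | None = None,
) -> EnvironmentTable:
    """Read an environment table from delimited text.

    ``rename`` maps source header names onto the canonical column names
    (``plot_id``, ``region``, ``habitat``, gradient names).  Rows missing
    plot_id, region or habitat are rejected with a report listing each of
    them — never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, **dialect.read_kwargs())
    if rename:
        df = df.rename(columns=dict(rename))
    if "plot_id" not in df.columns:
        raise ValidationError(["no 'plot_id' column after renaming"])
    issues = []
    for col in ("plot_id",) + EnvironmentTable.REQUIRED:
        if col in df.columns:
            for i in df.index[df[col].isna()]:
                issues.append(f"row {i}: missing required field '{col}'")
    if issues:
        raise ValidationError(issues)
    df = df.set_index("plot_id")
    return EnvironmentTable(df)


# --------------------------------------------------------------------------
# AbundanceMatrix
# --------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Plot × species matrix of non-negative integer counts.

    Derived quantities follow the usual community-matrix bookkeeping:
    ``plot_totals`` (total individuals per plot), ``species_totals`` (total
    abundance of each species) and ``occurrence`` (number of plots where the
    species was found).
    """

    counts: pd.DataFrame  # index = plot_id, columns = species

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValidationError(["negative count in abundance matrix"])
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError(["non-integer count in abundance matrix"])
            self.counts = c.astype(np.int64)

    @property
    def plots(self) -> pd.Index:
        return self.counts.index

    @property
    def species(self) -> pd.Index:
        return self.counts.columns

    @property
    def plot_totals(self) -> pd.Series:
        """Total abundance of all individuals in each plot (A_p)."""
        return self.counts.sum(axis=1)

    @property
    def species_totals(self) -> pd.Series:
        """Total abundance of each species across plots (A_i)."""
        return self.counts.sum(axis=0)

    @property
    def occurrence(self) -> pd.Series:
        """Number of plots in which each species was found (N_i)."""
        return (self.counts > 0).sum(axis=0)

    @property
    def total_individuals(self) -> int:
        return int(self.counts.to_numpy().sum())

    def drop_empty_species(self) -> "AbundanceMatrix":
        empty = self.species_totals[self.species_totals == 0].index
        if len(empty):
            logger.info("dropping %d species with zero total abundance: %s",
                        len(empty), list(empty))
            return AbundanceMatrix(self.counts.drop(columns=empty))
        return self

    def align_to(self, env: EnvironmentTable) -> "AbundanceMatrix":
        """Reorder rows to the environment table's plot order.

        Every matrix plot must exist in the environment table; plots present
        in the environment but without a matrix row get zero counts (no
        individuals found there).
        """
        missing = self.plots.difference(env.plots)
        if len(missing):
            raise ValidationError(
                [f"plot '{p}' in abundance matrix absent from environment table"
                 for p in missing]
            )
        aligned = self.counts.reindex(env.plots, fill_value=0)
        return AbundanceMatrix(aligned)

    def subset_plots(self, plots: Iterable[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.counts.loc[list(plots)])

    def to_csv(self, path: str | Path, dialect: Dialect = CSV,
               orientation: str = "plots-as-rows") -> None:
        out = self.counts if orientation == "plots-as-rows" else self.counts.T
        label = "plot_id" if orientation == "plots-as-rows" else "species"
        out.to_csv(path, sep=dialect.sep, index_label=label)


def load_abundance_table(
    path: str | Path,
    orientation: str = "plots-as-rows",
    dialect: Dialect = CSV,
) -> AbundanceMatrix:
    """Read a plot × species count table.

    ``orientation`` is one of ``plots-as-rows`` (wide, plots down the side),
    ``species-as-rows`` (the transpose), or ``long`` (three columns: plot,
    species, count — one row per nonzero record, the common deposited
    format).  Species whose total abundance is zero are dropped with a
    logged notice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, **dialect.read_kwargs())
    if orientation == "long":
        plot_col, sp_col, n_col = df.columns[:3]
        wide = df.pivot_table(index=plot_col, columns=sp_col, values=n_col,
                              aggfunc="sum", fill_value=0)
        wide.columns.name = None
        wide.index.name = None
        counts = wide
    else:
        counts = df.set_index(df.columns[0])
        counts.index.name = None
        if orientation == "species-as-rows":
            counts = counts.T
        elif orientation != "plots-as-rows":
            raise ValueError(f"unknown orientation {orientation!r}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(["non-numeric count in abundance table"])
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError(["counts must be non-negative integers"])
    return AbundanceMatrix(counts.astype(np.int64)).drop_empty_species()


# --------------------------------------------------------------------------
# TraitTable / RedListTable
# --------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Per-species trait values, one row per species (index = species).

    Ordinal traits are coded as consecutive integers 1..k in the order the
    categories escalate (e.g. light preference: deep shade=1, light shade=2,
    no shade=3, indifferent=4); the coding is overridable by supplying an
    already-recoded table.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        issues = []
        if self.data.index.has_duplicates:
            issues.append("duplicate species in trait table")
        if "shell_size" in self.data.columns:
            bad = self.data.index[self.data["shell_size"] <= 0]
            issues.extend(f"species '{s}': shell_size must be > 0" for s in bad)
        for col, levels in TRAIT_LEVELS.items():
            if levels is None or col not in self.data.columns:
                continue
            vals = self.data[col].dropna()
            off = vals.index[~vals.isin(levels)]
            issues.extend(
                f"species '{s}': {col}={self.data.loc[s, col]} not in {levels}"
                for s in off
            )
        if issues:
            raise ValidationError(issues)

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | Path, dialect: Dialect = CSV) -> None:
        self.data.to_csv(path, sep=dialect.sep, index_label="species")


def load_trait_table(path: str | Path, dialect: Dialect = CSV,
                     rename: Mapping[str, str] | None = None) -> TraitTable:
    df = pd.read_csv(path, **dialect.read_kwargs())
    if rename:
        df = df.rename(columns=dict(rename))
    return TraitTable(df.set_index("species"))


@dataclass
class RedListTable:
    """Per-species Red-List code (index = species, column ``code``)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        issues = []
        if self.data.index.has_duplicates:
            issues.append("duplicate species in Red-List table")
        codes = self.data["code"].astype(str)
        bad = codes.index[~codes.isin(REDLIST_CODES)]
        issues.extend(
            f"species '{s}': unknown Red-List code {self.data.loc[s, 'code']!r}"
            for s in bad
        )
        if issues:
            raise ValidationError(issues)
        self.data = self.data.assign(code=codes)

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def codes(self) -> pd.Series:
        return self.data["code"]

    def to_csv(self, path: str | Path, dialect: Dialect = CSV) -> None:
        self.data.to_csv(path, sep=dialect.sep, index_label="species")


def load_redlist_table(path: str | Path, dialect: Dialect = CSV) -> RedListTable:
    df = pd.read_csv(path, dtype={"code": str}, **dialect.read_kwargs())
    return RedListTable(df.set_index("species"))


# --------------------------------------------------------------------------
# Cross-table validation
# --------------------------------------------------------------------------

@dataclass
class Issue:
    kind: str      # e.g. "missing-trait", "missing-gradient"
    subject: str   # species or plot id
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"[{self.kind}] {self.subject}: {self.message}"


@dataclass
class ValidationReport:
    """Outcome of cross-table validation.

    ``issues`` lists every inconsistency found; ``blocked_stages`` names the
    analysis stages whose required inputs are incomplete (e.g.
    ``cwm_model:pH`` when a plot lacks a pH value).  Stages not listed are
    runnable.  The pipeline refuses to run blocked stages.
    """

    issues: list[Issue] = field(default_factory=list)
    notices: list[Issue] = field(default_factory=list)
    blocked_stages: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues

    def stage_runnable(self, stage: str) -> bool:
        return stage not in self.blocked_stages

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "issues": [vars(i) for i in self.issues],
                "notices": [vars(i) for i in self.notices],
                "blocked_stages": self.blocked_stages,
            },
            indent=2,
        )

    def to_text(self) -> str:
        if self.ok:
            return "dataset valid: no issues found"
        lines = [f"{len(self.issues)} issue(s) found:"]
        lines += [f"  - {i}" for i in self.issues]
        if self.blocked_stages:
            lines.append("blocked stages:")
            lines += [f"  - {s}: {r}" for s, r in self.blocked_stages.items()]
        return "\n".join(lines)


def validate_dataset(
    env: EnvironmentTable,
    abund: AbundanceMatrix,
    traits: TraitTable | None = None,
    redlist: RedListTable | None = None,
) -> ValidationReport:
    """Check cross-table consistency and work out which stages can run.

    Missing traits block only the CWM stage for the affected species (niche
    statistics need no traits); a missing gradient value blocks the per-
    gradient model stages for that gradient; species without a Red-List code
    block the vulnerability stage.
    """
    report = ValidationReport()

    extra_plots = abund.plots.difference(env.plots)
    for p in extra_plots:
        report.issues.append(Issue("unknown-plot", str(p),
                                   "plot in abundance matrix absent from environment table"))

    for g in env.gradients:
        # A gradient is only required on plots of the habitat where it is
        # measured (forest and grassland have disjoint land-use components).
        if g in FOREST_GRADIENTS and g not in GRASSLAND_GRADIENTS:
            scope = env.data[env.data["habitat"] == "forest"]
        elif g in GRASSLAND_GRADIENTS and g not in FOREST_GRADIENTS:
            scope = env.data[env.data["habitat"] == "grassland"]
        else:
            scope = env.data
        missing = scope.index[scope[g].isna()]
        for p in missing:
            report.issues.append(Issue("missing-gradient", str(p),
                                       f"no value for gradient '{g}'"))
        if len(missing):
            for stage in (f"cwm_model:{g}", f"niche:{g}"):
                report.blocked_stages[stage] = (
                    f"gradient '{g}' missing for plot(s) {list(missing)}"
                )

    if traits is not None:
        untraited = abund.species.difference(traits.species)
        for s in untraited:
            report.issues.append(Issue("missing-trait", str(s),
                                       "species has no trait record; excluded from CWM stage"))

    if redlist is not None:
        uncoded = abund.species.difference(redlist.species)
        for s in uncoded:
            report.issues.append(Issue("missing-redlist", str(s),
                                       "species has no Red-List code"))
        if len(uncoded):
            report.blocked_stages["vulnerability"] = (
                f"Red-List code missing for {len(uncoded)} species"
            )

    # Snail-free plots are legitimate data, not defects: they are counted
    # here and excluded from CWM models downstream.
    empty_plots = abund.plot_totals[abund.plot_totals == 0].index
    for p in empty_plots:
        report.notices.append(Issue("empty-plot", str(p),
                                    "plot holds no individuals; excluded from CWM models"))

    return report
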