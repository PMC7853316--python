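"""Accessors for the published species-status tables bundled with the package.

The study printed, per habitat, one row per land-snail species with its
national Red-List code, the regions it was recorded in (A/H/S letters), its
occurrence (number of plots) and total abundance, and its classified
response to each gradient.  These printed tables are inputs — they let the
habitat-association, Red-List and report machinery be driven with the real
species list without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import RedListTable

_DATA = resources.files("gradient_niche") / "data"


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, dtype={"redlist": str}).set_index("species")


def forest_status_table() -> pd.DataFrame:
    """Published forest species table (49 species)."""
    return _load("forest_species_status.csv")


def grassland_status_table() -> pd.DataFrame:
    """Published grassland species table (48 species)."""
    return _load("grassland_species_status.csv")


def union_redlist_table() -> RedListTable:
    """Red-List codes over the union of the forest and grassland species lists.

    Codes agree between the two tables for every shared species.
    """
    f = forest_status_table()["redlist"]
    g = grassland_status_table()["redlist"]
    combined = pd.concat([f, g])
    conflicting = combined.groupby(level=0).nunique()
    bad = conflicting[conflicting > 1]
    if len(bad):  # defensive: would indicate a transcription fault
        raise ValueError(f"conflicting Red-List codes for {list(bad.index)}")
    codes = combined.groupby(level=0).first().rename("code")
    return RedListTable(codes.to_frame())


def status_share(table: pd.DataFrame, gradient: str, status: str) -> float:
    """Percentage of the table's species with ``status`` on ``gradient``."""
    col = table[gradient].str.lower()
    return 100.0 * float((col == status).sum()) / len(table)
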