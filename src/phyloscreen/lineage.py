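"""Phylogenetic lineage classification and taxonomic re-keying.

Animal phyla are grouped into four lineages following the modern
molecular phylogenetic synthesis: Early-Metazoan (Porifera),
Early-Eumetazoan (Cnidaria), Deuterostome (Echinodermata, Chordata) and
non-Deuterostome (Bryozoa, Mollusca, Annelida, Crustacea); plant and
algal phyla form a fifth plant/algae class.  A coarser binary grouping
places Porifera and Cnidaria — the ancestral phyla on the deuterostome
pathway — together with the deuterostomes; the binary scheme covers
animal phyla only, so plant/algal phyla map to NOT_APPLICABLE.

The default scheme ships as an editable two-column-per-fact TSV so that
users can follow future phylogenetic revisions without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LINEAGES",
    "BINARY_GROUPS",
    "LineageScheme",
    "default_scheme",
    "load_scheme",
    "assign_lineage",
    "assign_binary_group",
    "rekey_records",
]

LINEAGES = (
    "PLANT_ALGAE",
    "EARLY_METAZOAN",
    "EARLY_EUMETAZOAN",
    "DEUTEROSTOME",
    "NON_DEUTEROSTOME",
)
BINARY_GROUPS = (
    "DEUTEROSTOME_INCL_ANCESTRAL",
    "NON_DEUTEROSTOME",
    "NOT_APPLICABLE",
)


@dataclass(frozen=True)
class LineageScheme:
    """Phylum -> lineage and phylum -> binary group lookup tables."""

    lineage: Mapping[str, str]
    binary_group: Mapping[str, str]

    def __post_init__(self) -> None:
        for phylum, lin in self.lineage.items():
            if lin not in LINEAGES:
                raise ValueError(f"unknown lineage {lin!r} for phylum {phylum!r}")
        for phylum, grp in self.binary_group.items():
            if grp not in BINARY_GROUPS:
                raise ValueError(f"unknown binary group {grp!r} for phylum {phylum!r}")
        if set(self.lineage) != set(self.binary_group):
            raise ValueError("lineage and binary_group must cover the same phyla")

    @property
    def phyla(self) -> tuple[str, ...]:
        return tuple(self.lineage)


def _scheme_from_frame(df: pd.DataFrame) -> LineageScheme:
    required = {"phylum", "lineage", "binary_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lineage scheme missing columns: {sorted(missing)}")
    return LineageScheme(
        lineage=dict(zip(df["phylum"], df["lineage"])),
        binary_group=dict(zip(df["phylum"], df["binary_group"])),
    )


def default_scheme() -> LineageScheme:
    """The packaged default scheme over the 13 analysed phyla."""
    ref = resources.files("phyloscreen").joinpath("data/lineage_scheme.tsv")
    with resources.as_file(ref) as path:
        return load_scheme(path)


def load_scheme(path: str | Path) -> LineageScheme:
    """Load a scheme from a tab-delimited table (phylum, lineage, binary_group)."""
    return _scheme_from_frame(pd.read_csv(path, sep="\t", dtype=str))


def assign_lineage(phylum: str, scheme: LineageScheme | None = None) -> str:
    """Lineage class of ``phylum``; raises KeyError for unknown phyla."""
    scheme = scheme or default_scheme()
    try:
        return scheme.lineage[phylum]
    except KeyError:
        raise KeyError(
            f"phylum {phylum!r} is not in the lineage scheme "
            f"(known: {sorted(scheme.lineage)})"
        ) from None


def assign_binary_group(phylum: str, scheme: LineageScheme | None = None) -> str:
    """Binary deuterostome-vs-non-deuterostome group of ``phylum``."""
    scheme = scheme or default_scheme()
    try:
        return scheme.binary_group[phylum]
    except KeyError:
        raise KeyError(
            f"phylum {phylum!r} is not in the lineage scheme "
            f"(known: {sorted(scheme.binary_group)})"
        ) from None


def rekey_records(
    records: pd.DataFrame, level: str = "phylum"
) -> tuple[pd.DataFrame, dict]:
    """Populate the ``taxon`` key column at phylum or genus aggregation.

    At GENUS level, records with a missing genus cannot be attributed and
    are excluded; each exclusion is warned about and counted in the
    returned report, never dropped silently.

    Returns the re-keyed table (a copy) and a report dict with
    ``n_in``, ``n_kept`` and ``n_dropped_missing_genus``.
    """
    level = level.lower()
    if level not in ("phylum", "genus"):
        raise ValueError(f"level must be 'phylum' or 'genus', got {level!r}")
    out = records.copy()
    report = {"level": level, "n_in": len(out), "n_dropped_missing_genus": 0}
    if level == "phylum":
        out["taxon"] = out["phylum"]
    else:
        if "genus" not in out.columns:
            raise ValueError("GENUS aggregation requires a 'genus' column")
        missing = out["genus"].isna() | (out["genus"].astype(str).str.strip() == "")
        n_missing = int(missing.sum())
        if n_missing:
            warnings.warn(
                f"excluding {n_missing} record(s) with missing genus from "
                "genus-level aggregation",
                stacklevel=2,
            )
            out = out.loc[~missing].copy()
        report["n_dropped_missing_genus"] = n_missing
        out["taxon"] = out["genus"]
    report["n_kept"] = len(out)
    return out, report


def lineage_of_taxa(
    taxa: Iterable[str],
    scheme: LineageScheme | None = None,
    phylum_of: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map taxon labels (phyla, or genera via ``phylum_of``) to lineages."""
    scheme = scheme or default_scheme()
    out = {}
    for t in taxa:
        phylum = phylum_of.get(t, t) if phylum_of else t
        out[t] = assign_lineage(phylum, scheme)
    return out
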