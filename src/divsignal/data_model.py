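"""Community data containers: occurrence matrices, site metadata, family tables.

The raw input of every analysis is a binary site × species incidence matrix
together with a species → family taxonomy, per-site environmental metadata
(projected coordinates, elevation, habitat cover proportions) and an optional
per-species trait table.  Families are the unit of analysis; this module
filters them by occupancy and richness and aggregates species-level traits to
family-level means, standard errors and incidences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceMatrix",
    "SiteMetadata",
    "read_occurrence",
    "filter_families",
    "aggregate_family_traits",
    "higher_level_features",
]


@dataclass
class OccurrenceMatrix:
    """Binary site × species incidence with a species → family taxonomy.

    ``incidence`` is a DataFrame with sites as rows and species as columns,
    entries in {0, 1}.  Every species maps to exactly one family.
    """

    incidence: pd.DataFrame
    taxonomy: pd.Series  # index: species, values: family

    def __post_init__(self) -> None:
        inc = self.incidence
        if inc.index.duplicated().any():
            raise ValueError("duplicated site identifiers")
        if inc.columns.duplicated().any():
            raise ValueError("duplicated species identifiers")
        vals = inc.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("incidence entries must be 0/1 (use read_occurrence to coerce)")
        missing = [sp for sp in inc.columns if sp not in self.taxonomy.index]
        if missing:
            raise ValueError(f"species lacking taxonomy: {missing}")
        self.taxonomy = self.taxonomy.loc[inc.columns]

    @property
    def sites(self) -> list:
        return list(self.incidence.index)

    @property
    def species(self) -> list:
        return list(self.incidence.columns)

    @property
    def families(self) -> list:
        return sorted(self.taxonomy.unique())

    def family_species(self, family: str) -> list:
        return list(self.taxonomy.index[self.taxonomy == family])

    def family_submatrix(self, family: str) -> pd.DataFrame:
        return self.incidence[self.family_species(family)]

    def family_occupancy_vector(self, family: str) -> pd.Series:
        """Binary per-site presence of the family (OR over member species)."""
        return (self.family_submatrix(family).sum(axis=1) > 0).astype(int)


@dataclass
class SiteMetadata:
    """Per-site coordinates (consistent projected units), elevation (m) and
    habitat cover proportions (columns ``habitat_*``)."""

    table: pd.DataFrame
    habitat_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("x", "y", "elevation"):
            if col not in t.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if not np.isfinite(t[["x", "y", "elevation"]].to_numpy()).all():
            raise ValueError("non-finite coordinates or elevation")
        if not self.habitat_columns:
            self.habitat_columns = [c for c in t.columns if c.startswith("habitat_")]
        hv = t[self.habitat_columns].to_numpy(dtype=float)
        if hv.size and ((hv < 0) | (hv > 1)).any():
            raise ValueError("habitat cover proportions must lie in [0, 1]")

    @property
    def sites(self) -> list:
        return list(self.table.index)

    def subset(self, sites) -> "SiteMetadata":
        return SiteMetadata(self.table.loc[list(sites)], self.habitat_columns)


def read_occurrence(
    matrix_path: str,
    taxonomy_path: str,
    metadata_path: str,
    sep: str = ",",
    transpose: bool = False,
) -> tuple[OccurrenceMatrix, SiteMetadata]:
    """Load and validate an occurrence matrix, taxonomy and site metadata.

    The matrix file has sites in rows (first column = site id) unless
    ``transpose`` is set.  Nonzero abundances are coerced to presence (1)
    with a logged warning; sites must align between matrix and metadata.
    """
    inc = pd.read_csv(matrix_path, sep=sep, index_col=0)
    if transpose:
        inc = inc.T
    vals = inc.to_numpy(dtype=float)
    nonbinary = (vals != 0) & (vals != 1)
    if nonbinary.any():
        logger.warning(
            "coerced %d non-binary abundance cells to presence", int(nonbinary.sum())
        )
        warnings.warn("non-binary cells coerced to presence", stacklevel=2)
    inc = pd.DataFrame(
        (vals != 0).astype(int), index=inc.index, columns=inc.columns
    )

    tax = pd.read_csv(taxonomy_path, sep=sep)
    tax = pd.Series(tax.iloc[:, 1].values, index=tax.iloc[:, 0].values, name="family")
    missing_tax = [sp for sp in inc.columns if sp not in tax.index]
    if missing_tax:
        raise ValueError(f"species lacking taxonomy: {missing_tax}")

    meta_t = pd.read_csv(metadata_path, sep=sep, index_col=0)
    missing_sites = [s for s in inc.index if s not in meta_t.index]
    if missing_sites:
        raise ValueError(f"sites missing from metadata: {missing_sites}")
    meta = SiteMetadata(meta_t.loc[inc.index])
    return OccurrenceMatrix(inc, tax), meta


def filter_families(
    occ: OccurrenceMatrix, min_plots: int = 50, min_species: int = 5
) -> tuple[list[str], pd.DataFrame]:
    """Retain families occupying ≥ ``min_plots`` sites with ≥ ``min_species``
    species (both thresholds inclusive).

    Returns the retained family list plus a flags table for *all* families
    (needed downstream by the widespread-vs-rare representativeness test).
    """
    if occ.incidence.size == 0:
        raise ValueError("empty occurrence matrix")
    rows = []
    for fam in occ.families:
        occ_vec = occ.family_occupancy_vector(fam)
        n_sp = len(occ.family_species(fam))
        n_plots = int(occ_vec.sum())
        rows.append(
            dict(
                family=fam,
                n_species=n_sp,
                occupancy=n_plots,
                retained=(n_plots >= min_plots) and (n_sp >= min_species),
            )
        )
    flags = pd.DataFrame(rows).set_index("family")
    retained = list(flags.index[flags["retained"]])
    return retained, flags


def aggregate_family_traits(
    species_traits: pd.DataFrame,
    taxonomy: pd.Series,
    families: list[str],
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    log_columns: tuple[str, ...] = ("body_size",),
    log_base: float = np.e,
) -> pd.DataFrame:
    """Aggregate species traits to family means/SEs and incidences.

    Continuous traits yield the mean and standard error over member species
    (columns named log before averaging, body size by default); binary
    features yield the incidence, the fraction of member species showing the
    feature.  Single-species families get SE = 0 with a warning.
    """
    traits = species_traits.copy()
    for col in log_columns:
        if col in traits.columns:
            traits[col] = np.log(traits[col].astype(float)) / np.log(log_base)
    if continuous is None:
        continuous = [
            c
            for c in traits.columns
            if traits[c].dtype.kind == "f"
            or (traits[c].dtype.kind in "iu" and traits[c].nunique() > 2)
        ]
    if binary is None:
        binary = [c for c in traits.columns if c not in continuous]
    rows = {}
    for fam in families:
        members = [sp for sp in taxonomy.index[taxonomy == fam] if sp in traits.index]
        if not members:
            raise ValueError(f"no trait data for family {fam!r}")
        sub = traits.loc[members]
        row = {}
        for c in continuous:
            x = sub[c].astype(float).dropna()
            row[f"{c}_mean"] = x.mean()
            if len(x) < 2:
                warnings.warn(
                    f"family {fam!r} has a single species; SE of {c!r} set to 0",
                    stacklevel=2,
                )
                row[f"{c}_se"] = 0.0
            else:
                row[f"{c}_se"] = x.std(ddof=1) / np.sqrt(len(x))
        for c in binary:
            x = sub[c].astype(float).dropna()
            row[f"{c}_incidence"] = float(x.mean())
        rows[fam] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def higher_level_features(occ: OccurrenceMatrix, retained: list[str]) -> pd.DataFrame:
    """Per-family regional richness, plot occupancy and the widespread flag.

    Richness counts member species; occupancy counts sites where at least one
    member occurs; ``widespread`` records whether the family passed the
    filter (the binary trait tested for phylogenetic clustering).
    """
    rows = []
    for fam in occ.families:
        rows.append(
            dict(
                family=fam,
                richness=len(occ.family_species(fam)),
                occupancy=int(occ.family_occupancy_vector(fam).sum()),
                widespread=int(fam in retained),
            )
        )
    return pd.DataFrame(rows).set_index("family")
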