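"""Domain types, table readers/writers, validation and dataset assembly.

A dataset is three rectangular CSV tables:

* **traits** — one row per measured individual, with its species and
  community labels plus one column per functional trait (mixed units;
  missing cells are empty).
* **composition** — long-format plot x species canopy cover from
  line-intercept transects (metres of canopy projecting on the transect;
  totals may exceed the transect length because of overlapping layers).
* **environment** — one row per plot of abiotic descriptors (altitude,
  orientation, slope, soil depth, soil chemistry).

All tables are plain CSV with a header row, UTF-8, "." decimal separator
and empty cells for missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CrossReferenceError,
    DegenerateCommunityError,
    DegeneratePlotError,
    IntegrityError,
    SchemaError,
)

#: The nine functional traits of the motivating study, with their units.
DEFAULT_TRAITS: dict[str, str] = {
    "LDMC": "mg g-1",        # leaf dry matter content
    "SLA": "m2 kg-1",        # specific leaf area
    "leaf_CN": "unitless",   # leaf carbon:nitrogen ratio
    "d13C": "permil",        # leaf carbon isotope composition
    "SDMC": "mg g-1",        # stem dry matter content
    "Hv": "cm2 cm-2",        # Huber value (sapwood area : leaf area)
    "SRA": "m2 kg-1",        # specific root area
    "Rdi": "mm",             # mean fine-root diameter
    "root_CN": "unitless",   # root carbon:nitrogen ratio
}

#: Abiotic plot descriptors used as candidate drivers.
DEFAULT_ABIOTIC: tuple[str, ...] = (
    "altitude",
    "orientation",
    "slope",
    "soil_depth",
    "soil_nitrate",
    "soil_phosphate",
    "total_soil_N",
    "SOM",
)

_TRAIT_ID_COLS = ("individual_id", "species_id", "community_id")
_COMP_COLS = ("plot_id", "community_id", "species_id", "cover")


def northness(aspect_degrees) -> np.ndarray | float:
    """Encode a circular aspect (degrees clockwise from north) as a single
    linear predictor, ``cos(aspect * pi / 180)``: +1 due north, -1 due south.

    Orientation enters the driver models as one continuous term, so a
    circular quantity has to be mapped to a line first; northness is the
    standard choice in terrain analysis.
    """
    return np.cos(np.asarray(aspect_degrees, dtype=float) * math.pi / 180.0)


@dataclass
class TraitMatrix:
    """Individual-level trait records.

    ``data`` holds one row per individual with ``individual_id``,
    ``species_id``, ``community_id`` and one column per trait in
    ``traits``.  Missing measurements are ``NaN``.  ``regional_traits``
    names traits measured at regional rather than community level (their
    within-community variation is not meaningful).
    """

    data: pd.DataFrame
    traits: list[str]
    regional_traits: set[str] = field(default_factory=lambda: {"Hv"})

    def __post_init__(self) -> None:
        missing = [c for c in (*_TRAIT_ID_COLS, *self.traits) if c not in self.data.columns]
        if missing:
            raise SchemaError("traits", missing)
        dup = self.data["individual_id"][self.data["individual_id"].duplicated()]
        if len(dup):
            offenders = sorted(map(str, dup.unique()))
            raise IntegrityError(
                f"duplicate individual_id value(s): {', '.join(offenders)}", offenders
            )
        vals = self.data[self.traits].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise IntegrityError("non-finite trait values present (use empty cells for missing)")
        self.regional_traits = {t for t in self.regional_traits if t in self.traits}

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    def species_in_community(self, community_id: str) -> set[str]:
        sub = self.data[self.data["community_id"] == community_id]
        return set(sub["species_id"].unique())


@dataclass
class CommunityComposition:
    """Plot-level species canopy cover (long format) and, once
    :func:`relative_abundance` has run, per-plot relative abundances."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COMP_COLS if c not in self.data.columns]
        if missing:
            raise SchemaError("composition", missing)
        cov = self.data["cover"].to_numpy(dtype=float)
        if not np.isfinite(cov).all() or (cov < 0).any():
            raise IntegrityError("cover values must be finite and >= 0")
        # each plot maps to exactly one community
        n_comm = self.data.groupby("plot_id")["community_id"].nunique()
        bad = n_comm[n_comm > 1]
        if len(bad):
            raise IntegrityError(
                f"plot(s) mapped to more than one community: {', '.join(map(str, bad.index))}",
                list(map(str, bad.index)),
            )
        dup = self.data.duplicated(subset=["plot_id", "species_id"])
        if dup.any():
            raise IntegrityError("duplicate (plot_id, species_id) cover rows")

    @property
    def plots(self) -> list[str]:
        return list(pd.unique(self.data["plot_id"]))

    @property
    def communities(self) -> list[str]:
        return list(pd.unique(self.data["community_id"]))

    def community_of(self, plot_id: str) -> str:
        sub = self.data.loc[self.data["plot_id"] == plot_id, "community_id"]
        if sub.empty:
            raise KeyError(plot_id)
        return sub.iloc[0]

    def plot_abundances(self, plot_id: str) -> pd.Series:
        """Relative abundances of species with positive cover in a plot."""
        if "relative_abundance" not in self.data.columns:
            raise IntegrityError("relative abundances not computed; call relative_abundance()")
        sub = self.data[(self.data["plot_id"] == plot_id) & (self.data["cover"] > 0)]
        if sub.empty:
            raise DegeneratePlotError(str(plot_id))
        return sub.set_index("species_id")["relative_abundance"]


@dataclass
class EnvironmentTable:
    """One row of abiotic descriptors per plot."""

    data: pd.DataFrame
    abiotic: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in ("plot_id", *self.abiotic) if c not in self.data.columns]
        if missing:
            raise SchemaError("environment", missing)
        dup = self.data["plot_id"][self.data["plot_id"].duplicated()]
        if len(dup):
            raise IntegrityError(
                f"duplicate plot_id in environment table: {', '.join(map(str, dup.unique()))}"
            )
        vals = self.data[self.abiotic].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise IntegrityError("environment table contains non-finite values")


@dataclass
class Dataset:
    """Validated bundle of the three tables plus cross-reference report."""

    traits: TraitMatrix
    composition: CommunityComposition
    environment: EnvironmentTable
    #: per community: species with cover somewhere in the community but no
    #: trait records there (typically sub-dominant species below the
    #: cumulative-cover measurement threshold)
    unmeasured_species: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comp_plots = set(map(str, self.composition.data["plot_id"]))
        env_plots = set(map(str, self.environment.data["plot_id"]))
        orphans = sorted(comp_plots - env_plots)
        if orphans:
            raise CrossReferenceError(
                f"plot(s) in composition but absent from environment: {', '.join(orphans)}"
            )
        report: dict[str, list[str]] = {}
        for community in self.composition.communities:
            sub = self.composition.data[
                (self.composition.data["community_id"] == community)
                & (self.composition.data["cover"] > 0)
            ]
            if sub.empty:
                raise DegenerateCommunityError(
                    f"community {community!r} has no species with positive cover"
                )
            present = set(sub["species_id"].unique())
            measured = self.traits.species_in_community(community)
            missing = sorted(map(str, present - measured))
            if missing:
                report[str(community)] = missing
        self.unmeasured_species = report


def _read_csv(path: str | Path, table: str, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(table, missing)
    return df


def load_dataset(
    trait_path: str | Path,
    composition_path: str | Path,
    environment_path: str | Path,
    trait_columns: list[str] | None = None,
    abiotic_columns: list[str] | None = None,
    regional_traits: set[str] | None = None,
) -> Dataset:
    """Read and cross-validate the three CSV tables into a :class:`Dataset`.

    Trait and abiotic columns default to every non-identifier column of the
    respective table, so standard files need no configuration.  Relative
    abundances are computed on load.
    """
    tdf = _read_csv(trait_path, "traits", _TRAIT_ID_COLS)
    if trait_columns is None:
        trait_columns = [c for c in tdf.columns if c not in _TRAIT_ID_COLS]
    cdf = _read_csv(composition_path, "composition", _COMP_COLS)
    edf = _read_csv(environment_path, "environment", ("plot_id",))
    if abiotic_columns is None:
        abiotic_columns = [c for c in edf.columns if c != "plot_id"]

    traits = TraitMatrix(tdf, trait_columns, regional_traits or {"Hv"})
    composition = relative_abundance(CommunityComposition(cdf))
    environment = EnvironmentTable(edf, abiotic_columns)
    return Dataset(traits, composition, environment)


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write the three tables back to CSV; inverse of :func:`load_dataset`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": outdir / "traits.csv",
        "composition": outdir / "composition.csv",
        "environment": outdir / "environment.csv",
    }
    dataset.traits.data.to_csv(paths["traits"], index=False)
    comp = dataset.composition.data.drop(columns=["relative_abundance"], errors="ignore")
    comp.to_csv(paths["composition"], index=False)
    dataset.environment.data.to_csv(paths["environment"], index=False)
    return paths


def relative_abundance(composition: CommunityComposition) -> CommunityComposition:
    """Fill ``relative_abundance = cover / plot total cover``.

    Normalisation is by the plot's own summed cover, regardless of transect
    length: overlapping vegetation layers can push raw totals above the
    transect length, and the weights used downstream must sum to one.
    """
    df = composition.data.copy()
    totals = df.groupby("plot_id")["cover"].transform("sum")
    zero = totals <= 0
    if zero.any():
        plot = str(df.loc[zero, "plot_id"].iloc[0])
        raise DegeneratePlotError(plot)
    df["relative_abundance"] = df["cover"] / totals
    return CommunityComposition(df)


def select_dominant_species(
    composition: CommunityComposition,
    community_id: str,
    threshold: float = 0.90,
) -> list[str]:
    """Species that together reach ``threshold`` of a community's summed cover.

    Species are ranked by total cover across the community's plots
    (descending, ties broken by species id) and the shortest prefix whose
    cumulative cover share is at least ``threshold`` is returned.  This is
    the standard dominant-species rule deciding which species get measured
    for traits.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    sub = composition.data[
        (composition.data["community_id"] == community_id) & (composition.data["cover"] > 0)
    ]
    if sub.empty:
        raise DegenerateCommunityError(
            f"community {community_id!r} has no species with positive cover"
        )
    totals = sub.groupby("species_id")["cover"].sum()
    order = totals.sort_index().sort_values(ascending=False, kind="stable")
    shares = order.cumsum() / order.sum()
    # shortest prefix with cumulative share >= threshold
    n_keep = int(np.searchsorted(shares.to_numpy(), threshold - 1e-12) + 1)
    return list(order.index[:n_keep])
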