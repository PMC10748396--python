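"""Exception hierarchy for dataset validation and analysis failures.

Every error carries enough context (column, identifier, plot, ...) to point
a user at the offending row of their input tables.
"""

from __future__ import annotations


class TraitMomentsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TraitMomentsError):
    """A required column is missing or a table header is malformed."""

    def __init__(self, table: str, missing: list[str]):
        self.table = table
        self.missing = list(missing)
        super().__init__(
            f"table {table!r} is missing required column(s): {', '.join(self.missing)}"
        )


class IntegrityError(TraitMomentsError):
    """Within-table invariant violated (e.g. duplicate individual ids)."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        self.offenders = list(offenders or [])
        super().__init__(message)


class CrossReferenceError(TraitMomentsError):
    """A label in one table has no counterpart in another."""


class DegeneratePlotError(TraitMomentsError):
    """A plot has zero total cover, so relative abundances are undefined."""

    def __init__(self, plot_id: str):
        self.plot_id = plot_id
        super().__init__(f"plot {plot_id!r} has zero total cover")


class DegenerateCommunityError(TraitMomentsError):
    """A community has no species with positive cover."""


class DegenerateTraitError(TraitMomentsError):
    """A trait column is constant, so it cannot be standardized."""

    def __init__(self, trait: str):
        self.trait = trait
        super().__init__(f"trait {trait!r} is constant and cannot be standardized")


class UnmeasurableSpeciesError(TraitMomentsError):
    """A trait is missing for an entire species with no fill source."""


class RankError(TraitMomentsError):
    """Input matrix has too few positive eigenvalues for the requested axes."""


class ValidationError(TraitMomentsError):
    """Invalid argument values (negative weights, unknown options, ...)."""


class MissingTraitDataError(TraitMomentsError):
    """A species has cover in a plot but no trait-scored individuals."""

    def __init__(self, species_id: str, plot_id: str):
        self.species_id = species_id
        self.plot_id = plot_id
        super().__init__(
            f"species {species_id!r} has cover in plot {plot_id!r} but no "
            f"scored individuals in that plot's community"
        )


class InsufficientReplicationError(TraitMomentsError):
    """Fewer than two defined plot-level values in a community."""


class CollinearityError(TraitMomentsError):
    """Rank-deficient design matrix."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(f"design is rank deficient; aliased term(s): {', '.join(self.aliased)}")


class OverparameterizedModelError(TraitMomentsError):
    """AICc undefined: sample size too small for the parameter count."""


class MissingSpeciesError(TraitMomentsError):
    """A species with cover was never trait-scored anywhere."""


class RegionalTraitError(TraitMomentsError):
    """Decomposition refused: the axis is dominated by a trait measured at
    regional (not community) level, so community-specific species means are
    not meaningful for it."""


class ConfigError(TraitMomentsError):
    """Invalid run configuration."""
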