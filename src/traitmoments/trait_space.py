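"""Trait-syndrome axes: standardization and principal component analysis.

Plants do not vary trait by trait but along coordinated syndromes (an
acquisitive-to-conservative leaf economics spectrum, a root economics
spectrum, a hydraulic-architecture axis ...).  This module builds those
axes from individual-level trait data: traits are z-scored (they carry
incommensurate units, so the PCA is on the correlation matrix), axes are
the eigenvectors of the trait correlation structure, axes with eigenvalue
greater than one are retained (Kaiser criterion — only meaningful on a
correlation matrix, where each trait contributes unit variance), and every
individual is scored by projection onto the retained axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateTraitError, RankError, UnmeasurableSpeciesError
from .io import TraitMatrix

#: eigenvalues closer to 1 than this are treated as exactly 1 and excluded
KAISER_TIE_TOL = 1e-9


@dataclass
class ScoreTable:
    """PCA result: individual scores, loadings and axis bookkeeping.

    ``scores`` has one row per individual (index ``individual_id``) and one
    column per axis; ``meta`` carries the species/community labels in the
    same row order.  ``loadings`` are unit-norm eigenvectors (trait x axis);
    ``explained`` are variance fractions over *all* axes and sum to one.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame
    loadings: pd.DataFrame
    eigenvalues: pd.Series
    explained: pd.Series
    retained: list[str]
    regional_traits: set[str] = field(default_factory=set)

    @property
    def axes(self) -> list[str]:
        return list(self.scores.columns)

    def dominant_trait(self, axis: str) -> str:
        """Trait with the largest-magnitude loading on ``axis``."""
        return self.loadings[axis].abs().idxmax()

    def scores_long(self, axes: list[str] | None = None) -> pd.DataFrame:
        """Scores joined with species/community labels, long format."""
        axes = axes or self.retained
        wide = pd.concat([self.meta, self.scores[axes]], axis=1)
        return wide.melt(
            id_vars=list(self.meta.columns),
            value_vars=axes,
            var_name="axis",
            value_name="score",
            ignore_index=False,
        )


def standardize_traits(
    traits: TraitMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cells from species-level means, then z-score each trait.

    Traits measured at a coarser grain than the individual (e.g. the Huber
    value, measured regionally on a few individuals per species) leave gaps
    in the individual x trait matrix; those gaps are filled with the
    species-level mean over all measured individuals of that species, which
    is the finest complete information available.  Each column is then
    centred to mean 0 and scaled to standard deviation 1 (n-1 denominator).

    Returns the standardized matrix (index ``individual_id``) and a fill
    report with one row per filled cell.
    """
    df = traits.data.set_index("individual_id")
    X = df[traits.traits].astype(float).copy()
    if len(X) < 2:
        raise ValueError("standardization needs at least two individuals")

    fills = []
    species = df["species_id"]
    for trait in traits.traits:
        col = X[trait]
        if col.isna().any():
            sp_means = col.groupby(species).transform("mean")
            missing = col.isna()
            unfillable = missing & sp_means.isna()
            if unfillable.any():
                bad = sorted(species[unfillable].unique().astype(str))
                raise UnmeasurableSpeciesError(
                    f"trait {trait!r} unmeasured for entire species: {', '.join(bad)}"
                )
            for ind in col.index[missing]:
                fills.append(
                    {
                        "individual_id": ind,
                        "species_id": species.loc[ind],
                        "trait": trait,
                        "filled_value": sp_means.loc[ind],
                    }
                )
            X.loc[missing, trait] = sp_means[missing]

    sd = X.std(ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise DegenerateTraitError(str(constant.index[0]))
    Z = (X - X.mean()) / sd
    report = pd.DataFrame(fills, columns=["individual_id", "species_id", "trait", "filled_value"])
    return Z, report


def fit_trait_pca(
    standardized: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    axis_names: dict[int, str] | None = None,
    pin_positive: dict[str, str] | None = None,
    n_axes: int | None = None,
    regional_traits: set[str] | None = None,
) -> ScoreTable:
    """Eigendecompose the trait correlation structure and score individuals.

    Parameters
    ----------
    standardized
        z-scored individual x trait matrix from :func:`standardize_traits`.
    meta
        optional per-individual labels (species_id, community_id) aligned
        with ``standardized``.
    axis_names
        optional renaming of axes by 1-based rank, e.g. ``{1: "LES",
        2: "RES", 3: "HyArq"}`` to label the leaf-economics, root-economics
        and hydraulic-architecture syndromes.
    pin_positive
        per axis (by final name), a trait whose loading is forced positive,
        e.g. ``{"LES": "SLA"}`` so acquisitive leaves score high.  Axes not
        pinned are oriented so their largest-magnitude loading is positive.
    n_axes
        if given, require at least this many numerically positive
        eigenvalues (raises :class:`RankError` otherwise).
    """
    traits = list(standardized.columns)
    n, p = standardized.shape
    if n <= p:
        raise ValueError(f"need more individuals ({n}) than traits ({p})")
    Z = standardized.to_numpy(dtype=float)

    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    n_pos = int(np.sum(evals > 1e-10))
    if n_axes is not None and n_pos < n_axes:
        raise RankError(
            f"only {n_pos} positive eigenvalues available, {n_axes} axes requested"
        )

    labels = []
    for k in range(p):
        name = (axis_names or {}).get(k + 1, f"PC{k + 1}")
        labels.append(name)

    pin_positive = pin_positive or {}
    for k, name in enumerate(labels):
        v = evecs[:, k]
        pin = pin_positive.get(name)
        if pin is not None:
            if pin not in traits:
                raise ValueError(f"pinned trait {pin!r} not in trait set")
            ref = v[traits.index(pin)]
        else:
            ref = v[int(np.argmax(np.abs(v)))]
        if ref < 0:
            evecs[:, k] = -v

    scores = Z @ evecs
    loadings = pd.DataFrame(evecs, index=traits, columns=labels)
    eigenvalues = pd.Series(evals, index=labels, name="eigenvalue")
    explained = pd.Series(evals / p, index=labels, name="explained_fraction")
    retained = [lab for lab, ev in eigenvalues.items() if ev > 1 + KAISER_TIE_TOL]

    score_df = pd.DataFrame(scores, index=standardized.index, columns=labels)
    if meta is None:
        meta = pd.DataFrame(index=standardized.index)
    else:
        meta = meta.loc[standardized.index]
    return ScoreTable(
        scores=score_df,
        meta=meta,
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained=explained,
        retained=retained,
        regional_traits=set(regional_traits or ()),
    )


def build_trait_space(
    traits: TraitMatrix,
    axis_names: dict[int, str] | None = None,
    pin_positive: dict[str, str] | None = None,
) -> tuple[ScoreTable, pd.DataFrame]:
    """Convenience wrapper: standardize, fit PCA, keep labels attached."""
    Z, fill_report = standardize_traits(traits)
    meta = traits.data.set_index("individual_id")[["species_id", "community_id"]]
    table = fit_trait_pca(
        Z,
        meta=meta,
        axis_names=axis_names,
        pin_positive=pin_positive,
        regional_traits=traits.regional_traits,
    )
    return table, fill_report
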