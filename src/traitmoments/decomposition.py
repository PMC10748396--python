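"""Species-turnover vs intraspecific-variability decomposition of CWM.

A plot's community-weighted mean can change along an environmental
gradient for two reasons: the species present (or their abundances) change
— *species turnover* — or the species themselves shift their trait values
— *intraspecific trait variability* (ITV).  The specific/fixed-average
construction separates the two:

* **specific CWM** — plot abundances weighting *community-specific*
  species mean scores (species measured in that plot's community);
* **fixed CWM** — the same abundances weighting species means *pooled
  across all communities*, so only turnover can move it;
* **ITV** — their difference, plot by plot, so by construction
  ``specific = fixed + ITV`` exactly.

The same linear model (community factor, or the abiotic predictors
selected by AICc) is fitted to all three series.  Because the per-plot
identity is linear and the design identical, fitted values and residuals
add too, and within each stratum (explained, residual, total) the sums of
squares satisfy

``SS_specific = SS_fixed + SS_itv + 2*cross``

The turnover component is the fixed-series SS, the ITV component the
ITV-series SS, and the covariation component is defined as the remainder
``SS_specific - SS_turnover - SS_itv`` (twice the cross term; it is
negative when plots where turnover raises the CWM are plots where species'
own shifts lower it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drivers import ModelFit, fit_ols
from .errors import MissingSpeciesError, RegionalTraitError, ValidationError
from .io import CommunityComposition
from .trait_space import ScoreTable

STRATA = ("explained", "residual", "total")
COMPONENTS = ("turnover", "itv", "covariation", "total_specific")


@dataclass
class CwmSeries:
    """Per-plot specific / fixed / ITV community-weighted means of one axis."""

    axis: str
    data: pd.DataFrame  # index plot_id; community_id, specific, fixed, itv

    def __post_init__(self) -> None:
        resid = self.data["specific"] - self.data["fixed"] - self.data["itv"]
        if np.abs(resid.to_numpy()).max() > 1e-10:
            raise ValidationError("specific = fixed + itv identity violated")


@dataclass
class DecompositionResult:
    """Sums of squares and shares per stratum for one axis and predictor set."""

    axis: str
    predictor_set: str
    #: index (stratum, component) -> SS; components: turnover, itv,
    #: covariation, total_specific
    ss: pd.DataFrame
    #: same shape, as % of the stratum's specific SS
    pct_of_stratum: pd.DataFrame
    #: same shape, as % of the total-stratum specific SS
    pct_of_total: pd.DataFrame
    fits: dict[str, ModelFit]

    def table(self) -> pd.DataFrame:
        """Long-format table: one row per stratum x component."""
        rows = []
        for stratum in STRATA:
            for comp in COMPONENTS:
                rows.append(
                    {
                        "axis": self.axis,
                        "predictor_set": self.predictor_set,
                        "stratum": stratum,
                        "component": comp,
                        "ss": self.ss.loc[stratum, comp],
                        "pct_of_stratum": self.pct_of_stratum.loc[stratum, comp],
                        "pct_of_total": self.pct_of_total.loc[stratum, comp],
                    }
                )
        return pd.DataFrame(rows)


def check_axis_decomposable(scores: ScoreTable, axis: str) -> None:
    """Refuse decomposition of an axis dominated by a regionally measured trait.

    If the trait with the largest-magnitude loading on the axis was
    measured at regional level (e.g. the Huber value), species means do not
    vary between communities by measurement design, so an ITV component on
    that axis would be an artifact of data structure, not biology.
    """
    dom = scores.dominant_trait(axis)
    if dom in scores.regional_traits:
        raise RegionalTraitError(
            f"axis {axis!r} is dominated by trait {dom!r}, which was measured at "
            f"regional level; community-specific species means are not available, "
            f"so the turnover/ITV decomposition is not meaningful for this axis"
        )


def build_cwm_series(
    scores: ScoreTable,
    composition: CommunityComposition,
    axis: str,
    check_regional: bool = True,
) -> CwmSeries:
    """Specific, fixed and ITV community-weighted means for every plot.

    Specific uses species x community mean scores; fixed uses species means
    pooled over all individuals across communities.  Abundance weights
    always come from the focal plot.
    """
    if check_regional:
        check_axis_decomposable(scores, axis)
    vals = scores.scores[axis]
    meta = scores.meta
    by_sp_comm = vals.groupby(
        [meta["species_id"], meta["community_id"]]
    ).mean()
    by_sp = vals.groupby(meta["species_id"]).mean()

    rows = {}
    for plot in composition.plots:
        community = composition.community_of(plot)
        p = composition.plot_abundances(plot)
        specific = fixed = 0.0
        for species, p_s in p.items():
            if species not in by_sp.index:
                raise MissingSpeciesError(
                    f"species {species!r} has cover but was never trait-scored"
                )
            key = (species, community)
            if key not in by_sp_comm.index:
                raise MissingSpeciesError(
                    f"species {species!r} has cover in plot {plot!r} but no scored "
                    f"individuals in community {community!r}"
                )
            specific += p_s * by_sp_comm.loc[key]
            fixed += p_s * by_sp.loc[species]
        rows[plot] = {
            "community_id": community,
            "specific": specific,
            "fixed": fixed,
            "itv": specific - fixed,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "plot_id"
    return CwmSeries(axis=axis, data=df)


def _ss_strata(fit: ModelFit) -> dict[str, float]:
    return {
        "explained": fit.tss - fit.rss,
        "residual": fit.rss,
        "total": fit.tss,
    }


def decompose(
    series: CwmSeries,
    predictors: pd.DataFrame | None = None,
    terms: list[str] | None = None,
    factor: str | None = None,
    predictor_set: str = "community",
) -> DecompositionResult:
    """Partition CWM variation into turnover, ITV and covariation.

    By default the predictor is the community factor; pass a plot-indexed
    ``predictors`` table (aligned with the series) and ``terms``/``factor``
    for an abiotic-variable partition.  The same model formula is fitted to
    the specific, fixed and ITV series, and within each stratum the
    covariation component is ``SS_specific - SS_turnover - SS_itv``.
    """
    data = series.data
    if predictors is None:
        predictors = data[["community_id"]].rename(columns={"community_id": "community"})
        terms = ["community"]
        factor = "community"
    else:
        predictors = predictors.loc[data.index]
        if terms is None:
            terms = list(predictors.columns)

    fits = {
        name: fit_ols(
            data[name].to_numpy(),
            predictors,
            terms=terms,
            factor=factor,
            response=f"{series.axis}:{name}",
        )
        for name in ("specific", "fixed", "itv")
    }

    ss = pd.DataFrame(index=list(STRATA), columns=list(COMPONENTS), dtype=float)
    for stratum in STRATA:
        spec = _ss_strata(fits["specific"])[stratum]
        turn = _ss_strata(fits["fixed"])[stratum]
        itv = _ss_strata(fits["itv"])[stratum]
        ss.loc[stratum] = [turn, itv, spec - turn - itv, spec]

    total_spec = ss.loc["total", "total_specific"]
    pct_stratum = ss.div(ss["total_specific"], axis=0) * 100.0
    pct_total = ss / total_spec * 100.0 if total_spec > 0 else ss * float("nan")
    return DecompositionResult(
        axis=series.axis,
        predictor_set=predictor_set,
        ss=ss,
        pct_of_stratum=pct_stratum,
        pct_of_total=pct_total,
        fits=fits,
    )
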