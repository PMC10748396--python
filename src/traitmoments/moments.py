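"""Abundance-weighted moments of trait-axis score distributions.

The community-weighted mean (CWM) summarises the dominant strategy in a
plot; the community-weighted skewness (CWS) measures asymmetry of the
score distribution (rare strategies on one flank); the community-weighted
excess kurtosis (CWK) measures its evenness — negative for flat or bimodal
distributions (strategy coexistence), positive for a narrow concentration
of values, zero for a Gaussian.

Weights come from canopy cover: each individual of species *s* in a plot
with relative abundance :math:`p_s` and :math:`n_s` scored conspecifics in
the plot's community receives weight :math:`p_s / n_s`, so species
contribute in proportion to their cover and the moments reduce to the
species-level community-weighted moments when conspecific individuals are
identical.

Estimators are the population (weight-only) form with no small-sample bias
correction:

.. math::

    \\mathrm{CWM} = \\sum_i w_i x_i, \\qquad
    \\mathrm{CWV} = \\sum_i w_i (x_i - \\mathrm{CWM})^2,

.. math::

    \\mathrm{CWS} = \\frac{\\sum_i w_i (x_i - \\mathrm{CWM})^3}{\\mathrm{CWV}^{3/2}},
    \\qquad
    \\mathrm{CWK} = \\frac{\\sum_i w_i (x_i - \\mathrm{CWM})^4}{\\mathrm{CWV}^{2}} - 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingTraitDataError, ValidationError
from .io import CommunityComposition
from .trait_space import ScoreTable

#: order of the moment columns in long-format output
MOMENT_NAMES = ("CWM", "CWV", "CWS", "CWK")


@dataclass
class WeightedMoments:
    """The four weighted moments of one value/weight sample.

    ``cws``/``cwk`` are ``nan`` (flagged by ``degenerate``) when the
    weighted variance is zero, where standardized moments are undefined.
    ``n_effective`` is the inverse Simpson concentration of the weights,
    :math:`1/\\sum w_i^2` — the equivalent number of equally-weighted
    observations.
    """

    cwm: float
    cwv: float
    cws: float
    cwk: float
    n_effective: float

    @property
    def degenerate(self) -> bool:
        return self.cwv == 0.0

    def as_dict(self) -> dict[str, float]:
        return {"CWM": self.cwm, "CWV": self.cwv, "CWS": self.cws, "CWK": self.cwk}


def weighted_moments(values, weights) -> WeightedMoments:
    """Weighted mean, variance, skewness and excess kurtosis of a sample.

    ``weights`` must be nonnegative and sum to 1 (to 1e-9).  A zero-variance
    sample yields ``CWV = 0`` with skewness/kurtosis flagged undefined
    (``nan``) rather than raising.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1 or x.size < 1:
        raise ValidationError("values and weights must be equal-length 1-d arrays")
    if not np.isfinite(x).all():
        raise ValidationError("values must be finite")
    if (w < 0).any():
        raise ValidationError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")

    cwm = float(w @ x)
    d = x - cwm
    cwv = float(w @ d**2)
    if cwv == 0.0:
        return WeightedMoments(cwm, 0.0, float("nan"), float("nan"), float(1.0 / (w @ w)))
    cws = float(w @ d**3) / cwv**1.5
    cwk = float(w @ d**4) / cwv**2 - 3.0
    return WeightedMoments(cwm, cwv, cws, cwk, float(1.0 / (w @ w)))


def individual_weights(
    scores: ScoreTable,
    composition: CommunityComposition,
    plot_id: str,
    drop_unscored: bool = False,
) -> pd.Series:
    """Per-individual weights :math:`p_s/n_s` for one plot.

    Individuals are those scored in the plot's community for species with
    positive cover in the plot.  If a covered species has no scored
    individuals there, a :class:`MissingTraitDataError` is raised unless
    ``drop_unscored`` is set, in which case the species is dropped and the
    remaining weights renormalised.
    """
    community = composition.community_of(plot_id)
    p = composition.plot_abundances(plot_id)
    meta = scores.meta
    in_comm = meta[meta["community_id"] == community]
    counts = in_comm.groupby("species_id").size()

    weights: dict[str, float] = {}
    dropped: list[str] = []
    for species, p_s in p.items():
        n_s = int(counts.get(species, 0))
        if n_s == 0:
            if drop_unscored:
                dropped.append(str(species))
                continue
            raise MissingTraitDataError(str(species), str(plot_id))
        ids = in_comm.index[in_comm["species_id"] == species]
        for ind in ids:
            weights[ind] = p_s / n_s
    if not weights:
        raise MissingTraitDataError(",".join(dropped), str(plot_id))
    ser = pd.Series(weights, name="weight")
    if dropped:
        ser = ser / ser.sum()
    return ser


def plot_moments(
    scores: ScoreTable,
    composition: CommunityComposition,
    axes: list[str] | None = None,
    drop_unscored: bool = False,
) -> pd.DataFrame:
    """Weighted moments of axis scores for every plot x retained axis.

    Returns a tidy frame with one row per (plot, axis) carrying the plot's
    community, CWM/CWV/CWS/CWK and the effective sample size.
    """
    axes = axes or scores.retained
    rows = []
    for plot in composition.plots:
        w = individual_weights(scores, composition, plot, drop_unscored=drop_unscored)
        community = composition.community_of(plot)
        for axis in axes:
            vals = scores.scores.loc[w.index, axis]
            m = weighted_moments(vals.to_numpy(), w.to_numpy())
            rows.append(
                {
                    "plot_id": plot,
                    "community_id": community,
                    "axis": axis,
                    **m.as_dict(),
                    "n_effective": m.n_effective,
                }
            )
    return pd.DataFrame(rows)


def summarize_moments(
    moments: pd.DataFrame,
    alpha: float = 0.05,
    moment_names: tuple[str, ...] = ("CWM", "CWS", "CWK"),
) -> pd.DataFrame:
    """Per community x axis x moment: mean, SE, SD, t confidence interval
    and a differs-from-zero flag.

    The flag is true when the two-sided ``1 - alpha`` Student-t interval
    over the community's plots excludes zero — the convention used to mark
    community-weighted moments as significantly non-Gaussian (CWS, CWK) or
    displaced (CWM).  Communities with fewer than two defined plot values
    get ``NaN`` interval bounds and a null flag.
    """
    rows = []
    for (community, axis), grp in moments.groupby(["community_id", "axis"], sort=True):
        for name in moment_names:
            vals = grp[name].dropna().to_numpy(dtype=float)
            n = vals.size
            if n < 2:
                rows.append(
                    {
                        "community_id": community,
                        "axis": axis,
                        "moment": name,
                        "n_plots": n,
                        "mean": float(vals.mean()) if n else float("nan"),
                        "sd": float("nan"),
                        "se": float("nan"),
                        "ci_low": float("nan"),
                        "ci_high": float("nan"),
                        "differs_from_zero": None,
                    }
                )
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            se = sd / np.sqrt(n)
            tcrit = float(stats.t.ppf(1 - alpha / 2, n - 1))
            lo, hi = mean - tcrit * se, mean + tcrit * se
            rows.append(
                {
                    "community_id": community,
                    "axis": axis,
                    "moment": name,
                    "n_plots": n,
                    "mean": mean,
                    "sd": sd,
                    "se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                    "differs_from_zero": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)
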