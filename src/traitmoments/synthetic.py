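"""Synthetic ecotone communities with known assembly ground truth.

The generator emulates the sampling design of a transect study across a
forest ecotone: a one-dimensional environmental gradient in ``[0, 1]``,
communities occupying equally spaced segments, ten plots per community
jittered around the segment centre, Gaussian species abundance responses
(optimum, breadth, maximum cover) producing compositional turnover, and
five measured individuals per species per community.

Traits are emitted at the individual level — never scores — so the whole
pipeline (standardize, PCA, weighting, moments, decomposition) is
exercised end to end.  Trait values follow a latent-factor model with
three blocks mirroring the leaf-economics, root-economics and
hydraulic-architecture syndromes: each trait is an affine function of one
(or two) latent dimensions plus independent measurement noise.  The first
two latents carry the assembly signal,

``latent(s, c) = alpha * u_s + beta * r_s * (g_c - gbar_s)``

where ``u_s`` is a species baseline (between-species differences = the
turnover signal), ``g_c`` the community's gradient position, ``gbar_s``
the mean position of the communities where species *s* occurs, and
``r_s`` a per-species relative slope (within-species drift along the
gradient = the ITV signal).  Because each species contributes equally many
individuals in every community where it occurs, its pooled mean is exactly
``alpha * u_s``, so the specific/fixed construction recovers the two
signals cleanly.

When a target ITV share ``theta`` is requested, the generator computes the
realized composition first and then *solves* for the slope scale ``beta``
that makes the latent-level ITV share of CWM variation exactly ``theta``
(a quadratic in ``beta``; ``theta = 1`` is produced by removing the
between-species signal instead).  The ground-truth record reports the
realized shares alongside the generating parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    CommunityComposition,
    Dataset,
    EnvironmentTable,
    TraitMatrix,
    relative_abundance,
)

TRAIT_KERNELS = ("gaussian", "lognormal-skewed", "two-point-bimodal")

#: trait -> (baseline, scale, block loadings on the three latents, residual sd)
#: loadings follow the acquisitive-conservative polarity of the three
#: syndromes: high SLA / SRA = acquisitive (positive); the carbon-isotope
#: composition also loads on the hydraulic latent (water-use efficiency).
_TRAIT_MODEL: dict[str, tuple[float, float, tuple[float, float, float], float]] = {
    "LDMC": (380.0, 60.0, (-0.85, 0.0, 0.0), 0.50),
    "SLA": (9.0, 2.5, (0.90, 0.0, 0.0), 0.45),
    "leaf_CN": (30.0, 8.0, (-0.80, 0.0, 0.0), 0.55),
    "d13C": (-28.0, 1.5, (0.0, 0.0, -0.58), 0.65),
    "SDMC": (420.0, 50.0, (-0.62, 0.0, -0.30), 0.50),
    "SRA": (25.0, 8.0, (0.0, 0.93, 0.0), 0.35),
    "Rdi": (0.35, 0.10, (0.0, -0.90, 0.0), 0.40),
    "root_CN": (40.0, 10.0, (0.0, -0.80, 0.0), 0.55),
    "Hv": (0.004, 0.0015, (0.0, 0.0, 0.82), 0.35),
}


@dataclass
class SyntheticScenario:
    """Generating parameters for one synthetic ecotone dataset.

    Defaults reproduce the sampling design the package targets: six
    communities along the gradient, ten plots each, a pool of nineteen
    woody species with Gaussian cover responses, five individuals per
    species and community, and nine traits in three correlated blocks.
    """

    n_communities: int = 6
    plots_per_community: int = 10
    n_species: int = 19
    individuals_per_species: int = 5
    #: multiplies the spread of species optima around mid-gradient; the
    #: turnover "knob" for compositional difference between communities
    optimum_spread: float = 1.0
    #: sd of the Gaussian abundance response along the gradient
    abundance_breadth: float = 0.12
    #: covers below this (metres of canopy intercept) are recorded as absent
    min_cover: float = 0.05
    #: between-species baseline scale (alpha) of the two economics latents
    turnover_sd: float = 1.0
    #: within-species gradient slope scale (beta); overridden when a target
    #: ITV share is requested
    itv_slope: float = 1.0
    #: per-species spread of relative ITV slopes around 1
    slope_heterogeneity: float = 0.25
    #: sd of individual latent deviations within a species x community
    individual_sd: float = 0.35
    #: distribution of the individual latent deviations
    trait_kernel: str = "gaussian"
    #: multiplies every trait's residual measurement noise (0 = traits are
    #: exact functions of the latents; useful for exactness checks)
    trait_noise_scale: float = 1.0
    #: target ITV share of CWM variation; the default 0.6 puts the
    #: generator in the ITV-dominant regime typical of fine-scale ecotone
    #: gradients.  None = use turnover_sd/itv_slope as given, no calibration
    theta: float | None = 0.6
    #: individuals measured for the regionally sampled trait (Hv) per species
    regional_trait_n: int = 3
    seed: int = 0
    traits: tuple[str, ...] = tuple(_TRAIT_MODEL)
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.trait_kernel not in TRAIT_KERNELS:
            raise ValidationError(
                f"unknown trait kernel {self.trait_kernel!r}; choose from {TRAIT_KERNELS}"
            )
        if self.theta is not None and not 0.0 <= self.theta <= 1.0:
            raise ValidationError("theta must lie in [0, 1]")
        for name, value in (
            ("individual_sd", self.individual_sd),
            ("turnover_sd", self.turnover_sd),
            ("itv_slope", self.itv_slope),
            ("abundance_breadth", self.abundance_breadth),
        ):
            if value < 0:
                raise ValidationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# standardized noise kernels


def _lognormal_shape(sigma: float) -> tuple[float, float]:
    """Closed-form skewness and excess kurtosis of a lognormal."""
    w = math.exp(sigma**2)
    skew = (w + 2.0) * math.sqrt(w - 1.0)
    exkurt = w**4 + 2.0 * w**3 + 3.0 * w**2 - 6.0
    return skew, exkurt


def _draw_kernel(rng: np.random.Generator, kind: str, size: int) -> np.ndarray:
    """Draws with mean 0 and variance 1 from the named shape family."""
    if kind == "gaussian":
        return rng.standard_normal(size)
    if kind == "lognormal-skewed":
        sigma = 0.5
        x = rng.lognormal(0.0, sigma, size)
        m = math.exp(sigma**2 / 2.0)
        sd = math.sqrt((math.exp(sigma**2) - 1.0) * math.exp(sigma**2))
        return (x - m) / sd
    if kind == "two-point-bimodal":
        return rng.choice([-1.0, 1.0], size=size)
    raise ValidationError(f"unknown kernel {kind!r}")


def make_shape_fixture(
    kind: str, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Equal-weight sample with analytic target skewness/excess kurtosis.

    ``kind`` is ``symmetric`` (standard Gaussian: 0, 0), ``right-skewed``
    (standardized lognormal, sigma = 0.5, closed-form moments) or
    ``bimodal`` (equal two-point at +-1: 0, -2).  Returns
    ``(values, weights, skewness, excess_kurtosis)``.
    """
    if n < 10:
        raise ValidationError("shape fixtures need n >= 10")
    rng = np.random.default_rng(seed)
    if kind == "symmetric":
        values = rng.standard_normal(n)
        target = (0.0, 0.0)
    elif kind == "right-skewed":
        values = _draw_kernel(rng, "lognormal-skewed", n)
        target = _lognormal_shape(0.5)
    elif kind == "bimodal":
        values = _draw_kernel(rng, "two-point-bimodal", n)
        target = (0.0, -2.0)
    else:
        raise ValidationError(
            f"unknown shape kind {kind!r}; choose symmetric, right-skewed or bimodal"
        )
    weights = np.full(n, 1.0 / n)
    return values, weights, target[0], target[1]


# ---------------------------------------------------------------------------
# generation


def _abundance_table(
    scenario: SyntheticScenario, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Plot positions, species cover matrix; retried until no plot is empty."""
    C, P, S = scenario.n_communities, scenario.plots_per_community, scenario.n_species
    centers = (np.arange(C) + 0.5) / C
    communities = [f"comm{c + 1}" for c in range(C)]
    species = [f"sp{s + 1:02d}" for s in range(S)]

    for _ in range(scenario.max_retries):
        g_plot = np.repeat(centers, P) + rng.uniform(-0.5 / C, 0.5 / C, C * P)
        base = np.linspace(0.0, 1.0, S)
        optima = 0.5 + scenario.optimum_spread * (base - 0.5) + rng.normal(0.0, 0.03, S)
        breadth = scenario.abundance_breadth * (1.0 + 0.2 * rng.standard_normal(S))
        breadth = np.clip(breadth, 0.04, None)
        max_cover = rng.lognormal(1.1, 0.35, S)  # metres of canopy, ~2-5 m

        cover = max_cover[None, :] * np.exp(
            -((g_plot[:, None] - optima[None, :]) ** 2) / (2.0 * breadth[None, :] ** 2)
        )
        cover[cover < scenario.min_cover] = 0.0
        if (cover.sum(axis=1) > 0).all():
            break
    else:
        raise ValidationError(
            f"could not draw a composition without empty plots in "
            f"{scenario.max_retries} attempts"
        )

    plots = pd.DataFrame(
        {
            "plot_id": [f"plot{i + 1:02d}" for i in range(C * P)],
            "community_id": np.repeat(communities, P),
            "gradient": g_plot,
        }
    )
    species_info = pd.DataFrame(
        {
            "species_id": species,
            "optimum": optima,
            "breadth": breadth,
            "max_cover": max_cover,
        }
    )
    return plots, cover, species_info


def _solve_beta(theta: float, Sf: float, Sh: float, C: float) -> float:
    """Slope scale making the latent ITV share of CWM variance equal theta.

    Solves ``beta^2 Sh (1 - theta) - 2 theta C beta - theta Sf = 0`` for the
    positive root; the share is ``beta^2 Sh / (Sf + beta^2 Sh + 2 beta C)``.
    """
    if theta == 0.0:
        return 0.0
    if Sh <= 0:
        raise ValidationError("degenerate composition: no within-species gradient signal")
    disc = theta**2 * C**2 + theta * (1.0 - theta) * Sf * Sh
    return (theta * C + math.sqrt(disc)) / (Sh * (1.0 - theta))


def mean_between_community_bray_curtis(composition: CommunityComposition) -> float:
    """Mean Bray-Curtis dissimilarity between community-level cover vectors."""
    totals = composition.data.pivot_table(
        index="community_id", columns="species_id", values="cover", aggfunc="sum", fill_value=0.0
    )
    vals = totals.to_numpy(dtype=float)
    dists = [
        np.abs(vals[i] - vals[j]).sum() / (vals[i] + vals[j]).sum()
        for i, j in itertools.combinations(range(len(vals)), 2)
    ]
    return float(np.mean(dists))


def _latent_cwm_shares(
    rel: pd.DataFrame, mean_latent: pd.DataFrame, pooled: pd.Series
) -> dict[str, float]:
    """Exact specific/fixed decomposition shares on a latent's realized means."""
    specific, fixed = [], []
    for _, row in rel.iterrows():
        comm = row["community_id"]
        p = row["abundances"]
        specific.append(sum(p[s] * mean_latent.loc[(s, comm)] for s in p))
        fixed.append(sum(p[s] * pooled.loc[s] for s in p))
    specific = np.asarray(specific)
    fixed = np.asarray(fixed)
    itv = specific - fixed

    def ss(x: np.ndarray) -> float:
        return float(np.sum((x - x.mean()) ** 2))

    total = ss(specific)
    if total == 0:
        return {"itv_share": float("nan"), "turnover_share": float("nan"), "cov_share": float("nan")}
    turn, iv = ss(fixed), ss(itv)
    return {
        "itv_share": iv / total,
        "turnover_share": turn / total,
        "cov_share": (total - turn - iv) / total,
    }


def generate(scenario: SyntheticScenario) -> tuple[Dataset, dict]:
    """Draw one complete dataset plus its ground-truth record.

    The returned :class:`~traitmoments.io.Dataset` satisfies every loading
    invariant (each covered species has measured individuals in its
    community); the ground truth carries the generating parameters, the
    realized latent-level turnover/ITV/covariation shares of CWM variation
    for the two economics latents, and the realized between-community
    compositional dissimilarity.
    """
    rng = np.random.default_rng(scenario.seed)
    plots, cover, species_info = _abundance_table(scenario, rng)
    C = scenario.n_communities
    centers = {f"comm{c + 1}": (c + 0.5) / C for c in range(C)}
    species = list(species_info["species_id"])
    S = len(species)

    # --- presence pattern and per-species gradient anchors -----------------
    present: dict[str, set[str]] = {s: set() for s in species}
    comp_rows = []
    for i, prow in plots.iterrows():
        for j, s in enumerate(species):
            if cover[i, j] > 0:
                present[s].add(prow["community_id"])
                comp_rows.append(
                    {
                        "plot_id": prow["plot_id"],
                        "community_id": prow["community_id"],
                        "species_id": s,
                        "cover": round(float(cover[i, j]), 6),
                    }
                )
    gbar = {
        s: float(np.mean([centers[c] for c in sorted(present[s])])) if present[s] else 0.5
        for s in species
    }

    # --- latent structure ---------------------------------------------------
    base_opt = species_info["optimum"].to_numpy()
    o_std = (base_opt - base_opt.mean()) / (base_opt.std(ddof=0) or 1.0)
    mix1, mix2 = 0.95, 0.0  # gradient alignment of the two economics baselines
    u3 = rng.standard_normal(S)  # hydraulic latent: species-level only
    u3 = (u3 - u3.mean()) / (u3.std(ddof=0) or 1.0)
    u = {
        1: mix1 * o_std + math.sqrt(1 - mix1**2) * rng.standard_normal(S),
        2: -mix2 * o_std + math.sqrt(1 - mix2**2) * rng.standard_normal(S),
        3: u3,
    }
    # per-species relative ITV slopes: leaf-side plasticity is directional
    # (all species drift the same way along the gradient, with spread);
    # root-side plasticity is idiosyncratic (zero-mean), so the two
    # latents' within-species drifts are uncorrelated
    r_slope = {
        1: 1.0 + scenario.slope_heterogeneity * rng.standard_normal(S),
        2: rng.standard_normal(S),
        3: np.zeros(S),
    }

    # per-plot relative abundances (dict per plot) used for calibration
    comp_df = pd.DataFrame(comp_rows)
    totals = comp_df.groupby("plot_id")["cover"].transform("sum")
    comp_df["rel"] = comp_df["cover"] / totals
    rel = (
        comp_df.groupby("plot_id")
        .apply(
            lambda d: pd.Series(
                {
                    "community_id": d["community_id"].iloc[0],
                    "abundances": dict(zip(d["species_id"], d["rel"])),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )

    sp_idx = {s: j for j, s in enumerate(species)}
    alphas, betas = {}, {}
    for latent in (1, 2):
        f_series, h_series = [], []
        for _, row in rel.iterrows():
            p = row["abundances"]
            comm = row["community_id"]
            f_series.append(sum(p[s] * u[latent][sp_idx[s]] for s in p))
            h_series.append(
                sum(p[s] * r_slope[latent][sp_idx[s]] * (centers[comm] - gbar[s]) for s in p)
            )
        f = np.asarray(f_series)
        h = np.asarray(h_series)
        Sf = float(np.sum((f - f.mean()) ** 2))
        Sh = float(np.sum((h - h.mean()) ** 2))
        Cfh = float(np.sum((f - f.mean()) * (h - h.mean())))
        if scenario.theta is None:
            alphas[latent] = scenario.turnover_sd
            betas[latent] = scenario.itv_slope
        elif scenario.theta >= 1.0:
            alphas[latent] = 0.0
            betas[latent] = math.sqrt(Sf / Sh) if Sh > 0 else 1.0
        else:
            alphas[latent] = scenario.turnover_sd
            betas[latent] = _solve_beta(
                scenario.theta, scenario.turnover_sd**2 * Sf, Sh, scenario.turnover_sd * Cfh
            )
    alphas[3], betas[3] = 1.0, 0.0

    # normalize each latent's species x community mean structure to unit
    # spread: the turnover/ITV shares are scale-invariant, and a fixed
    # latent variance keeps the trait correlation blocks (and hence the
    # axis ordering) comparable across scenarios and seeds
    pairs = [(s, c) for s in species for c in sorted(present[s])]

    def _raw_mean(lat: int, j: int, s: str, c: str) -> float:
        return alphas[lat] * u[lat][j] + betas[lat] * r_slope[lat][j] * (
            centers[c] - gbar[s]
        )

    mean_scale = {}
    for lat in (1, 2, 3):
        raw = np.array([_raw_mean(lat, sp_idx[s], s, c) for s, c in pairs])
        sd = raw.std(ddof=0)
        mean_scale[lat] = 1.0 / sd if sd > 0 else 1.0

    # --- individuals --------------------------------------------------------
    n_ind = scenario.individuals_per_species
    trait_rows = []
    mean_latents = {lat: {} for lat in (1, 2, 3)}
    counter = 0
    for s, c in pairs:
        j = sp_idx[s]
        means = {
            lat: mean_scale[lat] * _raw_mean(lat, j, s, c) for lat in (1, 2, 3)
        }
        eps = {
            lat: scenario.individual_sd * _draw_kernel(rng, scenario.trait_kernel, n_ind)
            for lat in (1, 2, 3)
        }
        L = {lat: means[lat] + eps[lat] for lat in (1, 2, 3)}
        for lat in (1, 2, 3):
            mean_latents[lat][(s, c)] = float(L[lat].mean())
        for i in range(n_ind):
            counter += 1
            row = {
                "individual_id": f"ind{counter:04d}",
                "species_id": s,
                "community_id": c,
            }
            for trait in scenario.traits:
                base, scale, loads, resid_sd = _TRAIT_MODEL[trait]
                latent_part = sum(loads[lat - 1] * L[lat][i] for lat in (1, 2, 3))
                noise = scenario.trait_noise_scale * resid_sd * rng.standard_normal()
                value = base + scale * (latent_part + noise)
                row[trait] = value
            trait_rows.append(row)
    traits_df = pd.DataFrame(trait_rows)

    # regional trait: only a few individuals measured per species, the rest
    # missing (exercises the species-mean fill)
    if "Hv" in traits_df.columns and scenario.regional_trait_n > 0:
        keep = set()
        for s in species:
            ids = traits_df.index[traits_df["species_id"] == s]
            keep.update(ids[: scenario.regional_trait_n])
        mask = ~traits_df.index.isin(keep)
        traits_df.loc[mask, "Hv"] = np.nan

    # --- abiotic table ------------------------------------------------------
    g = plots["gradient"].to_numpy()
    n_plots = len(plots)
    env = pd.DataFrame(
        {
            "plot_id": plots["plot_id"],
            "altitude": 1250.0 + 350.0 * g + rng.normal(0, 15, n_plots),
            "orientation": np.clip(
                -0.8 + 1.6 * g + rng.normal(0, 0.15, n_plots), -1.0, 1.0
            ),
            "slope": np.clip(25.0 - 10.0 * g + rng.normal(0, 4, n_plots), 0.0, None),
            "soil_depth": np.clip(20.0 + 40.0 * g + rng.normal(0, 5, n_plots), 2.0, None),
            "soil_nitrate": np.clip(8.0 - 4.0 * g + rng.normal(0, 1, n_plots), 0.1, None),
            "soil_phosphate": np.clip(6.0 - 2.0 * g + rng.normal(0, 0.8, n_plots), 0.1, None),
            "total_soil_N": np.clip(0.2 + 0.15 * g + rng.normal(0, 0.03, n_plots), 0.01, None),
            "SOM": np.clip(6.0 + 3.0 * g + rng.normal(0, 0.8, n_plots), 0.5, None),
        }
    ).round(6)

    composition = relative_abundance(
        CommunityComposition(comp_df.drop(columns=["rel"]))
    )
    dataset = Dataset(
        traits=TraitMatrix(traits_df, list(scenario.traits), {"Hv"}),
        composition=composition,
        environment=EnvironmentTable(env, [c for c in env.columns if c != "plot_id"]),
    )

    # --- ground truth -------------------------------------------------------
    truth: dict = {
        "scenario": asdict(scenario),
        "alpha": {f"latent{k}": float(v) for k, v in alphas.items()},
        "beta": {f"latent{k}": float(v) for k, v in betas.items()},
        "n_individuals": int(len(traits_df)),
        "n_species_community_pairs": len(pairs),
        "mean_between_community_bray_curtis": mean_between_community_bray_curtis(
            composition
        ),
        "species": {
            s: {
                "optimum": float(species_info["optimum"][sp_idx[s]]),
                "n_communities": len(present[s]),
                "baseline_latent1": float(u[1][sp_idx[s]]),
                "baseline_latent2": float(u[2][sp_idx[s]]),
            }
            for s in species
        },
    }
    for lat in (1, 2):
        ml = pd.Series(mean_latents[lat])
        pooled = ml.groupby(level=0).mean()
        shares = _latent_cwm_shares(rel, ml, pooled)
        truth[f"latent{lat}_shares"] = {k: float(v) for k, v in shares.items()}
        truth[f"latent{lat}_mean_traits"] = {
            f"{s}|{c}": float(v) for (s, c), v in ml.items()
        }
    return dataset, truth
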