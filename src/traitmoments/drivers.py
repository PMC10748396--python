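"""Environmental drivers of community-weighted moments.

Each plot-level moment (one response per axis x moment) is modelled as a
linear function of continuous abiotic predictors plus an optional
community factor.  Candidate models are every subset of the terms
(exhaustive enumeration, factor entering as a block), ranked by the
small-sample-corrected Akaike information criterion

.. math::

    \\mathrm{AIC} = n \\ln(\\mathrm{RSS}/n) + n \\ln 2\\pi + n + 2k, \\qquad
    \\mathrm{AICc} = \\mathrm{AIC} + \\frac{2k(k+1)}{n-k-1},

with :math:`k` counting all estimated parameters including the residual
variance.  Models within 2 AICc units of the best are conventionally
treated as equally supported.  For the best model the contribution of each
term is reported as its Type-II sum of squares (the increase in residual SS
when the term is dropped; equal to the partial SS in these
interaction-free models) as a percentage of the total SS of the response.

Community differences in a moment are tested by one-way ANOVA with Tukey
HSD pairwise comparisons (studentized-range distribution, Tukey-Kramer
correction for unequal group sizes) and summarised as a compact letter
display.
"""

from __future__ import annotations

import itertools
import math
import string
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, OverparameterizedModelError, ValidationError

_RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# design construction and ordinary least squares


def _factor_dummies(values: pd.Series, name: str) -> pd.DataFrame:
    """Treatment contrasts; reference level = first level lexicographically."""
    levels = sorted(map(str, pd.unique(values.astype(str))))
    cols = {}
    vals = values.astype(str).to_numpy()
    for lev in levels[1:]:
        cols[f"{name}[{lev}]"] = (vals == lev).astype(float)
    return pd.DataFrame(cols, index=values.index)


@dataclass
class ModelFit:
    """An ordinary-least-squares fit of one moment response."""

    response: str
    terms: list[str]
    factor: str | None
    coef: pd.Series
    n: int
    k: int            # estimated parameters: coefficients + residual variance
    rss: float
    tss: float
    r2: float
    adj_r2: float
    fitted: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    design: pd.DataFrame = field(repr=False)

    @property
    def n_coef(self) -> int:
        return len(self.coef)

    def term_columns(self, term: str) -> list[str]:
        if term == self.factor:
            return [c for c in self.design.columns if c.startswith(f"{term}[")]
        return [term]


def _design_matrix(
    predictors: pd.DataFrame, terms: list[str], factor: str | None
) -> pd.DataFrame:
    parts = [pd.DataFrame({"Intercept": np.ones(len(predictors))}, index=predictors.index)]
    for term in terms:
        if factor is not None and term == factor:
            parts.append(_factor_dummies(predictors[term], term))
        else:
            parts.append(predictors[[term]].astype(float))
    return pd.concat(parts, axis=1)


def _lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), rank


def fit_ols(
    y,
    predictors: pd.DataFrame,
    terms: list[str] | None = None,
    factor: str | None = None,
    response: str = "y",
) -> ModelFit:
    """Least-squares fit of ``y`` on the named predictor terms.

    ``terms`` lists the columns of ``predictors`` to use (default: all);
    ``factor`` names the one categorical column among them, expanded to
    treatment contrasts with the lexicographically first level as
    reference.  Raises :class:`CollinearityError` naming the aliased terms
    if the design is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    if terms is None:
        terms = list(predictors.columns)
    if factor is not None and factor in terms and factor not in predictors.columns:
        raise ValidationError(f"factor column {factor!r} not in predictor table")
    design = _design_matrix(predictors, terms, factor)
    X = design.to_numpy(dtype=float)
    n, p_cols = X.shape
    if n <= p_cols:
        raise ValidationError(f"n = {n} observations cannot identify {p_cols} coefficients")

    rank = np.linalg.matrix_rank(X, tol=_RANK_TOL * max(X.shape) * np.abs(X).max())
    if rank < p_cols:
        aliased = _find_aliased(design, terms, factor)
        raise CollinearityError(aliased)

    beta, rss, _ = _lstsq(X, y)
    fitted = X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p = p_cols - 1  # non-intercept coefficients
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else float("nan")
    return ModelFit(
        response=response,
        terms=list(terms),
        factor=factor if factor in terms else None,
        coef=pd.Series(beta, index=design.columns),
        n=n,
        k=p_cols + 1,
        rss=rss,
        tss=tss,
        r2=r2,
        adj_r2=adj_r2,
        fitted=fitted,
        y=y,
        design=design,
    )


def _find_aliased(design: pd.DataFrame, terms: list[str], factor: str | None) -> list[str]:
    """Greedy scan: terms whose columns add no rank given the earlier ones."""
    X = design[["Intercept"]].to_numpy(dtype=float)
    aliased = []
    for term in terms:
        cols = (
            [c for c in design.columns if c.startswith(f"{term}[")]
            if term == factor
            else [term]
        )
        cand = np.column_stack([X, design[cols].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) < X.shape[1] + len(cols):
            aliased.append(term)
        else:
            X = cand
    return aliased


# ---------------------------------------------------------------------------
# information criteria


def aic(fit: ModelFit) -> float:
    """Gaussian-likelihood AIC with k counting the residual variance."""
    n, k = fit.n, fit.k
    if fit.rss <= 0:
        return float("-inf")
    return n * math.log(fit.rss / n) + n * math.log(2 * math.pi) + n + 2 * k


def aicc(fit: ModelFit) -> float:
    """Small-sample-corrected AIC; requires ``n - k - 1 > 0``."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise OverparameterizedModelError(
            f"AICc undefined for n = {n}, k = {k} (need n > k + 1)"
        )
    return aic(fit) + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# exhaustive model selection


@dataclass
class ModelSelectionResult:
    """All-subsets AICc selection for one response."""

    response: str
    candidates: pd.DataFrame      # terms, k, rss, aicc, delta_aicc, adj_r2
    best: ModelFit
    best_aicc: float
    supported: pd.DataFrame       # the delta AICc < 2 subset of candidates
    shares: pd.DataFrame          # per-term sign and % of total SS, best model

    @property
    def best_terms(self) -> list[str]:
        return list(self.best.terms)


def all_subsets_selection(
    y,
    predictors: pd.DataFrame,
    terms: list[str] | None = None,
    factor: str | None = None,
    response: str = "y",
    delta_threshold: float = 2.0,
) -> ModelSelectionResult:
    """Fit every subset of terms (intercept always included) and rank by AICc.

    The factor enters or leaves as a block.  Ties at the minimum AICc are
    broken by fewer parameters, then by lexicographic term order.
    Rank-deficient subsets are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    if terms is None:
        terms = list(predictors.columns)
    if len(terms) > 16:
        raise ValidationError(f"{len(terms)} terms: exhaustive enumeration capped at 16")

    full_design = _design_matrix(predictors, terms, factor)
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    col_idx = {c: i for i, c in enumerate(full_design.columns)}
    Xfull = full_design.to_numpy(dtype=float)

    def cols_for(subset: tuple[str, ...]) -> list[int]:
        idx = [col_idx["Intercept"]]
        for t in subset:
            if factor is not None and t == factor:
                idx += [col_idx[c] for c in full_design.columns if c.startswith(f"{t}[")]
            else:
                idx.append(col_idx[t])
        return idx

    records = []
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            idx = cols_for(subset)
            X = Xfull[:, idx]
            p_cols = X.shape[1]
            k = p_cols + 1
            if n - k - 1 <= 0:
                continue
            beta, rss, rank = _lstsq(X, y)
            if rank < p_cols:
                warnings.warn(
                    f"skipping rank-deficient subset {subset!r}", stacklevel=2
                )
                continue
            r2 = 1.0 - rss / tss if tss > 0 else 0.0
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_cols) if n - p_cols > 0 else np.nan
            a = (
                n * math.log(rss / n) + n * math.log(2 * math.pi) + n + 2 * k
                if rss > 0
                else float("-inf")
            )
            records.append(
                {
                    "terms": " + ".join(subset) if subset else "1",
                    "term_tuple": subset,
                    "k": k,
                    "rss": rss,
                    "r2": r2,
                    "adj_r2": adj,
                    "aicc": a + 2 * k * (k + 1) / (n - k - 1),
                }
            )
    if not records:
        raise ValidationError("no fittable candidate models")

    cand = pd.DataFrame(records)
    cand = cand.sort_values(
        by=["aicc", "k", "terms"], kind="stable", ignore_index=True
    )
    cand["delta_aicc"] = cand["aicc"] - cand["aicc"].iloc[0]
    best_terms = list(cand["term_tuple"].iloc[0])
    best = fit_ols(y, predictors, terms=best_terms, factor=factor, response=response)
    supported = cand[cand["delta_aicc"] < delta_threshold].copy()
    shares = variance_shares(best) if best_terms else pd.DataFrame(
        columns=["term", "sign", "ss", "pct_of_total"]
    )
    return ModelSelectionResult(
        response=response,
        candidates=cand.drop(columns="term_tuple"),
        best=best,
        best_aicc=float(cand["aicc"].iloc[0]),
        supported=supported.drop(columns="term_tuple"),
        shares=shares,
    )


def variance_shares(fit: ModelFit) -> pd.DataFrame:
    """Type-II sum of squares per term as % of the response total SS.

    For each term the model is refitted without it (factor dummies dropped
    as a block); the increase in residual SS is that term's SS.  Shares are
    ``100 * SS_term / SS_total`` with ``SS_total = sum((y - mean)^2)``, and
    the residual share of the full model is appended, so that in an
    orthogonal design shares plus residual total 100%.  The sign column is
    the coefficient sign for continuous terms and ``+`` for the factor
    (a multi-level factor has no single direction).
    """
    if not fit.terms:
        raise ValidationError("variance shares need at least one non-intercept term")
    y = fit.y
    rows = []
    for term in fit.terms:
        keep = [c for c in fit.design.columns if c not in fit.term_columns(term)]
        X = fit.design[keep].to_numpy(dtype=float)
        _, rss_red, _ = _lstsq(X, y)
        ss = rss_red - fit.rss
        if term == fit.factor:
            sign = "+"
        else:
            sign = "+" if fit.coef[term] >= 0 else "-"
        rows.append(
            {
                "term": term,
                "sign": sign,
                "ss": ss,
                "pct_of_total": 100.0 * ss / fit.tss if fit.tss > 0 else float("nan"),
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "sign": "",
            "ss": fit.rss,
            "pct_of_total": 100.0 * fit.rss / fit.tss if fit.tss > 0 else float("nan"),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-way ANOVA and Tukey HSD


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: pd.Series
    pairwise: pd.DataFrame        # group_a, group_b, diff, q, p_adj
    letters: dict[str, str]       # compact letter display at alpha
    alpha: float
    excluded_groups: list[str]


def oneway_anova_tukey(
    values, groups, alpha: float = 0.05, tukey: bool = True
) -> AnovaTukeyResult:
    """Classical one-way F test plus Tukey HSD pairwise p-values.

    Pairwise p-values come from the studentized-range distribution with
    ``N - g`` error degrees of freedom (Tukey-Kramer form for unequal group
    sizes).  Groups with fewer than two values are excluded with a warning.
    The compact letter display assigns a shared letter to every maximal set
    of mutually non-different groups (maximal cliques of the
    non-significance graph), so two groups share a letter exactly when
    their adjusted p-value is at or above ``alpha``.  ``tukey=False`` skips
    the pairwise stage (the studentized-range tail is costly), e.g. in
    simulation loops that only need the F test.
    """
    ser = pd.Series(np.asarray(values, dtype=float))
    grp = pd.Series(np.asarray(groups, dtype=object), index=ser.index).astype(str)
    counts = grp.value_counts()
    excluded = sorted(counts[counts < 2].index)
    if excluded:
        warnings.warn(f"excluding group(s) with < 2 values: {excluded}", stacklevel=2)
        keep = ~grp.isin(excluded)
        ser, grp = ser[keep], grp[keep]
    labels = sorted(grp.unique())
    g = len(labels)
    if g < 2:
        raise ValidationError("need at least two groups with >= 2 values each")

    arrays = [ser[grp == lab].to_numpy() for lab in labels]
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    N = int(ns.sum())
    grand = ser.mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    df_b, df_w = g - 1, N - g
    mse = ss_within / df_w
    if mse == 0.0:
        f_stat = 0.0 if ss_between == 0.0 else float("inf")
        p_val = 1.0 if ss_between == 0.0 else 0.0
    else:
        f_stat = (ss_between / df_b) / mse
        p_val = float(stats.f.sf(f_stat, df_b, df_w))

    if not tukey:
        return AnovaTukeyResult(
            f_statistic=f_stat,
            df_between=df_b,
            df_within=df_w,
            p_value=p_val,
            group_means=pd.Series(means, index=labels, name="mean"),
            pairwise=pd.DataFrame(columns=["group_a", "group_b", "diff", "q", "p_adj"]),
            letters={},
            alpha=alpha,
            excluded_groups=excluded,
        )

    rows = []
    for i, j in itertools.combinations(range(g), 2):
        diff = means[j] - means[i]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, g, df_w))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "diff": diff,
                "q": q,
                "p_adj": min(max(p_adj, 0.0), 1.0),
            }
        )
    pairwise = pd.DataFrame(rows)
    letters = _compact_letters(labels, pairwise, alpha)
    return AnovaTukeyResult(
        f_statistic=f_stat,
        df_between=df_b,
        df_within=df_w,
        p_value=p_val,
        group_means=pd.Series(means, index=labels, name="mean"),
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        excluded_groups=excluded,
    )


def _compact_letters(
    labels: list[str], pairwise: pd.DataFrame, alpha: float
) -> dict[str, str]:
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    for _, row in pairwise.iterrows():
        if row["p_adj"] >= alpha:
            graph.add_edge(row["group_a"], row["group_b"])
    cliques = sorted(
        nx.find_cliques(graph), key=lambda c: (min(labels.index(x) for x in c), sorted(c))
    )
    assigned: dict[str, list[str]] = {lab: [] for lab in labels}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for lab in clique:
            assigned[lab].append(letter)
    return {lab: "".join(sorted(ls)) for lab, ls in assigned.items()}
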