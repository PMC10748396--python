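"""Weighted moment estimators, per-plot weighting and community summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitmoments import (
    build_trait_space,
    individual_weights,
    plot_moments,
    summarize_moments,
    weighted_moments,
)
from traitmoments.errors import MissingTraitDataError, ValidationError


def oracle_moments(values, weights):
    """Independent direct-summation oracle (plain Python loops)."""
    cwm = sum(w * x for x, w in zip(values, weights))
    cwv = sum(w * (x - cwm) ** 2 for x, w in zip(values, weights))
    if cwv == 0:
        return cwm, cwv, float("nan"), float("nan")
    cws = sum(w * (x - cwm) ** 3 for x, w in zip(values, weights)) / cwv**1.5
    cwk = sum(w * (x - cwm) ** 4 for x, w in zip(values, weights)) / cwv**2 - 3.0
    return cwm, cwv, cws, cwk


class TestWeightedMoments:
    def test_symmetric_two_point(self):
        m = weighted_moments([-1.0, 1.0], [0.5, 0.5])
        assert (m.cwm, m.cwv, m.cws, m.cwk) == (0.0, 1.0, 0.0, -2.0)

    def test_constant_sample_degenerate(self):
        m = weighted_moments([3.0, 3.0, 3.0], [0.2, 0.5, 0.3])
        assert m.cwm == pytest.approx(3.0)
        assert m.cwv == 0.0
        assert m.degenerate
        assert math.isnan(m.cws) and math.isnan(m.cwk)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = rng.integers(2, 12)
            x = rng.normal(size=n)
            w = rng.random(n)
            w /= w.sum()
            m = weighted_moments(x, w)
            np.testing.assert_allclose(
                [m.cwm, m.cwv, m.cws, m.cwk], oracle_moments(x, w), atol=1e-12
            )

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            weighted_moments([1.0, 2.0], [-0.5, 1.5])

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            weighted_moments([1.0, 2.0], [0.5, 0.6])

    @settings(max_examples=60, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.floats(-50, 50), st.floats(0.01, 1.0)),
            min_size=3,
            max_size=12,
        ),
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-10, 10),
    )
    def test_location_scale_equivariance(self, data, a, b):
        from hypothesis import assume

        x = np.array([d[0] for d in data])
        w = np.array([d[1] for d in data])
        w /= w.sum()
        # shifts of near-constant samples are dominated by cancellation noise
        assume(np.ptp(x) > 0.01)
        base = weighted_moments(x, w)
        trans = weighted_moments(a * x + b, w)
        assert trans.cwm == pytest.approx(a * base.cwm + b, rel=1e-9, abs=1e-9)
        assert trans.cwv == pytest.approx(a**2 * base.cwv, rel=1e-9, abs=1e-12)
        if not base.degenerate:
            assert trans.cws == pytest.approx(
                math.copysign(1.0, a) * base.cws, rel=1e-7, abs=1e-10
            )
            assert trans.cwk == pytest.approx(base.cwk, rel=1e-7, abs=1e-10)

    def test_weight_replication_equivalence(self):
        # one observation at weight 2w equals two copies at weight w
        x = [1.0, 2.0, 5.0]
        w = [0.5, 0.3, 0.2]
        xr = [1.0, 1.0, 2.0, 5.0]
        wr = [0.25, 0.25, 0.3, 0.2]
        a, b = weighted_moments(x, w), weighted_moments(xr, wr)
        np.testing.assert_allclose(
            [a.cwm, a.cwv, a.cws, a.cwk], [b.cwm, b.cwv, b.cws, b.cwk], atol=1e-12
        )

    def test_lognormal_consistency_at_large_n(self):
        # uniform weights, n large: sample CWS/CWK approach the closed-form
        # lognormal shape; tolerance from replicate spread at this n
        sigma = 0.5
        w_ = math.exp(sigma**2)
        skew_true = (w_ + 2) * math.sqrt(w_ - 1)
        kurt_true = w_**4 + 2 * w_**3 + 3 * w_**2 - 6
        rng = np.random.default_rng(4)
        n = 10**5
        cws_reps, cwk_reps = [], []
        for _ in range(5):
            x = rng.lognormal(0.0, sigma, n)
            m = weighted_moments(x, np.full(n, 1.0 / n))
            cws_reps.append(m.cws)
            cwk_reps.append(m.cwk)
        assert np.mean(cws_reps) == pytest.approx(skew_true, abs=4 * np.std(cws_reps) + 0.01)
        assert np.mean(cwk_reps) == pytest.approx(kurt_true, abs=4 * np.std(cwk_reps) + 0.05)


class TestPlotMoments:
    @pytest.fixture()
    def scored(self, tiny_dataset):
        scores, _ = build_trait_space(tiny_dataset.traits)
        return scores

    def test_single_species_plot_uniform_weights(self, tiny_dataset, scored):
        # plot covering only s1: each of the 2 individuals gets weight 1/2
        comp = tiny_dataset.composition.data.copy()
        comp = comp[~((comp.plot_id == "pA1") & (comp.species_id != "s1"))]
        from traitmoments import CommunityComposition, relative_abundance

        comp = relative_abundance(CommunityComposition(comp))
        w = individual_weights(scored, comp, "pA1")
        np.testing.assert_allclose(w.to_numpy(), 0.5)

    def test_weight_rule_p_over_n(self, tiny_dataset, scored):
        w = individual_weights(scored, tiny_dataset.composition, "pA1")
        # covers 10/6/4 over 20 -> p = .5/.3/.2, two individuals each
        expected = {"s1": 0.25, "s2": 0.15, "s3": 0.10}
        meta = scored.meta.loc[w.index]
        for sp, val in expected.items():
            np.testing.assert_allclose(w[meta.species_id == sp], val)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_moments_match_oracle_per_plot(self, tiny_dataset, scored):
        mom = plot_moments(scored, tiny_dataset.composition, axes=[scored.axes[0]])
        assert len(mom) == 4
        for _, row in mom.iterrows():
            w = individual_weights(scored, tiny_dataset.composition, row.plot_id)
            x = scored.scores.loc[w.index, row.axis].to_numpy()
            exp = oracle_moments(x, w.to_numpy())
            np.testing.assert_allclose(
                [row.CWM, row.CWV, row.CWS, row.CWK], exp, atol=1e-12
            )

    def test_missing_species_raises_unless_dropped(self, tiny_dataset):
        traits = tiny_dataset.traits.data
        reduced = traits[~((traits.species_id == "s3") & (traits.community_id == "cA"))]
        from traitmoments import TraitMatrix

        scores, _ = build_trait_space(
            TraitMatrix(reduced, ["height", "mass", "area"], set())
        )
        with pytest.raises(MissingTraitDataError) as err:
            individual_weights(scores, tiny_dataset.composition, "pA1")
        assert "s3" in str(err.value)
        w = individual_weights(
            scores, tiny_dataset.composition, "pA1", drop_unscored=True
        )
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestSummaries:
    def _moments_frame(self, values, community="c1", axis="PC1"):
        return pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(len(values))],
                "community_id": community,
                "axis": axis,
                "CWM": values,
                "CWS": values,
                "CWK": values,
            }
        )

    def test_zero_spread_flags_nonzero(self):
        out = summarize_moments(self._moments_frame([0.7] * 10))
        row = out[out.moment == "CWM"].iloc[0]
        assert row.sd == 0.0
        assert row.ci_low == row.ci_high == pytest.approx(0.7)
        assert bool(row.differs_from_zero)

    def test_symmetric_values_not_flagged(self):
        out = summarize_moments(self._moments_frame([-1.0, 1.0, -1.0, 1.0]))
        row = out[out.moment == "CWM"].iloc[0]
        assert row["mean"] == pytest.approx(0.0)
        assert not bool(row.differs_from_zero)

    def test_single_plot_gives_sentinel(self):
        out = summarize_moments(self._moments_frame([0.3]))
        row = out[out.moment == "CWM"].iloc[0]
        assert row.differs_from_zero is None
        assert math.isnan(row.ci_low)

    def test_t_interval_ci_bounds_match_scipy(self):
        from scipy import stats

        vals = [0.1, 0.5, -0.2, 0.9, 0.4]
        out = summarize_moments(self._moments_frame(vals))
        row = out[out.moment == "CWM"].iloc[0]
        lo, hi = stats.t.interval(
            0.95, len(vals) - 1, loc=np.mean(vals), scale=stats.sem(vals)
        )
        assert row.ci_low == pytest.approx(lo)
        assert row.ci_high == pytest.approx(hi)

    def test_t_interval_false_positive_rate(self):
        # under a zero-mean Gaussian the 95% interval should exclude zero
        # in about 5% of repetitions
        rng = np.random.default_rng(23)
        reps = 4000
        hits = 0
        for _ in range(reps):
            out = summarize_moments(
                self._moments_frame(rng.normal(size=10)), moment_names=("CWM",)
            )
            hits += bool(out.iloc[0].differs_from_zero)
        rate = hits / reps
        assert 0.035 < rate < 0.065
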