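"""Odds ratios, heterogeneity shares, summary tables, DIC comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lanelogit as ll
from lanelogit.model import DICResult
from lanelogit.reference import MODELS, SHARE_CLAIMS
from lanelogit.validation import or_tolerance


class TestOddsRatio:
    @pytest.mark.parametrize(
        "mean, expected",
        [(1.822, 6.184), (0.0, 1.0), (4.140, 62.803)],
    )
    def test_published_values(self, mean, expected):
        assert ll.odds_ratio(mean) == pytest.approx(expected, abs=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(-5, 5, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
    )
    def test_multiplicative_and_increasing(self, a, b):
        assert ll.odds_ratio(a + b) == pytest.approx(
            ll.odds_ratio(a) * ll.odds_ratio(b), rel=1e-12
        )
        if a + 1e-9 < b:  # strictly separated beyond float resolution
            assert ll.odds_ratio(a) < ll.odds_ratio(b)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ll.odds_ratio(float("nan"))


class TestHeterogeneityShare:
    def test_middle_aged_published_split(self):
        """Mean -0.088, SD 0.079: 86.74% of riders carry a negative effect."""
        pos, neg = ll.heterogeneity_share(-0.088, 0.079)
        assert neg * 100 == pytest.approx(86.74, abs=0.1)

    def test_shared_lane_old_rider_split(self):
        pos, neg = ll.heterogeneity_share(-0.340, 0.116)
        assert neg * 100 == pytest.approx(99.83, abs=0.1)

    def test_zero_mean_splits_evenly(self):
        assert ll.heterogeneity_share(0.0, 2.7) == (0.5, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-3, 3, allow_nan=False), st.floats(0.01, 3, allow_nan=False))
    def test_mirror_symmetry(self, mu, sigma):
        pos, neg = ll.heterogeneity_share(mu, sigma)
        pos_m, neg_m = ll.heterogeneity_share(-mu, sigma)
        assert pos == pytest.approx(neg_m, abs=1e-12)
        assert neg == pytest.approx(pos_m, abs=1e-12)
        assert pos + neg == pytest.approx(1.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ll.heterogeneity_share(0.5, 0.0)


class TestPublishedTableRegression:
    def test_every_printed_or_equals_exp_mean(self):
        """Across all published per-facility and pooled tables, the printed
        odds ratio round-trips from the printed posterior mean to 0.001, up
        to what three-decimal rounding of both numbers can guarantee."""
        checked = 0
        for model, rows in MODELS.items():
            for row in rows:
                if row.odds_ratio is None:
                    continue
                assert math.exp(row.mean) == pytest.approx(
                    row.odds_ratio, abs=or_tolerance(row.odds_ratio)
                ), (model, row.label)
                checked += 1
        assert checked == 94

    def test_checkable_shares_reproduce_from_printed_moments(self):
        rows = {(m, r.label): r for m, rl in MODELS.items() for r in rl}
        checked = 0
        for claim in SHARE_CLAIMS:
            if not claim.checkable:
                continue
            row = rows[(claim.model, claim.label)]
            pos, neg = ll.heterogeneity_share(row.mean, row.random_sd[0])
            value = (pos if claim.side == "pos" else neg) * 100
            assert value == pytest.approx(claim.printed_pct, abs=0.1), (claim.model, claim.label)
            checked += 1
        assert checked == 21


class TestSummarize:
    def _draws(self, mu, sigma2=None, random_set=()):
        chains, n_draws, k = mu.shape
        if sigma2 is None:
            sigma2 = np.zeros((chains, n_draws, 0))
        return ll.PosteriorDraws(
            columns=["intercept", "x:1 vs 0"][:k], random_set=list(random_set),
            mu=mu, sigma2=sigma2, deviance=np.zeros((chains, n_draws)),
            beta_mean=np.zeros((1, len(random_set))), n_obs=1,
        )

    def test_constant_draws(self):
        mu = np.full((2, 40, 2), 0.7)
        table = ll.summarize(self._draws(mu))
        row = table[table.parameter == "x:1 vs 0"].iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert row["sd"] == pytest.approx(0.0)
        assert (row["q2.5"], row["q97.5"]) == (pytest.approx(0.7), pytest.approx(0.7))
        assert row["odds_ratio"] == pytest.approx(math.exp(0.7))

    def test_normal_draws_recover_moments(self):
        rng = np.random.default_rng(27)
        mu = 0.6 + 0.1 * rng.standard_normal((2, 50_000, 1))
        table = ll.summarize(self._draws(mu[:, :, :1]))
        row = table.iloc[0]
        n = mu.size
        assert row["mean"] == pytest.approx(0.6, abs=3 * 0.1 / np.sqrt(n))
        assert row["sd"] == pytest.approx(0.1, rel=0.02)
        assert row["q2.5"] == pytest.approx(0.6 - 1.96 * 0.1, abs=0.005)
        assert row["q97.5"] == pytest.approx(0.6 + 1.96 * 0.1, abs=0.005)

    def test_identical_chains_pool_to_single_chain_summary(self):
        rng = np.random.default_rng(28)
        one = rng.standard_normal((1, 4_000, 2))
        both = np.concatenate([one, one])
        t1 = ll.summarize(self._draws(one))
        t2 = ll.summarize(self._draws(both))
        np.testing.assert_allclose(t1["mean"], t2["mean"], atol=1e-12)
        # empirical quantiles interpolate between order statistics, so the
        # duplicated sample can differ by at most one inter-draw gap
        for col in ["q2.5", "q97.5"]:
            np.testing.assert_allclose(t1[col], t2[col], atol=0.02)

    def test_random_coefficient_reports_shares(self):
        rng = np.random.default_rng(29)
        mu = 0.5 + 0.05 * rng.standard_normal((2, 2_000, 2))
        sigma2 = (0.3 + 0.02 * rng.standard_normal((2, 2_000, 1))) ** 2
        table = ll.summarize(self._draws(mu, sigma2, random_set=("x:1 vs 0",)))
        row = table[table.parameter == "x:1 vs 0"].iloc[0]
        assert row["share_positive"] + row["share_negative"] == pytest.approx(1.0)
        expected_pos, _ = ll.heterogeneity_share(row["mean"], row["sigma_mean"])
        assert row["share_positive"] == pytest.approx(expected_pos)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ll.summarize(self._draws(np.zeros((2, 0, 2))))


class TestCompareModels:
    def test_published_dic_pair_excludes_higher(self):
        """DICs 33,230 vs 33,210 differ by 20: the higher-DIC model goes."""
        a = DICResult(dbar=33_210.0, dhat=33_210.0)
        b = DICResult(dbar=33_230.0, dhat=33_230.0)
        cmp = ll.compare_models(a, b, "random", "fixed")
        assert cmp.difference == pytest.approx(20.0)
        assert cmp.preferred == "random"
        assert "exclude" in cmp.verdict

    def test_equal_dic_no_exclusion(self):
        cmp = ll.compare_models(DICResult(100, 95), DICResult(100, 95))
        assert cmp.preferred is None

    def test_difference_exactly_ten_is_no_exclusion(self):
        cmp = ll.compare_models(DICResult(100, 100), DICResult(110, 110))
        assert cmp.preferred is None
        assert cmp.verdict == "no exclusion"

    def test_mismatched_fingerprints_rejected(self):
        a = DICResult(100, 95, fingerprint="aa")
        b = DICResult(100, 95, fingerprint="bb")
        with pytest.raises(ValueError, match="different datasets"):
            ll.compare_models(a, b)
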