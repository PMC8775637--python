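"""Synthetic-data generator: frequencies, outcome model, determinism, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import lanelogit as ll
from lanelogit.reference import CATEGORY_COUNTS, N_TOTAL
from lanelogit.synthetic import DEFAULT_SITES, GEOMETRY_VARIABLES


class TestSampleCovariates:
    def test_marginal_frequencies_converge(self, scheme):
        """At n=1e5 every category frequency is within 1% of its target;
        in particular the male share approaches the observed 48.0%."""
        obs = ll.sample_covariates(scheme, 100_000, seed=7)
        male = (obs.covariates["gender"] == "male").mean()
        assert abs(male - 16_617 / N_TOTAL) < 0.01
        for var, counts in CATEGORY_COUNTS.items():
            freqs = obs.covariates[var].value_counts(normalize=True)
            for cat, cnt in counts.items():
                assert abs(freqs.get(cat, 0.0) - cnt / N_TOTAL) < 0.01, (var, cat)

    def test_degenerate_scheme_yields_identical_rows(self):
        scheme = ll.CovariateScheme(
            categories={"gender": ("female",), "workday": ("yes",)},
            probabilities={"gender": np.array([1.0]), "workday": np.array([1.0])},
        )
        obs = ll.sample_covariates(scheme, 50, seed=0)
        assert (obs.covariates.nunique() == 1).all()

    def test_same_seed_is_bitwise_identical(self, scheme):
        a = ll.sample_covariates(scheme, 500, seed=3)
        b = ll.sample_covariates(scheme, 500, seed=3)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)

    def test_adding_a_variable_does_not_perturb_others(self, scheme):
        full = ll.sample_covariates(scheme, 200, seed=9).covariates
        reduced_scheme = ll.CovariateScheme(
            categories={"gender": scheme.categories["gender"]},
            probabilities={"gender": scheme.probabilities["gender"]},
        )
        reduced = ll.sample_covariates(reduced_scheme, 200, seed=9).covariates
        assert (full["gender"] == reduced["gender"]).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ll.CovariateScheme(
                categories={"gender": ("female", "male")},
                probabilities={"gender": np.array([0.6, 0.6])},
            )

    def test_n_zero_rejected(self, scheme):
        with pytest.raises(ValueError):
            ll.sample_covariates(scheme, 0, seed=0)

    def test_site_block_mode_ties_geometry_to_sites(self):
        obs = ll.sample_covariates(ll.default_scheme(site_block=True), 3000, seed=1)
        profiles = {
            (p.dividing_strip, p.bike_lane_width, p.vehicle_lanes, p.on_street_parking)
            for p in DEFAULT_SITES
        }
        observed = set(
            map(tuple, obs.covariates[list(GEOMETRY_VARIABLES)].itertuples(index=False))
        )
        assert observed <= profiles


class TestSimulateOutcomes:
    def test_zero_coefficients_give_half_occupancy(self, scheme):
        n = 20_000
        covs = ll.sample_covariates(scheme, n, seed=11)
        covs.covariates = covs.covariates[["gender"]]
        ds = ll.simulate_outcomes(covs, ll.TrueModel(mu={}, seed=11))
        assert abs(ds.observations.y.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_intercept_only_matches_observed_occupancy_rate(self, scheme):
        """An intercept at logit(0.2864) reproduces the observed 28.64%
        occupancy share within Monte-Carlo error."""
        n = 50_000
        covs = ll.sample_covariates(scheme, n, seed=12)
        covs.covariates = covs.covariates[["gender"]]
        truth = ll.TrueModel(mu={"intercept": float(logit(0.2864))}, seed=12)
        ds = ll.simulate_outcomes(covs, truth)
        assert abs(ds.observations.y.mean() - 0.2864) < 3 * np.sqrt(0.2864 * 0.7136 / n)

    def test_realized_coefficient_variance_matches_sigma(self, scheme):
        n = 20_000
        covs = ll.sample_covariates(scheme, n, seed=13)
        covs.covariates = covs.covariates[["gender"]]
        truth = ll.TrueModel(
            mu={"gender:male vs female": 0.4}, sigma={"gender:male vs female": 0.5}, seed=13
        )
        ds = ll.simulate_outcomes(covs, truth)
        j = ds.design.column_index("gender:male vs female")
        var = ds.realized_beta[:, j].var(ddof=1)
        assert abs(var - 0.25) < 4 * 0.25 * np.sqrt(2 / n)

    def test_outcome_mean_matches_stored_probabilities(self, small_dataset):
        n = small_dataset.n
        assert abs(small_dataset.observations.y.mean() - small_dataset.p.mean()) < 4 * np.sqrt(
            0.25 / n
        )

    def test_unknown_truth_label_names_column(self, scheme):
        covs = ll.sample_covariates(scheme, 10, seed=1)
        covs.covariates = covs.covariates[["gender"]]
        truth = ll.TrueModel(mu={"bike_type:e_bike vs c_bike": 1.0}, seed=1)
        with pytest.raises(ValueError, match="bike_type:e_bike vs c_bike"):
            ll.simulate_outcomes(covs, truth)

    def test_group_level_heterogeneity_shared_within_group(self, scheme):
        covs = ll.sample_covariates(scheme, 200, seed=14)
        covs.covariates = covs.covariates[["gender"]]
        truth = ll.TrueModel(mu={}, sigma={"intercept": 1.0}, seed=14)
        groups = np.arange(200) % 10
        ds = ll.simulate_outcomes(covs, truth, groups=groups)
        for grp in range(10):
            vals = ds.realized_beta[groups == grp, 0]
            assert np.ptp(vals) == 0.0
        assert len(np.unique(ds.realized_beta[:, 0])) == 10


class TestDatasetIO:
    def test_round_trip_preserves_observations(self, small_dataset, tmp_path):
        path = ll.write_dataset(small_dataset, tmp_path / "ds.csv")
        loaded = ll.read_dataset(path)
        pd.testing.assert_frame_equal(
            loaded.to_frame(), small_dataset.observations.to_frame(), check_dtype=False
        )

    def test_truth_saved_alongside(self, small_dataset, tmp_path):
        path = ll.write_dataset(small_dataset, tmp_path / "ds.csv")
        truth_file = path.with_suffix(".csv.truth.json")
        assert truth_file.exists()

    def test_column_order_stable(self, small_dataset, tmp_path):
        p1 = ll.write_dataset(small_dataset, tmp_path / "a.csv")
        p2 = ll.write_dataset(small_dataset, tmp_path / "b.csv")
        assert p1.read_text() == p2.read_text()

    def test_bad_outcome_value_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("occupying,gender\n1,male\n2,female\n")
        with pytest.raises(ValueError, match=r"\b1\b"):
            ll.read_dataset(path)
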