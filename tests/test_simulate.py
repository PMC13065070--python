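"""Synthetic cohort generator: determinism, closure, round-trips, recovery."""

import numpy as np
import pandas as pd
import pytest

import timeuse_coda as tc
from timeuse_coda.errors import ConfigurationError, PreconditionError

from conftest import analytic_from_cohort


class TestCovariates:
    def test_degenerate_distribution(self):
        truth = tc.weekday_truth(seed=1)
        truth.covariate_freqs["sex"] = {"female": 1.0}
        covs = tc.generate_covariates(truth, 10)
        assert (covs["sex"] == "female").all()

    def test_seeded_reproducibility(self):
        t1 = tc.weekday_truth(seed=33)
        t2 = tc.weekday_truth(seed=33)
        pd.testing.assert_frame_equal(
            tc.generate_covariates(t1, 50), tc.generate_covariates(t2, 50)
        )

    def test_marginal_frequency_at_large_n(self):
        covs = tc.generate_covariates(tc.weekday_truth(seed=12), 20000)
        prop_female = (covs["sex"] == "female").mean()
        assert abs(prop_female - 0.542) < 0.01

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ConfigurationError):
            tc.weekday_truth(covariate_freqs={"sex": {"female": 0.8, "male": 0.1}})


class TestGridRounding:
    def test_largest_remainder_hand_example(self):
        x = np.array([897.0, 23.0, 143.0, 50.0, 61.0, 266.0])
        out = tc.round_to_grid(x)
        # remainders .7, .3, .3, 0, .1, .6 -> two leftover units go to
        # sleep (.7) and domestic (.6)
        assert out.tolist() == [900.0, 20.0, 140.0, 50.0, 60.0, 270.0]

    def test_rows_sum_exactly_to_1440(self):
        rng = np.random.default_rng(3)
        x = rng.dirichlet(np.ones(6), size=500) * 1440.0
        out = tc.round_to_grid(x)
        assert (out.sum(axis=1) == 1440.0).all()
        assert np.all(np.mod(out, 10.0) == 0.0)

    def test_ties_broken_by_part_order(self):
        # equal remainders: first parts get the leftover units
        x = np.array([725.0, 715.0, 0.0, 0.0])
        out = tc.round_to_grid(x)
        assert out.tolist() == [730.0, 710.0, 0.0, 0.0]


class TestCompositions:
    def test_zero_variance_returns_rounded_target(self):
        truth = tc.weekday_truth(seed=4, ilr_scale=np.zeros((5, 5)))
        comps = tc.generate_compositions(truth, 3)
        expected = tc.round_to_grid(
            np.array(list(truth.target_geometric_mean.values()))
        )
        for i in range(3):
            assert comps.iloc[i].tolist() == expected.tolist()

    def test_every_composition_closes_to_1440(self):
        truth = tc.weekday_truth(seed=5)
        comps = tc.generate_compositions(truth, 200)
        assert (comps.sum(axis=1) == 1440.0).all()
        assert (comps.to_numpy() >= 0).all()

    def test_structural_zeros_arise_from_the_grid(self):
        truth = tc.weekday_truth(seed=6)
        comps = tc.generate_compositions(truth, 500)
        assert (comps.to_numpy() == 0).any()

    def test_geometric_mean_recovery_at_moderate_spread(self):
        truth = tc.weekday_truth(seed=7, ilr_scale=np.eye(5) * 0.09)
        comps = tc.generate_compositions(truth, 5000)
        gm = tc.compositional_mean(tc.multiplicative_zero_replace(comps, 5.0))
        target = pd.Series(truth.target_geometric_mean)
        assert (np.abs(gm - target) / target).max() < 0.05

    def test_non_psd_scale_rejected(self):
        bad = -np.eye(5)
        with pytest.raises(ConfigurationError):
            tc.weekday_truth(ilr_scale=bad)

    def test_seeded_reproducibility(self):
        a = tc.generate_compositions(tc.weekday_truth(seed=42), 20)
        b = tc.generate_compositions(tc.weekday_truth(seed=42), 20)
        pd.testing.assert_frame_equal(a, b)


class TestOutcome:
    def test_pure_intercept_when_all_effects_zero(self):
        truth = tc.weekday_truth(
            seed=8, noise_sd=0.0, beta_ilr=(0.0,) * 5,
            beta_cov={}, intercept=47.5,
        )
        cohort = tc.generate_cohort(truth, 25)
        assert np.allclose(cohort.outcomes["attainment8"], 47.5)

    def test_zero_composition_rejected(self):
        truth = tc.weekday_truth(seed=9)
        covs = tc.generate_covariates(truth, 4)
        comps = pd.DataFrame(
            [[900.0, 0.0, 200.0, 50.0, 60.0, 230.0]] * 4,
            columns=list(truth.parts),
        )
        with pytest.raises(PreconditionError, match="zero replacement"):
            tc.generate_outcome(comps, covs, truth)

    def test_noiseless_refit_recovers_generating_coefficients(self):
        truth = tc.weekday_truth(seed=10, noise_sd=0.0)
        cohort = tc.generate_cohort(truth, 300)
        fit = tc.fit_outcome_model(analytic_from_cohort(cohort), truth.basis())
        assert np.max(np.abs(fit.beta_ilr - np.array(truth.beta_ilr))) < 1e-8

    def test_clipping_off_by_default_and_flagged_when_on(self):
        truth = tc.weekday_truth(seed=11, intercept=150.0, noise_sd=0.0,
                                 beta_ilr=(0.0,) * 5, beta_cov={})
        cohort = tc.generate_cohort(truth, 5)
        assert (cohort.outcomes["attainment8"] > 90).all()
        clipped = tc.weekday_truth(seed=11, intercept=150.0, noise_sd=0.0,
                                   beta_ilr=(0.0,) * 5, beta_cov={},
                                   clip_outcome=True)
        with pytest.warns(UserWarning, match="clipping"):
            cohort2 = tc.generate_cohort(clipped, 5)
        assert (cohort2.outcomes["attainment8"] == 90.0).all()


class TestDiaryExpansion:
    def test_all_sleep_day_fills_144_slots(self, mapping):
        truth = tc.weekday_truth(seed=12)
        comp = pd.Series(
            {p: 1440.0 if p == "sleep" else 0.0 for p in truth.parts}
        )
        d = tc.expand_to_diary(comp, truth, mapping)
        assert all(mapping.set_of(c) == "sleep" for c in d.slots)

    def test_roundtrip_without_corruption(self, mapping):
        truth = tc.weekday_truth(seed=13)
        comps = tc.generate_compositions(truth, 25)
        for i in range(len(comps)):
            d = tc.expand_to_diary(comps.iloc[i], truth, mapping)
            back = tc.recode_diary(d, mapping)
            assert back.tolist() == comps.iloc[i].tolist()

    def test_off_grid_part_rejected(self, mapping):
        truth = tc.weekday_truth(seed=14)
        comp = pd.Series(
            {p: 1435.0 if p == "sleep" else 0.0 for p in truth.parts}
        )
        comp["media"] = 5.0
        with pytest.raises(PreconditionError):
            tc.expand_to_diary(comp, truth, mapping)

    def test_certain_missingness_fails_validation(self, mapping):
        truth = tc.weekday_truth(seed=15, missing_slot_rate=1.0)
        comps = tc.generate_compositions(truth, 1)
        d = tc.expand_to_diary(comps.iloc[0], truth, mapping)
        res = tc.validate_diary(d, mapping)
        assert not res.valid
        assert res.reason is tc.InvalidReason.MISSING_DATA

    def test_sleep_relabelling_trips_no_sleep_filter(self, mapping):
        truth = tc.weekday_truth(seed=16, zero_sleep_rate=1.0)
        comps = tc.generate_compositions(truth, 1)
        d = tc.expand_to_diary(comps.iloc[0], truth, mapping)
        assert tc.validate_diary(d, mapping).reason is tc.InvalidReason.NO_SLEEP


class TestCohort:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        for sub in ("a", "b"):
            truth = tc.weekend_truth(seed=77)
            tc.generate_cohort(truth, 15, day_type="weekend").write(tmp_path / sub)
        for name in ("diaries.csv", "covariates.csv", "outcomes.csv",
                     "compositions.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_weekend_cohort_roundtrip_through_subcomposition(self, mapping):
        truth = tc.weekend_truth(seed=78)
        cohort = tc.generate_cohort(truth, 20, day_type="weekend")
        table, _ = tc.build_analytic_sample(
            cohort.diaries, cohort.covariates, cohort.outcomes, "weekend"
        )
        merged = table.set_index("participant_id")
        src = cohort.compositions.set_index("participant_id")
        for pid in merged.index:
            assert np.allclose(
                merged.loc[pid, list(tc.WEEKEND_PARTS)],
                src.loc[pid, list(tc.WEEKEND_PARTS)],
            )

    def test_mismatched_parts_rejected(self):
        with pytest.raises(ConfigurationError):
            tc.generate_cohort(tc.weekday_truth(seed=1), 5, day_type="weekend")
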