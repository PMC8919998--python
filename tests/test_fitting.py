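"""Coefficient estimation and grouped cross-validation."""

import numpy as np
import pandas as pd
import pytest

from lcda_backpack.fitting import (
    FitOptions,
    NonIdentifiableDesignError,
    cross_validate,
    fit_backpacking_model,
    kfold_split,
)
from lcda_backpack.models import LCDA_BACKPACKING_2022, ModelCoefficients
from lcda_backpack.synthetic_data import NoiseModel, generate_study

TRUTH = LCDA_BACKPACKING_2022.as_array()


def perturbed_init(seed: int) -> ModelCoefficients:
    rng = np.random.default_rng(seed)
    theta = np.clip(TRUTH * rng.uniform(0.5, 1.5, 6),
                    [-10, 0, 0.1, 0, 0, 0.5], [10, 20, 1, 10, 20, 3])
    return ModelCoefficients.from_array(theta)


class TestKFoldSplit:
    def test_study_design_split(self):
        pairs = [(f"F{i}", "female") for i in range(3)] + [
            (f"M{i}", "male") for i in range(27)
        ]
        folds = kfold_split(pairs, k=3, seed=0)
        for f in (1, 2, 3):
            members = folds.members(f)
            females = [m for m in members if m.startswith("F")]
            assert len(females) == 1 and len(members) == 10

    def test_deterministic_given_seed(self):
        pairs = [(f"M{i}", "male") for i in range(12)]
        assert kfold_split(pairs, k=3, seed=9).mapping == kfold_split(pairs, k=3, seed=9).mapping

    def test_balanced_partition_sizes(self):
        pairs = [(f"M{i}", "male") for i in range(5)]
        folds = kfold_split(pairs, k=2, seed=1)
        sizes = sorted(len(folds.members(f)) for f in (1, 2))
        assert sizes == [2, 3]

    def test_k_exceeding_participants_rejected(self):
        with pytest.raises(ValueError):
            kfold_split([("a", "male"), ("b", "male")], k=3)

    def test_female_round_robin_generalizes(self):
        pairs = [(f"F{i}", "female") for i in range(5)] + [
            (f"M{i}", "male") for i in range(7)
        ]
        folds = kfold_split(pairs, k=4, seed=3)
        female_counts = sorted(
            sum(m.startswith("F") for m in folds.members(f)) for f in range(1, 5)
        )
        assert max(female_counts) - min(female_counts) <= 1


class TestFit:
    def test_noise_free_round_trip_recovers_coefficients(self, noise_free_study):
        _, trials, _, m_rest = noise_free_study
        fit = fit_backpacking_model(trials, m_rest, init=perturbed_init(1))
        rel = np.abs(fit.coefficients.as_array() / TRUTH - 1.0)
        assert rel.max() <= 1e-6
        assert fit.converged
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_row_order_invariance(self, default_study):
        _, trials, _, m_rest = default_study
        fit1 = fit_backpacking_model(trials, m_rest, init=perturbed_init(2))
        shuffled = trials.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = fit_backpacking_model(shuffled, m_rest, init=perturbed_init(2))
        # identical up to the solver's own tolerance (row order changes the
        # floating-point summation order inside the trust-region steps)
        np.testing.assert_allclose(
            fit1.coefficients.as_array(), fit2.coefficients.as_array(), rtol=1e-6
        )

    def test_variance_components_recovered(self, default_study):
        _, trials, truth, m_rest = default_study
        fit = fit_backpacking_model(trials, m_rest, init=perturbed_init(3))
        assert fit.residual_sd == pytest.approx(truth["noise"]["residual_sd"], rel=0.25)
        assert fit.participant_intercept_sd == pytest.approx(
            truth["noise"]["participant_intercept_sd"], rel=0.60
        )

    def test_common_intercept_shift_absorbed_without_degrading_fit(self, default_study):
        """A constant shift of every participant's level is soaked up by the
        fixed surface and intercepts together: the fitted values track the
        shift and the fit quality is unchanged.  (No zero-mean random-
        intercept estimator can keep the fixed coefficients exactly fixed
        under a common shift, since intercepts are shrunk toward zero.)"""
        _, trials, _, m_rest = default_study
        shift = 0.3
        shifted = trials.assign(m_wkg=trials["m_wkg"] + shift)
        base = fit_backpacking_model(trials, m_rest, init=perturbed_init(4))
        moved = fit_backpacking_model(shifted, m_rest, init=perturbed_init(4))
        assert moved.residual_sd == pytest.approx(base.residual_sd, rel=0.05)

        def fitted_values(fit, table):
            from lcda_backpack.models import predict_metabolic_rate

            u = table["participant_id"].map(fit.random_intercepts).to_numpy()
            return (
                predict_metabolic_rate(
                    table["participant_id"].map(m_rest).to_numpy(),
                    table["speed_mps"].to_numpy(),
                    table["load_fraction"].to_numpy(),
                    coeffs=fit.coefficients,
                )
                + u
            )

        delta = fitted_values(moved, shifted) - fitted_values(base, trials)
        assert delta.mean() == pytest.approx(shift, abs=0.05)

    def test_zero_mean_intercept_draws_leave_coefficients_stable(self, default_study):
        """Re-drawing zero-mean participant offsets perturbs the fixed
        coefficients only within their sampling noise."""
        _, trials, _, m_rest = default_study
        rng = np.random.default_rng(42)
        ids = trials["participant_id"].to_numpy()
        uniq = np.unique(ids)
        offsets = dict(zip(uniq, rng.normal(0.0, 0.35, uniq.size)))
        bumped = trials.assign(
            m_wkg=trials["m_wkg"] + trials["participant_id"].map(offsets)
        )
        base = fit_backpacking_model(trials, m_rest, init=perturbed_init(4))
        moved = fit_backpacking_model(bumped, m_rest, init=perturbed_init(4))
        np.testing.assert_allclose(
            base.coefficients.as_array(), moved.coefficients.as_array(), atol=0.15
        )

    def test_monotone_descent_within_rounds(self, default_study):
        _, trials, _, m_rest = default_study
        fit = fit_backpacking_model(trials, m_rest, init=perturbed_init(5))
        for round_info in fit.trace:
            assert round_info["objective_after"] <= round_info["objective_before"] + 1e-9

    def test_estimator_consistency_direction(self):
        """Estimate dispersion shrinks when residual noise is halved."""

        def dispersion(residual_sd: float) -> float:
            ests = []
            for r in range(10):
                parts, trials, _ = generate_study(
                    seed=100 + r,
                    noise=NoiseModel(residual_sd=residual_sd,
                                     participant_intercept_sd=0.35),
                )
                m_rest = {p.id: p.resting_rate for p in parts}
                fit = fit_backpacking_model(trials, m_rest, init=perturbed_init(200 + r))
                ests.append(fit.coefficients.as_array())
            ests = np.array(ests)
            return float(np.sum(ests.std(axis=0) / TRUTH))

        assert dispersion(0.225) < dispersion(0.45)

    def test_non_identifiable_designs_rejected(self, default_study):
        parts, trials, _, m_rest = default_study
        single_load = trials[trials["load_fraction"] == 0.44]
        with pytest.raises(NonIdentifiableDesignError):
            fit_backpacking_model(single_load, m_rest)
        single_speed = trials[trials["speed_mps"] == 1.34]
        with pytest.raises(NonIdentifiableDesignError):
            fit_backpacking_model(single_speed, m_rest)
        one_person = trials[trials["participant_id"] == parts[0].id]
        with pytest.raises(NonIdentifiableDesignError):
            fit_backpacking_model(one_person, {parts[0].id: m_rest[parts[0].id]})


class TestCrossValidate:
    def test_noise_free_folds_are_perfect(self, noise_free_study):
        _, trials, _, m_rest = noise_free_study
        reports, pooled, _ = cross_validate(
            trials, m_rest, k=3, seed=1, n_boot=200
        )
        for rep in reports:
            assert rep.bias == pytest.approx(0.0, abs=1e-6)
            assert rep.ccc == pytest.approx(1.0, abs=1e-9)
        assert pooled.bias == pytest.approx(0.0, abs=1e-6)

    def test_default_noise_folds_reach_equivalence(self, default_study):
        _, trials, _, m_rest = default_study
        reports, pooled, folds = cross_validate(trials, m_rest, k=3, seed=2, n_boot=500)
        assert len(reports) == 3
        for rep in reports:
            lo, hi = rep.ci90
            assert -rep.equivalence_limit < lo and hi < rep.equivalence_limit
            assert rep.tost_passed
        assert pooled.tost_passed

    def test_subject_level_separation(self, default_study):
        parts, trials, _, m_rest = default_study
        reports, pooled, folds = cross_validate(trials, m_rest, k=3, seed=3, n_boot=100)
        all_members = [m for f in (1, 2, 3) for m in folds.members(f)]
        assert sorted(all_members) == sorted(p.id for p in parts)
        assert pooled.n_pairs == len(trials)

    def test_leave_one_subject_out_boundary(self):
        parts, trials, _ = generate_study(
            seed=50,
            noise=NoiseModel(residual_sd=0.2, participant_intercept_sd=0.1),
        )
        m_rest = {p.id: p.resting_rate for p in parts}
        keep = [p.id for p in parts[:5]]
        small = trials[trials["participant_id"].isin(keep)]
        reports, pooled, _ = cross_validate(
            small, m_rest, participants=[p for p in parts[:5]], k=5, seed=4, n_boot=100
        )
        assert len(reports) == 5
        assert {rep.n_participants for rep in reports} == {1}
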