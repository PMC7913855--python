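"""Affine estimation of non-recorded angles: OLS fit, application, scoring."""

import numpy as np
import pytest

from handsyn import (
    LinearEstimatorBank,
    RepresentativeSet,
    estimate_angles,
    fit_estimators,
    rmse,
    score_and_select,
)
from handsyn.dof import DOF_NAMES, dof_index
from handsyn.errors import DegenerateDesignError, ParameterError
from handsyn.estimation import estimate_from_full

REP = RepresentativeSet(
    ["CMC1F", "CMC1A", "MCP1F", "IP1F", "PIP2F", "PalmArch"], ["PIP4F", "MCP4F"]
)


def _frames(rng, n=500, rep_set=REP):
    """Random full-rank frames with the representative columns independent."""
    X = rng.normal(loc=20, scale=10, size=(n, 16))
    return X


class TestFitEstimators:
    def test_exact_affine_target_recovered(self, rng):
        """target = 2*rep1 - rep2 + 5 exactly: intercept 5, coefficients
        (2, -1, 0, ...), zero residual."""
        frames = _frames(rng)
        rep = REP.labels
        target = "MCP2F"
        frames[:, dof_index(target)] = (
            5.0
            + 2.0 * frames[:, dof_index(rep[0])]
            - 1.0 * frames[:, dof_index(rep[1])]
        )
        bank = fit_estimators(REP, frames)
        j = bank.estimated_labels.index(target)
        assert bank.intercepts[j] == pytest.approx(5.0, abs=1e-8)
        expected = np.zeros(len(rep))
        expected[0], expected[1] = 2.0, -1.0
        assert np.allclose(bank.coefficients[j], expected, atol=1e-8)
        est = estimate_from_full(bank, frames)
        assert rmse(est[:, j], frames[:, dof_index(target)]) < 1e-8

    def test_constant_target_gives_intercept_only(self, rng):
        frames = _frames(rng)
        frames[:, dof_index("MCP3F")] = 12.0
        bank = fit_estimators(REP, frames)
        j = bank.estimated_labels.index("MCP3F")
        assert bank.intercepts[j] == pytest.approx(12.0, abs=1e-8)
        assert np.allclose(bank.coefficients[j], 0.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS solution equals the closed-form (X'X)^-1 X'y on a small
        instance."""
        frames = _frames(rng, n=1000)
        bank = fit_estimators(REP, frames)
        rep_idx = [dof_index(n) for n in bank.representative_labels]
        X = np.column_stack([np.ones(1000), frames[:, rep_idx]])
        for j, name in enumerate(bank.estimated_labels):
            y = frames[:, dof_index(name)]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert bank.intercepts[j] == pytest.approx(beta[0], abs=1e-8)
            assert np.allclose(bank.coefficients[j], beta[1:], atol=1e-8)

    def test_fitted_coefficients_are_a_local_minimum(self, rng):
        """Perturbing any coefficient by +-1e-3 never lowers the summed
        squared error (OLS optimality)."""
        frames = _frames(rng, n=300)
        bank = fit_estimators(REP, frames)
        rep_idx = [dof_index(n) for n in bank.representative_labels]
        X = np.column_stack([np.ones(300), frames[:, rep_idx]])
        j = 0
        y = frames[:, dof_index(bank.estimated_labels[j])]
        beta = np.concatenate([[bank.intercepts[j]], bank.coefficients[j]])
        base = np.sum((X @ beta - y) ** 2)
        for k in range(beta.size):
            for delta in (1e-3, -1e-3):
                pert = beta.copy()
                pert[k] += delta
                assert np.sum((X @ pert - y) ** 2) >= base - 1e-9

    def test_beats_intercept_only_predictor(self, rng):
        frames = _frames(rng, n=400)
        bank = fit_estimators(REP, frames)
        est = estimate_from_full(bank, frames)
        for j, name in enumerate(bank.estimated_labels):
            y = frames[:, dof_index(name)]
            assert rmse(est[:, j], y) <= rmse(np.full_like(y, y.mean()), y) + 1e-12

    def test_collinear_design_raises_degenerate(self, rng):
        frames = _frames(rng)
        frames[:, dof_index("MCP4F")] = 2.0 * frames[:, dof_index("PIP4F")]
        with pytest.raises(DegenerateDesignError):
            fit_estimators(REP, frames)

    def test_parameter_recovery_under_vanishing_noise(self, rng):
        """Coefficients of a known affine map are recovered to < 1e-3 at
        noise SD 1e-4 with 10,000 frames."""
        n = 10_000
        frames = rng.normal(loc=15, scale=8, size=(n, 16))
        rep_idx = [dof_index(l) for l in REP.labels]
        true_coef = rng.normal(scale=0.5, size=len(rep_idx))
        target = "PIP5F"
        frames[:, dof_index(target)] = (
            3.0 + frames[:, rep_idx] @ true_coef + rng.normal(scale=1e-4, size=n)
        )
        bank = fit_estimators(REP, frames)
        j = bank.estimated_labels.index(target)
        assert np.max(np.abs(bank.coefficients[j] - true_coef)) < 1e-3
        assert abs(bank.intercepts[j] - 3.0) < 1e-3


class TestEstimateAngles:
    def _bank(self, intercepts, coefficients):
        return LinearEstimatorBank(
            representative_labels=REP.labels,
            estimated_labels=REP.estimated_labels,
            intercepts=np.asarray(intercepts, dtype=float),
            coefficients=np.asarray(coefficients, dtype=float),
        )

    def test_zero_coefficients_return_intercept(self):
        n_est, n_rep = len(REP.estimated_labels), REP.n
        bank = self._bank(np.arange(n_est, dtype=float), np.zeros((n_est, n_rep)))
        out = estimate_angles(bank, np.random.default_rng(0).normal(size=(7, n_rep)))
        assert np.allclose(out, np.arange(n_est)[None, :])

    def test_identity_like_bank_copies_column(self):
        n_est, n_rep = len(REP.estimated_labels), REP.n
        coef = np.zeros((n_est, n_rep))
        coef[0, 3] = 1.0
        bank = self._bank(np.zeros(n_est), coef)
        rep_frames = np.random.default_rng(1).normal(size=(9, n_rep))
        out = estimate_angles(bank, rep_frames)
        assert np.allclose(out[:, 0], rep_frames[:, 3])

    def test_matches_per_frame_scalar_oracle(self, rng):
        """Vectorised application equals naive frame-by-frame evaluation."""
        n_est, n_rep = len(REP.estimated_labels), REP.n
        bank = self._bank(rng.normal(size=n_est), rng.normal(size=(n_est, n_rep)))
        rep_frames = rng.normal(size=(50, n_rep))
        out = estimate_angles(bank, rep_frames)
        for i in range(50):
            for j in range(n_est):
                naive = bank.intercepts[j] + sum(
                    rep_frames[i, k] * bank.coefficients[j, k] for k in range(n_rep)
                )
                assert out[i, j] == pytest.approx(naive, abs=1e-9)

    def test_wrong_column_count_rejected(self):
        n_est, n_rep = len(REP.estimated_labels), REP.n
        bank = self._bank(np.zeros(n_est), np.zeros((n_est, n_rep)))
        with pytest.raises(ParameterError):
            estimate_angles(bank, np.zeros((5, n_rep + 1)))


class TestRMSE:
    def test_identical_traces_zero(self):
        v = np.arange(10.0)
        assert rmse(v, v) == 0.0

    def test_constant_offset(self):
        v = np.arange(10.0)
        assert rmse(v + 3.0, v) == pytest.approx(3.0)

    def test_mixed_errors_formula(self):
        """Errors (3, 4): sqrt((9 + 16) / 2) = 3.5355."""
        assert rmse(np.array([3.0, 4.0]), np.zeros(2)) == pytest.approx(
            3.5355, abs=1e-4
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            rmse(np.array([]), np.array([]))


class TestScoreAndSelect:
    def test_exactly_linear_system_scores_zero(self, rng):
        frames = _frames(rng, n=300)
        rep_idx = [dof_index(l) for l in REP.labels]
        for name in REP.estimated_labels:
            frames[:, dof_index(name)] = 1.0 + frames[:, rep_idx] @ np.full(
                len(rep_idx), 0.1
            )
        scores, best, bank = score_and_select([REP], frames)
        assert best is REP
        assert scores[0].mean_rmse == pytest.approx(0.0, abs=1e-8)

    def test_tie_breaks_by_enumeration_order(self, rng):
        frames = _frames(rng, n=200)
        twin = RepresentativeSet(list(REP.independent), list(REP.chosen_candidates))
        scores, best, _ = score_and_select([REP, twin], frames)
        assert best is REP
        assert scores[0].mean_rmse == pytest.approx(scores[1].mean_rmse, abs=1e-12)

    def test_lowest_mean_rmse_wins(self, rng):
        """The combination whose representatives actually generate the data
        beats an alternative choice."""
        frames = _frames(rng, n=400)
        rep_idx = [dof_index(l) for l in REP.labels]
        for name in REP.estimated_labels:
            w = rng.normal(scale=0.4, size=len(rep_idx))
            frames[:, dof_index(name)] = (
                2.0 + frames[:, rep_idx] @ w + rng.normal(scale=0.01, size=400)
            )
        other = RepresentativeSet(
            list(REP.independent), ["PIP3F", "MCP2F"]
        )
        scores, best, _ = score_and_select([other, REP], frames)
        assert best.chosen_candidates == REP.chosen_candidates
        assert scores[1].mean_rmse < scores[0].mean_rmse


def test_bank_csv_roundtrip(tmp_path, rng):
    frames = _frames(rng, n=200)
    bank = fit_estimators(REP, frames, dataset_id="unit")
    path = tmp_path / "bank.csv"
    bank.to_csv(path)
    back = LinearEstimatorBank.from_csv(path)
    assert back.representative_labels == bank.representative_labels
    assert back.estimated_labels == bank.estimated_labels
    assert np.allclose(back.intercepts, bank.intercepts, atol=1e-12)
    assert np.allclose(back.coefficients, bank.coefficients, atol=1e-12)
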