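"""ADMM solver vs. independent convex oracles, plus its contracts."""

import numpy as np
import pytest
import scipy.linalg

from dygnet import io
from dygnet.penalty import PenaltyConfig, build_penalty_matrix, build_weight_vector
from dygnet.pseudotime import CellTimeAssignment
from dygnet.solver import (
    CoefficientMatrix,
    SolverConfig,
    assemble_design,
    DesignBundle,
    fit_panel,
    fit_target,
    lambda_max_upper_bound,
    objective_value,
    threshold_coefficients,
)
from oracles import gen_lasso_dual_oracle, weighted_lasso_cd

TIGHT = SolverConfig(tol_abs=1e-9, tol_rel=1e-8, max_iter=50_000)


def random_instance(rng, p1=None, T=None, weights=None):
    """Random full-rank design with optional mixed penalty weights."""
    p1 = p1 or int(rng.integers(2, 6))
    T = T or int(rng.integers(1, 4))
    n_t = p1 + int(rng.integers(3, 10))
    X_blocks = [rng.standard_normal((n_t, p1)) for _ in range(T)]
    b_true = np.where(rng.uniform(size=(T, p1)) < 0.4, rng.standard_normal((T, p1)), 0.0)
    y_blocks = [
        X @ b_true[t] + 0.3 * rng.standard_normal(X.shape[0])
        for t, X in enumerate(X_blocks)
    ]
    if weights is None:
        weights = rng.uniform(0.25, 1.0, size=p1)
    design = DesignBundle(X_blocks, y_blocks, [f"G{j}" for j in range(p1)], "TARGET")
    D = build_penalty_matrix(weights, T)
    return design, D


def stacked(design):
    X = scipy.linalg.block_diag(*design.X_blocks)
    y = np.concatenate(design.y_blocks)
    return X, y


class TestAssembleDesign:
    @staticmethod
    def _expr_and_times(rng, n=6, p=3, T=2):
        vals = rng.standard_normal((n, p))
        vals = (vals - vals.mean(0)) / vals.std(0)
        expr = io.ExpressionMatrix(
            vals, [f"c{i}" for i in range(n)], [f"g{j}" for j in range(p)],
            "standardized",
        )
        t_hat = np.repeat(np.arange(1, T + 1), n // T)
        times = CellTimeAssignment(
            cell_ids=expr.cell_ids, t_hat=t_hat, T=T, trajectory=[]
        )
        return expr, times

    def test_blocks_and_predictor_exclusion(self, rng):
        expr, times = self._expr_and_times(rng)
        design = assemble_design(expr, times, "g0")
        assert design.T == 2
        assert all(X.shape == (3, 2) for X in design.X_blocks)
        assert "g0" not in design.predictor_ids

    def test_unassigned_cell_excluded_with_warning(self, rng):
        expr, times = self._expr_and_times(rng)
        times.t_hat = times.t_hat.copy()
        times.t_hat[0] = -1
        with pytest.warns(UserWarning, match="no time assignment"):
            design = assemble_design(expr, times, "g0")
        assert design.X_blocks[0].shape[0] == 2

    def test_empty_bin_errors(self, rng):
        expr, times = self._expr_and_times(rng)
        times.t_hat = np.ones(6, dtype=int)  # T says 2 but bin 2 empty
        with pytest.raises(ValueError, match="bin 2"):
            assemble_design(expr, times, "g0")

    def test_requires_standardized(self, rng):
        expr, times = self._expr_and_times(rng)
        expr.state = "log1p"
        with pytest.raises(ValueError, match="standardized"):
            assemble_design(expr, times, "g0")


class TestFitTarget:
    def test_lambda_above_lambda_max_zeroes_everything(self, rng):
        design, D = random_instance(rng, p1=4, T=3)
        lam = lambda_max_upper_bound(design, D.weights) * 1.01
        fit = fit_target(design, D, PenaltyConfig(lam=lam), TIGHT)
        assert np.all(np.abs(fit.b) < 1e-8)

    def test_unpenalized_limit_matches_ols(self, rng):
        # lambda -> 0 with T=1 and full-rank design reduces to OLS
        design, D = random_instance(rng, p1=3, T=1, weights=np.ones(3))
        fit = fit_target(design, D, PenaltyConfig(lam=1e-10), TIGHT)
        X, y = design.X_blocks[0], design.y_blocks[0]
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.b[0], ols, atol=1e-6)

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_objective_matches_dual_oracle(self, seed):
        rng = np.random.default_rng(seed)
        design, D = random_instance(rng)
        lam = 2.0
        fit = fit_target(design, D, PenaltyConfig(lam=lam), TIGHT)
        X, y = stacked(design)
        _, obj_oracle = gen_lasso_dual_oracle(X, y, D.D, lam)
        obj_admm = objective_value(design, D, lam, fit.b)
        assert abs(obj_admm - obj_oracle) / obj_oracle <= 1e-6

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_t1_matches_weighted_lasso_cd(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.25, 1.0, size=4)
        design, D = random_instance(rng, p1=4, T=1, weights=w)
        lam = 3.0
        fit = fit_target(design, D, PenaltyConfig(lam=lam), TIGHT)
        b_cd = weighted_lasso_cd(design.X_blocks[0], design.y_blocks[0], w, lam)
        np.testing.assert_allclose(fit.b[0], b_cd, atol=1e-5)

    def test_report_objective_consistent(self, rng):
        design, D = random_instance(rng, p1=3, T=2)
        fit = fit_target(design, D, PenaltyConfig(lam=5.0))
        recomputed = objective_value(design, D, 5.0, fit.b)
        assert fit.report.objective == pytest.approx(recomputed, abs=1e-8)

    def test_within_bin_cell_permutation_invariance(self, rng):
        design, D = random_instance(rng, p1=3, T=2)
        fit1 = fit_target(design, D, PenaltyConfig(lam=5.0), TIGHT)
        perm_blocks = []
        perm_y = []
        for X, y in zip(design.X_blocks, design.y_blocks):
            perm = rng.permutation(len(y))
            perm_blocks.append(X[perm])
            perm_y.append(y[perm])
        design2 = DesignBundle(perm_blocks, perm_y, design.predictor_ids, "TARGET")
        fit2 = fit_target(design2, D, PenaltyConfig(lam=5.0), TIGHT)
        np.testing.assert_allclose(fit1.b, fit2.b, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        design, _ = random_instance(rng, p1=3, T=2)
        D_wrong = build_penalty_matrix(np.ones(4), T=2)
        with pytest.raises(ValueError, match="penalty matrix"):
            fit_target(design, D_wrong, PenaltyConfig())

    @pytest.mark.parametrize("seed", range(31, 41))
    def test_fusion_shrinks_total_variation(self, seed):
        """Fused fit's across-time total variation never exceeds that of
        independent per-bin lasso fits at the same lambda."""
        rng = np.random.default_rng(seed)
        design, D = random_instance(rng, p1=4, T=3, weights=np.ones(4))
        lam = 4.0
        fused = fit_target(design, D, PenaltyConfig(lam=lam), TIGHT)
        tv_fused = np.abs(np.diff(fused.b, axis=0)).sum()
        per_bin = np.vstack(
            [
                weighted_lasso_cd(X, y, np.ones(4), lam)
                for X, y in zip(design.X_blocks, design.y_blocks)
            ]
        )
        tv_indep = np.abs(np.diff(per_bin, axis=0)).sum()
        assert tv_fused <= tv_indep + 1e-8

    @pytest.mark.parametrize("seed", range(51, 61))
    def test_binding_prior_never_decreases_true_effect(self, seed):
        """Setting p_ji = 1 for a true regulator lowers its penalty and
        must not shrink its fitted coefficient magnitude."""
        rng = np.random.default_rng(seed)
        p1, T = 5, 2
        n_t = 25
        X_blocks = [rng.standard_normal((n_t, p1)) for _ in range(T)]
        b_true = np.zeros((T, p1))
        b_true[:, 0] = 0.8
        y_blocks = [
            X @ b_true[t] + 0.3 * rng.standard_normal(n_t)
            for t, X in enumerate(X_blocks)
        ]
        design = DesignBundle(X_blocks, y_blocks, [f"G{j}" for j in range(p1)], "T")
        cfg = PenaltyConfig(lam=15.0)
        flat = fit_target(design, build_penalty_matrix(np.ones(p1), T), cfg, TIGHT)
        w = np.ones(p1)
        w[0] = 1.0 / cfg.eta  # p_ji = 1 for the true regulator
        informed = fit_target(design, build_penalty_matrix(w, T), cfg, TIGHT)
        assert np.abs(informed.b[:, 0]).max() >= np.abs(flat.b[:, 0]).max() - 1e-9


class TestThreshold:
    def test_small_entries_zeroed(self):
        coef = CoefficientMatrix(
            b=np.array([[0.5, 0.004, -0.3]]), intercept=0.0,
            target_id="T", predictor_ids=["a", "b", "c"],
        )
        out = threshold_coefficients(coef, 0.01)
        np.testing.assert_array_equal(out.b, [[0.5, 0.0, -0.3]])

    def test_tau_zero_is_identity(self):
        coef = CoefficientMatrix(
            b=np.array([[0.001, -0.002]]), intercept=0.0,
            target_id="T", predictor_ids=["a", "b"],
        )
        np.testing.assert_array_equal(threshold_coefficients(coef, 0.0).b, coef.b)

    def test_all_below_tau(self):
        coef = CoefficientMatrix(
            b=np.array([[0.01, -0.02]]), intercept=0.0,
            target_id="T", predictor_ids=["a", "b"],
        )
        assert np.all(threshold_coefficients(coef, 0.1).b == 0.0)


class TestFitPanel:
    @staticmethod
    def _dataset(seed=5):
        from dygnet import simulate

        truth = simulate.simulate_truth(8, 2, 2, seed=seed)
        ds = simulate.simulate_expression(truth, cells_per_bin=15, seed=seed)
        expr, _ = io.standardize(io.log1p_transform(ds.expr))
        return expr, ds.times

    def test_panel_equals_independent_fits(self):
        expr, times = self._dataset()
        targets = io.GeneSet("panel", ("G0001", "G0002"))
        cfg, scfg = PenaltyConfig(lam=5.0), SolverConfig()
        panel = fit_panel(targets, expr, times, io.BindingPriorTable(), cfg, scfg)
        for tgt in targets:
            design = assemble_design(expr, times, tgt)
            wv = build_weight_vector(tgt, design.predictor_ids, io.BindingPriorTable(), cfg)
            single = fit_target(design, build_penalty_matrix(wv, design.T), cfg, scfg)
            np.testing.assert_array_equal(panel[tgt].b, single.b)

    def test_empty_gene_set(self):
        expr, times = self._dataset()
        assert fit_panel(io.GeneSet("none", ()), expr, times, io.BindingPriorTable()) == {}

    def test_missing_target_skipped_with_warning(self):
        expr, times = self._dataset()
        targets = io.GeneSet("panel", ("G0001", "NOT_A_GENE"))
        with pytest.warns(UserWarning, match="skipping"):
            out = fit_panel(targets, expr, times, io.BindingPriorTable(),
                            PenaltyConfig(lam=5.0))
        assert set(out) == {"G0001"}

    def test_serial_vs_parallel_bit_identical(self):
        expr, times = self._dataset()
        targets = io.GeneSet("panel", ("G0001", "G0002", "G0003", "G0004"))
        cfg = PenaltyConfig(lam=5.0)
        serial = fit_panel(targets, expr, times, io.BindingPriorTable(), cfg, n_jobs=1)
        parallel = fit_panel(targets, expr, times, io.BindingPriorTable(), cfg, n_jobs=4)
        for tgt in targets:
            np.testing.assert_array_equal(serial[tgt].b, parallel[tgt].b)
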