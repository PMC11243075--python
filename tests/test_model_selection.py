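"""Leverages, VLOO scores, model ranking and the complexity scan."""

import numpy as np
import pytest

from gmshift.model_selection import (
    SelectionResult,
    complexity_scan,
    leverages,
    output_jacobian_matrix,
    rank_and_select,
    vloo_of_model,
    vloo_score,
)
from gmshift.node_model import NodeFunctionParameters, parameter_count
from gmshift.training import TrainConfig, lm_fit, multi_restart_train, predictions


def brute_force_loo_rmse_linear(x, y):
    """Exact leave-one-out RMSE of ordinary least squares by n refits."""
    n = len(y)
    errors = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta = np.linalg.lstsq(x[mask], y[mask], rcond=None)[0]
        errors[i] = y[i] - x[i] @ beta
    return float(np.sqrt(np.mean(errors**2)))


class TestLeverages:
    def test_sum_equals_q_for_full_rank(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(30, 6))
        assert leverages(z).sum() == pytest.approx(6.0, rel=1e-10)

    def test_orthonormal_columns_row_norms(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(20, 4)))
        np.testing.assert_allclose(leverages(q), np.sum(q**2, axis=1), rtol=1e-10)

    def test_square_full_rank_clamped_to_one(self):
        z = np.random.default_rng(2).normal(size=(5, 5))
        lev = leverages(z)
        np.testing.assert_allclose(lev, 1.0 - 1e-8, rtol=1e-9)

    def test_rank_deficient_sums_to_rank(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(25, 3))
        z = np.hstack([base, base[:, :1]])  # rank 3, 4 columns
        assert leverages(z).sum() == pytest.approx(3.0, rel=1e-8)


class TestVlooScore:
    def test_zero_leverage_limit_is_rmse(self):
        r = np.array([0.5, -1.0, 0.25])
        assert vloo_score(r, np.zeros(3)) == pytest.approx(
            float(np.sqrt(np.mean(r**2)))
        )

    def test_never_below_rmse(self):
        rng = np.random.default_rng(4)
        r = rng.normal(size=50)
        lev = rng.uniform(0, 0.9, size=50)
        assert vloo_score(r, lev) >= float(np.sqrt(np.mean(r**2)))

    def test_press_identity_linear_model(self):
        """For OLS the leverage formula reproduces exact LOO to 10+ digits."""
        rng = np.random.default_rng(5)
        n, p = 40, 4
        x = rng.normal(size=(n, p))
        y = x @ rng.normal(size=p) + rng.normal(0, 0.5, size=n)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        residuals = y - x @ beta
        virtual = vloo_score(residuals, leverages(x))
        brute = brute_force_loo_rmse_linear(x, y)
        assert virtual == pytest.approx(brute, rel=1e-11)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            vloo_score(np.zeros(3), np.zeros(4))


class TestOutputJacobian:
    def test_shape_and_finite(self, small_additive_dataset):
        params = NodeFunctionParameters.random(3, np.random.default_rng(0))
        z = output_jacobian_matrix(params, small_additive_dataset)
        assert z.shape == (small_additive_dataset.n_records, parameter_count(3))
        assert np.all(np.isfinite(z))

    def test_single_record_row(self, small_additive_dataset):
        one = small_additive_dataset.subset([0])
        params = NodeFunctionParameters.random(2, np.random.default_rng(1))
        z = output_jacobian_matrix(params, one)
        assert z.shape == (1, parameter_count(2))

    def test_row_matches_gm_jacobian(self, small_additive_dataset):
        from gmshift.chem_graph import build_rooted_dag
        from gmshift.node_model import gm_jacobian

        params = NodeFunctionParameters.random(3, np.random.default_rng(2))
        z = output_jacobian_matrix(params, small_additive_dataset)
        mol, _ = small_additive_dataset.records[5]
        row = gm_jacobian(build_rooted_dag(mol), params, small_additive_dataset.scaling())
        np.testing.assert_allclose(z[5], row, rtol=1e-12)


class TestNonlinearVlooQuality:
    def test_within_25_percent_of_brute_force_loo(self):
        """First-order VLOO approximates true LOO on a small nonlinear fit.

        Exact LOO retrains the graph machine N times from the converged
        parameters (warm start), the regime in which the first-order
        leverage approximation is derived.
        """
        from gmshift.synthetic import SubstituentLibrary, make_dataset

        # every substituent recurs many times, so no single record owns a
        # parameter direction and the leverages stay moderate
        library = SubstituentLibrary.restricted(("*C", "*Cl", "*OC"))
        ds = make_dataset(
            20, 0.5, seed=23, mode="additive", max_substituents=2, library=library
        )
        cfg = TrainConfig(h=1, restarts=1, max_iterations=1500, master_seed=3)
        theta0 = NodeFunctionParameters.random(1, np.random.default_rng(3)).theta
        model = lm_fit(ds, theta0, cfg)
        virtual = vloo_of_model(model, ds)

        warm_cfg = TrainConfig(h=1, restarts=1, max_iterations=150, master_seed=3)
        errors = []
        for i in range(ds.n_records):
            rest = ds.subset([j for j in range(ds.n_records) if j != i])
            refit = lm_fit(rest, model.params.theta.copy(), warm_cfg)
            held_out = predictions(refit, ds.subset([i]))[0]
            errors.append(ds.shifts[i] - held_out)
        brute = float(np.sqrt(np.mean(np.square(errors))))
        assert virtual == pytest.approx(brute, rel=0.25)


class TestVlooProperties:
    """Structural facts about the VLOO formula for arbitrary inputs."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        residuals=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=1, max_size=40
        ),
        seed=st.integers(0, 2**16),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_vloo_at_least_rmse_and_finite(self, residuals, seed):
        r = np.array(residuals)
        lev = np.random.default_rng(seed).uniform(0, 1 - 1e-8, size=r.size)
        score = vloo_score(r, lev)
        assert np.isfinite(score)
        assert score >= float(np.sqrt(np.mean(r**2))) - 1e-12

    @given(
        n=st.integers(5, 30), p=st.integers(1, 4), seed=st.integers(0, 2**16)
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_leverages_bounded_and_trace_at_most_p(self, n, p, seed):
        z = np.random.default_rng(seed).normal(size=(n, p))
        lev = leverages(z)
        assert np.all(lev >= 0) and np.all(lev <= 1 - 1e-9)
        assert lev.sum() <= min(n, p) + 1e-6


@pytest.fixture(scope="module")
def trained_pool(small_additive_dataset):
    cfg = TrainConfig(h=2, restarts=4, max_iterations=60, master_seed=9)
    return small_additive_dataset, multi_restart_train(small_additive_dataset, cfg)


class TestRankAndSelect:

    def test_selects_k_smallest(self, trained_pool):
        ds, models = trained_pool
        sel = rank_and_select(models, ds, k=2)
        assert isinstance(sel, SelectionResult)
        assert len(sel.selected_indices) == 2
        chosen = [sel.scores[i] for i in sel.selected_indices]
        assert chosen == sorted(sel.scores)[:2]
        assert sel.mean_selected == pytest.approx(np.mean(chosen))

    def test_vloo_at_least_rmste(self, trained_pool):
        ds, models = trained_pool
        rank_and_select(models, ds, k=1)
        for m in models:
            assert m.vloo_score >= m.rmste - 1e-9

    def test_k_one_is_argmin(self, trained_pool):
        ds, models = trained_pool
        sel = rank_and_select(models, ds, k=1)
        assert sel.selected_indices[0] == int(np.argmin(sel.scores))

    def test_tie_broken_by_restart_order(self, trained_pool):
        ds, models = trained_pool
        sel = rank_and_select(models, ds, k=len(models))
        scores = np.array(sel.scores)
        for a, b in zip(sel.selected_indices[:-1], sel.selected_indices[1:]):
            assert (scores[a], a) <= (scores[b], b)

    def test_k_too_large_raises(self, trained_pool):
        ds, models = trained_pool
        with pytest.raises(ValueError):
            rank_and_select(models, ds, k=len(models) + 1)


class TestComplexityScan:
    def test_single_h_single_row(self, small_additive_dataset):
        cfg = TrainConfig(restarts=2, max_iterations=40, master_seed=5)
        rows = complexity_scan(small_additive_dataset, [2], cfg, k=2)
        assert len(rows) == 1 and rows[0].h == 2

    def test_vloo_at_least_rmste_per_row(self, small_additive_dataset):
        cfg = TrainConfig(restarts=2, max_iterations=40, master_seed=5)
        rows = complexity_scan(small_additive_dataset, [1, 2], cfg, k=1)
        for row in rows:
            assert row.mean_vloo >= row.best_rmste - 1e-9

    def test_empty_h_list_rejected(self, small_additive_dataset):
        with pytest.raises(ValueError):
            complexity_scan(small_additive_dataset, [], TrainConfig())
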