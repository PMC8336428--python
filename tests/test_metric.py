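"""PSD metric learning: prediction, fitting, eigenstructure, model selection."""

import numpy as np
import pytest

from percepspace.metric import (
    FeatureSpace,
    FitConfig,
    MetricModel,
    dimension_contributions,
    eigendecompose,
    fit_metric,
    heldout_cc,
    predict_dissimilarity,
    predict_pairs,
    select_coefficient,
    split_pairs,
    subset_table,
    transform,
    truncation_curve,
)
from percepspace.synthetic import make_world, sample_pairs, true_dissimilarity

from conftest import table_from_values


def model_from(W, b):
    vals, vecs = np.linalg.eigh(np.asarray(W, float))
    order = np.argsort(-vals)
    return MetricModel(
        W=np.asarray(W, float), b=float(b), U=vecs[:, order].T, eigvals=np.maximum(vals[order], 0)
    )


@pytest.mark.parametrize(
    "W,b,xi,xj,expected",
    [
        (np.eye(2), 0.0, (0, 0), (1, 0), 1.0),
        (np.diag([3.0, 7.0]), 2.5, (1, 1), (1, 1), 2.5),
        (np.diag([2.0, 0.0]), 0.5, (1, 1), (0, 0), 2.5),
    ],
)
def test_predict_dissimilarity(W, b, xi, xj, expected):
    m = model_from(W, b)
    assert predict_dissimilarity(m, np.array(xi, float), np.array(xj, float)) == pytest.approx(expected)
    # symmetry in (i, j)
    assert predict_dissimilarity(m, np.array(xj, float), np.array(xi, float)) == pytest.approx(expected)


def test_predict_dimension_mismatch():
    m = model_from(np.eye(2), 0.0)
    with pytest.raises(ValueError):
        predict_dissimilarity(m, np.zeros(3), np.zeros(3))


class TestFit:
    def test_noiseless_recovery(self, small_world, small_fit):
        """Planted rank-3 metric, 700 noiseless pairs: near-exact recovery."""
        rel = np.linalg.norm(small_fit.W - small_world.W) / np.linalg.norm(small_world.W)
        assert rel < 1e-3
        assert abs(small_fit.b - small_world.b) < 1e-3

    def test_model_invariants(self, small_fit):
        W = small_fit.W
        assert np.abs(W - W.T).max() <= 1e-8 * max(np.abs(W).max(), 1e-30)
        assert small_fit.eigvals.min() >= -1e-8 * max(small_fit.eigvals.max(), 1.0)
        assert small_fit.b >= 0
        recon = small_fit.U.T @ np.diag(small_fit.eigvals) @ small_fit.U
        np.testing.assert_allclose(recon, W, atol=1e-8)

    def test_huge_trace_coefficient_kills_W(self, small_world, small_world_data):
        table = small_world_data["train"]
        m = fit_metric(small_world.features, table, FitConfig(regularizer="trace", coefficient=1e6))
        y = np.array(list(table.entries.values()))
        assert np.abs(m.W).max() < 1e-6
        assert m.b == pytest.approx(y.mean(), abs=1e-4)

    def test_small_coefficients_match_unregularized(self, small_world, small_world_data):
        table = small_world_data["train"]
        D = small_world.features.deltas(table.pairs())
        y = np.array([table.entries[p] for p in table.pairs()])

        def loss(m):
            return float(((predict_pairs(m, D) - y) ** 2).sum())

        base = fit_metric(small_world.features, table, FitConfig(regularizer="none"))
        for reg in ("l1", "l2", "trace"):
            m = fit_metric(small_world.features, table, FitConfig(regularizer=reg, coefficient=1e-8))
            assert loss(m) <= loss(base) + 1e-4

    def test_dimension_cap_guard(self, small_world, small_world_data):
        with pytest.raises(ValueError, match="dimensionality"):
            fit_metric(
                small_world.features, small_world_data["train"], FitConfig(max_dense_dim=5)
            )

    def test_penalty_path_monotone(self, small_world, small_world_data):
        """Penalty value at the optimum is non-increasing in the coefficient."""
        table = small_world_data["train"]
        for reg in ("trace", "l1", "l2"):
            pens = []
            for coeff in (0.0, 0.1, 1.0, 10.0):
                m = fit_metric(small_world.features, table, FitConfig(regularizer=reg, coefficient=coeff))
                pens.append(m.penalty_value())
            assert all(pens[k + 1] <= pens[k] + 1e-6 for k in range(len(pens) - 1)), (reg, pens)

    def test_l2_penalty_equals_sum_squared_eigenvalues(self, small_fit):
        """tr(W^T W) = sum of squared eigenvalues."""
        assert float(np.trace(small_fit.W.T @ small_fit.W)) == pytest.approx(
            float((small_fit.eigvals**2).sum()), rel=1e-8
        )

    def test_diagonal_fit_matches_bruteforce_oracle(self):
        """n=2 diagonal restriction vs exhaustive grid + polish least-squares oracle."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 2))
        ids = [f"i{k}" for k in range(40)]
        fs = FeatureSpace(ids, X)
        w_true, b_true = np.array([0.8, 0.3]), 0.2
        pairs = [(ids[i], ids[j]) for i in range(40) for j in range(i + 1, 40)][:300]
        D = fs.deltas(pairs)
        y = (D**2) @ w_true + b_true
        table = table_from_values(pairs, y)
        m = fit_metric(fs, table, FitConfig(diagonal=True, tol=1e-13, max_iter=50000))

        # oracle: coarse grid over (w1, w2, b) then local refinement
        grid = np.linspace(0, 1.5, 31)
        best, best_obj = None, np.inf
        for w1 in grid:
            for w2 in grid:
                resid_wo_b = y - (D**2) @ np.array([w1, w2])
                b = max(resid_wo_b.mean(), 0.0)
                obj = ((resid_wo_b - b) ** 2).sum()
                if obj < best_obj:
                    best, best_obj = (w1, w2, b), obj
        from scipy.optimize import minimize

        def f(p):
            return (((D**2) @ p[:2] + p[2] - y) ** 2).sum()

        res = minimize(f, best, bounds=[(0, None)] * 3, method="L-BFGS-B")
        oracle = res.x
        np.testing.assert_allclose(np.diag(m.W), oracle[:2], rtol=1e-3)
        assert m.b == pytest.approx(oracle[2], abs=1e-3)

    def test_save_load_roundtrip(self, small_fit, tmp_path):
        path = tmp_path / "model.npz"
        small_fit.save(path)
        loaded = MetricModel.load(path)
        assert np.array_equal(loaded.W, small_fit.W)
        assert loaded.b == small_fit.b
        assert np.array_equal(loaded.U, small_fit.U)
        assert loaded.regularizer == small_fit.regularizer
        assert loaded.ids == small_fit.ids


class TestEigendecompose:
    def test_diagonal(self):
        m = model_from(np.diag([3.0, 1.0]), 0.0)
        U, lam = eigendecompose(m)
        np.testing.assert_allclose(lam, [3.0, 1.0])
        np.testing.assert_allclose(np.abs(U), np.eye(2), atol=1e-12)

    def test_zero(self):
        U, lam = eigendecompose(model_from(np.zeros((3, 3)), 0.0))
        np.testing.assert_allclose(lam, 0.0)

    def test_planted_factors(self):
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        lam_true = np.array([5.0, 3.0, 1.0, 0.5, 0.2, 0.0])
        W = Q @ np.diag(lam_true) @ Q.T
        U, lam = eigendecompose(model_from(W, 0.0))
        np.testing.assert_allclose(lam, lam_true, atol=1e-8)
        np.testing.assert_allclose(U.T @ np.diag(lam) @ U, W, atol=1e-8)


class TestTransform:
    def test_full_rank_identity(self, small_world, small_fit):
        Z = transform(small_world.features, small_fit)
        pairs = sample_pairs(small_world, 50, seed=3)
        idx = {im: k for k, im in enumerate(small_world.features.ids)}
        for i, j in pairs:
            dz = Z[idx[i]] - Z[idx[j]]
            f = predict_dissimilarity(small_fit, small_world.features.vector(i), small_world.features.vector(j))
            assert dz @ dz + small_fit.b == pytest.approx(f, abs=1e-8)

    def test_rank3_truncation_lossless(self, small_world, small_fit):
        Z3 = transform(small_world.features, small_fit, k=3)
        Zn = transform(small_world.features, small_fit)
        d3 = ((Z3[:20, None] - Z3[None, :20]) ** 2).sum(-1)
        dn = ((Zn[:20, None] - Zn[None, :20]) ** 2).sum(-1)
        np.testing.assert_allclose(d3, dn, atol=1e-6)

    def test_monotone_in_k(self, small_world, small_fit):
        prev = None
        for k in range(1, small_fit.n_dims + 1):
            Z = transform(small_world.features, small_fit, k=k)
            d = ((Z[:15, None] - Z[None, :15]) ** 2).sum(-1)
            if prev is not None:
                assert np.all(d >= prev - 1e-12)
            prev = d

    def test_k_out_of_range(self, small_world, small_fit):
        with pytest.raises(ValueError):
            transform(small_world.features, small_fit, k=0)
        with pytest.raises(ValueError):
            transform(small_world.features, small_fit, k=99)


class TestTruncationCurve:
    def test_plateau_at_planted_rank(self, small_world, small_world_data, small_fit):
        curve, k_star = truncation_curve(
            small_world.features, small_fit, small_world_data["heldout"]
        )
        assert k_star <= 3  # planted rank 3, noiseless
        assert curve[2] >= 0.99 * curve[-1]

    def test_last_point_equals_full_model_cc(self, small_world, small_world_data, small_fit):
        curve, _ = truncation_curve(small_world.features, small_fit, small_world_data["heldout"])
        full = heldout_cc(small_world.features, small_fit, small_world_data["heldout"])
        assert curve[-1] == pytest.approx(full, abs=1e-12)

    def test_pure_noise_curve_near_zero(self, small_world, small_fit):
        rng = np.random.default_rng(12)
        pairs = sample_pairs(small_world, 400, seed=13)
        noise_table = table_from_values(pairs, rng.uniform(0, 1, len(pairs)))
        curve, _ = truncation_curve(small_world.features, small_fit, noise_table)
        assert np.abs(curve).max() < 3 / np.sqrt(len(pairs))


class TestSelectCoefficient:
    def test_noiseless_chooses_zero(self, small_world, small_world_data):
        cfg = FitConfig(regularizer="trace", grid=(0.0, 0.1, 1.0))
        model, coeff, ccs = select_coefficient(
            small_world.features, small_world_data["train"], small_world_data["heldout"], cfg
        )
        assert coeff == 0.0

    def test_singleton_grid(self, small_world, small_world_data):
        cfg = FitConfig(regularizer="trace", grid=(0.5,))
        _, coeff, _ = select_coefficient(
            small_world.features, small_world_data["train"], small_world_data["heldout"], cfg
        )
        assert coeff == 0.5

    def test_empty_grid_errors(self, small_world, small_world_data):
        cfg = FitConfig(regularizer="trace")
        cfg.grid = ()
        with pytest.raises(ValueError, match="grid"):
            select_coefficient(
                small_world.features, small_world_data["train"], small_world_data["heldout"], cfg
            )

    def test_regularization_helps_under_noise(self):
        world = make_world(n_items=120, n_dims=12, rank=3, b=0.4, seed=21)
        pairs = sample_pairs(world, 700, seed=22)
        f = true_dissimilarity(world, pairs)
        rng = np.random.default_rng(23)
        y = f + rng.normal(0, 0.15, len(f))
        train = table_from_values(pairs[:500], y[:500])
        val = table_from_values(pairs[500:600], y[500:600])
        cfg = FitConfig(regularizer="trace", grid=(0.0, 1.0, 10.0, 100.0))
        model, coeff, ccs = select_coefficient(world.features, train, val, cfg)
        assert coeff > 0
        assert ccs.max() >= ccs[0]  # validated fit at least as good as unregularized


class TestDimensionContributions:
    def test_zero_metric(self, small_world):
        m = model_from(np.zeros((10, 10)), 0.3)
        pairs = sample_pairs(small_world, 40, seed=4)
        contrib = dimension_contributions(small_world.features, m, pairs)
        np.testing.assert_allclose(contrib, 0.0)

    def test_conservation_identity(self, small_world, small_world_data, small_fit):
        pairs = small_world_data["pairs"][:300]
        contrib = dimension_contributions(small_world.features, small_fit, pairs)
        D = small_world.features.deltas(pairs)
        mean_pred = predict_pairs(small_fit, D).mean()
        assert contrib.sum() + small_fit.b == pytest.approx(mean_pred, rel=1e-8)
        assert np.all(contrib >= 0)

    def test_isotropic_ratio(self):
        """W=diag(2,1) on isotropic data: contributions in 2:1 ratio (Monte Carlo)."""
        rng = np.random.default_rng(6)
        n = 4000
        X = rng.standard_normal((n, 2))
        ids = [f"i{k}" for k in range(n)]
        fs = FeatureSpace(ids, X)
        m = model_from(np.diag([2.0, 1.0]), 0.0)
        pairs = [(ids[2 * k], ids[2 * k + 1]) for k in range(n // 2)]
        contrib = dimension_contributions(fs, m, pairs)
        assert contrib[0] / contrib[1] == pytest.approx(2.0, rel=0.15)

    def test_empty_pairs_error(self, small_world, small_fit):
        with pytest.raises(ValueError):
            dimension_contributions(small_world.features, small_fit, [])


def test_split_pairs_disjoint_and_sized():
    pairs = [(f"a{k}", f"b{k}") for k in range(100)]
    tr, va, te = split_pairs(pairs, (8, 1, 1), seed=5)
    assert len(tr) == 80 and len(va) == 10 and len(te) == 10
    assert not (set(tr) & set(va)) and not (set(tr) & set(te)) and not (set(va) & set(te))
    tr2, _, _ = split_pairs(pairs, (8, 1, 1), seed=5)
    assert tr == tr2  # deterministic given seed


def test_split_by_images_keeps_pairs_internal():
    ids = [f"x{k}" for k in range(20)]
    pairs = [(ids[i], ids[j]) for i in range(20) for j in range(i + 1, 20)]
    tr, va, te = split_pairs(pairs, (8, 1, 1), seed=6, by="images")
    img_tr = {im for p in tr for im in p}
    img_va = {im for p in va for im in p}
    assert not img_tr & img_va
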