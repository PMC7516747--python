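import numpy as np
import pytest

from immigrate.core import (
    InteractionWeightMatrix,
    NeighborWeights,
    cost,
    quad_manhattan,
)
from immigrate.data import LabeledDataset
from immigrate.optimizer import (
    DegenerateSpectrumError,
    ImmigrateModel,
    SigmaSpectrum,
    accumulate_sigma,
    fit_immigrate,
    predict,
    predict_batch,
    prune_weight_matrix,
    random_weight_matrix,
    solve_weight_matrix,
    tune_hyperparameters,
    update_neighbor_weights,
)
from immigrate.preprocess import Scaler
from immigrate.relief import relief_closed_form

from conftest import random_dataset, uniform_neighbor_weights


def spectrum_of(S):
    mu, psi = np.linalg.eigh(S)
    return SigmaSpectrum(Sigma=S, eigenvalues=mu, eigenvectors=psi)


def random_feasible_W(rng, a):
    """Random symmetric PSD matrix with unit Frobenius norm."""
    while True:
        B = rng.standard_normal((a, a))
        S = (B + B.T) / 2
        mu, psi = np.linalg.eigh(S)
        W = (psi * np.maximum(mu, 0)) @ psi.T
        nrm = np.linalg.norm(W)
        if nrm > 0:
            return W / nrm


class TestNeighborUpdate:
    def test_equidistant_hits_share_mass(self):
        X = np.array([[0.0], [1.0], [-1.0], [5.0], [6.0]])
        y = np.array([0, 0, 0, 1, 1])
        nw = update_neighbor_weights(LabeledDataset(X, y), np.array([[1.0]]), 1.0)
        np.testing.assert_allclose(nw.alpha[0], [0.5, 0.5])

    def test_log2_distance_ratio(self):
        # hit distances give q = (0, ln 2) at sigma = 1 -> alpha = (2/3, 1/3)
        X = np.array([[0.0], [0.0], [np.sqrt(np.log(2.0))], [9.0], [10.0]])
        y = np.array([0, 0, 0, 1, 1])
        nw = update_neighbor_weights(LabeledDataset(X, y), np.array([[1.0]]), 1.0)
        np.testing.assert_allclose(nw.alpha[0], [2 / 3, 1 / 3], atol=1e-12)

    def test_small_sigma_softmin_limit(self):
        X = np.array([[0.0], [1.0], [2.0], [9.0], [10.0]])
        y = np.array([0, 0, 0, 1, 1])
        nw = update_neighbor_weights(
            LabeledDataset(X, y), np.array([[1.0]]), 1e-6
        )
        np.testing.assert_allclose(nw.alpha[0], [1.0, 0.0], atol=1e-12)
        assert np.all(np.isfinite(nw.beta[0]))

    def test_nonpositive_sigma_rejected(self, four_point):
        with pytest.raises(ValueError, match="sigma"):
            update_neighbor_weights(four_point, np.eye(2) / np.sqrt(2), -1.0)


class TestScatter:
    def test_exact_hit_miss_cancellation(self):
        # both classes occupy identical duplicated positions; alpha puts
        # half its mass on the duplicate so hit and miss scatters coincide
        p, q = np.array([0.0, 0.0]), np.array([1.0, 2.0])
        X = np.vstack([p, p, q, q, p, p, q, q])
        y = np.array([0] * 4 + [1] * 4)
        data = LabeledDataset(X, y)
        hs, ms, al, be = [], [], [], []
        for n in range(8):
            h = data.hit_indices(n)
            m = data.miss_indices(n)
            dup = np.array([np.allclose(X[j], X[n]) for j in h])
            a = np.where(dup, 0.5 / dup.sum(), 0.5 / (~dup).sum())
            hs.append(h)
            ms.append(m)
            al.append(a)
            be.append(np.full(len(m), 1.0 / len(m)))
        nw = NeighborWeights(hs, ms, al, be)
        S = accumulate_sigma(data, nw).Sigma
        np.testing.assert_allclose(S, np.zeros((2, 2)), atol=1e-14)

    def test_brute_force_four_points(self, four_point):
        nw = uniform_neighbor_weights(four_point)
        X = four_point.features
        expected = np.zeros((2, 2))
        for n in range(4):
            for w, idx in ((nw.alpha[n], nw.hit_sets[n]), (-nw.beta[n], nw.miss_sets[n])):
                for wk, j in zip(w, idx):
                    d = np.abs(X[n] - X[j])
                    expected += 0.25 * wk * np.outer(d, d)
        np.testing.assert_allclose(accumulate_sigma(four_point, nw).Sigma, expected,
                                   atol=1e-12)

    def test_feature_scaling_is_quadratic(self, rng):
        data = random_dataset(rng)
        nw = uniform_neighbor_weights(data)
        S1 = accumulate_sigma(data, nw).Sigma
        scaled = LabeledDataset(3.0 * data.features, data.labels)
        S2 = accumulate_sigma(scaled, nw).Sigma
        np.testing.assert_allclose(S2, 9.0 * S1, atol=1e-10)


class TestSpectralStep:
    @pytest.mark.parametrize(
        "diag, expected",
        [
            ([-3.0, -4.0], [0.6, 0.8]),
            ([2.0, -1.0], [0.0, 1.0]),
        ],
    )
    def test_diagonal_solutions(self, diag, expected):
        W = solve_weight_matrix(spectrum_of(np.diag(diag)))
        np.testing.assert_allclose(np.diag(W.W), expected, atol=1e-12)
        np.testing.assert_allclose(W.W - np.diag(np.diag(W.W)), 0, atol=1e-12)

    def test_degenerate_spectrum_raises(self):
        with pytest.raises(DegenerateSpectrumError):
            solve_weight_matrix(spectrum_of(np.diag([1.0, 2.0])))

    def test_optimality_against_random_feasible_matrices(self, rng):
        for _ in range(10):
            B = rng.standard_normal((4, 4))
            S = (B + B.T) / 2 - 0.5 * np.eye(4)
            spec = spectrum_of(S)
            if spec.eigenvalues.min() >= 0:
                continue
            W = solve_weight_matrix(spec)
            attained = float(np.trace(W.W @ S))
            target = -np.linalg.norm(np.maximum(-spec.eigenvalues, 0))
            assert attained == pytest.approx(target, abs=1e-9)
            for _ in range(200):
                Wr = random_feasible_W(rng, 4)
                assert attained <= np.trace(Wr @ S) + 1e-9

    def test_relief_diagonal_limit(self, rng):
        """Diagonal scatter reduces the spectral step to closed-form Relief."""
        for _ in range(10):
            d = rng.standard_normal(5)
            d[rng.integers(0, 5)] = -abs(d).max() - 0.1  # ensure a negative
            W = solve_weight_matrix(spectrum_of(np.diag(d)))
            expected = relief_closed_form(d).w
            np.testing.assert_allclose(np.diag(W.W), expected, atol=1e-10)
            np.testing.assert_allclose(
                W.W - np.diag(np.diag(W.W)), 0, atol=1e-10
            )

    def test_psd_unit_norm_postconditions(self, rng):
        for _ in range(20):
            B = rng.standard_normal((5, 5))
            S = (B + B.T) / 2 - 0.2 * np.eye(5)
            spec = spectrum_of(S)
            if spec.eigenvalues.min() >= 0:
                continue
            W = solve_weight_matrix(spec)
            assert np.linalg.norm(W.W) == pytest.approx(1.0, abs=1e-10)
            assert np.linalg.eigvalsh(W.W).min() >= -1e-10
            assert np.max(np.abs(W.W - W.W.T)) < 1e-12


class TestSaddleStructure:
    def _perturb_simplex(self, p, rng, eps=1e-3):
        d = rng.standard_normal(p.shape)
        d -= d.mean()
        nrm = np.linalg.norm(d)
        if nrm == 0:
            d = np.zeros_like(p)
            d[0], d[-1] = 1, -1
            nrm = np.linalg.norm(d)
        d *= eps / nrm
        q = p + d
        if np.any(q <= 0):  # stay interior
            q = p + d * 0.5 * p.min() / (np.abs(d).max() + 1e-300)
        return q / q.sum()

    def test_stationary_point_is_min_in_alpha_max_in_beta(self, rng):
        sigma = 1.0
        for _ in range(20):
            data = random_dataset(rng, n_per_class=5, a=2)
            W = random_weight_matrix(2, rng)
            nw = update_neighbor_weights(data, W, sigma)
            c0 = cost(data, W, nw, sigma)
            n = int(rng.integers(0, data.n_samples))
            a_pert = [a.copy() for a in nw.alpha]
            a_pert[n] = self._perturb_simplex(nw.alpha[n], rng)
            nw_a = NeighborWeights(nw.hit_sets, nw.miss_sets, a_pert, nw.beta)
            assert cost(data, W, nw_a, sigma) > c0
            b_pert = [b.copy() for b in nw.beta]
            b_pert[n] = self._perturb_simplex(nw.beta[n], rng)
            nw_b = NeighborWeights(nw.hit_sets, nw.miss_sets, nw.alpha, b_pert)
            assert cost(data, W, nw_b, sigma) < c0


class TestPruning:
    def test_all_survivors_unchanged(self):
        W = InteractionWeightMatrix(np.full((2, 2), 0.5))
        out = prune_weight_matrix(W, threshold=0.4)
        np.testing.assert_allclose(out.W, W.W)
        assert out.pruned

    def test_renormalizes_survivor(self):
        W = InteractionWeightMatrix(np.diag([0.6, 0.8]))
        out = prune_weight_matrix(W, threshold=0.7)
        np.testing.assert_allclose(out.W, np.diag([0.0, 1.0]))

    def test_everything_pruned_rejected(self):
        W = InteractionWeightMatrix(np.diag([0.6, 0.8]))
        with pytest.raises(ValueError, match="lower the threshold"):
            prune_weight_matrix(W, threshold=2.0)

    def test_unit_norm_after_pruning(self, rng):
        for _ in range(100):
            W = InteractionWeightMatrix(random_feasible_W(rng, 4))
            thr = float(rng.uniform(0, np.abs(W.W).max()))
            out = prune_weight_matrix(W, thr)
            assert np.linalg.norm(out.W) == pytest.approx(1.0, abs=1e-12)


class TestFit:
    def test_seeded_determinism_is_bit_identical(self, rng):
        data = random_dataset(rng, n_per_class=8, a=3)
        m1 = fit_immigrate(data, sigma=1.0, seed=11)
        m2 = fit_immigrate(data, sigma=1.0, seed=11)
        np.testing.assert_array_equal(m1.W.W, m2.W.W)
        assert m1.cost_trace == m2.cost_trace

    def test_informative_feature_dominates_weight_matrix(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(300 + s)
            n = 30
            X = np.column_stack(
                [
                    np.concatenate([r.normal(0, 0.3, n), r.normal(4, 0.3, n)]),
                    r.standard_normal(2 * n),
                    r.standard_normal(2 * n),
                ]
            )
            y = np.array([0] * n + [1] * n)
            m = fit_immigrate(LabeledDataset(X, y), sigma=1.0, seed=s)
            i, j = np.unravel_index(np.argmax(np.abs(m.W.W)), (3, 3))
            hits += (i, j) == (0, 0)
        assert hits >= 8

    def test_cost_trace_finite_and_bounded_iterations(self, rng):
        data = random_dataset(rng, n_per_class=10, a=2)
        m = fit_immigrate(data, sigma=0.5, max_iter=7, seed=0)
        assert m.n_iterations <= 7
        assert np.all(np.isfinite(m.cost_trace))

    def test_model_json_roundtrip(self, tmp_path, rng):
        data = random_dataset(rng, n_per_class=6, a=2)
        m = fit_immigrate(data, sigma=2.0, prune=True, seed=3)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = ImmigrateModel.from_json(path)
        np.testing.assert_allclose(back.W.W, m.W.W)
        assert back.sigma == m.sigma
        assert back.class_order == m.class_order
        Xq = rng.standard_normal((5, 2))
        np.testing.assert_array_equal(predict_batch(back, Xq), predict_batch(m, Xq))


class TestPredict:
    def test_training_point_recovers_its_class(self, rng):
        data = random_dataset(rng, n_per_class=8, a=2, shift=3.0)
        m = fit_immigrate(data, sigma=1.0, seed=0)
        m.sigma = 1e-4  # sharpen the softmin for the query
        label, _ = predict(m, data.features[2])
        assert label == data.labels[2]

    def test_matches_direct_summation(self, rng):
        data = random_dataset(rng, n_per_class=6, a=3)
        m = fit_immigrate(data, sigma=1.5, seed=2)
        x = rng.standard_normal(3)
        label, scores = predict(m, x)
        xs = m.scaler.transform(x[None, :])[0]
        expected = {}
        for c in m.class_order:
            idx = np.flatnonzero(m.training_labels == c)
            q = np.array(
                [quad_manhattan(m.W, xs, m.training_features[i]) for i in idx]
            )
            a = np.exp(-(q - q.min()) / m.sigma)
            a /= a.sum()
            expected[c] = float(a @ q)
        for c in expected:
            assert scores[c] == pytest.approx(expected[c], rel=1e-9)
        assert label == min(expected, key=lambda c: (expected[c],))

    def test_small_sigma_limit_is_nearest_neighbor_under_q(self, rng):
        data = random_dataset(rng, n_per_class=10, a=2)
        m = fit_immigrate(data, sigma=1.0, seed=4)
        m.sigma = 1e-6
        for _ in range(30):
            x = rng.standard_normal(2) * 2
            xs = m.scaler.transform(x[None, :])[0]
            q = np.array(
                [quad_manhattan(m.W, xs, t) for t in m.training_features]
            )
            nn_label = m.training_labels[int(np.argmin(q))]
            assert predict(m, x)[0] == nn_label

    def test_forced_tie_goes_to_larger_class(self):
        # symmetric configuration: both classes at mirror positions, class
        # "a" larger; the query on the axis of symmetry scores equally
        X = np.array([[-1.0], [-1.0], [-1.0], [1.0], [1.0]])
        y = np.array(["a", "a", "a", "b", "b"])
        model = ImmigrateModel(
            W=InteractionWeightMatrix(np.array([[1.0]])),
            sigma=1.0,
            training_features=X,
            training_labels=y,
            scaler=Scaler(mean=np.zeros(1), scale=np.ones(1)),
            class_order=["a", "b"],
        )
        label, scores = predict(model, np.array([0.0]))
        assert scores["a"] == pytest.approx(scores["b"])
        assert label == "a"


class TestTuning:
    def test_grid_membership_and_tie_break(self):
        # perfectly separated data: every configuration scores 1.0, so the
        # documented tie-break picks the largest sigma without pruning
        r = np.random.default_rng(1)
        X = np.column_stack(
            [
                np.concatenate([r.normal(0, 0.2, 20), r.normal(10, 0.2, 20)]),
                r.standard_normal(40),
            ]
        )
        y = np.array([0] * 20 + [1] * 20)
        sigma, prune = tune_hyperparameters(LabeledDataset(X, y), folds=4, seed=0)
        assert sigma == 4.0
        assert prune is False
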