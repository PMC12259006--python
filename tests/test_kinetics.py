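import numpy as np
import pandas as pd
import pytest

from allostate import kinetics, synthdata


class TestCovariances:
    def test_constant_features_degenerate(self):
        X = np.ones((100, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            cov = kinetics.estimate_covariances(X, 1)
        assert cov.degenerate
        assert np.abs(cov.c0).max() < 1e-12

    def test_white_noise_lagged_covariance_vanishes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20000, 4))
        cov = kinetics.estimate_covariances(X, 1)
        # sampling error of a lag-1 cross-covariance is ~1/sqrt(n)
        assert np.abs(cov.ctau).max() < 3 / np.sqrt(X.shape[0])

    def test_ar1_autocovariance_ratio(self):
        rho = 0.9
        rng = np.random.default_rng(2)
        n = 200_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n - 1)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t - 1]
        cov = kinetics.estimate_covariances(x[:, None], 1)
        assert cov.ctau[0, 0] / cov.c0[0, 0] == pytest.approx(rho, abs=0.01)

    def test_all_short_trajectories_raise(self):
        with pytest.raises(ValueError, match="insufficient"):
            kinetics.estimate_covariances([np.zeros((3, 2))], 5)


class TestSolveTica:
    def test_already_diagonal(self):
        model = kinetics.solve_tica(np.eye(2), np.diag([0.8, 0.1]), ridge=0.0)
        assert np.allclose(model.eigenvalues, [0.8, 0.1])
        assert np.allclose(np.abs(model.components), np.eye(2), atol=1e-12)

    def test_eigen_residual_defining_property(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(8, 8))
        C0 = A @ A.T + 8 * np.eye(8)
        B = rng.normal(size=(8, 8))
        Ct = 0.5 * (B + B.T)
        m = kinetics.solve_tica(C0, Ct, ridge=0.0)
        res = Ct @ m.components - C0 @ (m.components * m.eigenvalues)
        assert np.abs(res).max() < 1e-8

    def test_matches_whitening_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(20, 20))
        C0 = A @ A.T + 20 * np.eye(20)
        B = rng.normal(size=(20, 20))
        Ct = 0.5 * (B + B.T)
        m = kinetics.solve_tica(C0, Ct, ridge=0.0)
        # oracle: whiten C0, then ordinary symmetric eigendecomposition
        ev, U = np.linalg.eigh(C0)
        W = U @ np.diag(ev**-0.5) @ U.T
        lam, V = np.linalg.eigh(W @ Ct @ W)
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        comps = W @ V[:, order]
        assert np.abs(m.eigenvalues - lam).max() < 1e-8
        for j in range(20):
            v_o = comps[:, j]
            k = int(np.argmax(np.abs(v_o)))
            if v_o[k] < 0:
                v_o = -v_o
            assert np.abs(m.components[:, j] - v_o).max() < 1e-8

    def test_c0_orthonormal_components(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 6))
        C0 = A @ A.T + 6 * np.eye(6)
        Ct = 0.5 * (A + A.T)
        m = kinetics.solve_tica(C0, Ct, ridge=0.0)
        G = m.components.T @ C0 @ m.components
        assert np.abs(G - np.eye(6)).max() < 1e-8

    def test_singular_without_ridge_raises(self):
        C0 = np.diag([1.0, 0.0])
        with pytest.raises(np.linalg.LinAlgError):
            kinetics.solve_tica(C0, np.eye(2), ridge=0.0)

    def test_projection_invariant_to_linear_reparameterization(self):
        rng = np.random.default_rng(6)
        # correlated AR(1) data in 3 dims
        n = 5000
        X = np.empty((n, 3))
        X[0] = 0
        for t in range(1, n):
            X[t] = 0.8 * X[t - 1] + rng.normal(size=3)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        m1 = kinetics.tica(X, lag=1, dim=2, ridge=0.0)
        m2 = kinetics.tica(X @ A.T, lag=1, dim=2, ridge=0.0)
        y1 = m1.transform(X)
        y2 = m2.transform(X @ A.T)
        for j in range(2):
            agree = np.abs(y1[:, j] - y2[:, j]).max()
            flipped = np.abs(y1[:, j] + y2[:, j]).max()
            assert min(agree, flipped) < 1e-6


class TestKMeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=(200, 2))
        b = rng.normal(0, 1, size=(200, 2)) + [30, 0]  # 10x the blob SD apart
        Y = np.vstack([a, b])
        _, (dtraj,) = kinetics.kmeans(Y, 2, seed=0)
        labels = dtraj
        # perfect recovery up to label permutation
        assert len(set(labels[:200])) == 1 and len(set(labels[200:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(10, 2))
        centers, (d,) = kinetics.kmeans(Y, 10, seed=0)
        assert np.abs(np.sort(centers, axis=0) - np.sort(Y, axis=0)).max() < 1e-12
        assert len(set(d.tolist())) == 10

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(300, 3))
        c1, d1 = kinetics.kmeans(Y, 5, seed=42)
        c2, d2 = kinetics.kmeans(Y, 5, seed=42)
        assert np.array_equal(c1, c2) and np.array_equal(d1[0], d2[0])

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            kinetics.kmeans(np.zeros((3, 2)), 5, seed=0)


class TestCountTransitions:
    def test_alternating_example(self):
        cm = kinetics.count_transitions(np.array([0, 1, 0, 1]), 1)
        assert np.array_equal(cm.counts, [[0, 2], [1, 0]])

    def test_self_transitions(self):
        cm = kinetics.count_transitions(np.array([0, 0, 0]), 1, n_states=2)
        assert np.array_equal(cm.counts, [[2, 0], [0, 0]])

    def test_total_sliding_count(self):
        d1 = np.array([0, 1, 2, 1, 0])
        d2 = np.array([2, 2, 2])
        cm = kinetics.count_transitions([d1, d2], 2)
        assert cm.counts.sum() == (5 - 2) + (3 - 2)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        d = rng.integers(0, 4, size=200)
        for lag in (1, 3, 7):
            cm = kinetics.count_transitions(d, lag)
            oracle = np.zeros((4, 4))
            for t in range(len(d) - lag):
                oracle[d[t], d[t + lag]] += 1
            assert np.array_equal(cm.counts, oracle)

    def test_lag_too_long_raises(self):
        with pytest.raises(ValueError):
            kinetics.count_transitions(np.array([0, 1]), 5)


class TestConnectedSet:
    def test_fully_connected(self):
        assert np.array_equal(kinetics.largest_connected_set(np.ones((2, 2))), [0, 1])

    def test_two_blocks(self):
        c = np.zeros((5, 5))
        c[np.ix_([0, 1, 2], [0, 1, 2])] = 1
        c[np.ix_([3, 4], [3, 4])] = 1
        assert np.array_equal(kinetics.largest_connected_set(c), [0, 1, 2])

    def test_matches_networkx_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(11)
        for _ in range(10):
            c = (rng.random((8, 8)) < 0.2).astype(float)
            ours = set(kinetics.largest_connected_set(c).tolist())
            g = nx.from_numpy_array(c, create_using=nx.DiGraph)
            sccs = sorted(nx.strongly_connected_components(g), key=lambda s: (-len(s), min(s)))
            assert ours == set(sccs[0])


class TestEstimateMSM:
    def test_symmetric_counts(self):
        m = kinetics.estimate_msm(np.array([[8.0, 2.0], [2.0, 8.0]]))
        assert np.allclose(m.transition_matrix, [[0.8, 0.2], [0.2, 0.8]])
        assert np.allclose(m.stationary_distribution, [0.5, 0.5])

    def test_asymmetric_stationary_solution(self):
        # T = [[0.5, 0.5], [0.25, 0.75]] has pi = (1/3, 2/3)
        m = kinetics.estimate_msm(np.array([[2.0, 2.0], [1.0, 3.0]]))
        assert np.allclose(m.stationary_distribution, [1 / 3, 2 / 3])

    def test_row_sums_and_stationarity(self):
        rng = np.random.default_rng(12)
        c = rng.integers(1, 50, size=(5, 5)).astype(float)
        m = kinetics.estimate_msm(c)
        assert np.abs(m.transition_matrix.sum(axis=1) - 1).max() < 1e-12
        pi = m.stationary_distribution
        assert abs(pi.sum() - 1) < 1e-12
        assert np.abs(pi @ m.transition_matrix - pi).max() < 1e-10

    def test_monte_carlo_recovery(self):
        T = np.array([[0.90, 0.05, 0.05], [0.05, 0.90, 0.05], [0.02, 0.03, 0.95]])
        d = synthdata.sample_markov_chain(T, 100_000, seed=13)
        m = kinetics.estimate_msm(kinetics.count_transitions(d, 1))
        assert np.abs(m.transition_matrix - T).max() <= 0.01

    def test_stationary_matches_empirical_frequencies(self):
        T = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        d = synthdata.sample_markov_chain(T, 1_000_000, seed=14)
        m = kinetics.estimate_msm(kinetics.count_transitions(d, 1))
        freq = np.bincount(d, minlength=3) / d.size
        assert np.abs(m.stationary_distribution - freq).max() < 0.005

    def test_trimming_warns(self):
        c = np.array([[5.0, 1.0, 0.0], [1.0, 5.0, 1.0], [0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="trimming"):
            m = kinetics.estimate_msm(c)
        assert np.array_equal(m.active_set, [0, 1])


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        m = kinetics.MSModel(np.array([[0.9, 0.1], [0.1, 0.9]]), np.array([0.5, 0.5]), 1, np.arange(2))
        assert m.timescales(1)[0] == pytest.approx(-1 / np.log(0.8), abs=1e-12)

    def test_zero_eigenvalue_undefined(self):
        m = kinetics.MSModel(np.full((2, 2), 0.5), np.array([0.5, 0.5]), 1, np.arange(2))
        assert np.isnan(m.timescales(1)[0])

    def test_flat_in_lag_for_markovian_data(self):
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        dtrajs = [synthdata.sample_markov_chain(T, 20_000, seed=s) for s in range(6)]
        its = kinetics.implied_timescales(dtrajs, lags=[1, 2, 5, 10], n_its=1)
        t_true = -1 / np.log(0.9)
        assert np.abs(its["t1"].values / t_true - 1).max() < 0.15

    def test_too_few_states_raise(self):
        with pytest.raises(ValueError, match="timescales"):
            kinetics.implied_timescales(np.zeros(50, dtype=int), lags=[1], n_its=2)


class TestVAMP2:
    def test_two_state_closed_form(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        d = synthdata.sample_markov_chain(T, 200_000, seed=15)
        s = kinetics.vamp2_score(d, d, 1, 2)
        assert s == pytest.approx(1 + 0.8**2, abs=0.01)

    def test_rank_one_is_unity(self):
        d = synthdata.sample_markov_chain(np.array([[0.7, 0.3], [0.4, 0.6]]), 5_000, seed=16)
        assert kinetics.vamp2_score(d, d, 1, 1) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(17)
        d = rng.integers(0, 5, size=5_000)
        scores = [kinetics.vamp2_score(d, d, 1, r) for r in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_rank_zero_raises(self):
        with pytest.raises(ValueError):
            kinetics.vamp2_score(np.zeros(10, int), np.zeros(10, int), 1, 0)


@pytest.fixture(scope="module")
def two_state_features():
    T = np.array([[0.95, 0.05], [0.05, 0.95]])
    planted = synthdata.PlantedKinetics(T, means=[[-3.0], [3.0]], covariances=np.ones((2, 1, 1)), seed=0)
    feats = []
    for s in range(6):
        d = synthdata.sample_markov_chain(T, 3_000, seed=20 + s)
        feats.append(synthdata.emit_features(d, planted, seed=30 + s).values)
    return feats


class TestCrossValidation:
    def test_score_stabilizes_at_two_states(self, two_state_features):
        df = kinetics.cross_validate_centers(two_state_features, k_grid=[2, 5, 10], lag=1, folds=3, seed=0, rank=2)
        # ideal rank-2 score at lag 1 is 1 + 0.9^2 = 1.81, resolved already at k=2
        assert df.loc[2, "mean_score"] > 1.6
        assert df["mean_score"].max() - df.loc[2, "mean_score"] < 0.2

    def test_fixed_seed_reproducible(self, two_state_features):
        a = kinetics.cross_validate_centers(two_state_features, k_grid=[2, 4], lag=1, folds=3, seed=1, rank=2)
        b = kinetics.cross_validate_centers(two_state_features, k_grid=[2, 4], lag=1, folds=3, seed=1, rank=2)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_train_test_equals_training_score(self):
        d = synthdata.sample_markov_chain(np.array([[0.9, 0.1], [0.2, 0.8]]), 10_000, seed=21)
        s_train = kinetics.vamp2_score(d, d, 1, 2)
        assert s_train == pytest.approx(kinetics.vamp2_score([d], [d], 1, 2), abs=1e-12)

    def test_too_few_folds_raise(self):
        with pytest.raises(ValueError):
            kinetics.cross_validate_centers([np.zeros((10, 1))], [2], lag=1, folds=1)


class TestSampleEquilibrium:
    def _model(self, pi):
        T = np.tile(np.asarray(pi), (len(pi), 1))
        return kinetics.MSModel(T, np.asarray(pi, float), 1, np.arange(len(pi)))

    def test_degenerate_distribution(self):
        dt = np.array([0] * 5 + [1] * 5)
        s = kinetics.sample_equilibrium(self._model([1.0, 0.0]), [dt], n=100, seed=0)
        assert np.all(dt[s.entries[:, 1]] == 0)

    def test_balanced_counts_within_binomial(self):
        dt = np.array([0] * 50 + [1] * 50)
        s = kinetics.sample_equilibrium(self._model([0.5, 0.5]), [dt], n=30_000, seed=1)
        c0 = int(np.sum(dt[s.entries[:, 1]] == 0))
        assert abs(c0 - 15_000) <= 225

    def test_same_seed_identical(self):
        dt = np.array([0, 1] * 20)
        a = kinetics.sample_equilibrium(self._model([0.4, 0.6]), [dt], n=500, seed=7)
        b = kinetics.sample_equilibrium(self._model([0.4, 0.6]), [dt], n=500, seed=7)
        assert np.array_equal(a.entries, b.entries)

    def test_state_without_frames_raises(self):
        dt = np.array([0] * 10)  # state 1 never visited
        with pytest.raises(ValueError, match="no frames"):
            kinetics.sample_equilibrium(self._model([0.5, 0.5]), [dt], n=10, seed=0)


class TestLagConversion:
    def test_exact_multiple(self):
        assert kinetics.lag_in_frames(10.0, 2.5) == 4

    def test_non_integer_raises(self):
        with pytest.raises(ValueError, match="integer"):
            kinetics.lag_in_frames(10.0, 3.0)
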