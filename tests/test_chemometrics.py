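"""NIPALS PCA/PLSR, median-linkage clustering and MCR-ALS, each checked
against an independent oracle (dense eigensolver, midpoint Lance-Williams
recomputation, scikit-learn PLS, exact bilinear factorizations)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aquaspec as aq
from aquaspec.chemometrics import (cosine_similarity, flag_outliers,
                                   match_components, mcr_als, mlc_cluster,
                                   pca_nipals, pca_press_loo, plsr_fit,
                                   plsr_loo)
from aquaspec.core import SpectraError, average_group, linear_offset_correct
from aquaspec.synthetic import (NOISE_FREE, NoiseModel, shift_free,
                                synthesize_dataset, water_component,
                                polymer_component)

DESIGN = (0.0, 0.01, 0.03, 0.05, 0.07, 0.10)


# ---------------------------------------------------------------------------
# PCA


class TestPCANipals:
    def test_rank_one_matrix_fully_explained(self):
        X = np.outer([1.0, 2.0, 3.0, 4.0], [0.5, -0.2, 0.8])
        m = pca_nipals(X, 1)
        assert m.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 10))
        m = pca_nipals(X, 3)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1]
        for a in range(3):
            v = V[:, order[a]]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.max(np.abs(v - m.loadings[:, a])) <= 1e-8
            assert np.sum(m.scores[:, a] ** 2) == pytest.approx(
                w[order[a]], rel=1e-8)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        m = pca_nipals(rng.normal(size=(8, 12)), 2)
        assert abs(m.scores[:, 0] @ m.scores[:, 1]) <= 1e-10

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 7))
        m = pca_nipals(X, 4)
        assert np.max(np.abs(m.reconstruct() - (X - X.mean(0)))) <= 1e-8

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(3)
        m = pca_nipals(rng.normal(size=(10, 6)), 4)
        ev = m.explained_variance_fraction
        assert np.all(np.diff(ev) <= 1e-12) and np.all(ev >= 0)

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(4)
        m = pca_nipals(rng.normal(size=(6, 5)), 2)
        for a in range(2):
            v = m.loadings[:, a]
            assert v[np.argmax(np.abs(v))] > 0

    @pytest.mark.filterwarnings("ignore:NIPALS PCA component")
    def test_press_reported_per_component_count(self):
        rng = np.random.default_rng(5)
        press = pca_press_loo(rng.normal(size=(8, 5)), 3)
        assert press.shape == (3,) and np.all(press > 0)
        assert np.all(np.diff(press) <= 0)  # more PCs reconstruct better here

    def test_invalid_k_rejected(self):
        with pytest.raises(SpectraError):
            pca_nipals(np.eye(3), 3)


# ---------------------------------------------------------------------------
# Median-linkage clustering


def _median_linkage_oracle(X):
    """Brute-force WPGMC: every cluster is represented by the midpoint of
    the two merged cluster representatives; merge heights are squared
    Euclidean distances between representatives."""
    points = {i: X[i].astype(float) for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(points) > 1:
        ids = sorted(points)
        best = None
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                d = float(np.sum((points[ids[a]] - points[ids[b]]) ** 2))
                if best is None or d < best[0]:
                    best = (d, ids[a], ids[b])
        d, i, j = best
        merges.append((i, j, d))
        points[next_id] = 0.5 * (points[i] + points[j])
        del points[i], points[j]
        next_id += 1
    return merges


class TestMedianLinkage:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)),
                       rng.normal(10, 0.1, (4, 2))])
        labels = mlc_cluster(X, 2).flat_labels(2)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_duplicate_points_merge_first_at_zero(self):
        X = np.array([[0.0, 0.0], [5.0, 1.0], [5.0, 1.0], [9.0, 3.0]])
        tree = mlc_cluster(X, 1)
        a, b, h = tree.merges[0]
        assert {a, b} == {1, 2} and h == 0.0

    @given(st.integers(0, 10_000), st.integers(5, 8))
    @settings(max_examples=40, deadline=None)
    def test_matches_midpoint_lance_williams_oracle(self, seed, n):
        X = np.random.default_rng(seed).normal(size=(n, 3))
        mine = mlc_cluster(X, 1).merges
        oracle = _median_linkage_oracle(X)
        for (a1, b1, h1), (a2, b2, h2) in zip(mine, oracle):
            assert {a1, b1} == {a2, b2}
            assert h1 == pytest.approx(h2, rel=1e-9, abs=1e-12)

    def test_matches_scipy_median_linkage(self):
        from scipy.cluster.hierarchy import linkage
        X = np.random.default_rng(9).normal(size=(9, 4))
        mine = mlc_cluster(X, 1).merges
        Z = linkage(X, method="median")
        assert [{a, b} for a, b, _ in mine] == \
            [{int(r[0]), int(r[1])} for r in Z]
        assert np.allclose([h for *_, h in mine], Z[:, 2] ** 2)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(SpectraError):
            mlc_cluster(np.eye(3), 4)


# ---------------------------------------------------------------------------
# PLSR


class TestPLSR:
    def test_single_informative_channel_perfect_cv(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 6))
        y = 3.0 * X[:, 2]
        X[:, [0, 1, 3, 4, 5]] = 0.0
        cv = plsr_loo(X, y, 1)
        assert cv.r2_cv == pytest.approx(1.0, abs=1e-10)

    def test_training_r2_reaches_one_at_full_rank(self):
        # noise-free response within X's column space
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        y = X @ rng.normal(size=5)
        m = plsr_fit(X, y, 5)
        assert m.r2_per_factor[-1] == pytest.approx(1.0, abs=1e-8)

    def test_explained_variances_cumulative_bounded(self):
        rng = np.random.default_rng(2)
        m = plsr_fit(rng.normal(size=(10, 8)), rng.normal(size=10), 4)
        for seq in (m.explained_x_variance, m.explained_y_variance):
            assert np.all(np.diff(seq) >= -1e-12)
            assert seq[-1] <= 1.0 + 1e-12

    def test_predictions_match_sklearn(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 9))
        y = rng.normal(size=15)
        mine = plsr_fit(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        assert np.allclose(mine.predict(X), ref.predict(X).ravel(),
                           atol=1e-8)

    def test_permuted_response_has_no_cv_skill(self, library, coarse_grid):
        ds = synthesize_dataset([library["cellulose"]], DESIGN, 6, 3,
                                NoiseModel(), seed=7, grid=coarse_grid)
        X = linear_offset_correct(ds).matrix
        y = ds.water_fractions()
        y_perm = np.random.default_rng(0).permutation(y)
        cv = plsr_loo(X, y_perm, 2)
        assert cv.r2_cv <= 0.2

    def test_coefficients_resemble_water_spectrum(self, library, grid):
        p = shift_free(library["PP"])
        ds = synthesize_dataset([p], DESIGN, 3, 1, NoiseModel(0.01, 1e-4),
                                seed=5, grid=grid)
        s = linear_offset_correct(ds)
        m = plsr_fit(s.matrix, s.water_fractions(), 2)
        water = water_component(grid, p, 0.10)
        assert cosine_similarity(m.coef_, water) >= 0.9

    def test_constant_response_rejected(self):
        with pytest.raises(SpectraError):
            plsr_fit(np.eye(4), np.ones(4), 2)

    def test_group_loo_leaves_whole_groups_out(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(9, 4))
        y = X @ rng.normal(size=4)
        groups = np.repeat([0, 1, 2], 3)
        cv = plsr_loo(X, y, 2, groups=groups)
        assert cv.y_pred.shape == (9,)
        assert cv.r2_cv > 0.5


class TestFlagOutliers:
    def test_uniform_residuals_flag_nothing(self):
        cv = aq.CVResult(np.zeros(5), np.full(5, 0.1), 0.0, 0.1)
        assert flag_outliers(cv).size == 0

    def test_spiked_sample_is_flagged(self, library, coarse_grid):
        ds = synthesize_dataset([library["PP"]], DESIGN, 3, 1,
                                NoiseModel(0.0, 1e-4), seed=2,
                                grid=coarse_grid)
        X = linear_offset_correct(ds).matrix.copy()
        y = ds.water_fractions()
        X[7] += np.random.default_rng(0).normal(
            0, 1e-3 * 10, X.shape[1])  # 10x the nominal noise
        cv = plsr_loo(X, y, 2)
        assert 7 in flag_outliers(cv)

    def test_infinite_threshold_flags_nothing(self):
        cv = aq.CVResult(np.arange(5.0), np.arange(5.0) + [0, 0, 9, 0, 0],
                         0.5, 1.0)
        assert flag_outliers(cv, np.inf).size == 0


# ---------------------------------------------------------------------------
# MCR-ALS


class TestMCRALS:
    def test_exact_bilinear_data_fits_immediately(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(0.1, 1.0, (6, 2))
        S = rng.uniform(0.0, 1.0, (2, 20))
        r = mcr_als(C @ S, S, tol=1e-12)
        assert r.lack_of_fit[0] <= 1e-10

    def test_recovers_generator_components(self, library, grid):
        p = shift_free(library["PP"])
        ds = synthesize_dataset([p], DESIGN, 1, 1, NoiseModel(0.0, 1e-4),
                                seed=3, grid=grid)
        avg = average_group(linear_offset_correct(ds))
        poly_true = polymer_component(grid, p, 0.0)
        water_true = water_component(grid, p, 0.10)
        S0 = np.vstack([np.maximum(avg.matrix[0], 0.0),
                        np.maximum(water_true, 0.0)])
        r = mcr_als(avg.matrix, S0)
        perm = match_components(r.S, np.vstack([poly_true, water_true]))
        assert cosine_similarity(r.S[perm[0]], poly_true) >= 0.99
        assert cosine_similarity(r.S[perm[1]], water_true) >= 0.99

    def test_lack_of_fit_non_increasing(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(size=(8, 15)))
        S0 = np.abs(rng.normal(size=(2, 15)))
        r = mcr_als(X, S0, tol=0.0, max_iter=30)
        assert np.all(np.diff(r.lack_of_fit) <= 1e-12)

    def test_factors_strictly_non_negative(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 12))  # signed data still yields C,S >= 0
        r = mcr_als(X, np.abs(rng.normal(size=(2, 12))), max_iter=20)
        assert np.min(r.C) >= 0.0 and np.min(r.S) >= 0.0

    def test_three_component_path_matches_scipy_nnls(self):
        rng = np.random.default_rng(6)
        C = rng.uniform(0.0, 1.0, (7, 3))
        S = rng.uniform(0.0, 1.0, (3, 11))
        r = mcr_als(C @ S, S + 0.01, tol=1e-12, max_iter=50)
        assert r.lack_of_fit[-1] <= 1e-6

    def test_negative_init_rejected(self):
        with pytest.raises(SpectraError):
            mcr_als(np.ones((3, 4)), -np.ones((2, 4)))

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(SpectraError):
            mcr_als(np.zeros((3, 4)), np.ones((2, 4)))
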