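"""Tests for PCA-LDA fitting, projection, ranking, permutation, curves.

The Fisher-direction tests check the fitted discriminant against two
independent oracles: the closed form (pooled within-covariance inverse times
the mean difference) and a brute-force grid search over unit directions
maximizing the between/within scatter ratio.
"""

import numpy as np
import pytest

from lipidlda import (
    BinGrid,
    EventMeta,
    IntensityMatrix,
    PCALDAModel,
    crossval_fullgroup,
    fit_pcalda,
    learning_curve,
    mahalanobis_d2,
    permute_labels,
    project,
    rank_loadings,
    restrict_features,
)
from lipidlda.markers import MARKER_BINS
from lipidlda.model import project_points

from conftest import make_toy_model


def _matrix_from_values(values, labels, specimens=None, grid=None, columns=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    specimens = specimens if specimens is not None else [f"s{i}" for i in range(n)]
    meta = [
        EventMeta(f"e{i}", str(specimens[i]), str(labels[i]), 10.0, 1e6)
        for i in range(n)
    ]
    grid = grid or BinGrid()
    if columns is None and values.shape[1] != grid.n_bins:
        columns = np.arange(values.shape[1]) * 0.1 + 100.05
    return IntensityMatrix(grid=grid, values=values, meta=meta, column_labels=columns)


def _two_class_gaussian(seed=0, n=300):
    rng = np.random.default_rng(seed)
    within = np.array([[1.0, 0.3], [0.3, 2.0]])
    L = np.linalg.cholesky(within)
    x0 = rng.standard_normal((n, 2)) @ L.T
    x1 = rng.standard_normal((n, 2)) @ L.T + np.array([4.0, 1.0])
    X = np.vstack([x0, x1])
    y = np.array(["a"] * n + ["b"] * n, dtype=object)
    return X, y


def _bin_space_direction(model):
    B = model.pc_loadings @ model.lda_axes
    return B[:, 0] / np.linalg.norm(B[:, 0])


class TestFisherOracles:
    def test_closed_form_direction(self):
        X, y = _two_class_gaussian(seed=3)
        m = fit_pcalda(_matrix_from_values(X, y), y, n_components=2)
        # oracle: w* proportional to Sw^-1 (mu_b - mu_a), from the sample
        mu_a, mu_b = X[y == "a"].mean(axis=0), X[y == "b"].mean(axis=0)
        Sw = (np.cov(X[y == "a"], rowvar=False) * (299)
              + np.cov(X[y == "b"], rowvar=False) * (299)) / (600 - 2)
        w_star = np.linalg.solve(Sw, mu_b - mu_a)
        w_star /= np.linalg.norm(w_star)
        cos = abs(_bin_space_direction(m) @ w_star)
        assert cos > 0.999

    def test_brute_force_scatter_ratio(self):
        X, y = _two_class_gaussian(seed=8)
        m = fit_pcalda(_matrix_from_values(X, y), y, n_components=2)
        mus = np.stack([X[y == c].mean(axis=0) for c in ("a", "b")])
        mbar = mus.mean(axis=0)
        Sb = (mus - mbar).T @ (mus - mbar) / 2
        Sw = np.zeros((2, 2))
        for c in ("a", "b"):
            D = X[y == c] - X[y == c].mean(axis=0)
            Sw += D.T @ D
        Sw /= X.shape[0] - 2
        thetas = np.linspace(0, np.pi, 20000, endpoint=False)
        dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
        ratios = np.einsum("ij,jk,ik->i", dirs, Sb, dirs) / np.einsum(
            "ij,jk,ik->i", dirs, Sw, dirs)
        w_best = dirs[np.argmax(ratios)]
        cos = abs(_bin_space_direction(m) @ w_best)
        assert cos > 0.999

    def test_one_dimensional_separation(self):
        # unit within-class variance, means 0 and 4: with the within-sphered
        # axis convention, centroid separation equals |mu_b - mu_a| / sigma_w
        rng = np.random.default_rng(5)
        n = 2000
        x = np.concatenate([rng.standard_normal(n), rng.standard_normal(n) + 4.0])
        y = np.array(["a"] * n + ["b"] * n, dtype=object)
        m = fit_pcalda(_matrix_from_values(x[:, None], y), y, n_components=1)
        gap = abs(m.centroids_[1, 0] - m.centroids_[0, 0])
        assert gap == pytest.approx(4.0, rel=0.1)


class TestFitContracts:
    def test_label_name_invariance_up_to_sign(self, sep_matrix):
        y1 = sep_matrix.labels
        rename = {"mening": "zz", "schwan": "aa", "metast": "mm"}  # reorders sort
        y2 = np.array([rename[c] for c in y1], dtype=object)
        m1 = fit_pcalda(sep_matrix, y1)
        m2 = fit_pcalda(sep_matrix, y2)
        z1, z2 = project(m1, sep_matrix), project(m2, sep_matrix)
        for j in range(z1.shape[1]):
            same = np.allclose(z1[:, j], z2[:, j], atol=1e-8)
            flipped = np.allclose(z1[:, j], -z2[:, j], atol=1e-8)
            assert same or flipped

    def test_three_class_model_shape_and_separation(self, sep_model):
        assert sep_model.n_discriminants == 2
        assert len(sep_model.classes_) == 3
        # pairwise centroid Mahalanobis distance beyond the SD gate
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                d2 = mahalanobis_d2(sep_model, sep_model.centroids_[j])
                assert np.sqrt(d2[i]) > sep_model.sd_gate

    def test_at_most_c_minus_1_discriminants(self, sep_model):
        assert sep_model.n_discriminants <= len(sep_model.classes_) - 1

    def test_too_few_classes_or_events_rejected(self):
        X = np.random.default_rng(0).uniform(size=(6, 4))
        with pytest.raises(ValueError):
            fit_pcalda(_matrix_from_values(X, ["a"] * 6), ["a"] * 6)
        with pytest.raises(ValueError):
            fit_pcalda(_matrix_from_values(X, ["a"] * 5 + ["b"]), ["a"] * 5 + ["b"])

    def test_json_roundtrip(self, sep_model, sep_matrix, tmp_path):
        path = tmp_path / "model.json"
        sep_model.to_json(path)
        back = PCALDAModel.from_json(path)
        np.testing.assert_allclose(project(back, sep_matrix), project(sep_model, sep_matrix))
        assert back.classes_ == sep_model.classes_
        assert back.sd_gate == sep_model.sd_gate


class TestProject:
    def test_training_scores_reproduced(self, sep_model, sep_matrix):
        z1 = project(sep_model, sep_matrix)
        z2 = project(sep_model, sep_matrix)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_global_mean_maps_to_origin(self, sep_model):
        z = project_points(sep_model, sep_model.mean_)
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_duplicated_rows_duplicate_scores(self, sep_model, sep_matrix):
        dup = sep_matrix.subset_rows(np.array([0, 0, 1]))
        z = project(sep_model, dup)
        np.testing.assert_allclose(z[0], z[1])

    def test_grid_mismatch_hard_error(self, sep_model, sep_matrix):
        wrong = restrict_features(sep_matrix, list(MARKER_BINS))
        with pytest.raises(ValueError, match="feature bins"):
            project(sep_model, wrong)


class TestRankLoadings:
    def test_single_informative_bin_ranks_first(self):
        rng = np.random.default_rng(1)
        n = 40
        X = np.full((n, 30), 0.5) + rng.normal(0, 1e-6, (n, 30))
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        X[:20, 7] += 5.0  # the only class-informative column
        m = fit_pcalda(_matrix_from_values(X, y), y, n_components=2)
        ranking = rank_loadings(m, top_n=5)
        assert ranking.bins[0] == pytest.approx(100.05 + 0.1 * 7)

    def test_tie_broken_by_ascending_label(self):
        m = make_toy_model(centroids=[[0.0, 0.0], [1.0, 1.0]],
                           covariances=[np.eye(2), np.eye(2)])
        ranking = rank_loadings(m, top_n=2)
        assert list(ranking.bins) == sorted(ranking.bins)
        assert ranking.scores[0] == pytest.approx(ranking.scores[1])

    def test_top_n_larger_than_bins_warns_and_returns_all(self, sep_model):
        with pytest.warns(UserWarning, match="returning all"):
            ranking = rank_loadings(sep_model, top_n=10**6)
        assert len(ranking) == sep_model.feature_bins.size

    def test_scores_descending(self, sep_model):
        ranking = rank_loadings(sep_model, top_n=100)
        assert np.all(np.diff(ranking.scores) <= 1e-12)


class TestPermuteLabels:
    @staticmethod
    def _cohort(n_spec=6, events=4):
        labels, groups = [], []
        for c in ("a", "b", "c"):
            for s in range(n_spec):
                for _ in range(events):
                    labels.append(c)
                    groups.append(f"{c}{s}")
        return np.array(labels, dtype=object), np.array(groups, dtype=object)

    def test_pseudo_classes_mix_true_classes(self):
        labels, groups = self._cohort()
        perm = permute_labels(labels, groups, seed=0)
        for pseudo in ("a", "b", "c"):
            true_mix = {c: int(np.sum(labels[perm == pseudo] == c)) for c in "abc"}
            total = sum(true_mix.values())
            for c in "abc":
                assert abs(true_mix[c] - total / 3) <= total / 6  # ~1/3 each

    def test_multiset_conserved_and_specimen_coherent(self):
        labels, groups = self._cohort()
        perm = permute_labels(labels, groups, seed=3)
        assert sorted(perm) == sorted(labels)
        for g in set(groups):
            assert len(set(perm[groups == g])) == 1

    def test_deterministic(self):
        labels, groups = self._cohort()
        np.testing.assert_array_equal(
            permute_labels(labels, groups, seed=5), permute_labels(labels, groups, seed=5)
        )

    def test_single_specimen_class_errors(self):
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        groups = np.array(["s1", "s1", "s2", "s3"], dtype=object)
        with pytest.raises(ValueError, match="single specimen"):
            permute_labels(labels, groups)

    def test_inconsistent_specimen_labels_error(self):
        with pytest.raises(ValueError, match="more than one class"):
            permute_labels(["a", "b"], ["s1", "s1"])


class TestRestrictFeatures:
    def test_marker_subset_has_41_columns(self, sep_matrix):
        sub = restrict_features(sep_matrix, list(MARKER_BINS))
        assert sub.values.shape[1] == 41
        np.testing.assert_allclose(sub.column_labels, MARKER_BINS)

    def test_restrict_to_all_is_identity(self, sep_matrix):
        sub = restrict_features(sep_matrix, list(sep_matrix.column_labels))
        np.testing.assert_array_equal(sub.values, sep_matrix.values)

    def test_single_bin_model_still_fits(self, sep_matrix):
        sub = restrict_features(sep_matrix, [MARKER_BINS[0]])
        m = fit_pcalda(sub)
        assert m.n_discriminants == 1
        z = project(m, sub)
        assert z.shape == (sep_matrix.n_events, 1)

    def test_unknown_bin_label_hard_error(self, sep_matrix):
        with pytest.raises(KeyError):
            restrict_features(sep_matrix, [123.456])


class TestLearningCurve:
    def test_fraction_one_matches_fullgroup_cv(self, sep_matrix):
        curve = learning_curve(sep_matrix, sep_matrix.labels, sep_matrix.specimens,
                               fractions=[0.5, 1.0], reps=2, seed=0)
        ref = crossval_fullgroup(sep_matrix, sep_matrix.labels, sep_matrix.specimens)
        full = curve.loc[curve["fraction"] == 1.0, "mean_accuracy"].iloc[0]
        assert full == pytest.approx(ref.accuracy)

    def test_unsorted_or_incomplete_fractions_rejected(self, sep_matrix):
        with pytest.raises(ValueError):
            learning_curve(sep_matrix, sep_matrix.labels, sep_matrix.specimens,
                           fractions=[1.0, 0.5])
        with pytest.raises(ValueError):
            learning_curve(sep_matrix, sep_matrix.labels, sep_matrix.specimens,
                           fractions=[0.5, 0.75])

    def test_tiny_fraction_skipped_with_warning(self, sep_matrix):
        with pytest.warns(UserWarning, match="skipped"):
            curve = learning_curve(sep_matrix, sep_matrix.labels, sep_matrix.specimens,
                                   fractions=[0.1, 1.0], reps=1, seed=0)
        assert 0.1 not in set(curve["fraction"])


class TestRefitIdempotence:
    def test_cv_accuracy_stable_under_refit_on_scores(self, sep_matrix, sep_model):
        z = project(sep_model, sep_matrix)
        zmat = _matrix_from_values(
            z, sep_matrix.labels, specimens=sep_matrix.specimens, grid=sep_matrix.grid
        )
        r1 = crossval_fullgroup(sep_matrix, sep_matrix.labels, sep_matrix.specimens)
        r2 = crossval_fullgroup(zmat, zmat.labels, zmat.specimens)
        assert abs(r1.accuracy - r2.accuracy) < 1e-6
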