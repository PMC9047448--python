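import numpy as np
import pytest

from msicelltyper import recognizer as rec, synthetic_data as sd
from msicelltyper.library_builder import SpectralLibrary
from msicelltyper.preprocess import BinGrid, bin_spectrum, rms_normalize

from oracles import align_signs, brute_force_lda


def toy_library(X, lines, subtypes=None, grid=None):
    X = np.asarray(X, float)
    n = X.shape[0]
    grid = grid or BinGrid(600.0, 600.0 + 0.2 * X.shape[1], 0.2)
    subtypes = subtypes or ["TRIPLE_NEG"] * n
    return SpectralLibrary(
        grid=grid, X=X,
        line_labels=np.array(lines, dtype=object),
        subtype_labels=np.array(subtypes, dtype=object),
        slide_ids=np.array([f"s{i % 2}" for i in range(n)], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
    )


class TestFitModel:
    def test_two_class_geometry(self, rng):
        # two noiseless distinct spectra, duplicated: 1 LDA direction, separated
        a, b = rng.uniform(0.5, 2.0, 6), rng.uniform(0.5, 2.0, 6)
        lib = toy_library([a, a, b, b], ["A", "A", "B", "B"])
        model = rec.fit_model(lib)
        assert model.n_discriminants == 1
        ya = model.project(a[None, :])[0]
        yb = model.project(b[None, :])[0]
        assert np.linalg.norm(ya - yb) > 0
        assert rec.classify(model, a, "force")[0] == "A"
        assert rec.classify(model, b, "force")[0] == "B"

    def test_pca_component_count_matches_variance_criterion(self, cellline_model):
        evr = cellline_model.explained_variance_ratio_
        k = cellline_model.n_components
        assert np.sum(evr[:k]) >= 0.95 - 1e-12
        assert np.sum(evr[: k - 1]) < 0.95

    def test_pca_components_orthonormal(self, cellline_model):
        P = cellline_model.components_
        np.testing.assert_allclose(P @ P.T, np.eye(P.shape[0]), atol=1e-10)

    def test_label_levels_give_14_and_3_classes(self, library):
        m14 = rec.fit_model(library, "cell_line")
        m3 = rec.fit_model(library, "subtype")
        assert len(m14.class_labels) == 14
        assert len(m3.class_labels) == 3
        assert m3.class_labels == sorted(sd.SUBTYPES)

    def test_one_row_class_rejected(self, rng):
        lib = toy_library(rng.uniform(0, 1, (3, 4)), ["A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            rec.fit_model(lib)


class TestClassify:
    def test_centroid_preimage_hits_class_with_zero_distance(self, rng):
        a, b = rng.uniform(0.5, 2.0, 5), rng.uniform(0.5, 2.0, 5)
        lib = toy_library([a, a, b, b], ["A", "A", "B", "B"])
        model = rec.fit_model(lib)
        label, dist = rec.classify(model, a, "outlier")
        assert label == "A"
        assert dist["A"] == pytest.approx(0.0, abs=1e-6)

    def test_constructed_far_vector_is_outlier_only_in_outlier_mode(self, cellline_model):
        model = cellline_model
        # build a spectrum whose discriminant-space image sits far from all centroids
        far_y = model.centroids_.max(axis=0) + 100.0 * model.dispersions_.max()
        a = far_y @ np.linalg.pinv(model.scalings_)
        x = model.mean_ + a @ model.components_
        d = np.linalg.norm(model.project(x[None, :])[0] - model.centroids_, axis=1)
        assert np.all(d > model.outlier_multiplier * model.dispersions_)
        assert rec.classify(model, x, "outlier")[0] == rec.OUTLIER
        assert rec.classify(model, x, "force")[0] in model.class_labels

    def test_force_mode_never_outlier(self, cellline_model, rng):
        X = rng.uniform(0, 1, (20, cellline_model.grid.n_bins))
        labels, _ = rec._classify_matrix(cellline_model, X, "force")
        assert rec.OUTLIER not in set(labels)

    def test_grid_mismatch_rejected(self, cellline_model):
        with pytest.raises(ValueError, match="does not match"):
            rec.classify(cellline_model, np.ones(7), "force")


class TestLdaOracle:
    def test_projections_and_labels_match_brute_force(self, rng):
        # tiny dense problem: 12 rows, 5 bins, 3 classes
        centers = rng.uniform(1.0, 3.0, (3, 5))
        X = np.vstack([c + rng.normal(0, 0.05, (4, 5)) for c in centers])
        y = np.repeat(["A", "B", "C"], 4)
        lib = toy_library(X, list(y))
        model = rec.fit_model(lib, variance_kept=1.0)
        mine = model.project(X)
        oracle_y, oracle_cents, oracle_labels = brute_force_lda(X, y)
        assert mine.shape == oracle_y.shape
        aligned = align_signs(mine, oracle_y)
        np.testing.assert_allclose(mine, aligned, atol=1e-8)
        labels, _ = rec._classify_matrix(model, X, "force")
        np.testing.assert_array_equal(labels, oracle_labels)

    def test_agrees_with_sklearn_discriminant_labels(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        centers = rng.uniform(1.0, 3.0, (3, 5))
        X = np.vstack([c + rng.normal(0, 0.3, (6, 5)) for c in centers])
        y = np.repeat(["A", "B", "C"], 6)
        model = rec.fit_model(toy_library(X, list(y)), variance_kept=1.0)
        labels, _ = rec._classify_matrix(model, X, "force")
        skl = LinearDiscriminantAnalysis(solver="eigen").fit(X, y).predict(X)
        assert np.mean(labels == skl) >= 0.95


class TestCrossval:
    def test_noiseless_separable_library_is_perfect(self, panel):
        profiles = sd.make_profiles(14, panel, separation=1.0, seed=2)
        lib = sd.synthetic_library(profiles, 10, panel, noise_cv=0.0, seed=2)
        report = rec.crossval(lib, "cell_line", k=5, seed=0)
        assert report.rate_excluding_outliers == pytest.approx(100.0)

    def test_rates_match_recount_of_predictions(self, library):
        report = rec.crossval(library, "cell_line", k=5, seed=42)
        correct = int(np.sum(report.truth == report.predicted))
        n_out = int(np.sum(report.predicted == rec.OUTLIER))
        n = len(report.truth)
        assert report.rate_excluding_outliers == pytest.approx(
            100.0 * correct / (n - n_out)
        )
        assert report.rate_including_outliers == pytest.approx(100.0 * correct / n)
        assert report.confusion.to_numpy().sum() == n
        # rate ordering: outliers only ever subtract from the denominator
        assert report.rate_including_outliers <= report.rate_excluding_outliers

    def test_seeded_determinism(self, library):
        a = rec.crossval(library, "subtype", k=5, seed=7)
        b = rec.crossval(library, "subtype", k=5, seed=7)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_small_class_rejected_by_name(self, rng):
        X = rng.uniform(0, 1, (9, 4))
        lib = toy_library(X, ["A"] * 5 + ["B"] * 4)
        with pytest.raises(ValueError, match="B"):
            rec.crossval(lib, k=5)


class TestHoldout:
    def test_two_thirds_split_sizes(self, panel):
        profiles = sd.make_profiles(3, panel, separation=1.0, seed=4)
        lib = sd.synthetic_library(profiles, 15, panel, noise_cv=0.02, seed=4)
        report = rec.holdout_validate(lib, "cell_line", seed=0)
        # class of 15 cells -> 10 train / 5 validation
        counts = {c: int(np.sum(report.truth == c)) for c in set(report.truth)}
        assert all(v == 5 for v in counts.values())
        assert report.rate_excluding_outliers == pytest.approx(100.0)

    def test_split_contract_holds_for_any_seed(self, panel):
        profiles = sd.make_profiles(3, panel, separation=1.0, seed=4)
        lib = sd.synthetic_library(profiles, 9, panel, noise_cv=0.05, seed=4)
        for seed in (1, 2, 3):
            r = rec.holdout_validate(lib, seed=seed)
            counts = {c: int(np.sum(r.truth == c)) for c in set(r.truth)}
            # round(2/3 * 9) = 6 train, 3 validation per class
            assert all(v == 3 for v in counts.values())

    def test_too_small_class_rejected(self, rng):
        lib = toy_library(rng.uniform(0, 1, (5, 4)), ["A"] * 3 + ["B"] * 2)
        with pytest.raises(ValueError, match="B"):
            rec.holdout_validate(lib)


class TestUnseenClassRejection:
    def test_unseen_15th_class_flagged_outlier(self, panel):
        profiles = sd.make_profiles(15, panel, separation=2.0, seed=3)
        lib = sd.synthetic_library(profiles[:14], 16, panel, noise_cv=0.05, seed=3)
        model = rec.fit_model(lib, "cell_line")
        rng = np.random.default_rng(9)
        flagged = 0
        n_draws = 50
        for _ in range(n_draws):
            spec = sd.synth_spectrum(profiles[14], panel, noise_cv=0.05, rng=rng)
            x = bin_spectrum(rms_normalize(spec), lib.grid).values
            flagged += rec.classify(model, x, "outlier")[0] == rec.OUTLIER
        assert flagged / n_draws >= 0.9
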