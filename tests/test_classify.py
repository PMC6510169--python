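import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from chanpred.classify import (
    CascadeModel,
    ConfusionMatrix,
    StageConfig,
    average_accuracy,
    cross_validate,
    grid_search_svm,
    overall_accuracy,
    predict_cascade,
    sensitivity,
    stage_labels,
    train_cascade,
    train_stage,
)
from chanpred.errors import ConfigurationError, InputDataError
from chanpred.features import encode_dataset
from chanpred.seqio import ProteinSequence
from chanpred.simulate import ClassProfile, benchmark_like_profiles, generate_dataset


def blobs(n_per_class=10, gap=10.0, seed=0):
    """Linearly separable two-class point cloud."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.5, size=(n_per_class, 2))
    b = rng.normal(gap, 0.5, size=(n_per_class, 2))
    X = pd.DataFrame(
        np.vstack([a, b]),
        columns=["x", "y"],
        index=[f"i{i:03d}" for i in range(2 * n_per_class)],
    )
    labels = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return X, labels


class TestMetrics:
    def test_hand_computed_binary_matrix(self):
        conf = ConfusionMatrix(np.array([[9, 1], [2, 8]]), ["pos", "neg"])
        assert sensitivity(conf, "pos") == pytest.approx(90.0)
        assert sensitivity(conf, "neg") == pytest.approx(80.0)
        assert overall_accuracy(conf) == pytest.approx(85.0)
        assert average_accuracy(conf) == pytest.approx(85.0)

    def test_diagonal_matrix_is_perfect(self):
        conf = ConfusionMatrix(np.diag([5, 3, 7, 2]), ["K", "Ca", "Na", "anion"])
        assert all(sensitivity(conf, i) == 100.0 for i in range(4))
        assert overall_accuracy(conf) == 100.0
        assert average_accuracy(conf) == 100.0

    def test_all_misses_row_gives_zero_sensitivity(self):
        conf = ConfusionMatrix(np.array([[0, 5], [0, 5]]), ["a", "b"])
        assert sensitivity(conf, "a") == 0.0

    def test_majority_only_predictor_on_imbalanced_data(self):
        # 90/10 split, everything predicted as the majority class
        conf = ConfusionMatrix(np.array([[90, 0], [10, 0]]), ["maj", "min"])
        assert overall_accuracy(conf) == pytest.approx(90.0)
        assert average_accuracy(conf) == pytest.approx(50.0)

    def test_empty_row_excluded_from_aa(self):
        conf = ConfusionMatrix(np.array([[4, 0], [0, 0]]), ["a", "b"])
        assert np.isnan(sensitivity(conf, "b"))
        assert average_accuracy(conf) == pytest.approx(100.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_oa_is_row_total_weighted_mean_of_sn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        counts = rng.integers(1, 30, size=(n, n))
        conf = ConfusionMatrix(counts, [f"c{i}" for i in range(n)])
        row_totals = counts.sum(axis=1)
        sns = np.array([sensitivity(conf, i) for i in range(n)])
        weighted = (sns * row_totals).sum() / row_totals.sum()
        assert overall_accuracy(conf) == pytest.approx(weighted)

    def test_balanced_classes_make_oa_equal_aa(self):
        conf = ConfusionMatrix(np.array([[7, 3], [4, 6]]), ["a", "b"])
        assert overall_accuracy(conf) == pytest.approx(average_accuracy(conf))


class TestGridSearch:
    def test_singleton_grid_returned(self):
        X, y = blobs()
        assert grid_search_svm(X, y, c_grid=[4.0], g_grid=[0.25], folds=2) == (4.0, 0.25)

    def test_separable_data_reaches_perfect_oa(self):
        X, y = blobs()
        c, g = grid_search_svm(X, y, c_grid=[1.0, 10.0], g_grid=[0.1, 1.0], folds=5)
        cv = cross_validate(X, y, folds=5, backend="svm-rbf", params={"c": c, "g": g})
        assert cv.oa == 100.0

    def test_ties_resolve_to_smallest_c_then_g(self):
        # everything separates these blobs, so all OAs tie at 100
        X, y = blobs()
        best = grid_search_svm(X, y, c_grid=[8.0, 1.0], g_grid=[1.0, 0.1], folds=3)
        assert best == (1.0, 0.1)

    def test_empty_grid_rejected(self):
        X, y = blobs()
        with pytest.raises(ConfigurationError):
            grid_search_svm(X, y, c_grid=[], g_grid=[1.0])


class TestTrainStage:
    def test_memorizes_separable_training_data(self):
        X, y = blobs()
        model = train_stage(X, y, backend="random-forest")
        assert np.mean(model.predict(X) == y) == 1.0

    def test_same_seed_same_predictions(self):
        X, y = blobs()
        p1 = train_stage(X, y, seed=7).predict(X)
        p2 = train_stage(X, y, seed=7).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_dimension_mismatch_rejected(self):
        X, y = blobs()
        model = train_stage(X, y)
        with pytest.raises(InputDataError, match="mismatch"):
            model.predict(np.ones((1, 5)))

    def test_tiny_class_error_names_the_class(self):
        X, _ = blobs(5)
        y = np.array(["a"] * 9 + ["rare"])
        with pytest.raises(InputDataError, match="rare"):
            train_stage(X, y)


class TestCrossValidate:
    def test_separable_data_perfect(self):
        X, y = blobs()
        cv = cross_validate(X, y, folds=5, seed=0)
        assert cv.oa == 100.0 and cv.aa == 100.0

    def test_instance_order_invariance(self):
        X, y = blobs(12, gap=2.0, seed=3)
        base = cross_validate(X, y, folds=4, seed=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        shuffled = cross_validate(X.iloc[perm], y[perm], folds=4, seed=1)
        np.testing.assert_array_equal(base.confusion.counts, shuffled.confusion.counts)

    def test_folds_reduced_for_tiny_class(self, caplog):
        X, _ = blobs(10)
        y = np.array(["a"] * 17 + ["b"] * 3)
        with caplog.at_level("WARNING"):
            cv = cross_validate(X, y, folds=10, seed=0)
        assert "reducing folds" in caplog.text
        assert cv.confusion.total == 20

    def test_folds_below_2_rejected(self):
        X, y = blobs()
        with pytest.raises(ConfigurationError):
            cross_validate(X, y, folds=1)

    def test_per_fold_scaling_differs_from_leaky_variant(self):
        """Refitting the scaler inside each fold must change the pooled
        result relative to fitting it once on the full data, on data whose
        scale is dominated by a single extreme outlier."""
        rng = np.random.default_rng(0)
        n = 40
        y = np.array(["a"] * 20 + ["b"] * 20)
        f0 = np.where(y == "a", 0.0, 1.0) + rng.normal(0, 0.05, n)
        f0[0] = 1000.0
        X = pd.DataFrame(
            {"f0": f0, "f1": rng.normal(size=n)},
            index=[f"i{i:02d}" for i in range(n)],
        )
        params = {"c": 1.0, "g": 1.0}
        clean = cross_validate(X, y, folds=5, seed=0, backend="svm-rbf", params=params)

        order = np.argsort(X.index.astype(str).to_numpy(), kind="stable")
        Xs, ys = X.iloc[order], y[order]
        S = MinMaxScaler().fit_transform(Xs.to_numpy())  # deliberately leaky
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        y_true, y_pred = [], []
        for tr, te in skf.split(np.zeros(n), ys):
            est = SVC(kernel="rbf", C=1.0, gamma=1.0, random_state=0).fit(S[tr], ys[tr])
            y_pred.extend(est.predict(S[te]))
            y_true.extend(ys[te])
        leaky = ConfusionMatrix(
            np.array(
                [
                    [sum(t == "a" and p == "a" for t, p in zip(y_true, y_pred)),
                     sum(t == "a" and p == "b" for t, p in zip(y_true, y_pred))],
                    [sum(t == "b" and p == "a" for t, p in zip(y_true, y_pred)),
                     sum(t == "b" and p == "b" for t, p in zip(y_true, y_pred))],
                ]
            ),
            ["a", "b"],
        )
        assert not np.array_equal(clean.confusion.counts, leaky.counts)


@pytest.fixture(scope="module")
def small_cascade():
    """Cascade trained on a small well-separated synthetic dataset."""
    profiles = [
        ClassProfile(p.label, p.frequencies, (50, 80), 8)
        for p in benchmark_like_profiles("high")
    ]
    dataset = generate_dataset(profiles, seed=11)
    model = train_cascade(dataset, seed=11)
    return model


class TestCascade:
    def test_stage_label_derivation(self):
        six = ["non-ion", "ligand", "K", "Ca", "Na", "anion"]
        assert stage_labels(six, "ion") == ["non-ion", "ion", "ion", "ion", "ion", "ion"]
        assert stage_labels(six, "gating") == [
            None, "ligand", "voltage", "voltage", "voltage", "voltage",
        ]
        assert stage_labels(six, "subtype") == [None, None, "K", "Ca", "Na", "anion"]

    def test_non_ion_short_circuits_with_trail_length_1(self, small_cascade):
        ds = generate_dataset(
            [
                ClassProfile(
                    "non-ion",
                    benchmark_like_profiles("high")[5].frequencies,
                    (50, 80),
                    5,
                )
            ],
            seed=21,
        )
        for seq in ds.sequences:
            label, trail = predict_cascade(seq, small_cascade)
            if label == "non-ion":
                assert [s for s, _ in trail] == ["ion"]

    def test_output_space_and_trail_lengths(self, small_cascade):
        ds = generate_dataset(benchmark_like_profiles("high", counts={
            "K": 3, "Ca": 3, "Na": 3, "anion": 3, "ligand": 3, "non-ion": 3,
        }, length_range=(50, 80)), seed=31)
        allowed = {"non-ion", "ligand", "K", "Ca", "Na", "anion"}
        for seq in ds.sequences:
            label, trail = predict_cascade(seq, small_cascade)
            assert label in allowed
            assert len(trail) in (1, 2, 3)
            assert label == trail[-1][1] or (label == "non-ion" and trail[-1][1] == "non-ion")

    def test_k_like_sequences_recovered(self, small_cascade):
        """Sequences drawn from the K-channel profile are routed
        ion -> voltage -> K by a cascade trained on well-separated data."""
        k_profile = benchmark_like_profiles("high")[0]
        ds = generate_dataset(
            [ClassProfile("K", k_profile.frequencies, (50, 80), 100)], seed=41
        )
        labels = [predict_cascade(seq, small_cascade)[0] for seq in ds.sequences]
        assert np.mean(np.array(labels) == "K") >= 0.9

    def test_invalid_sequence_propagates_stage_context(self, small_cascade):
        bad = ProteinSequence("bad", "ACXDEFGHIKLMNP")
        with pytest.raises(InputDataError, match="ion"):
            predict_cascade(bad, small_cascade)

    def test_save_load_roundtrip_is_deterministic(self, small_cascade, tmp_path):
        path = tmp_path / "cascade.joblib"
        small_cascade.save(path)
        loaded = CascadeModel.load(path)
        ds = generate_dataset(
            [ClassProfile("K", benchmark_like_profiles("high")[0].frequencies, (50, 80), 5)],
            seed=51,
        )
        for seq in ds.sequences:
            assert predict_cascade(seq, small_cascade) == predict_cascade(seq, loaded)

    def test_incompatible_bundle_version_refused(self, small_cascade, tmp_path):
        import joblib

        path = tmp_path / "old.joblib"
        joblib.dump({"format_major": 99, "model": small_cascade}, path)
        with pytest.raises(ConfigurationError, match="incompatible"):
            CascadeModel.load(path)

    def test_non_six_scheme_rejected(self):
        from chanpred.seqio import LabeledDataset

        ds = LabeledDataset([], scheme="ion")
        with pytest.raises(ConfigurationError):
            train_cascade(ds)
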