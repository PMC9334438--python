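import numpy as np
import pandas as pd
import pytest

from vocalid.speaker_space import (
    CollinearityFilter,
    SpeakerLDA,
    acoustic_distance,
    classification_success,
    collinearity_filter,
    distance_table,
    select_markers,
)


def gaussian_corpus(rng, n_groups=3, n_per=10, p=4, sep=4.0):
    """Feature-table stand-in: Gaussian clusters, one per speaker."""
    X = rng.normal(size=(n_groups * n_per, p))
    y = np.repeat(np.arange(n_groups), n_per)
    means = rng.normal(scale=sep, size=(n_groups, p))
    X += means[y]
    return X, y


class TestCollinearityFilter:
    def test_identical_columns_keep_exactly_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        df = pd.DataFrame({"f0_mean": a, "f0_max": a.copy(), "ppj": rng.normal(size=50)})
        kept = collinearity_filter(df, features=["f0_mean", "f0_max", "ppj"], r_max=0.8)
        assert "ppj" in kept
        assert ("f0_mean" in kept) != ("f0_max" in kept)

    def test_orthogonal_columns_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        kept = collinearity_filter(df, features=list("abcde"), r_max=0.8)
        assert kept == list("abcde")

    def test_derived_feature_triple_resolved(self):
        # range = max - min: never keep the child plus both parents
        rng = np.random.default_rng(2)
        mx = rng.normal(200, 30, 300)
        mn = mx - np.abs(rng.normal(40, 5, 300))
        df = pd.DataFrame({"f0_max": mx, "f0_min": mn, "f0_range": mx - mn})
        kept = collinearity_filter(df, features=["f0_range", "f0_max", "f0_min"], r_max=0.8)
        corr = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.8

    def test_invalid_r_max(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                collinearity_filter(df, features=["a", "b"], r_max=bad)

    def test_transformer_roundtrip(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=100)
        df = pd.DataFrame({"a": a, "b": a + 1e-9 * rng.normal(size=100), "c": rng.normal(size=100)})
        f = CollinearityFilter(r_max=0.9, features=["a", "b", "c"]).fit(df)
        assert len(f.retained_) == 2
        assert f.transform(df).shape[1] == 2


class TestSpeakerLDA:
    def test_matches_brute_force_generalized_eigenproblem(self):
        rng = np.random.default_rng(4)
        X, y = gaussian_corpus(rng, n_groups=3, n_per=10, p=5)
        m = SpeakerLDA(ridge=0.0).fit(X, y)

        # independent oracle: eig of inv(Sw) @ Sb with the same normalization
        g = 3
        means = np.vstack([X[y == k].mean(axis=0) for k in range(g)])
        sw = sum(
            (X[y == k] - means[k]).T @ (X[y == k] - means[k]) for k in range(g)
        ) / (len(y) - g)
        counts = np.bincount(y)
        dm = means - X.mean(axis=0)
        sb = (dm * counts[:, None]).T @ dm / (g - 1)
        evals, evecs = np.linalg.eig(np.linalg.inv(sw) @ sb)
        order = np.argsort(evals.real)[::-1][: g - 1]
        V = evecs[:, order].real
        for j in range(V.shape[1]):
            V[:, j] /= np.sqrt(V[:, j] @ sw @ V[:, j])
            if V[np.argmax(np.abs(V[:, j])), j] < 0:
                V[:, j] = -V[:, j]
        assert np.max(np.abs(m.scalings_ - V)) < 1e-8
        assert np.max(np.abs(X @ m.scalings_ - X @ V)) < 1e-8

    def test_informative_feature_has_largest_loading(self):
        rng = np.random.default_rng(5)
        n = 40
        X = rng.normal(size=(2 * n, 6))
        y = np.repeat([0, 1], n)
        X[y == 1, 0] += 5.0  # only feature 0 separates the two speakers
        m = SpeakerLDA().fit(
            pd.DataFrame(X, columns=["f0_mean", "a", "b", "c", "d", "e"]), y
        )
        assert np.argmax(np.abs(m.loadings_[:, 0])) == 0

    def test_rescaling_leaves_loadings_and_predictions_unchanged(self):
        rng = np.random.default_rng(6)
        X, y = gaussian_corpus(rng, n_groups=4, n_per=12, p=5)
        m1 = SpeakerLDA().fit(X, y)
        scale = np.array([1e-3, 1.0, 10.0, 1e3, 5.0])  # e.g. Hz -> kHz
        m2 = SpeakerLDA().fit(X * scale, y)
        assert np.max(np.abs(m1.loadings_ - m2.loadings_)) < 1e-6
        assert np.array_equal(m1.predict(X), m2.predict(X * scale))

    def test_requires_two_groups_and_replication(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            SpeakerLDA().fit(X, np.zeros(10))
        with pytest.raises(ValueError):
            SpeakerLDA().fit(X, np.array([0] * 9 + [1]))

    def test_nan_rows_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            SpeakerLDA().fit(X, np.repeat([0, 1], 5))


class TestClassificationSuccess:
    def test_zero_within_variance_perfect(self):
        X = np.repeat(np.eye(3), 5, axis=0) + 0.0
        y = np.repeat(np.arange(3), 5)
        X += np.random.default_rng(0).normal(scale=1e-6, size=X.shape)
        assert classification_success(X, y, mode="resubstitution") == 100.0
        assert classification_success(X, y, mode="loo") == 100.0

    def test_permuted_labels_fall_to_chance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15 * 20, 6))
        y = np.repeat(np.arange(15), 20)  # labels independent of X
        acc = classification_success(X, y, mode="loo")
        assert abs(acc - 100.0 / 15) <= 5.0

    def test_resubstitution_not_below_loo_on_average(self):
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(20):
            X, y = gaussian_corpus(rng, n_groups=4, n_per=8, p=5, sep=1.0)
            diffs.append(
                classification_success(X, y, mode="resubstitution")
                - classification_success(X, y, mode="loo")
            )
        assert np.mean(diffs) >= 0

    def test_unknown_mode(self):
        X, y = gaussian_corpus(np.random.default_rng(0))
        with pytest.raises(ValueError, match="mode"):
            classification_success(X, y, mode="bootstrap")


class TestSelectMarkers:
    def make_model(self, loadings, names, threshold=1.3):
        m = SpeakerLDA(selection_threshold=threshold)
        m.loadings_ = np.asarray(loadings, float)
        m.feature_names_in_ = list(names)
        return m

    def test_hand_built_loadings_rule_applied_exactly(self):
        m = self.make_model([[2.0], [-1.5], [0.4]], ["a", "b", "c"])
        assert select_markers(m) == ["a", "b"]

    def test_threshold_is_strict(self):
        m = self.make_model([[1.3], [1.3000001]], ["x", "y"])
        assert select_markers(m) == ["y"]

    def test_all_below_threshold_warns_empty(self):
        m = self.make_model([[0.2], [-1.0]], ["x", "y"])
        with pytest.warns(UserWarning):
            assert select_markers(m) == []

    def test_any_function_counts(self):
        m = self.make_model([[0.1, 1.8], [1.0, 0.2]], ["x", "y"])
        assert select_markers(m) == ["x"]


class TestAcousticDistance:
    def test_formula_and_symmetry(self):
        owner = {"f0_mean": 180.0, "ppj": 0.02}
        control = {"f0_mean": 220.0, "ppj": 0.05}
        d = acoustic_distance(owner, control, ["f0_mean", "ppj"])
        assert d["f0_mean"] == pytest.approx(40.0)
        assert d == acoustic_distance(control, owner, ["f0_mean", "ppj"])

    def test_identity_and_translation_invariance(self):
        owner = {"f0_mean": 180.0}
        assert acoustic_distance(owner, owner, ["f0_mean"])["f0_mean"] == 0.0
        shifted = (
            acoustic_distance({"f0_mean": 180 + 37}, {"f0_mean": 220 + 37}, ["f0_mean"])
        )
        assert shifted["f0_mean"] == pytest.approx(40.0)

    def test_distance_table_zscores_and_flags(self):
        sv = pd.DataFrame(
            {
                "speaker_id": ["owner", "c1", "c2", "c3"],
                "f0_mean": [180.0, 200.0, 150.0, np.nan],
            }
        )
        trials = pd.DataFrame({"control_speaker_id": ["c1", "c2", "c3", "c1"]})
        out = distance_table(sv, trials, markers=["f0_mean"])
        assert out["dist_f0_mean"].tolist()[:2] == [20.0, 30.0]
        assert out["distance_missing"].tolist() == [False, False, True, False]
        z = out["dist_f0_mean_z"].dropna()
        assert abs(z.mean()) < 1e-12
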