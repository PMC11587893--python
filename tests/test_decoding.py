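"""Window grid, sensor selection, vectorization, pseudo-trials, SVM CV."""

import numpy as np
import pytest
from sklearn.svm import SVC

from conftest import make_epochs
from facedecode.decoding import (
    WindowSpec,
    _cv_from_folds,
    _linear_svm_predict,
    average_triplets,
    binary_svm_cv,
    category_pairs,
    intertrial_synchrony,
    make_windows,
    select_channels,
    static_decoding,
    time_resolved_decoding,
    vectorize,
)
from facedecode.synthetic import (
    SimulationConfig,
    StimulusDesign,
    build_layout,
    make_design,
    simulate_subject,
)


class TestWindows:
    def test_default_grid_has_11_windows_ending_at_500(self):
        spec = WindowSpec.overlapping()
        wins = make_windows(spec)
        assert len(wins) == 11
        assert wins[0] == (0.0, 80.0)
        assert wins[-1] == (420.0, 500.0)
        starts = [w[0] for w in wins]
        assert np.allclose(np.diff(starts), 42.0)

    def test_80ms_window_at_600hz_has_49_samples(self):
        assert WindowSpec.overlapping().n_samples(600.0) == 49

    def test_full_span_gives_single_window(self):
        spec = WindowSpec(0.0, 500.0, 500.0, step_ms=123.0)
        assert make_windows(spec) == [(0.0, 500.0)]

    def test_non_tiling_step_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            WindowSpec(0.0, 500.0, 80.0, step_ms=40.0)

    def test_category_pair_counts(self):
        assert len(category_pairs(list("ABCDEFGH"))) == 28
        assert category_pairs(["A", "B"]) == [("A", "B")]


class TestSynchrony:
    def test_identical_trials_score_one(self, small_layout):
        rng = np.random.default_rng(0)
        trial = rng.standard_normal((small_layout.n_channels, 421))
        ep = make_epochs(np.repeat(trial[None], 6, axis=0), ["AD"] * 6, small_layout)
        scores = intertrial_synchrony(ep)
        assert np.allclose(scores, 1.0)

    def test_white_noise_scores_near_zero(self, small_layout):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, small_layout.n_channels, 421))
        ep = make_epochs(x, ["AD"] * 60, small_layout)
        scores = intertrial_synchrony(ep)
        assert np.abs(scores).max() < 0.05

    def test_matches_bruteforce_pairwise_correlation(self, small_layout):
        rng = np.random.default_rng(2)
        n, C = 5, small_layout.n_channels
        x = rng.standard_normal((n, C, 421))
        ep = make_epochs(x, ["AD"] * n, small_layout)
        window = (0.0, 500.0)
        scores = intertrial_synchrony(ep, window)
        sl = ep.window_slice(*window)
        for c in range(C):
            corrs = [
                np.corrcoef(x[i, c, sl], x[j, c, sl])[0, 1]
                for i in range(n)
                for j in range(i + 1, n)
            ]
            assert scores[c] == pytest.approx(np.mean(corrs), abs=1e-12)

    def test_zero_variance_trial_counts_as_zero_correlation(self, small_layout):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, small_layout.n_channels, 421))
        x[2, 0, :] = 5.0  # flat trace on channel 0
        ep = make_epochs(x, ["AD"] * 3, small_layout)
        scores = intertrial_synchrony(ep)
        sl = ep.window_slice(0.0, 500.0)
        r01 = np.corrcoef(x[0, 0, sl], x[1, 0, sl])[0, 1]
        assert scores[0] == pytest.approx((r01 + 0.0 + 0.0) / 3.0, abs=1e-12)

    def test_fewer_than_two_trials_rejected(self, small_layout):
        ep = make_epochs(
            np.zeros((1, small_layout.n_channels, 421)), ["AD"], small_layout
        )
        with pytest.raises(ValueError):
            intertrial_synchrony(ep)


class TestSelectChannels:
    def test_all_channels_is_identity(self):
        scores = np.array([0.3, 0.1, 0.5])
        assert list(select_channels(scores, 3)) == [0, 1, 2]

    def test_single_best_channel(self):
        scores = np.zeros(10)
        scores[7] = 1.0
        assert list(select_channels(scores, 1)) == [7]

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(100)
        got = set(select_channels(scores, 50).tolist())
        want = set(np.argsort(-scores)[:50].tolist())
        assert got == want

    def test_ties_broken_by_layout_order(self):
        scores = np.array([0.5, 0.5, 0.5, 0.1])
        assert list(select_channels(scores, 2)) == [0, 1]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_channels(np.zeros(3), 4)


class TestVectorize:
    def test_meg_and_eeg_feature_dimensions(self):
        lay = build_layout()  # 204 gradiometers + 32 EEG
        rng = np.random.default_rng(5)
        ep = make_epochs(rng.standard_normal((3, lay.n_channels, 421)), ["AD"] * 3, lay)
        X = vectorize(ep, (0.0, 80.0), lay.grad_indices[:50])
        assert X.shape == (3, 2450)  # 49 samples x 50 MEG channels
        X = vectorize(ep, (0.0, 80.0), lay.eeg_indices)
        assert X.shape == (3, 1568)  # 49 samples x 32 EEG channels

    def test_channel_major_ordering(self, small_layout):
        n_ch = small_layout.n_channels
        data = np.zeros((1, n_ch, 421))
        for c in range(n_ch):
            data[0, c] = 1000.0 * c + np.arange(421)
        ep = make_epochs(data, ["AD"], small_layout)
        X = vectorize(ep, (0.0, 5.0), [2, 5])  # 4 samples each
        sl = ep.window_slice(0.0, 5.0)
        expect = np.concatenate([data[0, 2, sl], data[0, 5, sl]])
        assert np.array_equal(X[0], expect)

    def test_single_channel_single_sample(self, small_layout):
        data = np.zeros((1, small_layout.n_channels, 421))
        data[0, 3, 120] = 42.0
        ep = make_epochs(data, ["AD"], small_layout)
        X = vectorize(ep, (0.0, 0.0), [3])
        assert X.shape == (1, 1) and X[0, 0] == 42.0

    def test_empty_channels_rejected(self, small_layout):
        ep = make_epochs(
            np.zeros((2, small_layout.n_channels, 421)), ["AD"] * 2, small_layout
        )
        with pytest.raises(ValueError):
            vectorize(ep, (0.0, 80.0), [])


class TestTriplets:
    def test_three_identical_trials_collapse(self):
        x = np.tile(np.arange(6.0), (3, 1))
        out = average_triplets(x, seed=0)
        assert out.shape == (1, 6)
        assert np.allclose(out[0], np.arange(6.0))

    @pytest.mark.parametrize("n,expected", [(88, 29), (176, 58), (9, 3), (11, 3)])
    def test_pseudo_trial_counts(self, n, expected):
        out = average_triplets(np.zeros((n, 4)), seed=1)
        assert out.shape[0] == expected

    def test_pseudo_trial_variance_is_one_third(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((3000, 8))
        out = average_triplets(x, seed=2)
        assert out.var() == pytest.approx(1.0 / 3.0, rel=0.1)

    def test_triplets_are_disjoint(self):
        x = np.arange(30.0)[:, None]
        out = average_triplets(x, seed=3)
        # disjoint triplets of distinct values: sums recover a partition
        assert len(out) == 10
        assert np.isclose(out.sum() * 3, x.sum())

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            average_triplets(np.zeros((2, 4)), seed=0)


class TestSvmCv:
    def test_far_separated_classes_reach_perfect_accuracy(self):
        rng = np.random.default_rng(7)
        X = np.r_[rng.standard_normal((25, 6)) - 10, rng.standard_normal((25, 6)) + 10]
        y = np.array(["a"] * 25 + ["b"] * 25)
        for seed in (0, 1, 2):
            acc, folds = binary_svm_cv(X, y, seed=seed)
            assert acc == 1.0
            assert acc == np.mean(folds)

    def test_exchangeable_null_near_chance(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 12))
        y = np.array(["a", "b"] * 100)
        acc, _ = binary_svm_cv(X, y, seed=3)
        # 99% binomial band around 0.5 for n = 200
        assert abs(acc - 0.5) < 2.576 * np.sqrt(0.25 / 200)

    def test_hand_built_instance_matches_margin_separator(self):
        # Eight points, two features, fixed 2-fold split.  Each training fold
        # holds two duplicated class clusters, so after per-fold
        # standardization the clusters sit exactly at -1 and +1 and the
        # max-margin separator (unit weight, zero slack at C=1) passes through
        # the training mean; predictions on the held-out fold follow by hand.
        y = np.array(["A", "A", "B", "B", "A", "A", "B", "B"])
        folds = [
            (np.array([4, 5, 6, 7]), np.array([0, 1, 2, 3])),
            (np.array([0, 1, 2, 3]), np.array([4, 5, 6, 7])),
        ]

        # Far-shifted second fold: its boundary (x = 7) misclassifies the
        # first fold's B cluster at x = 3, and vice versa -> 0.5 per fold.
        X = np.array(
            [[-2.0, 0.0], [-2.0, 0.0], [3.0, 0.0], [3.0, 0.0],   # fold 0
             [4.0, 5.0], [4.0, 5.0], [10.0, 5.0], [10.0, 5.0]]   # fold 1
        )
        acc, fold_accs = _cv_from_folds(X, y, folds)
        assert fold_accs == [0.5, 0.5]
        assert acc == 0.5

        # Aligned folds: boundaries x = 0.5 and x = 2 classify every held-out
        # point correctly -> 1.0.
        X2 = np.array(
            [[-2.0, 0.0], [-2.0, 0.0], [3.0, 0.0], [3.0, 0.0],
             [-1.0, 5.0], [-1.0, 5.0], [5.0, 5.0], [5.0, 5.0]]
        )
        acc2, fold_accs2 = _cv_from_folds(X2, y, folds)
        assert fold_accs2 == [1.0, 1.0]
        assert acc2 == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 5))
        y = np.array(["a", "b"] * 30)
        assert binary_svm_cv(X, y, seed=5) == binary_svm_cv(X, y, seed=5)

    def test_class_counts_validated(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError):
            binary_svm_cv(X, np.array(["a"] * 4 + ["b"] * 2), k_folds=5)
        with pytest.raises(ValueError):
            binary_svm_cv(X, np.array(["a"] * 6), k_folds=2)

    @pytest.mark.parametrize("tol", [1e-3, 1e-2])
    def test_fast_path_matches_svc(self, tol):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n, d = int(rng.integers(12, 60)), int(rng.integers(2, 40))
            X = rng.standard_normal((n, d))
            y = np.array(["x", "y"])[rng.integers(0, 2, n)]
            if len(np.unique(y)) < 2:
                continue
            X[y == "y"] += 0.4 * rng.standard_normal(d)
            Xt = rng.standard_normal((10, d))
            ref = SVC(kernel="linear", C=1.0, tol=tol).fit(X, y).predict(Xt)
            assert (ref == _linear_svm_predict(X, y, Xt, 1.0, tol)).all()


@pytest.fixture(scope="module")
def four_cat_epochs():
    lay = build_layout(6, 0, ["left-occipital", "right-occipital"], (2, 20))
    design = make_design(
        StimulusDesign(categories=("AD", "HD", "OB", "S"), trials_per_category_per_set=10)
    )
    cfg = SimulationConfig(sampling_rate=300.0, category_amplitude=1.5)
    return simulate_subject(cfg, design, lay, seed=21)


class TestDrivers:
    def test_time_resolved_grid_shape(self, four_cat_epochs):
        spec = WindowSpec(0.0, 500.0, 100.0, 100.0)
        res = time_resolved_decoding(four_cat_epochs, spec, k_channels=4, seed=1)
        assert len(res) == 6 * 5  # 6 pairs x 5 windows
        for r in res:
            assert r.n_features == 4 * spec.n_samples(300.0)
            assert r.accuracy == pytest.approx(np.mean(r.fold_accuracies))
            assert len(r.selected_channels) == 4
        # selection is shared across all pairs and windows
        assert len({tuple(r.selected_channels) for r in res}) == 1

    def test_two_categories_give_single_pair(self, small_layout, two_cat_design):
        cfg = SimulationConfig(pair_effects={("AD", "HD"): 4.0})
        ep = simulate_subject(cfg, two_cat_design, small_layout, seed=2)
        res = time_resolved_decoding(
            ep, WindowSpec(0.0, 500.0, 250.0, 250.0), k_channels=4, seed=0
        )
        assert {r.pair for r in res} == {("AD", "HD")}

    def test_time_resolved_deterministic(self, four_cat_epochs):
        spec = WindowSpec(0.0, 500.0, 250.0, 250.0)
        a = time_resolved_decoding(four_cat_epochs, spec, k_channels=4, seed=3)
        b = time_resolved_decoding(four_cat_epochs, spec, k_channels=4, seed=3)
        assert [(r.pair, r.window, r.accuracy) for r in a] == [
            (r.pair, r.window, r.accuracy) for r in b
        ]

    def test_static_feature_count_and_pseudo_trials(self, four_cat_epochs):
        res = static_decoding(four_cat_epochs, k_channels=4, n_folds=2, seed=4)
        # 0-500 ms at 300 Hz inclusive = 151 samples
        assert all(r.n_features == 4 * 151 for r in res)
        assert all(r.window == "static" for r in res)
        assert len(res) == 6
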