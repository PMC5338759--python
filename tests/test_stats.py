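"""F statistics, FDR, effect-size accumulation and the RLS classifier."""

import numpy as np
import pytest
from scipy import stats as sps

from prpkit import stats, synthetic
from prpkit.types import EpochSet


def brute_force_bh(pvals, q):
    """Step-up definition evaluated literally (independent oracle)."""
    p = np.asarray(pvals)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_max = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_max]] = True
    return mask


class TestBhFdr:
    def test_hand_example(self):
        mask = stats.bh_fdr(np.array([0.01, 0.02, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, False]

    def test_all_ones_none_rejected(self):
        assert not stats.bh_fdr(np.ones(10), q=0.05).any()

    def test_all_zeros_all_rejected(self):
        assert stats.bh_fdr(np.zeros(10), q=0.05).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_fdr(np.array([0.5, 1.5]), q=0.05)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            q = rng.uniform(0.01, 0.2)
            np.testing.assert_array_equal(stats.bh_fdr(p, q), brute_force_bh(p, q))


class TestFOneWay:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((40, 7))
        groups = np.array(["a", "b", "c", "d"] * 10)
        f, p, dfb, dfw, _ = stats.f_oneway_lags(values, groups)
        for t in range(7):
            ref = sps.f_oneway(*[values[groups == g, t] for g in "abcd"])
            assert abs(f[t] - ref.statistic) < 1e-10
            assert abs(p[t] - ref.pvalue) < 1e-10

    def test_exact_separation_flagged_infinite(self):
        values = np.array([[0.0], [0.0], [10.0], [10.0]])
        groups = np.array(["a", "a", "b", "b"])
        f, p, _, _, exact = stats.f_oneway_lags(values, groups)
        assert np.isinf(f[0]) and exact[0] and p[0] == 0.0

    def test_null_mean_f_near_one(self):
        rng = np.random.default_rng(2)
        fs = []
        for _ in range(200):
            v = rng.standard_normal((24, 1))
            g = np.array(["a", "b", "c", "d"] * 6)
            f, *_ = stats.f_oneway_lags(v, g)
            fs.append(f[0])
        # E[F] = dfw / (dfw - 2) = 20/18 for df (3, 20)
        assert abs(np.mean(fs) - 20 / 18) < 0.15

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            stats.f_oneway_lags(np.zeros((3, 2)), np.array(["a", "a", "b"]))
        with pytest.raises(ValueError):
            stats.f_oneway_lags(np.zeros((4, 2)), np.array(["a"] * 4))


class TestMannerFSeries:
    def test_identical_inputs_identical_output_for_both_sources(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((20, 5))
        g = np.array(["a", "b"] * 10)
        lags = np.arange(5.0)
        neural = stats.manner_f_series(v, g, lags, source="response")
        acoustic = stats.manner_f_series(v, g, lags, source="stimulus")
        np.testing.assert_array_equal(neural.f, acoustic.f)
        np.testing.assert_array_equal(neural.mask, acoustic.mask)

    def test_null_significant_fraction_controlled(self):
        rng = np.random.default_rng(4)
        sig = total = 0
        for _ in range(200):
            v = rng.standard_normal((40, 30))
            g = np.array(["a", "b", "c", "d"] * 10)
            fs = stats.manner_f_series(v, g, np.arange(30.0), q=0.05)
            sig += fs.mask.sum()
            total += fs.mask.size
        assert sig / total <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)


class TestPerElectrodeMaps:
    def _epochs_with_discriminative_electrodes(self, good=(0, 1, 2)):
        rng = np.random.default_rng(5)
        n, n_e, n_l = 160, 6, 50
        lags = np.arange(n_l) * 4.0
        labels = ["P", "F", "N", "V"] * (n // 4)
        vals = 0.5 * rng.standard_normal((n, n_e, n_l))
        bump = np.exp(-0.5 * ((lags - 120.0) / 20.0) ** 2)
        amp = {"P": 1.5, "F": 0.5, "N": -0.5, "V": -1.5}
        for i, lab in enumerate(labels):
            for e in good:
                vals[i, e] += amp[lab] * bump
        return EpochSet(vals, lags, labels, ["S1"] * n, [0] * n, np.arange(n, dtype=float))

    def test_discriminative_electrodes_rank_highest(self):
        epochs = self._epochs_with_discriminative_electrodes()
        part = stats.MannerPartition(
            {"P": "plosive", "F": "fricative", "N": "nasal", "V": "vowel"}
        )
        out, names = stats.per_electrode_f_maps(
            epochs, part, {"R2": (100.0, 140.0)}
        )
        top3 = set(np.argsort(out[:, 0])[-3:])
        assert top3 == {0, 1, 2}

    def test_single_window_spanning_all_lags_equals_mean_f(self):
        epochs = self._epochs_with_discriminative_electrodes()
        part = stats.MannerPartition(
            {"P": "plosive", "F": "fricative", "N": "nasal", "V": "vowel"}
        )
        out, _ = stats.per_electrode_f_maps(epochs, part, {"all": (0.0, 196.0)})
        f, *_ = stats.f_oneway_lags(epochs.epochs[:, 0, :], part.groups_for(epochs.labels))
        assert out[0, 0] == pytest.approx(np.mean(f))


class TestEffectSizeAccumulation:
    def _subjects(self, n=3):
        out = []
        for s in range(n):
            rng = np.random.default_rng(100 + s)
            n_tok, n_l = 120, 30
            lags = np.arange(n_l) * 4.0
            labels = ["P", "F", "N", "V"] * (n_tok // 4)
            bump = np.exp(-0.5 * ((lags - 60.0) / 15.0) ** 2)
            amp = {"P": 1.0, "F": 0.4, "N": -0.4, "V": -1.0}
            vals = rng.standard_normal((n_tok, 2, n_l))
            for i, lab in enumerate(labels):
                vals[i, 0] += amp[lab] * bump
            out.append(
                EpochSet(vals, lags, labels, ["S1"] * n_tok, [0] * n_tok,
                         np.linspace(0, 300, n_tok))
            )
        return out

    def test_full_grid_cell_matches_direct_analysis(self):
        subs = self._subjects(2)
        part = stats.MannerPartition(
            {"P": "plosive", "F": "fricative", "N": "nasal", "V": "vowel"}
        )
        grid = stats.effect_size_accumulation(
            subs, part, electrode=0, n_subjects_grid=[2], duration_grid_s=[1000.0],
            n_repeats=1, seed=0,
        )
        vals = np.concatenate([s.epochs[:, 0, :] for s in subs])
        grps = np.concatenate([part.groups_for(s.labels) for s in subs])
        f, *_ = stats.f_oneway_lags(vals, grps)
        assert grid[0, 0] == pytest.approx(np.max(f))

    def test_monotone_in_expectation_and_finite_at_minimum(self):
        subs = self._subjects(3)
        part = stats.MannerPartition(
            {"P": "plosive", "F": "fricative", "N": "nasal", "V": "vowel"}
        )
        grid = stats.effect_size_accumulation(
            subs, part, electrode=0, n_subjects_grid=[1, 3],
            duration_grid_s=[80.0, 1000.0], n_repeats=4, seed=1,
        )
        assert np.isfinite(grid).all()
        assert grid[1, 1] > grid[0, 0]


def make_separable_epochs(seed=0, n_per=60, noise=0.25):
    """Balanced manner classes built from the forward-model kernels."""
    rng = np.random.default_rng(seed)
    inv = synthetic.default_inventory()
    kernels = synthetic.default_kernels(6)
    prpk = synthetic.kernel_prps(kernels, inv, 0, fs=250.0, n_electrodes=6,
                                 window_ms=(0.0, 500.0))
    classes = ["plosive", "fricative", "nasal", "vowel"]
    protos = {
        m: np.mean(
            [prpk.values[i] for i, c in enumerate(prpk.categories) if inv.manner(c) == m],
            axis=0,
        )
        for m in classes
    }
    x, y = [], []
    for m in classes:
        for _ in range(n_per):
            x.append(protos[m] + noise * rng.standard_normal(protos[m].shape))
            y.append(m)
    x, y = np.array(x), np.array(y)
    epochs = EpochSet(x, prpk.lags_ms, list(y), ["S1"] * len(y), [0] * len(y),
                      np.arange(len(y), dtype=float))
    return epochs, y


class TestRlsClassifier:
    def test_separable_classes_classified_accurately(self):
        epochs, y = make_separable_epochs()
        _, cm = stats.rls_classifier(epochs, y, holdout=0.10, seed=0)
        assert cm.accuracy > 0.9
        assert cm.counts.sum(axis=1).sum() == len(y) * 0.10

    def test_shuffled_labels_at_chance(self):
        epochs, y = make_separable_epochs()
        rng = np.random.default_rng(1)
        _, cm = stats.rls_classifier(epochs, rng.permutation(y), holdout=0.10, seed=0)
        n_test = int(len(y) * 0.10)
        ci = 2 * np.sqrt(0.25 * 0.75 / n_test)
        assert abs(cm.accuracy - 0.25) < 2 * ci

    def test_duplicating_epochs_with_doubled_ridge_gives_same_predictions(self):
        epochs, y = make_separable_epochs(n_per=30)
        m1, _ = stats.rls_classifier(epochs, y, holdout=0.5, seed=0, alphas=[10.0])
        dup = EpochSet(
            np.concatenate([epochs.epochs, epochs.epochs]),
            epochs.lags_ms, epochs.labels * 2, epochs.speakers * 2,
            epochs.utterances * 2, np.concatenate([epochs.onsets, epochs.onsets]),
        )
        # normal equations: duplicating the data doubles X'X and X'y, so the
        # fit is unchanged when lambda is doubled too
        x = epochs.epochs.reshape(len(epochs), -1)
        from sklearn.linear_model import Ridge

        r1 = Ridge(alpha=5.0).fit(x, (y == "vowel") * 2.0 - 1)
        x2 = np.concatenate([x, x])
        y2 = np.concatenate([(y == "vowel") * 2.0 - 1] * 2)
        r2 = Ridge(alpha=10.0).fit(x2, y2)
        np.testing.assert_allclose(r1.coef_, r2.coef_, atol=1e-8)

    def test_missing_class_rejected(self):
        epochs, y = make_separable_epochs(n_per=10)
        with pytest.raises(ValueError):
            stats.rls_classifier(epochs, ["vowel"] * len(y), holdout=0.1, seed=0)


class TestConfusionCorrelation:
    def test_identical_matrices_correlate_perfectly(self):
        cm = stats.ConfusionMatrix(
            np.array([[8, 1, 1, 0], [1, 7, 1, 1], [0, 2, 8, 0], [1, 0, 1, 8]]),
            ["plosive", "fricative", "nasal", "vowel"],
        )
        r, p = stats.confusion_correlation(cm, cm)
        assert r == pytest.approx(1.0)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(6)
        a = stats.ConfusionMatrix(rng.integers(1, 20, (4, 4)).astype(float), list("abcd"))
        b = stats.ConfusionMatrix(rng.integers(1, 20, (4, 4)).astype(float), list("abcd"))
        r, _ = stats.confusion_correlation(a, b)
        x = a.row_normalized().ravel()
        y = b.row_normalized().ravel()
        xc, yc = x - x.mean(), y - y.mean()
        expect = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert abs(r - expect) < 1e-12

    def test_constant_matrix_rejected(self):
        cm = stats.ConfusionMatrix(np.ones((4, 4)), list("abcd"))
        with pytest.raises(ValueError):
            stats.confusion_correlation(cm, cm)
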